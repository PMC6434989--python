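"""Partial-effect prediction and removal (remef-style).

Given the fitted per-sample fixed-effect estimates, the predicted
contribution of any subset of coefficients can be subtracted from the
single-trial data, yielding waveforms cleaned of, e.g., the widespread
word-position drift so that the predictability effect can be inspected in
isolation.  Random-intercept contributions are retained in the cleaned
data (only fixed terms are removed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet, TimeWindow, check_alignment
from .design import Design
from .fit import TermStatMap


@dataclass(frozen=True)
class PartialEffectSelection:
    """Which fitted coefficients to remove from the data.

    The intercept is never removed implicitly: it must be named in
    ``terms`` explicitly.  ``keep_random=True`` (the only supported mode)
    leaves random-intercept contributions in the cleaned data; per-level
    random-effect removal is out of scope.
    """

    terms: tuple[str, ...]
    keep_random: bool = True

    def __post_init__(self) -> None:
        if not self.keep_random:
            raise NotImplementedError(
                "removal of random-intercept contributions is not supported"
            )


def _selected_indices(selection: PartialEffectSelection, stats: TermStatMap) -> list[int]:
    return [stats.term_index(t) for t in selection.terms]


def predict_partial(
    design: Design, stats: TermStatMap, selection: PartialEffectSelection
) -> np.ndarray:
    """Predicted contribution tensor of the selected fixed terms.

    For each electrode × time sample the contribution is the selected
    design columns times their per-sample estimates; the result has shape
    (trials, electrodes, times) and is linear in the selection: the
    prediction of a union of terms is the sum of the single-term
    predictions, exactly.
    """
    idx = _selected_indices(selection, stats)
    if not idx:
        return np.zeros((design.n_obs, len(stats.electrodes), stats.times.size))
    X_sel = design.X[:, idx]                    # (n, k)
    B_sel = stats.estimates[idx]                # (k, E, T)
    return np.einsum("nk,ket->net", X_sel, B_sel)


def remove_partial(
    epochs: EpochSet,
    design: Design,
    stats: TermStatMap,
    selection: PartialEffectSelection,
) -> EpochSet:
    """Subtract the selected terms' predicted contribution from the data."""
    if design.n_obs != epochs.n_trials:
        raise ValueError("design rows do not match epoch trials")
    out = epochs.copy()
    out.amplitudes = out.amplitudes - predict_partial(design, stats, selection)
    return out


def condition_average(
    epochs: EpochSet,
    table: pd.DataFrame,
    grouping: list[str],
    roi: list[str] | None = None,
    window: TimeWindow | None = None,
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Grand-average waveforms per condition with across-subject SE.

    Trials are first averaged within subject × condition cell; the grand
    mean and its standard error are then taken across subjects, so the
    dispersion band reflects between-subject variability.  Returns a long
    table with columns ``group columns..., time_ms, mean, se, n_subjects``.
    Empty groups are simply absent; a warning is emitted when a grouping
    level never co-occurs with a subject.
    """
    check_alignment(epochs, table)
    amps = epochs.amplitudes
    if roi is not None:
        amps = amps[:, epochs.electrode_indices(roi), :]
    amps = amps.mean(axis=1)  # (trials, times) after ROI average
    times = epochs.times
    if window is not None:
        mask = epochs.time_mask(window)
        amps, times = amps[:, mask], times[mask]

    df = table[[subject_col] + grouping].copy().reset_index(drop=True)
    per_subject = (
        pd.concat([df, pd.DataFrame(amps)], axis=1)
        .groupby([subject_col] + grouping, observed=True)
        .mean()
    )
    rows = []
    for key, sub in per_subject.groupby(level=grouping, observed=True):
        vals = sub.to_numpy()  # (subjects, times)
        n_sub = vals.shape[0]
        mean = vals.mean(axis=0)
        se = (
            vals.std(axis=0, ddof=1) / np.sqrt(n_sub)
            if n_sub > 1
            else np.zeros_like(mean)
        )
        key = key if isinstance(key, tuple) else (key,)
        for j, t_ms in enumerate(times):
            rows.append(
                dict(zip(grouping, key))
                | {"time_ms": t_ms, "mean": mean[j], "se": se[j], "n_subjects": n_sub}
            )
    return pd.DataFrame(rows)
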