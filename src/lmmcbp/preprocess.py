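"""Epoch- and word-level preprocessing filters.

Baseline correction over the pre-stimulus window, amplitude-based epoch
rejection, content-word filtering, smoothed logit transform of cloze
proportions, and rank-based tercile categorisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CONTENT_POS_TAGS,
    EpochSet,
    TimeWindow,
    check_alignment,
)

DEFAULT_BASELINE = TimeWindow(-100.0, 0.0)


def baseline_correct(epochs: EpochSet, window: TimeWindow = DEFAULT_BASELINE) -> EpochSet:
    """Subtract the per-trial per-electrode mean over ``window``.

    The window is half-open [start, end), so with the default −100..0 ms
    window the onset sample belongs to the response, not the baseline.
    After correction the mean over the window is zero (to ~1e-9) for every
    trial–electrode trace.
    """
    mask = epochs.time_mask(window)
    out = epochs.copy()
    means = out.amplitudes[:, :, mask].mean(axis=2, keepdims=True)
    out.amplitudes = out.amplitudes - means
    return out


@dataclass
class RejectionLog:
    """Per-trial bookkeeping from amplitude-based epoch rejection."""

    bad_electrode_counts: np.ndarray  # per input trial
    rejected_trial_ids: np.ndarray
    threshold_uv: float
    max_bad_electrodes: int

    @property
    def n_rejected(self) -> int:
        return self.rejected_trial_ids.size


def reject_epochs(
    epochs: EpochSet,
    table: pd.DataFrame,
    amp_threshold_uv: float = 80.0,
    max_bad_electrodes: int = 5,
) -> tuple[EpochSet, pd.DataFrame, RejectionLog]:
    """Drop trials where more than ``max_bad_electrodes`` electrodes clip.

    An electrode is "bad" within a trial when any sample reaches
    ``amp_threshold_uv`` in absolute value; a trial is rejected iff
    strictly more than ``max_bad_electrodes`` electrodes are bad.
    """
    if amp_threshold_uv <= 0:
        raise ValueError("amp_threshold_uv must be positive")
    check_alignment(epochs, table)
    bad = np.abs(epochs.amplitudes) >= amp_threshold_uv  # (tr, el, ti)
    counts = bad.any(axis=2).sum(axis=1)
    keep = counts <= max_bad_electrodes
    log = RejectionLog(
        bad_electrode_counts=counts,
        rejected_trial_ids=epochs.trial_ids[~keep],
        threshold_uv=amp_threshold_uv,
        max_bad_electrodes=max_bad_electrodes,
    )
    if not keep.any():
        import warnings

        warnings.warn("all epochs rejected", stacklevel=2)
    idx = np.flatnonzero(keep)
    return epochs.select_trials(idx), table.iloc[idx].reset_index(drop=True), log


def filter_words(table: pd.DataFrame, min_length: int = 3) -> pd.DataFrame:
    """Keep content words (adjective/verb/noun) of at least ``min_length``
    characters that are not sentence-initial."""
    if "pos_tag" not in table.columns or table["pos_tag"].isna().any():
        bad = (
            table.index[table["pos_tag"].isna()].tolist()
            if "pos_tag" in table.columns
            else "all"
        )
        raise ValueError(f"pos_tag missing for rows: {bad}")
    keep = (
        table["pos_tag"].isin(CONTENT_POS_TAGS)
        & (table["word_length"] >= min_length)
        & (table["position"] > 1)
    )
    return table.loc[keep].reset_index(drop=True)


def apply_word_filter(
    epochs: EpochSet, table: pd.DataFrame, min_length: int = 3
) -> tuple[EpochSet, pd.DataFrame]:
    """``filter_words`` applied jointly to the table and the epoch tensor."""
    check_alignment(epochs, table)
    filtered = filter_words(table, min_length=min_length)
    pos = pd.Index(table["trial_id"]).get_indexer(filtered["trial_id"])
    return epochs.select_trials(pos), filtered


def logit_predictability(raw, n_respondents: int):
    """Smoothed logit of a cloze proportion.

    Raw proportions of 0 and 1 occur whenever all (or none) of the cloze
    respondents produce the word, so the plain logit diverges.  The count
    is smoothed as ``p' = (raw·n + 0.5) / (n + 1)`` (add-half on the
    success count) before the logit, which keeps the transform strictly
    increasing and finite on [0, 1].
    """
    raw_arr = np.asarray(raw, dtype=float)
    if np.any((raw_arr < 0) | (raw_arr > 1)):
        raise ValueError("raw predictability must lie in [0, 1]")
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    p = (raw_arr * n_respondents + 0.5) / (n_respondents + 1.0)
    out = np.log(p / (1.0 - p))
    return float(out) if np.isscalar(raw) or raw_arr.ndim == 0 else out


def tercile_split(values) -> np.ndarray:
    """Rank-based split into ``low`` / ``mid`` / ``high`` terciles.

    Ties are broken by stable input order, so the grouping depends only on
    ranks and is invariant under strictly monotone transforms of the input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError("need a 1-d vector with at least 3 values")
    if np.unique(arr).size < 3:
        raise ValueError("tercile split is degenerate: fewer than 3 distinct values")
    order = np.argsort(arr, kind="stable")
    n = arr.size
    # rank cutpoints at the 1/3 and 2/3 empirical quantiles
    c1, c2 = int(np.ceil(n / 3.0)), int(np.ceil(2.0 * n / 3.0))
    labels = np.empty(n, dtype=object)
    labels[order[:c1]] = "low"
    labels[order[c1:c2]] = "mid"
    labels[order[c2:]] = "high"
    return labels
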