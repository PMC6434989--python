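"""Core containers for epoched single-trial ERP data.

An :class:`EpochSet` holds the trials × electrodes × time amplitude tensor
(microvolts, time in milliseconds relative to word onset); the covariate
table is a plain :class:`pandas.DataFrame` with one row per trial, kept in
one-to-one correspondence with the epoch tensor through ``trial_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Columns the mixed-model pipeline expects in a covariate table.
COVARIATE_COLUMNS = (
    "trial_id",
    "subject_id",
    "word_form",
    "sentence_id",
    "sentence_type",
    "position",
    "predictability_raw",
    "predictability",
    "frequency",
    "pos_tag",
    "word_length",
)

SENTENCE_TYPES = ("memory_encoded", "common")
CONTENT_POS_TAGS = frozenset({"adjective", "verb", "noun"})


class InvalidWindowError(ValueError):
    """A baseline/analysis window falls outside the epoch time span."""


@dataclass(frozen=True)
class TimeWindow:
    """Half-open window [start_ms, end_ms) on the epoch time axis.

    Used both for the pre-stimulus baseline (default −100..0 ms) and for
    analysis windows such as the N400 interval (300..450 ms), optionally
    restricted to a region-of-interest electrode subset.
    """

    start_ms: float
    end_ms: float
    roi_electrodes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise InvalidWindowError(
                f"window start {self.start_ms} must be < end {self.end_ms}"
            )

    def mask(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask of time samples inside [start, end)."""
        return (times >= self.start_ms) & (times < self.end_ms)


BaselineWindow = TimeWindow
AnalysisWindow = TimeWindow


@dataclass
class EpochSet:
    """Trials × electrodes × time amplitude tensor with axis metadata.

    Parameters
    ----------
    amplitudes
        Array of shape ``(n_trials, n_electrodes, n_times)`` in microvolts.
    times
        Time axis in ms relative to stimulus onset; strictly increasing,
        uniformly spaced.
    electrodes
        Ordered electrode labels.
    trial_ids
        Unique trial keys matching covariate-table rows.
    """

    amplitudes: np.ndarray
    times: np.ndarray
    electrodes: list[str]
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.electrodes = [str(e) for e in self.electrodes]
        if self.amplitudes.ndim != 3:
            raise ValueError("amplitudes must be (trials, electrodes, times)")
        n_tr, n_el, n_ti = self.amplitudes.shape
        # zero trials can legitimately result from epoch rejection; the
        # electrode and time axes must always be nonempty
        if min(n_el, n_ti) == 0:
            raise ValueError("electrode and time axes must be nonempty")
        if n_el != len(self.electrodes):
            raise ValueError("electrode axis length mismatch")
        if n_ti != self.times.size:
            raise ValueError("time axis length mismatch")
        dt = np.diff(self.times)
        if self.times.size > 1:
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time axis must be uniformly spaced")
        if self.trial_ids is None:
            self.trial_ids = np.arange(n_tr)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.trial_ids.size != n_tr:
            raise ValueError("trial_ids length mismatch")
        if len(set(self.trial_ids.tolist())) != n_tr:
            raise ValueError("trial_ids must be unique")

    # -- basic geometry -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def n_times(self) -> int:
        return self.amplitudes.shape[2]

    @property
    def n_samples(self) -> int:
        """Number of electrode × time samples, i.e. per-sample model fits."""
        return self.n_electrodes * self.n_times

    def copy(self) -> "EpochSet":
        return replace(
            self,
            amplitudes=self.amplitudes.copy(),
            times=self.times.copy(),
            electrodes=list(self.electrodes),
            trial_ids=self.trial_ids.copy(),
        )

    def electrode_indices(self, labels) -> np.ndarray:
        lookup = {e: i for i, e in enumerate(self.electrodes)}
        missing = [l for l in labels if l not in lookup]
        if missing:
            raise KeyError(f"electrodes not in epoch set: {missing}")
        return np.array([lookup[l] for l in labels], dtype=int)

    def time_mask(self, window: TimeWindow) -> np.ndarray:
        if window.start_ms < self.times[0] or window.end_ms > self.times[-1] + (
            self.times[1] - self.times[0] if self.n_times > 1 else 0.0
        ):
            raise InvalidWindowError(
                f"window [{window.start_ms}, {window.end_ms}) outside epoch "
                f"span [{self.times[0]}, {self.times[-1]}]"
            )
        mask = window.mask(self.times)
        if not mask.any():
            raise InvalidWindowError("window contains no time samples")
        return mask

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        """Subset trials by positional index, preserving alignment metadata."""
        return EpochSet(
            amplitudes=self.amplitudes[index],
            times=self.times.copy(),
            electrodes=list(self.electrodes),
            trial_ids=self.trial_ids[index],
        )


def check_alignment(epochs: EpochSet, table: pd.DataFrame) -> None:
    """Assert one-to-one trial correspondence between epochs and covariates."""
    if len(table) != epochs.n_trials:
        raise ValueError(
            f"covariate table has {len(table)} rows but epochs hold "
            f"{epochs.n_trials} trials"
        )
    if "trial_id" in table.columns:
        if not np.array_equal(np.asarray(table["trial_id"]), epochs.trial_ids):
            raise ValueError("trial_id order differs between table and epochs")


def validate_covariates(table: pd.DataFrame, required=COVARIATE_COLUMNS) -> None:
    """Check presence and basic sanity of modeled covariate columns."""
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    if table["subject_id"].isna().any() or table["word_form"].isna().any():
        raise ValueError("subject_id and word_form must be non-null")
    levels = set(table["sentence_type"].unique())
    if not levels <= set(SENTENCE_TYPES):
        raise ValueError(
            f"sentence_type levels {levels} not within {set(SENTENCE_TYPES)}"
        )
    pred = np.asarray(table["predictability"], dtype=float)
    if not np.all(np.isfinite(pred)):
        raise ValueError("predictability (logit) must be finite for all trials")
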