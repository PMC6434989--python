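"""Mass-univariate grid fitting: one mixed model per electrode × time sample."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .containers import EpochSet, check_alignment
from .design import Design, ModelSpec, build_design
from .reml import CrossedREML

DEFAULT_T_THRESHOLD = 2.0

_STATUS_CODES = {"converged": 0, "singular": 1, "fallback": 2}
_STATUS_NAMES = {v: k for k, v in _STATUS_CODES.items()}


@dataclass
class TermStatMap:
    """Per-coefficient estimate/SE/t matrices over the electrode × time grid.

    ``estimates``, ``se`` and ``t`` have shape (n_terms, n_electrodes,
    n_times); ``status`` codes per sample: 0 converged, 1 singular
    (a variance ratio on the zero boundary), 2 OLS fallback.
    """

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    t: np.ndarray
    status: np.ndarray
    electrodes: list[str]
    times: np.ndarray
    sigma2: np.ndarray = field(default=None)  # type: ignore[assignment]
    variance_components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_terms = len(self.terms)
        grid = (len(self.electrodes), self.times.size)
        for name in ("estimates", "se", "t"):
            arr = getattr(self, name)
            if arr.shape != (n_terms,) + grid:
                raise ValueError(f"{name} shape {arr.shape} != {(n_terms,) + grid}")
        if self.status.shape != grid:
            raise ValueError("status grid shape mismatch")

    def term_index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise KeyError(f"unknown term {term!r}; have {self.terms}") from None

    def t_map(self, term: str) -> np.ndarray:
        """Electrode × time t-value matrix for one coefficient."""
        return self.t[self.term_index(term)]

    def significance_mask(self, term: str, t_th: float = DEFAULT_T_THRESHOLD) -> np.ndarray:
        """|t| > t_th mask; the per-sample significance criterion."""
        return np.abs(self.t_map(term)) > t_th

    def status_name(self, code: int) -> str:
        return _STATUS_NAMES[code]


def _fit_chunk(solver: CrossedREML, Y: np.ndarray) -> list:
    return solver.fit_many(Y)


def fit_grid(
    epochs: EpochSet,
    table: pd.DataFrame,
    spec: ModelSpec,
    n_jobs: int = 1,
    design: Design | None = None,
) -> TermStatMap:
    """Fit the mixed model independently at every electrode × time sample.

    The fixed/random design is shared by all samples, so its
    cross-products are formed once; per-sample work is the variance-ratio
    optimisation only.  Results are a deterministic function of the data
    and design: every sample's optimisation is self-contained, so the grid
    is bitwise identical for any ``n_jobs`` or execution order.  A sample
    whose optimiser diverges is retried as ordinary least squares and
    flagged in ``status`` — it never aborts the grid.
    """
    check_alignment(epochs, table)
    if design is None:
        design = build_design(table, spec)
    solver = CrossedREML(design)
    n_el, n_ti = epochs.n_electrodes, epochs.n_times
    Y = epochs.amplitudes.reshape(epochs.n_trials, n_el * n_ti)

    # fixed chunk boundaries (independent of n_jobs): floating-point results
    # of blocked BLAS kernels depend on operand width, so identical chunking
    # is what guarantees bitwise-identical output for any worker count
    n_samples = Y.shape[1]
    chunk = 64
    starts = range(0, n_samples, chunk)
    if n_jobs == 1:
        chunks = [_fit_chunk(solver, Y[:, a:a + chunk]) for a in starts]
    else:
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_fit_chunk)(solver, Y[:, a:a + chunk]) for a in starts
        )
    fits = [f for c in chunks for f in c]

    p = len(design.coef_names)
    est = np.empty((p, n_samples))
    se = np.empty((p, n_samples))
    t = np.empty((p, n_samples))
    status = np.empty(n_samples, dtype=np.int8)
    sigma2 = np.empty(n_samples)
    vc = {name: np.empty(n_samples) for name in design.random_names}
    for j, f in enumerate(fits):
        est[:, j], se[:, j], t[:, j] = f.estimates, f.se, f.t
        status[j] = _STATUS_CODES[f.status]
        sigma2[j] = f.sigma2
        for name in design.random_names:
            vc[name][j] = f.variance_components[name]
    grid = (n_el, n_ti)
    return TermStatMap(
        terms=list(design.coef_names),
        estimates=est.reshape((p,) + grid),
        se=se.reshape((p,) + grid),
        t=t.reshape((p,) + grid),
        status=status.reshape(grid),
        electrodes=list(epochs.electrodes),
        times=epochs.times.copy(),
        sigma2=sigma2.reshape(grid),
        variance_components={k: v.reshape(grid) for k, v in vc.items()},
    )
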