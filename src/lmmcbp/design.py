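"""Model specification and fixed/random design construction.

The model dialect mirrors the usual mixed-model formula syntax, e.g.::

    amplitude ~ frequency + predictability:sentence_type
              + position:sentence_type + (1|subject_id) + (1|word_form)

Fixed terms are either continuous main effects or ``continuous:categorical``
interactions.  Interactions use *nested-slope coding*: one slope column per
level of the categorical factor, equal to the (optionally mean-centered)
continuous covariate where the factor takes that level and zero elsewhere.
This yields directly interpretable per-level slopes (e.g. a predictability
slope within common sentences and another within memory-encoded ones)
rather than difference contrasts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ModelSpec:
    """Fixed terms, random-intercept factors, and centering policy.

    ``fixed_terms`` entries are covariate names or ``"cont:cat"`` pairs;
    ``random_factors`` are categorical column names receiving independent
    random intercepts; continuous covariates are mean-centered when
    ``center`` is true (the default), which makes the intercept estimate
    the grand-average ERP at each sample.
    """

    fixed_terms: tuple[str, ...] = (
        "frequency",
        "predictability:sentence_type",
        "position:sentence_type",
    )
    random_factors: tuple[str, ...] = ("subject_id", "word_form")
    center: bool = True
    include_intercept: bool = True

    @classmethod
    def from_formula(cls, formula: str, center: bool = True) -> "ModelSpec":
        """Parse ``lhs ~ term + term + (1|factor) + ...`` into a spec."""
        rhs = formula.split("~", 1)[1] if "~" in formula else formula
        fixed: list[str] = []
        random: list[str] = []
        for term in (t.strip() for t in rhs.split("+")):
            if not term or term == "1":
                continue
            m = re.fullmatch(r"\(\s*1\s*\|\s*([\w.]+)\s*\)", term)
            if m:
                random.append(m.group(1))
            else:
                if not re.fullmatch(r"[\w.]+(:[\w.]+)?", term):
                    raise ValueError(f"cannot parse model term {term!r}")
                fixed.append(term)
        if not fixed and not random:
            raise ValueError("formula defines no terms")
        return cls(fixed_terms=tuple(fixed), random_factors=tuple(random), center=center)

    def to_formula(self, lhs: str = "amplitude") -> str:
        parts = list(self.fixed_terms) + [f"(1|{f})" for f in self.random_factors]
        return f"{lhs} ~ " + " + ".join(parts)


@dataclass
class Design:
    """Materialised design: fixed matrix, random-factor indices, labels."""

    X: np.ndarray                       # (n, p) fixed design
    coef_names: list[str]               # length p
    random_indices: list[np.ndarray]    # per factor: (n,) integer level codes
    random_levels: list[list]           # per factor: ordered level values
    random_names: list[str]
    spec: ModelSpec = field(default=None)  # type: ignore[assignment]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


def _centered(col: np.ndarray, center: bool) -> np.ndarray:
    col = np.asarray(col, dtype=float)
    return col - col.mean() if center else col


def build_design(table: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the fixed design matrix and random-factor index vectors.

    A ``cont:cat`` term expands to one column per level of ``cat`` whose
    support partitions the trials; continuous covariates are mean-centered
    over all trials before the split when ``spec.center`` is set.  Raises
    on a rank-deficient fixed design, naming the collinear columns.
    """
    n = len(table)
    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.include_intercept:
        cols.append(np.ones(n))
        names.append("Intercept")
    for term in spec.fixed_terms:
        if ":" in term:
            cont, cat = term.split(":", 1)
            _require(table, cont), _require(table, cat)
            x = _centered(table[cont].to_numpy(), spec.center)
            levels = _ordered_levels(table[cat])
            for lev in levels:
                mask = (table[cat] == lev).to_numpy()
                cols.append(np.where(mask, x, 0.0))
                names.append(f"{cont}:{lev}")
        else:
            _require(table, term)
            cols.append(_centered(table[term].to_numpy(), spec.center))
            names.append(term)
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    if X.shape[1]:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            guilty = _collinear_columns(X, names)
            raise ValueError(
                f"fixed design is rank deficient (rank {rank} < {X.shape[1]}); "
                f"collinear columns: {guilty}"
            )
    rand_idx, rand_levels = [], []
    for fac in spec.random_factors:
        _require(table, fac)
        codes, levels = pd.factorize(table[fac], sort=True)
        if (codes < 0).any():
            raise ValueError(f"random factor {fac} has missing values")
        rand_idx.append(codes.astype(np.int64))
        rand_levels.append(list(levels))
    return Design(
        X=X,
        coef_names=names,
        random_indices=rand_idx,
        random_levels=rand_levels,
        random_names=list(spec.random_factors),
        spec=spec,
    )


def _require(table: pd.DataFrame, col: str) -> None:
    if col not in table.columns:
        raise KeyError(f"covariate {col!r} not in table")


def _ordered_levels(series: pd.Series) -> list:
    return sorted(series.unique().tolist())


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Identify columns implicated in the rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    dropped = piv[np.sum(diag > tol):]
    return [names[i] for i in sorted(dropped)]
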