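"""Classical baseline analyses: windowed ROI statistics, rank tests,
pooled regression with subject dummies, and the two-condition t-test CBP.

These are the standard single-value-per-trial and paired-t approaches the
mass-univariate mixed-model pipeline is designed to improve on; they are
included both as sanity baselines and because each answers a narrower
question cheaply (e.g. "is there an N400-window predictability effect at
the centro-parietal ROI?").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .adjacency import AdjacencyGraph
from .clusters import find_clusters, max_cluster_mass
from .containers import EpochSet, TimeWindow, check_alignment
from .permutation import TermClusters
from .preprocess import tercile_split


def window_roi_average(
    epochs: EpochSet, roi: list[str], window: TimeWindow
) -> np.ndarray:
    """Per-trial mean amplitude over the ROI × window submatrix (μV)."""
    if not roi:
        raise ValueError("ROI must name at least one electrode")
    e_idx = epochs.electrode_indices(roi)
    t_mask = epochs.time_mask(window)
    return epochs.amplitudes[:, e_idx][:, :, t_mask].mean(axis=(1, 2))


def subject_condition_scores(
    scores: np.ndarray,
    table: pd.DataFrame,
    condition: str,
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Subject × condition mean of per-trial window scores (wide layout)."""
    df = pd.DataFrame(
        {
            subject_col: table[subject_col].to_numpy(),
            condition: table[condition].to_numpy(),
            "score": scores,
        }
    )
    return df.pivot_table(index=subject_col, columns=condition, values="score")


def rank_tests(cell_means: pd.DataFrame, design: str) -> dict:
    """Nonparametric tests on per-subject condition means.

    ``design="paired_two_level"`` runs the Wilcoxon signed-rank test on
    the paired difference between the two columns (exact null when there
    are no ties and n is small, normal approximation otherwise — scipy's
    default policy); ``design="k_level"`` runs the Kruskal-Wallis test
    across the columns with the usual tie correction.
    """
    if cell_means.isna().any().any():
        missing = cell_means.index[cell_means.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete condition cells for subjects: {missing}")
    if len(cell_means) < 2:
        raise ValueError("need at least 2 subjects")
    if design == "paired_two_level":
        if cell_means.shape[1] != 2:
            raise ValueError("paired design needs exactly two condition levels")
        a, b = (cell_means.iloc[:, j].to_numpy() for j in (0, 1))
        res = sps.wilcoxon(a, b)
        return {"test": "wilcoxon_signed_rank", "statistic": float(res.statistic), "p": float(res.pvalue)}
    if design == "k_level":
        groups = [cell_means[c].to_numpy() for c in cell_means.columns]
        if np.ptp(np.concatenate(groups)) == 0:
            return {"test": "kruskal_wallis", "statistic": 0.0, "p": 1.0}
        res = sps.kruskal(*groups)
        return {"test": "kruskal_wallis", "statistic": float(res.statistic), "p": float(res.pvalue)}
    raise ValueError(f"unknown design {design!r}")


def regression_n400(
    scores: np.ndarray,
    table: pd.DataFrame,
    predictor: str = "predictability",
    subject_col: str = "subject_id",
) -> dict:
    """Pooled OLS of window scores on a continuous predictor with subject
    indicator variables.

    Reports the predictor slope, its p-value, and the *partial* R² — the
    share of variance the predictor explains beyond the subject dummies
    (SSE_reduced − SSE_full) / SSE_reduced.
    """
    import statsmodels.api as sm

    y = np.asarray(scores, dtype=float)
    x = np.asarray(table[predictor], dtype=float)
    subj = pd.get_dummies(
        table[subject_col].astype(str), prefix="subj", drop_first=True, dtype=float
    )
    if subj.shape[1] + 2 >= len(y):
        raise ValueError("too few trials for subject dummies")
    X_full = sm.add_constant(pd.concat([pd.Series(x, name=predictor), subj], axis=1))
    if np.linalg.matrix_rank(X_full.to_numpy()) < X_full.shape[1]:
        raise ValueError("rank-deficient regression design")
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, sm.add_constant(subj)).fit()
    partial_r2 = float((reduced.ssr - full.ssr) / reduced.ssr)
    return {
        "beta": float(full.params[predictor]),
        "se": float(full.bse[predictor]),
        "p": float(full.pvalues[predictor]),
        "partial_r2": partial_r2,
        "n_trials": int(len(y)),
    }


def high_low_labels(values: np.ndarray) -> np.ndarray:
    """Two-level reduction of a continuous covariate: outer terciles.

    Returns an object array with ``"high"``/``"low"`` for the outer
    terciles and ``None`` for the middle one (to be dropped).
    """
    terc = tercile_split(values)
    return np.where(terc == "mid", None, terc)


@dataclass
class PairedCBPResult:
    """Two-condition cluster-based permutation outcome."""

    clusters: TermClusters
    t_map: np.ndarray
    null_max_abs: np.ndarray
    n_subjects: int
    condition_levels: tuple
    provenance: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05):
        return self.clusters.significant(alpha)


def cbp_ttest(
    epochs: EpochSet,
    table: pd.DataFrame,
    condition: str,
    adjacency: AdjacencyGraph,
    t_th: float = 2.0,
    n_permutations: int = 500,
    seed: int = 0,
    min_cluster_size: int = 2,
    subject_col: str = "subject_id",
) -> PairedCBPResult:
    """Paired two-condition CBP with a per-sample t-test across subjects.

    Subject-level condition-mean difference maps are tested with a
    one-sample t at every electrode × time sample; clusters of
    supra-threshold samples are compared against a sign-flip null (random
    within-subject exchange of the two condition labels, identical flips
    at every sample).  P-values follow the plain-proportion rule with the
    1/N_P floor.
    """
    import warnings

    check_alignment(epochs, table)
    labels = table[condition].to_numpy()
    levels = sorted({l for l in labels if l is not None and not pd.isna(l)})
    if len(levels) != 2:
        raise ValueError(f"condition {condition!r} must have exactly 2 levels, got {levels}")
    subjects = sorted(table[subject_col].unique().tolist())
    diffs = []
    for s in subjects:
        m = (table[subject_col] == s).to_numpy()
        means = []
        for lev in levels:
            sel = m & (labels == lev)
            if not sel.any():
                means = None
                break
            means.append(epochs.amplitudes[sel].mean(axis=0))
        if means is None:
            warnings.warn(f"subject {s!r} lacks a condition level; excluded", stacklevel=2)
            continue
        diffs.append(means[1] - means[0])  # second level minus first
    if len(diffs) < 2:
        raise ValueError("fewer than 2 subjects with both condition levels")
    D = np.stack(diffs)  # (subjects, E, T)
    n = D.shape[0]

    def paired_t(d: np.ndarray) -> np.ndarray:
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)

    t_obs = paired_t(D)
    observed = find_clusters(
        t_obs, adjacency, epochs.electrodes, t_th=t_th, min_cluster_size=min_cluster_size
    )
    rng_root = int(seed) % (2**31)
    null_abs = np.empty(n_permutations)
    for p in range(n_permutations):
        rng = np.random.default_rng([rng_root, p + 1])
        flips = rng.choice([-1.0, 1.0], size=n)
        t_p = paired_t(D * flips[:, None, None])
        perm_clusters = find_clusters(
            t_p, adjacency, epochs.electrodes, t_th=t_th, min_cluster_size=min_cluster_size
        )
        null_abs[p] = max_cluster_mass(perm_clusters)[2]

    tc = TermClusters(term=condition, clusters=observed)
    for c in observed:
        count = int(np.sum(null_abs > abs(c.mass)))
        if count > 0:
            tc.p_values.append(count / n_permutations)
            tc.is_bound.append(False)
        else:
            tc.p_values.append(1.0 / n_permutations)
            tc.is_bound.append(True)
    return PairedCBPResult(
        clusters=tc,
        t_map=t_obs,
        null_max_abs=null_abs,
        n_subjects=n,
        condition_levels=tuple(levels),
        provenance={
            "seed": seed,
            "n_permutations": n_permutations,
            "t_th": t_th,
            "condition": condition,
            "contrast": f"{levels[1]} - {levels[0]}",
        },
    )
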