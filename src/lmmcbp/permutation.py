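"""Structure-preserving permutation inference for the mass-univariate LMM.

The null hypothesis is exchangeability of whole covariate rows across
trials: each permutation reassigns every epoch to another trial's complete
covariate vector, so the correlation structure among covariates is never
broken.  Because the model carries crossed random intercepts (subjects and
word forms), free shuffling would also destroy the random-factor structure
and be anti-conservative; the two structured schemes therefore permute
only within levels of one factor at a time, mirroring the classic F1/F2
(by-subject / by-item) analysis pair.

For every permutation the whole electrode × time grid is refitted with the
*same* trial shuffling at every sample, the per-term t-maps are
re-clustered, and the mass of the largest cluster (MaxSum) is collected.
An observed cluster's p-value is the fraction of permutation MaxSum values
exceeding its mass; with zero exceedances the p-value is reported as the
strict bound 1/N_P.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .adjacency import AdjacencyGraph
from .clusters import Cluster, find_clusters, max_cluster_mass
from .containers import EpochSet, check_alignment
from .design import ModelSpec, build_design
from .fit import DEFAULT_T_THRESHOLD, TermStatMap, fit_grid

SCHEME_KINDS = ("free", "within_subject", "within_word")
_SCHEME_COLUMNS = {"within_subject": "subject_id", "within_word": "word_form"}


@dataclass(frozen=True)
class PermutationScheme:
    """Permutation family: how trials may be exchanged, and how many draws."""

    kind: str = "within_subject"
    n_permutations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"kind must be one of {SCHEME_KINDS}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def make_permutation(
    table: pd.DataFrame, scheme: PermutationScheme, iteration: int
) -> np.ndarray:
    """Deterministic trial-index bijection for one permutation draw.

    ``mapping[i] = j`` assigns trial i's epoch the complete covariate row
    of trial j.  Under a within-factor scheme every trial maps to a trial
    of the same factor level, so that factor's column is exactly preserved;
    a level with a single trial stays fixed (the only valid permutation).
    The mapping depends only on ``(scheme.seed, iteration)``.
    """
    n = len(table)
    rng = np.random.default_rng([int(scheme.seed) % (2**31), int(iteration)])
    if scheme.kind == "free":
        return rng.permutation(n)
    col = _SCHEME_COLUMNS[scheme.kind]
    if col not in table.columns:
        raise KeyError(f"scheme {scheme.kind} needs column {col!r}")
    mapping = np.arange(n)
    codes, levels = pd.factorize(table[col], sort=True)
    for lev in range(len(levels)):
        idx = np.flatnonzero(codes == lev)
        if idx.size > 1:
            mapping[idx] = idx[rng.permutation(idx.size)]
    return mapping


def effective_shuffling_fraction(
    table: pd.DataFrame, scheme: PermutationScheme, n_draws: int = 100
) -> float:
    """Mean fraction of trials that move under the scheme.

    Diagnostic for near-degenerate schemes: when most word forms occur
    once, the within-word scheme leaves most trials fixed (or swaps them
    between subjects reading the same word), which makes its null very
    conservative.
    """
    n = len(table)
    moved = 0
    for it in range(n_draws):
        mapping = make_permutation(table, scheme, it)
        moved += int(np.sum(mapping != np.arange(n)))
    return moved / (n * n_draws)


@dataclass
class NullDistribution:
    """Per-term MaxSum null: positive-side, negative-side and absolute maxima."""

    terms: list[str]
    max_pos: np.ndarray   # (n_terms, N_P)
    max_neg: np.ndarray
    max_abs: np.ndarray
    scheme: PermutationScheme
    t_th: float
    mappings: np.ndarray  # (N_P, n_trials) permutation index matrix

    @property
    def n_permutations(self) -> int:
        return self.max_abs.shape[1]

    def for_term(self, term: str, side: str = "abs") -> np.ndarray:
        i = self.terms.index(term)
        return {"pos": self.max_pos, "neg": self.max_neg, "abs": self.max_abs}[side][i]


@dataclass
class TermClusters:
    """Observed clusters of one model term with permutation p-values."""

    term: str
    clusters: list[Cluster]
    p_values: list[float] = field(default_factory=list)
    is_bound: list[bool] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [
            c
            for c, p, b in zip(self.clusters, self.p_values, self.is_bound)
            if (p < alpha if not b else p <= alpha)
        ]


@dataclass
class ClusterTestResult:
    """Full outcome of one CBP run under one permutation scheme."""

    terms: dict[str, TermClusters]
    null: NullDistribution
    scheme: PermutationScheme
    t_th: float
    alpha: float
    provenance: dict = field(default_factory=dict)

    def significant(self, term: str, alpha: float | None = None):
        return self.terms[term].significant(alpha if alpha is not None else self.alpha)

    def cluster_table(self, times: np.ndarray, electrodes: list[str]) -> pd.DataFrame:
        """Flat per-cluster report: term, sign, mass, p, span, extent."""
        rows = []
        for term, tc in self.terms.items():
            for c, p, b in zip(tc.clusters, tc.p_values, tc.is_bound):
                t0, t1 = c.time_span()
                rows.append(
                    {
                        "term": term,
                        "sign": "+" if c.sign > 0 else "-",
                        "mass": c.mass,
                        "size": c.size,
                        "p_value": p,
                        "p_is_bound": b,
                        "time_start_ms": times[t0],
                        "time_end_ms": times[t1],
                        "n_electrodes": len(c.electrode_set()),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "term",
                "sign",
                "mass",
                "size",
                "p_value",
                "p_is_bound",
                "time_start_ms",
                "time_end_ms",
                "n_electrodes",
            ],
        )


def _permutation_maxima(
    epochs: EpochSet,
    table: pd.DataFrame,
    spec: ModelSpec,
    adjacency: AdjacencyGraph,
    t_th: float,
    min_cluster_size: int,
    mapping: np.ndarray,
    terms: list[str],
) -> np.ndarray:
    """(n_terms, 3) MaxSum pos/neg/abs for one permuted assignment."""
    permuted = table.iloc[mapping].reset_index(drop=True)
    permuted["trial_id"] = np.asarray(table["trial_id"])
    stats = fit_grid(epochs, permuted, spec)
    out = np.zeros((len(terms), 3))
    for i, term in enumerate(terms):
        clusters = find_clusters(
            stats.t_map(term),
            adjacency,
            epochs.electrodes,
            t_th=t_th,
            min_cluster_size=min_cluster_size,
        )
        out[i] = max_cluster_mass(clusters)
    return out


def null_distribution(
    epochs: EpochSet,
    table: pd.DataFrame,
    spec: ModelSpec,
    adjacency: AdjacencyGraph,
    scheme: PermutationScheme,
    t_th: float = DEFAULT_T_THRESHOLD,
    min_cluster_size: int = 2,
    terms: list[str] | None = None,
    n_jobs: int = 1,
    progress: bool = False,
) -> NullDistribution:
    """Build the per-term MaxSum null under a permutation scheme.

    All permutation index vectors are precomputed from (seed, iteration)
    and the same shuffling is applied at every electrode × time sample of
    a given permutation; results are independent of ``n_jobs``.
    """
    check_alignment(epochs, table)
    if terms is None:
        terms = build_design(table, spec).coef_names
    mappings = np.stack(
        [make_permutation(table, scheme, it) for it in range(1, scheme.n_permutations + 1)]
    )
    t_start = time.time()

    def job(p):
        res = _permutation_maxima(
            epochs, table, spec, adjacency, t_th, min_cluster_size, mappings[p], terms
        )
        if progress:
            print(
                f"  permutation {p + 1}/{scheme.n_permutations} "
                f"({time.time() - t_start:.1f}s elapsed)",
                flush=True,
            )
        return res

    if n_jobs == 1:
        maxima = [job(p) for p in range(scheme.n_permutations)]
    else:
        maxima = Parallel(n_jobs=n_jobs)(
            delayed(_permutation_maxima)(
                epochs, table, spec, adjacency, t_th, min_cluster_size, mappings[p], terms
            )
            for p in range(scheme.n_permutations)
        )
    arr = np.stack(maxima, axis=-1)  # (n_terms, 3, N_P)
    return NullDistribution(
        terms=list(terms),
        max_pos=arr[:, 0],
        max_neg=arr[:, 1],
        max_abs=arr[:, 2],
        scheme=scheme,
        t_th=t_th,
        mappings=mappings,
    )


def cluster_p_values(
    observed: dict[str, list[Cluster]],
    null: NullDistribution,
    alpha: float = 0.05,
    two_sided: bool = True,
    add_observed: bool = False,
) -> dict[str, TermClusters]:
    """Assign permutation p-values to observed clusters, term by term.

    ``p = #{MaxSum_p > |mass|} / N_P``; when the count is zero the p-value
    is reported as the strict bound ``1/N_P`` with ``is_bound`` set.  With
    ``two_sided`` (default) the null is the per-permutation maximum
    absolute mass over both signs.  ``add_observed`` switches to the
    (N+1)-style convention that counts the observed statistic as one more
    permutation; the default follows the plain-proportion rule.
    """
    out = {}
    n_p = null.n_permutations
    for term, clusters in observed.items():
        if term not in null.terms:
            raise KeyError(f"term {term!r} missing from null distribution {null.terms}")
        tc = TermClusters(term=term, clusters=list(clusters))
        for c in clusters:
            if two_sided:
                ref, stat = null.for_term(term, "abs"), abs(c.mass)
            elif c.sign > 0:
                ref, stat = null.for_term(term, "pos"), c.mass
            else:
                ref, stat = -null.for_term(term, "neg"), -c.mass
            count = int(np.sum(ref > stat))
            if add_observed:
                tc.p_values.append((count + 1) / (n_p + 1))
                tc.is_bound.append(False)
            elif count > 0:
                tc.p_values.append(count / n_p)
                tc.is_bound.append(False)
            else:
                tc.p_values.append(1.0 / n_p)
                tc.is_bound.append(True)  # strict bound: p < 1/N_P
        out[term] = tc
    return out


def run_cbp_scheme(
    epochs: EpochSet,
    table: pd.DataFrame,
    spec: ModelSpec,
    adjacency: AdjacencyGraph,
    scheme: PermutationScheme,
    stats: TermStatMap | None = None,
    t_th: float = DEFAULT_T_THRESHOLD,
    min_cluster_size: int = 2,
    alpha: float = 0.05,
    terms: list[str] | None = None,
    n_jobs: int = 1,
    two_sided: bool = True,
    add_observed: bool = False,
    progress: bool = False,
) -> tuple[ClusterTestResult, TermStatMap]:
    """One complete LMM-CBP pass under a single permutation scheme."""
    if stats is None:
        stats = fit_grid(epochs, table, spec, n_jobs=n_jobs)
    if terms is None:
        terms = [t for t in stats.terms if t != "Intercept"]
    observed = {
        term: find_clusters(
            stats.t_map(term),
            adjacency,
            epochs.electrodes,
            t_th=t_th,
            min_cluster_size=min_cluster_size,
        )
        for term in terms
    }
    null = null_distribution(
        epochs,
        table,
        spec,
        adjacency,
        scheme,
        t_th=t_th,
        min_cluster_size=min_cluster_size,
        terms=terms,
        n_jobs=n_jobs,
        progress=progress,
    )
    term_clusters = cluster_p_values(
        observed, null, alpha=alpha, two_sided=two_sided, add_observed=add_observed
    )
    result = ClusterTestResult(
        terms=term_clusters,
        null=null,
        scheme=scheme,
        t_th=t_th,
        alpha=alpha,
        provenance={
            "seed": scheme.seed,
            "n_permutations": scheme.n_permutations,
            "t_th": t_th,
            "model": spec.to_formula(),
            "effective_shuffling_fraction": effective_shuffling_fraction(
                table, scheme, n_draws=20
            ),
        },
    )
    return result, stats


def run_lmm_cbp(
    epochs: EpochSet,
    table: pd.DataFrame,
    spec: ModelSpec,
    adjacency: AdjacencyGraph,
    n_permutations: int = 500,
    seed: int = 0,
    t_th: float = DEFAULT_T_THRESHOLD,
    min_cluster_size: int = 2,
    alpha: float = 0.05,
    schemes: tuple[str, ...] = ("within_subject", "within_word"),
    n_jobs: int = 1,
    two_sided: bool = True,
    add_observed: bool = False,
    progress: bool = False,
) -> dict:
    """Full LMM-CBP: fit the grid once, then one CBP pass per scheme.

    Returns ``{"stats": TermStatMap, "<scheme>": ClusterTestResult, ...}``
    — the joint report layout: original t-maps plus subject-scheme and
    word-scheme cluster tests.
    """
    check_alignment(epochs, table)
    stats = fit_grid(epochs, table, spec, n_jobs=n_jobs)
    out: dict = {"stats": stats}
    for kind in schemes:
        scheme = PermutationScheme(kind=kind, n_permutations=n_permutations, seed=seed)
        result, _ = run_cbp_scheme(
            epochs,
            table,
            spec,
            adjacency,
            scheme,
            stats=stats,
            t_th=t_th,
            min_cluster_size=min_cluster_size,
            alpha=alpha,
            n_jobs=n_jobs,
            two_sided=two_sided,
            add_observed=add_observed,
            progress=progress,
        )
        out[kind] = result
    return out
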