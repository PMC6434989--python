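"""Profiled REML for linear mixed models with crossed random intercepts.

The model fitted at every electrode × time sample is

    y = X b + Z u + e,   u ~ N(0, s2 * G),   e ~ N(0, s2 * I),

where Z stacks indicator blocks for each random factor (e.g. subject and
word form) and ``G = blockdiag(g_k I)`` holds one variance *ratio* g_k per
factor.  Both the fixed coefficients and the residual variance s2 are
profiled out analytically, leaving a bounded optimisation over the log
variance ratios only.  All heavy algebra runs through the q × q system
``M = G^-1 + Z'Z`` (Woodbury / mixed-model equations), so the cost per
candidate ratio is one Cholesky of M plus triangular solves — independent
of the number of trials once the cross-products are formed.

Because thousands of samples share one design, the cross-products
``X'X, Z'X, Z'Z`` are computed once and ``[X Z]' Y`` for all samples in a
single matrix product; only the per-sample optimisation loops in Python.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .design import Design

#: bounds for log variance ratios; the lower bound acts as the "variance
#: zero" boundary (g = e^-12 ~ 6e-6 is numerically indistinguishable from 0)
LOG_RATIO_BOUNDS = (-12.0, 8.0)
#: initial / final lattice spacing of the pattern search in log-ratio units;
#: a final per-axis quadratic interpolation refines below the lattice step
COARSE_STEP = 2.0
FINAL_STEP = COARSE_STEP / 64.0

CONVERGED, SINGULAR, FALLBACK = "converged", "singular", "fallback"


@dataclass
class SampleFit:
    """Per-coefficient estimates for one electrode × time sample."""

    estimates: np.ndarray
    se: np.ndarray
    t: np.ndarray
    coef_names: list[str]
    sigma2: float                      # residual variance
    variance_components: dict[str, float]
    log_ratios: np.ndarray
    status: str
    reml_criterion: float


class CrossedREML:
    """REML solver bound to one fixed/random design.

    Parameters
    ----------
    design
        Output of :func:`lmmcbp.design.build_design`.

    Notes
    -----
    The criterion is minimised per sample over the log variance ratios by
    a bounded derivative-free pattern search on a successively refined
    lattice (coarse spacing 2.0 down to 1/32 in log-ratio units) followed
    by a per-axis quadratic interpolation through the final three-point
    stencil, which resolves the ratios well below the lattice step.
    Candidate lattice points are shared across
    samples, so each candidate costs one Cholesky of the q × q system
    regardless of how many samples consider it — this is what makes
    refitting the grid hundreds of times for the permutation null
    affordable.  Each sample's optimum depends only on its own response,
    never on which other samples are in the batch, so any chunking or
    parallel schedule gives bitwise-identical results.  A ratio pinned at
    the lower bound is a boundary ("singular") fit: accepted and flagged,
    not an error.  If the linear algebra fails for a sample it falls back
    to ordinary least squares with status ``"fallback"``.
    """

    def __init__(self, design: Design):
        self.design = design
        X = design.X
        n, p = X.shape
        if p >= n:
            raise ValueError(f"fewer observations ({n}) than fixed coefficients ({p})")
        self.n, self.p = n, p
        self.k = len(design.random_indices)
        self.q_per_factor = []
        Z_blocks = []
        for codes, levels in zip(design.random_indices, design.random_levels):
            q_k = len(levels)
            if q_k < 2:
                raise ValueError("each random factor needs >= 2 levels")
            Zk = np.zeros((n, q_k))
            Zk[np.arange(n), codes] = 1.0
            Z_blocks.append(Zk)
            self.q_per_factor.append(q_k)
        self.Z = np.concatenate(Z_blocks, axis=1) if Z_blocks else np.empty((n, 0))
        self.q = self.Z.shape[1]
        # cross-products shared by every sample
        self.XtX = X.T @ X
        self.ZtX = self.Z.T @ X
        self.ZtZ = self.Z.T @ self.Z
        self._ratio_expand = np.repeat(np.arange(self.k), self.q_per_factor)

    # -- criterion ------------------------------------------------------

    def _system(self, theta: np.ndarray):
        """Cholesky of M(g) and the pieces shared across samples."""
        g = np.exp(theta)
        M = self.ZtZ + np.diag(1.0 / g[self._ratio_expand])
        L = cholesky(M, lower=True, check_finite=False)
        U = solve_triangular(L, self.ZtX, lower=True, check_finite=False)  # (q, p)
        A = self.XtX - U.T @ U                                 # X'V*^-1 X
        logdet_vstar = 2.0 * np.log(np.diag(L)).sum() + float(
            np.dot(self.q_per_factor, theta)
        )
        return L, U, A, logdet_vstar

    def _criterion_many(self, theta, Zty, Xty, yty):
        """-2 REML log-likelihood (up to a constant) for every sample.

        ``Zty`` is (q, S), ``Xty`` (p, S), ``yty`` (S,).  Returns the
        criterion vector (S,) or +inf where the linear algebra fails.
        """
        try:
            L, U, A, logdet_vstar = self._system(theta)
            La = cho_factor(A, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.full(yty.shape, np.inf)
        v = solve_triangular(L, Zty, lower=True, check_finite=False)               # (q, S)
        c = Xty - U.T @ v                                      # X'V^-1 y
        d = yty - np.einsum("qs,qs->s", v, v)                  # y'V^-1 y
        beta = cho_solve(La, c, check_finite=False)                                # (p, S)
        rss = d - np.einsum("ps,ps->s", c, beta)
        rss = np.maximum(rss, 1e-300)
        logdet_a = 2.0 * np.log(np.diag(La[0])).sum()
        return (self.n - self.p) * np.log(rss) + logdet_vstar + logdet_a

    def _solve_sample(self, theta, Zty, Xty, yty, active=None):
        """Estimates, SEs and variance components at fixed ratios.

        ``active`` masks the random factors: factors whose ratio sits on
        the zero boundary are dropped from the system entirely, i.e.
        treated as exactly zero variance rather than epsilon variance (so
        a fully-boundary fit reproduces ordinary least squares exactly).
        """
        if active is None:
            active = np.ones(self.k, dtype=bool)
        cols = np.isin(self._ratio_expand, np.flatnonzero(active))
        if cols.any():
            g = np.exp(theta)
            M = self.ZtZ[np.ix_(cols, cols)] + np.diag(
                1.0 / g[self._ratio_expand[cols]]
            )
            L = cholesky(M, lower=True, check_finite=False)
            U = solve_triangular(L, self.ZtX[cols], lower=True, check_finite=False)
            A = self.XtX - U.T @ U
            logdet_vstar = 2.0 * np.log(np.diag(L)).sum() + float(
                np.dot(theta[active], np.asarray(self.q_per_factor)[active])
            )
            v = solve_triangular(L, Zty[cols], lower=True, check_finite=False)
            c = Xty - U.T @ v
            d = float(yty - v @ v)
        else:
            A = self.XtX
            logdet_vstar = 0.0
            c = Xty.copy()
            d = float(yty)
        La = cho_factor(A, lower=True, check_finite=False)
        beta = cho_solve(La, c, check_finite=False)
        rss = max(d - float(c @ beta), 1e-300)
        sigma2 = rss / (self.n - self.p)
        Ainv = cho_solve(La, np.eye(self.p), check_finite=False)
        se = np.sqrt(sigma2 * np.diag(Ainv))
        crit = (self.n - self.p) * np.log(rss) + logdet_vstar + 2.0 * np.log(
            np.diag(La[0])
        ).sum()
        return beta, se, sigma2, crit

    # -- fitting --------------------------------------------------------

    def _ols(self, y: np.ndarray) -> SampleFit:
        X = self.design.X
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(self.n - self.p, 1)
        sigma2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(self.XtX)
        se = np.sqrt(sigma2 * np.diag(XtX_inv))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        return SampleFit(
            estimates=beta,
            se=se,
            t=t,
            coef_names=list(self.design.coef_names),
            sigma2=sigma2,
            variance_components={name: 0.0 for name in self.design.random_names},
            log_ratios=np.full(self.k, LOG_RATIO_BOUNDS[0]),
            status=FALLBACK,
            reml_criterion=np.nan,
        )

    def _search_ratios(self, Zty, Xty, yty) -> np.ndarray:
        """Per-sample optimum of the REML criterion via quantised pattern
        search plus a quadratic polish; returns θ̂ of shape (S, k).

        Candidate points live on the integer lattice ``lo + FINAL_STEP·Z``
        so keys are exact; each unique candidate is evaluated once for all
        samples (one Cholesky, vectorised solves) and cached.  After the
        lattice converges, a per-axis quadratic interpolation through the
        cached three-point stencil refines each sample's optimum below the
        lattice resolution.
        """
        lo, hi = LOG_RATIO_BOUNDS
        S = yty.size
        cache: dict[tuple, np.ndarray] = {}

        def crit(key: tuple) -> np.ndarray:
            if key not in cache:
                theta = lo + FINAL_STEP * np.asarray(key, dtype=float)
                cache[key] = self._criterion_many(theta, Zty, Xty, yty)
            return cache[key]

        n_steps = int(round((hi - lo) / FINAL_STEP))
        coarse = int(round(COARSE_STEP / FINAL_STEP))
        axis = list(range(0, n_steps + 1, coarse))
        grid = [
            tuple(p)
            for p in np.array(np.meshgrid(*([axis] * self.k), indexing="ij"))
            .reshape(self.k, -1)
            .T
        ]
        vals = np.stack([crit(key) for key in grid])       # (L, S)
        current = [grid[i] for i in np.argmin(vals, axis=0)]
        best = vals.min(axis=0)

        h = coarse
        while h >= 1:
            moved = True
            guard = 0
            while moved and guard < 300:
                moved = False
                guard += 1
                # propose +/- h along each axis for every sample
                proposals: dict[tuple, list[int]] = {}
                for s in range(S):
                    for d in range(self.k):
                        for sign in (-h, h):
                            c = list(current[s])
                            c[d] = min(max(c[d] + sign, 0), n_steps)
                            key = tuple(c)
                            if key != current[s]:
                                proposals.setdefault(key, []).append(s)
                for key, samples in proposals.items():
                    v = crit(key)
                    for s in samples:
                        if v[s] < best[s] - 1e-12:
                            best[s] = v[s]
                            current[s] = key
                            moved = True
            h //= 2

        # quadratic polish from the cached unit stencil around each optimum
        theta = lo + FINAL_STEP * np.asarray(current, dtype=float)
        for s in range(S):
            for d in range(self.k):
                c = current[s][d]
                if c == 0 or c == n_steps:
                    continue  # boundary optimum stays on the boundary
                km = tuple(current[s][:d] + (c - 1,) + current[s][d + 1:])
                kp = tuple(current[s][:d] + (c + 1,) + current[s][d + 1:])
                if km not in cache or kp not in cache:
                    continue
                fm, f0, fp = cache[km][s], best[s], cache[kp][s]
                denom = fm - 2.0 * f0 + fp
                if denom > 0:
                    delta = 0.5 * (fm - fp) / denom
                    theta[s, d] += FINAL_STEP * float(np.clip(delta, -0.5, 0.5))
        return theta

    def _finish_sample(self, theta_hat, Zty_col, Xty_col, yty_s) -> SampleFit:
        near_zero = theta_hat <= LOG_RATIO_BOUNDS[0] + FINAL_STEP / 2
        try:
            beta, se, sigma2, crit = self._solve_sample(
                theta_hat, Zty_col, Xty_col, yty_s, active=~near_zero
            )
        except np.linalg.LinAlgError:
            return None  # caller falls back to OLS
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        g = np.exp(theta_hat)
        vc = {
            name: (0.0 if nz else float(gk * sigma2))
            for name, gk, nz in zip(self.design.random_names, g, near_zero)
        }
        return SampleFit(
            estimates=beta,
            se=se,
            t=t,
            coef_names=list(self.design.coef_names),
            sigma2=sigma2,
            variance_components=vc,
            log_ratios=theta_hat,
            status=SINGULAR if near_zero.any() else CONVERGED,
            reml_criterion=crit,
        )

    def fit_many(self, Y: np.ndarray) -> list[SampleFit]:
        """Fit every column of ``Y`` (n_obs × n_samples), independently.

        Candidate variance-ratio evaluations are shared across samples,
        but each sample's optimum depends only on its own response, so
        the result for a sample never changes with batch composition,
        chunking or execution order.
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if self.k == 0:
            return [self._ols(Y[:, j]) for j in range(Y.shape[1])]
        Zty = self.Z.T @ Y
        Xty = self.design.X.T @ Y
        yty = np.einsum("ns,ns->s", Y, Y)
        theta = self._search_ratios(Zty, Xty, yty)
        out = []
        for j in range(Y.shape[1]):
            fit = self._finish_sample(theta[j], Zty[:, j], Xty[:, j], yty[j])
            out.append(fit if fit is not None else self._ols(Y[:, j]))
        return out

    def fit_sample(self, y: np.ndarray) -> SampleFit:
        """Fit one response vector; see class notes for the optimiser."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(f"y must have length {self.n}")
        return self.fit_many(y[:, None])[0]


def fit_lmm_sample(y: np.ndarray, design: Design) -> SampleFit:
    """Convenience wrapper: REML fit of one sample for a built design."""
    return CrossedREML(design).fit_sample(y)
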