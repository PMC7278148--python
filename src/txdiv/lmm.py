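"""Fast Gaussian mixed-model fits used across the pipeline.

Two model families appear over and over here, once per gene, so both are
profiled down to one-dimensional likelihoods:

* one-way random intercept: y_ij = x_i' beta + u_i + e_ij with u_i the
  accession effect and fixed effects constant within accession. Profiling
  beta and sigma2_e leaves a 1-D (RE)ML problem in the variance ratio
  lambda = sigma2_a / sigma2_e.
* GRM model: y = X beta + g + e with g ~ N(0, sigma2_g G). After one
  eigendecomposition of G the covariance is diagonal for every gene, and
  REML again reduces to 1-D optimization in lambda = sigma2_g / sigma2_e.

Boundary estimates (lambda = 0) are handled explicitly; heritabilities are
therefore always in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "OneWayFit",
    "group_stats",
    "fit_one_way",
    "balanced_one_way_reml_many",
    "rlrt_broad",
    "rlrt_null_distribution",
    "GrmEigen",
    "GrmFit",
]

_LOG_LAM_LO, _LOG_LAM_HI = -12.0, 12.0


@dataclass
class OneWayFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_a: float
    sigma2_e: float
    loglik: float
    reml: bool

    @property
    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0


def group_stats(y: np.ndarray, group_idx: np.ndarray, n_groups: int):
    """Per-group size, mean and within-group sum of squares."""
    n = np.bincount(group_idx, minlength=n_groups).astype(float)
    if (n == 0).any():
        raise ValueError("empty group")
    s = np.bincount(group_idx, weights=y, minlength=n_groups)
    ybar = s / n
    ssw = float(np.sum((y - ybar[group_idx]) ** 2))
    return n, ybar, ssw


def _profile_m2ll(log_lam, n, ybar, ssw, X, reml):
    """-2 log likelihood with beta and sigma2_e profiled out, at lambda."""
    lam = np.exp(log_lam) if np.isfinite(log_lam) else 0.0
    w = 1.0 / (lam + 1.0 / n)
    XtWX = (X.T * w) @ X
    beta = np.linalg.solve(XtWX, (X.T * w) @ ybar)
    r = ybar - X @ beta
    Q = ssw + float(np.sum(w * r * r))
    N, p = float(n.sum()), X.shape[1]
    logdetV = float(np.sum(np.log1p(lam * n)))
    if reml:
        df = N - p
        s2 = Q / df
        m2ll = df * (np.log(2 * np.pi * s2) + 1.0) + logdetV
        m2ll += float(np.linalg.slogdet(XtWX)[1])
    else:
        s2 = Q / N
        m2ll = N * (np.log(2 * np.pi * s2) + 1.0) + logdetV
    return m2ll, beta, s2, lam, XtWX


def fit_one_way(
    y: np.ndarray,
    group_idx: np.ndarray,
    X_group: np.ndarray | None = None,
    reml: bool = False,
) -> OneWayFit:
    """Fit the one-way random-intercept model.

    Parameters
    ----------
    y : observation vector
    group_idx : group (accession) index per observation, 0..k-1
    X_group : (k, p) fixed-effect design on groups; default intercept only.
        Fixed effects must be constant within groups.
    reml : REML (for variance components) or ML (for fixed-effect LRTs).
    """
    y = np.asarray(y, dtype=float)
    group_idx = np.asarray(group_idx)
    k = int(group_idx.max()) + 1
    if X_group is None:
        X_group = np.ones((k, 1))
    n, ybar, ssw = group_stats(y, group_idx, k)

    def obj(u):
        return _profile_m2ll(u, n, ybar, ssw, X_group, reml)[0]

    res = optimize.minimize_scalar(
        obj, bounds=(_LOG_LAM_LO, _LOG_LAM_HI), method="bounded",
        options={"xatol": 1e-8},
    )
    best_u = res.x
    # compare against the lambda -> 0 boundary explicitly
    m2_zero = _profile_m2ll(-np.inf, n, ybar, ssw, X_group, reml)[0]
    if m2_zero <= res.fun:
        best_u = -np.inf
    m2ll, beta, s2e, lam, XtWX = _profile_m2ll(best_u, n, ybar, ssw, X_group, reml)
    cov_beta = s2e * np.linalg.inv(XtWX)
    return OneWayFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_a=lam * s2e,
        sigma2_e=s2e,
        loglik=-0.5 * m2ll,
        reml=reml,
    )


def balanced_one_way_reml_many(Y: np.ndarray, group_idx: np.ndarray):
    """Closed-form REML for the intercept-only one-way model, balanced
    designs, vectorized over genes (rows of Y).

    With k groups of r observations the REML solution is sigma2_e = MSW
    and sigma2_e + r*sigma2_a = MSB when MSB >= MSW, else the boundary
    sigma2_a = 0; the restricted LRT against sigma2_a = 0 follows in
    closed form. Returns (sigma2_a, sigma2_e, h2, rlrt) arrays.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    group_idx = np.asarray(group_idx)
    k = int(group_idx.max()) + 1
    sizes = np.bincount(group_idx, minlength=k)
    if not np.all(sizes == sizes[0]):
        raise ValueError("design is not balanced")
    r = int(sizes[0])
    if r < 2:
        raise ValueError("need >= 2 replicates per group")
    N = k * r
    # per-gene group means via one matmul-free pass
    sums = np.zeros((Y.shape[0], k))
    np.add.at(sums.T, group_idx, Y.T)
    means = sums / r
    ssw = np.sum(Y * Y, axis=1) - np.sum(sums * sums, axis=1) / r
    grand = Y.mean(axis=1)
    ssb = r * np.sum((means - grand[:, None]) ** 2, axis=1)
    msw = ssw / (k * (r - 1))
    msb = ssb / (k - 1)
    s2e = msw
    s2a = np.maximum((msb - msw) / r, 0.0)
    h2 = np.where(s2a + s2e > 0, s2a / np.where(s2a + s2e > 0, s2a + s2e, 1.0), 0.0)
    t_hat = np.maximum(1.0, msb / np.maximum(msw, 1e-300))

    def g(t):
        return (N - 1) * np.log(ssw + ssb / t) + (k - 1) * np.log(t)

    rlrt = np.maximum(g(1.0) - g(t_hat), 0.0)
    return s2a, s2e, h2, rlrt


def rlrt_broad(y: np.ndarray, group_idx: np.ndarray) -> tuple[float, OneWayFit]:
    """Restricted LRT of sigma2_a = 0 in the intercept-only one-way model."""
    fit = fit_one_way(y, group_idx, reml=True)
    y = np.asarray(y, dtype=float)
    group_idx = np.asarray(group_idx)
    k = int(group_idx.max()) + 1
    n, ybar, ssw = group_stats(y, group_idx, k)
    m2_null = _profile_m2ll(-np.inf, n, ybar, ssw, np.ones((k, 1)), True)[0]
    stat = max(m2_null - (-2.0 * fit.loglik), 0.0)
    return stat, fit


def rlrt_null_distribution(
    group_sizes: np.ndarray, B: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Simulated null distribution of the broad-sense RLRT for one design.

    The null depends only on the replicate structure (group sizes), so a
    single distribution serves every gene sharing the design. Balanced
    designs use the closed-form REML solution (vectorized over B);
    unbalanced designs fall back to per-draw 1-D fits.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    group_sizes = np.asarray(group_sizes, dtype=int)
    k = len(group_sizes)
    N = int(group_sizes.sum())
    rng = np.random.default_rng(seed)
    if np.all(group_sizes == group_sizes[0]):
        n = int(group_sizes[0])
        ssw = rng.chisquare(k * (n - 1), size=B)
        ssb = rng.chisquare(k - 1, size=B)
        msb, msw = ssb / (k - 1), ssw / (k * (n - 1))
        t_hat = np.maximum(1.0, msb / msw)

        def g(t):
            return (N - 1) * np.log(ssw + ssb / t) + (k - 1) * np.log(t)

        return g(1.0) - g(t_hat)
    stats = np.empty(B)
    group_idx = np.repeat(np.arange(k), group_sizes)
    for b in range(B):
        y = rng.standard_normal(N)
        stats[b], _ = rlrt_broad(y, group_idx)
    return stats


@dataclass
class GrmFit:
    h2: float
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    loglik: float
    lrt: float


class GrmEigen:
    """One spectral decomposition of the GRM, reused for every gene.

    In the rotated basis U'y the covariance sigma2_g*G + sigma2_e*I is
    diagonal, so each per-gene REML fit is a 1-D optimization over
    log lambda in [-10, 10] (Brent), with the lambda = 0 boundary checked.
    """

    def __init__(self, G: np.ndarray, X: np.ndarray | None = None):
        G = np.asarray(G, dtype=float)
        n = G.shape[0]
        vals, vecs = np.linalg.eigh(G)
        self.d = np.maximum(vals, 0.0)
        self.U = vecs
        if X is None:
            X = np.ones((n, 1))
        self.Xr = self.U.T @ X
        self.n, self.p = n, X.shape[1]

    def _m2ll(self, log_lam, yr, reml=True):
        lam = np.exp(log_lam) if np.isfinite(log_lam) else 0.0
        v = lam * self.d + 1.0
        w = 1.0 / v
        XtWX = (self.Xr.T * w) @ self.Xr
        beta = np.linalg.solve(XtWX, (self.Xr.T * w) @ yr)
        r = yr - self.Xr @ beta
        Q = float(np.sum(w * r * r))
        logdetV = float(np.sum(np.log(v)))
        if reml:
            df = self.n - self.p
            s2 = Q / df
            m2 = df * (np.log(2 * np.pi * s2) + 1.0) + logdetV
            m2 += float(np.linalg.slogdet(XtWX)[1])
        else:
            s2 = Q / self.n
            m2 = self.n * (np.log(2 * np.pi * s2) + 1.0) + logdetV
        return m2, beta, s2, lam

    def _m2ll_many(self, log_lam, Yr, reml=True):
        """Profiled -2ll at one lambda, vectorized over genes (rows of Yr).

        Intercept-only fixed effects (p = 1), the case every per-gene scan
        uses.
        """
        lam = np.exp(log_lam) if np.isfinite(log_lam) else 0.0
        v = lam * self.d + 1.0
        w = 1.0 / v
        xr = self.Xr[:, 0]
        xtwx = float(np.sum(w * xr * xr))
        beta = (Yr @ (w * xr)) / xtwx
        Q = (Yr * Yr) @ w - beta * beta * xtwx
        Q = np.maximum(Q, 1e-300)
        logdetV = float(np.sum(np.log(v)))
        if reml:
            df = self.n - 1
            m2 = df * (np.log(2 * np.pi * Q / df) + 1.0) + logdetV + np.log(xtwx)
        else:
            m2 = self.n * (np.log(2 * np.pi * Q / self.n) + 1.0) + logdetV
        return m2

    def fit_many(self, Y: np.ndarray, reml: bool = True, n_grid: int = 81,
                 n_refine: int = 25):
        """Profile REML for many genes at once (intercept-only model).

        A shared grid over log lambda in [-10, 10] locates each gene's
        optimum; vectorized golden-section refinement narrows it. Returns
        (h2, sigma2_g, sigma2_e, lrt) arrays matching rows of Y.
        """
        if self.p != 1:
            raise ValueError("fit_many supports the intercept-only model")
        Yr = np.atleast_2d(Y) @ self.U
        grid = np.linspace(-10.0, 10.0, n_grid)
        vals = np.stack([self._m2ll_many(u, Yr, reml) for u in grid])
        best = np.argmin(vals, axis=0)
        lo = grid[np.maximum(best - 1, 0)]
        hi = grid[np.minimum(best + 1, n_grid - 1)]
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo.copy(), hi.copy()
        c = b - gr * (b - a)
        d_ = a + gr * (b - a)
        fc = self._eval_per_gene(c, Yr, reml)
        fd = self._eval_per_gene(d_, Yr, reml)
        for _ in range(n_refine):
            left = fc < fd
            b = np.where(left, d_, b)
            a = np.where(left, a, c)
            c = b - gr * (b - a)
            d_ = a + gr * (b - a)
            fc = self._eval_per_gene(c, Yr, reml)
            fd = self._eval_per_gene(d_, Yr, reml)
        u_hat = (a + b) / 2.0
        m2_hat = self._eval_per_gene(u_hat, Yr, reml)
        m2_zero = self._m2ll_many(-np.inf, Yr, reml)
        at_zero = m2_zero <= m2_hat
        u_hat = np.where(at_zero, -np.inf, u_hat)
        m2_hat = np.where(at_zero, m2_zero, m2_hat)
        lam = np.where(np.isfinite(u_hat), np.exp(u_hat), 0.0)
        # recover sigma2_e at the optimum per gene
        s2e = np.empty(Yr.shape[0])
        for gi in range(Yr.shape[0]):
            s2e[gi] = self._m2ll(u_hat[gi], Yr[gi], reml)[2]
        s2g = lam * s2e
        h2 = np.where(s2g + s2e > 0, s2g / np.where(s2g + s2e > 0, s2g + s2e, 1.0), 0.0)
        lrt = np.maximum(m2_zero - m2_hat, 0.0)
        return h2, s2g, s2e, lrt

    def _eval_per_gene(self, u_vec, Yr, reml):
        """m2ll with a per-gene lambda (used by vectorized refinement)."""
        lam = np.exp(u_vec)
        v = lam[:, None] * self.d[None, :] + 1.0  # (G, n)
        w = 1.0 / v
        xr = self.Xr[:, 0]
        xtwx = np.sum(w * (xr * xr)[None, :], axis=1)
        beta = np.sum(w * Yr * xr[None, :], axis=1) / xtwx
        Q = np.maximum(np.sum(w * Yr * Yr, axis=1) - beta * beta * xtwx, 1e-300)
        logdetV = np.sum(np.log(v), axis=1)
        if reml:
            df = self.n - 1
            return df * (np.log(2 * np.pi * Q / df) + 1.0) + logdetV + np.log(xtwx)
        return self.n * (np.log(2 * np.pi * Q / self.n) + 1.0) + logdetV

    def fit(self, y: np.ndarray, reml: bool = True) -> GrmFit:
        """REML fit of one phenotype; LRT against sigma2_g = 0."""
        yr = self.U.T @ np.asarray(y, dtype=float)

        def obj(u):
            return self._m2ll(u, yr, reml)[0]

        res = optimize.minimize_scalar(
            obj, bounds=(-10.0, 10.0), method="bounded", options={"xatol": 1e-8}
        )
        m2_zero = self._m2ll(-np.inf, yr, reml)[0]
        best_u = res.x if res.fun < m2_zero else -np.inf
        m2, beta, s2e, lam = self._m2ll(best_u, yr, reml)
        if not np.isfinite(m2):
            raise FloatingPointError("non-finite likelihood in GRM fit")
        s2g = lam * s2e
        h2 = s2g / (s2g + s2e) if s2g + s2e > 0 else 0.0
        return GrmFit(
            h2=h2,
            sigma2_g=s2g,
            sigma2_e=s2e,
            beta=beta,
            loglik=-0.5 * m2,
            lrt=max(m2_zero - m2, 0.0),
        )
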