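"""Joint cis-eQTL mapping across two subspecies by Bayesian model averaging.

For each gene, every SNP within a cis window of the TSS is tested in each
subspecies separately (OLS on accession-level expression with genotype-PC
covariates; independent error model). Per-SNP evidence is a Wakefield-type
asymptotic Bayes factor averaged over a fixed grid of prior effect
variances. Evidence is combined over activity configurations — eQTL in
Indica only, Japonica only, or both (product of the per-subspecies BFs
under error independence) — and a hierarchical model with EM estimates pi0
(probability a gene has no eQTL anywhere) and the configuration weights.
Posterior probabilities classify genes; gene-level significance comes from
within-subspecies permutations of the residualized expression, with BH FDR
across genes.

A SNP monomorphic within one subspecies keeps BF = 1 there: that is exactly
what lets a variant absent from one group surface as a subspecies-specific
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .dataio import GeneTable, GenotypeTable

__all__ = [
    "GRID_W",
    "CONFIGS",
    "cis_candidates",
    "subspecies_assoc",
    "log_abf",
    "log_abf_grid",
    "config_log_bf",
    "config_log_bf_joint",
    "BfTensor",
    "HyperParams",
    "build_bf_tensor",
    "em_hyperparams",
    "compute_posteriors",
    "permutation_fdr_classify",
    "run_eqtl",
]

GRID_W = (0.01, 0.04, 0.16, 0.64)
CONFIGS = ("indica_specific", "japonica_specific", "shared")
_MIN_VAR = 1e-12
# configurations ruled out by the data (e.g. an effect at a SNP that does
# not vary in that subspecies); finite so log-space sums stay NaN-free
_LOG_IMPOSSIBLE = -1e6


def cis_candidates(
    gene, genotypes: GenotypeTable, window: int = 100_000, maf_min: float = 0.10
) -> np.ndarray:
    """Indices of SNPs with |pos - TSS| <= window (closed) and pooled MAF
    >= maf_min."""
    snps = genotypes.snps
    near = (snps["chrom"] == gene.chrom).to_numpy() & (
        np.abs(snps["pos"].to_numpy() - gene.tss) <= window
    )
    maf = genotypes.maf()
    return np.flatnonzero(near & (maf >= maf_min))


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def subspecies_assoc(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """OLS of y on each SNP column of X with covariates C (incl. intercept).

    Returns (beta, se, z, ok) arrays over SNPs; ok is False where the SNP
    has no variation after residualization or the fit is degenerate.
    """
    n = y.shape[0]
    k = C.shape[1] + 1
    yr = _residualize(y[:, None], C)[:, 0]
    Xr = _residualize(X, C)
    xtx = np.einsum("ij,ij->j", Xr, Xr)
    ok = xtx > _MIN_VAR
    xtx_safe = np.where(ok, xtx, 1.0)
    beta = (Xr.T @ yr) / xtx_safe
    yty = float(yr @ yr)
    rss = np.maximum(yty - beta**2 * xtx_safe, 0.0)
    df = n - k
    if df <= 0:
        raise ValueError("not enough accessions for the covariate model")
    s2 = rss / df
    se = np.sqrt(np.where(ok, s2 / xtx_safe, np.nan))
    ok = ok & (se > 0) & np.isfinite(se)
    z = np.where(ok, beta / np.where(ok, se, 1.0), 0.0)
    return beta, se, z, ok


def log_abf(z, V, W) -> np.ndarray:
    """Wakefield asymptotic log Bayes factor for one prior variance W."""
    z, V = np.asarray(z, float), np.asarray(V, float)
    return 0.5 * np.log(V / (V + W)) + 0.5 * z * z * W / (V + W)


def log_abf_grid(z, V, grid=GRID_W) -> np.ndarray:
    """Unweighted grid average of the ABF (computed in log space)."""
    stack = np.stack([log_abf(z, V, W) for W in grid])
    return logsumexp(stack, axis=0) - np.log(len(grid))


def config_log_bf(log_bf_I: np.ndarray, log_bf_J: np.ndarray) -> np.ndarray:
    """Per-configuration log BF under independent effects: (I-only,
    J-only, both), the 'both' BF being the product. Kept as the simple
    combination rule; the default scan uses the shared-effect form
    (:func:`config_log_bf_joint`), which actually discriminates
    subspecies-specific from shared signals."""
    return np.stack([log_bf_I, log_bf_J, log_bf_I + log_bf_J], axis=-1)


def _log_abf_joint(bI, VI, bJ, VJ, W):
    """log BF for a single effect beta ~ N(0, W) shared by both
    subspecies: (bI, bJ) ~ N(0, diag(V) + W 11') against diag(V)."""
    det1 = (VI + W) * (VJ + W) - W * W
    q0 = bI * bI / VI + bJ * bJ / VJ
    # inverse of the 2x2 alternative covariance
    q1 = ((VJ + W) * bI * bI - 2 * W * bI * bJ + (VI + W) * bJ * bJ) / det1
    return 0.5 * (q0 - q1) - 0.5 * np.log(det1 / (VI * VJ))


def config_log_bf_joint(zI, VI, zJ, VJ, okI=True, okJ=True, grid=GRID_W):
    """Configuration log BFs averaged over the prior grid at the
    configuration level: (I-only, J-only, both-shared-effect).

    For the 'both' configuration a single effect size is shared between
    subspecies (fixed-effect meta-analytic BF); a near-zero estimate in
    one subspecies then weighs against 'both' in proportion to the data's
    precision, which is what separates specific from shared eQTL.

    A SNP with no variation within a subspecies (okX = False) cannot
    carry an eQTL there, so configurations requiring an effect in that
    subspecies get (effectively) zero support at that SNP, while the
    per-subspecies BF itself stays at 1 (flagged upstream). This is what
    lets a variant absent from one subspecies surface as a specific
    configuration instead of tying with 'shared'.
    """
    zI, VI = np.asarray(zI, float), np.asarray(VI, float)
    zJ, VJ = np.asarray(zJ, float), np.asarray(VJ, float)
    okI = np.broadcast_to(okI, zI.shape)
    okJ = np.broadcast_to(okJ, zJ.shape)
    bI, bJ = zI * np.sqrt(VI), zJ * np.sqrt(VJ)
    lbf_I = np.where(okI, log_abf_grid(zI, VI, grid), 0.0)
    lbf_J = np.where(okJ, log_abf_grid(zJ, VJ, grid), 0.0)
    joint = logsumexp(
        np.stack([
            _log_abf_joint(bI, np.where(okI, VI, 1.0), bJ,
                           np.where(okJ, VJ, 1.0), W)
            for W in grid
        ]),
        axis=0,
    ) - np.log(len(grid))
    out = np.stack([lbf_I, lbf_J, joint], axis=-1)
    out[..., 0] = np.where(okI, out[..., 0], _LOG_IMPOSSIBLE)
    out[..., 1] = np.where(okJ, out[..., 1], _LOG_IMPOSSIBLE)
    out[..., 2] = np.where(okI & okJ, out[..., 2], _LOG_IMPOSSIBLE)
    return out


@dataclass
class BfTensor:
    """Configuration Bayes factors per gene over its cis SNPs."""

    gene_ids: list
    snp_indices: list  # per gene: array of SNP column indices
    log_bf: list  # per gene: (S_g, 3) array over CONFIGS
    flags: list = field(default_factory=list)  # per gene: monomorphic masks


@dataclass
class HyperParams:
    pi0: float
    w: np.ndarray  # configuration weights, on the simplex
    loglik_trace: np.ndarray
    identifiable: bool = True

    def __post_init__(self):
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must be in [0, 1]")
        if abs(self.w.sum() - 1.0) > 1e-8 or (self.w < 0).any():
            raise ValueError("configuration weights must lie on the simplex")


def build_bf_tensor(
    expr_acc: np.ndarray,
    gene_ids,
    gene_table: GeneTable,
    genotypes: GenotypeTable,
    is_I: np.ndarray,
    covariates: np.ndarray,
    window: int = 100_000,
    maf_min: float = 0.10,
    grid=GRID_W,
) -> BfTensor:
    """Association scans and configuration BFs for every gene.

    ``expr_acc`` is accession-level (BLUP + INT) expression aligned to
    ``genotypes.accessions``; ``is_I`` the subspecies mask; ``covariates``
    the genotype-PC matrix (no intercept column; one is added).
    """
    gt_rows = {g: r for g, r in zip(gene_table.table["gene_id"], gene_table.table.itertuples(index=False))}
    masks = {"I": np.asarray(is_I, bool), "J": ~np.asarray(is_I, bool)}
    C = {
        k: np.column_stack([np.ones(m.sum()), covariates[m]])
        for k, m in masks.items()
    }
    snp_idx_list, log_bf_list, flag_list = [], [], []
    for gi, gid in enumerate(gene_ids):
        gene = gt_rows[gid]
        idx = cis_candidates(gene, genotypes, window, maf_min)
        snp_idx_list.append(idx)
        if idx.size == 0:
            log_bf_list.append(np.zeros((0, 3)))
            flag_list.append({})
            continue
        stats_pop = {}
        flags = {}
        for pop in ("I", "J"):
            m = masks[pop]
            if m.sum() < C[pop].shape[1] + 3:
                # too few accessions: no evidence either way, BF = 1
                stats_pop[pop] = (np.zeros(idx.size), np.ones(idx.size),
                                  np.zeros(idx.size, dtype=bool))
                flags[pop] = np.ones(idx.size, dtype=bool)
                continue
            X = np.nan_to_num(
                genotypes.dosages[np.ix_(np.flatnonzero(m), idx)], nan=0.5
            )
            y = expr_acc[gi, m]
            beta, se, z, ok = subspecies_assoc(y, X, C[pop])
            V = np.where(ok, se**2, 1.0)
            stats_pop[pop] = (np.where(ok, z, 0.0), V, ok)
            flags[pop] = ~ok
        zI, VI, okI = stats_pop["I"]
        zJ, VJ, okJ = stats_pop["J"]
        log_bf_list.append(config_log_bf_joint(zI, VI, zJ, VJ, okI, okJ, grid))
        flag_list.append(flags)
    return BfTensor(list(gene_ids), snp_idx_list, log_bf_list, flag_list)


def _gene_log_alt(log_bf: np.ndarray, log_w: np.ndarray) -> float:
    """log of the averaged alternative likelihood A_g = (1/S) sum_sc w_c BF."""
    S = log_bf.shape[0]
    return float(logsumexp(log_bf + log_w[None, :]) - np.log(S))


def em_hyperparams(
    bf: BfTensor, tol: float = 1e-6, max_iter: int = 1000
) -> HyperParams:
    """EM for pi0 and configuration weights in the hierarchical model.

    Likelihood per gene: L_g = pi0 + (1 - pi0) * (1/S_g) * sum_s sum_c
    w_c BF_gsc. Responsibilities split each gene between the null and
    (SNP, configuration) pairs; the total log-likelihood is non-decreasing.
    """
    genes = [lb for lb in bf.log_bf if lb.shape[0] > 0]
    if not genes:
        raise ValueError("no gene has cis candidates")
    if all(np.allclose(lb, 0.0) for lb in genes):
        return HyperParams(
            0.5, np.full(3, 1.0 / 3), np.array([]), identifiable=False
        )
    # flatten all (gene, SNP) rows; segmented reductions over gene slices
    sizes = np.array([lb.shape[0] for lb in genes])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    flat = np.vstack(genes)  # (sum S_g, 3)
    log_S = np.log(sizes)
    G = len(genes)

    def seg_logsumexp(v):
        m = np.maximum.reduceat(v, starts)
        s = np.add.reduceat(np.exp(v - np.repeat(m, sizes)), starts)
        return m + np.log(s)

    pi0, w = 0.5, np.full(3, 1.0 / 3)
    trace = []
    for _ in range(max_iter):
        log_w = np.log(np.maximum(w, 1e-300))
        row = logsumexp(flat + log_w[None, :], axis=1)  # per (gene, SNP)
        la = seg_logsumexp(row) - log_S  # log A_g
        with np.errstate(divide="ignore"):
            lL = np.logaddexp(np.log(pi0), np.log1p(-pi0) + la)
        ll = float(lL.sum())
        r_null = np.exp(np.log(pi0) - lL) if pi0 > 0 else np.zeros(G)
        # configuration responsibilities, summed over genes and SNPs
        lr = (
            flat + log_w[None, :]
            + np.repeat(np.log1p(-pi0) - log_S - lL, sizes)[:, None]
        )
        w_acc = np.exp(logsumexp(lr, axis=0))
        trace.append(ll)
        pi0 = float(np.mean(r_null))
        tot = w_acc.sum()
        w = w_acc / tot if tot > 0 else w
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    return HyperParams(float(pi0), w, np.array(trace))


def compute_posteriors(bf: BfTensor, hyper: HyperParams) -> pd.DataFrame:
    """Per-gene posteriors: PP of an eQTL anywhere, best SNP, and the
    configuration PPs at the best SNP."""
    log_w = np.log(np.maximum(hyper.w, 1e-300))
    pi0 = hyper.pi0
    rows = []
    for gid, idx, lb in zip(bf.gene_ids, bf.snp_indices, bf.log_bf):
        if lb.shape[0] == 0:
            rows.append((gid, np.nan, -1, np.nan, np.nan, np.nan, np.nan))
            continue
        la = _gene_log_alt(lb, log_w)
        lL = np.logaddexp(np.log(pi0), np.log1p(-pi0) + la) if 0 < pi0 < 1 else (
            0.0 if pi0 == 1.0 else la
        )
        pp_gene = float(np.exp(np.log1p(-pi0) + la - lL)) if pi0 > 0 else 1.0
        lsnp = logsumexp(lb + log_w[None, :], axis=1)
        pp_snp = np.exp(lsnp - logsumexp(lsnp))
        top = int(np.argmax(pp_snp))
        lc = lb[top] + log_w
        pp_c = np.exp(lc - logsumexp(lc))
        rows.append(
            (gid, pp_gene, int(idx[top]), float(pp_snp[top]), *map(float, pp_c))
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "pp_gene",
            "top_snp",
            "pp_top_snp",
            "pp_indica_specific",
            "pp_japonica_specific",
            "pp_shared",
        ],
    )


def permutation_fdr_classify(
    expr_acc: np.ndarray,
    bf: BfTensor,
    hyper: HyperParams,
    genotypes: GenotypeTable,
    is_I: np.ndarray,
    covariates: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
    pp_threshold: float = 0.5,
    grid=GRID_W,
) -> pd.DataFrame:
    """Gene-level permutation FDR and configuration calls.

    The statistic is the averaged alternative likelihood A_g recomputed
    under permutations of residualized expression across accessions within
    each subspecies independently (hyperparameters held fixed). Per-gene
    permutation streams derive from (seed, gene index) so results do not
    depend on execution order.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    is_I = np.asarray(is_I, bool)
    masks = {"I": is_I, "J": ~is_I}
    C = {k: np.column_stack([np.ones(m.sum()), covariates[m]]) for k, m in masks.items()}
    log_w = np.log(np.maximum(hyper.w, 1e-300))
    post = compute_posteriors(bf, hyper)

    pvals = np.full(len(bf.gene_ids), np.nan)
    for gi, (idx, lb) in enumerate(zip(bf.snp_indices, bf.log_bf)):
        if lb.shape[0] == 0:
            continue
        a_obs = _gene_log_alt(lb, log_w)
        rng = np.random.default_rng([seed, gi])
        zperm, Vperm, okperm = {}, {}, {}
        for pop in ("I", "J"):
            m = masks[pop]
            if m.sum() < C[pop].shape[1] + 3:
                zperm[pop] = np.zeros((B, idx.size))
                Vperm[pop] = np.ones((B, idx.size))
                okperm[pop] = np.zeros((B, idx.size), dtype=bool)
                continue
            rows = np.flatnonzero(m)
            X = np.nan_to_num(genotypes.dosages[np.ix_(rows, idx)], nan=0.5)
            Xr = _residualize(X, C[pop])
            yr = _residualize(expr_acc[gi, m][:, None], C[pop])[:, 0]
            xtx = np.einsum("ij,ij->j", Xr, Xr)
            ok = xtx > _MIN_VAR
            xtx_safe = np.where(ok, xtx, 1.0)
            n = yr.size
            df = n - C[pop].shape[1] - 1
            yty = float(yr @ yr)
            # B permuted copies of the residualized phenotype
            P = np.array([rng.permutation(yr) for _ in range(B)])
            beta = (P @ Xr) / xtx_safe[None, :]
            rss = np.maximum(yty - beta**2 * xtx_safe[None, :], _MIN_VAR)
            se2 = rss / df / xtx_safe[None, :]
            zperm[pop] = np.where(ok[None, :], beta / np.sqrt(se2), 0.0)
            Vperm[pop] = np.where(ok[None, :], se2, 1.0)
            okperm[pop] = np.broadcast_to(ok, (B, idx.size))
        lb_cfg = config_log_bf_joint(
            zperm["I"], Vperm["I"], zperm["J"], Vperm["J"],
            okperm["I"], okperm["J"], grid,
        )  # (B, S, 3)
        a_perm = logsumexp(
            lb_cfg + log_w[None, None, :], axis=(1, 2)
        ) - np.log(idx.size)
        pvals[gi] = (1.0 + np.sum(a_perm >= a_obs)) / (B + 1.0)

    from .divergence import bh_adjust

    post["p"] = pvals
    post["q"] = bh_adjust(pvals)
    # Storey-type pi0 from the permutation p-values: under the null p is
    # ~uniform, so the density above 1/2 estimates the null fraction
    ok_p = pvals[~np.isnan(pvals)]
    post.attrs["pi0_perm"] = (
        float(min(np.mean(ok_p > 0.5) / 0.5, 1.0)) if ok_p.size else np.nan
    )
    pp_cfg = post[
        ["pp_indica_specific", "pp_japonica_specific", "pp_shared"]
    ].to_numpy()
    best = np.nanargmax(np.nan_to_num(pp_cfg, nan=-1.0), axis=1)
    call = np.array([CONFIGS[b] for b in best], dtype=object)
    ok = (post["q"].to_numpy() <= fdr) & (
        np.nanmax(np.nan_to_num(pp_cfg, nan=-1.0), axis=1) > pp_threshold
    )
    call[~ok] = "none"
    post["call"] = call
    snp_ids = genotypes.snps["snp_id"].to_numpy()
    post["top_snp_id"] = [
        snp_ids[t] if t >= 0 else None for t in post["top_snp"]
    ]
    return post


def run_eqtl(
    expr_acc: np.ndarray,
    gene_ids,
    gene_table: GeneTable,
    genotypes: GenotypeTable,
    is_I: np.ndarray,
    covariates: np.ndarray,
    window: int = 100_000,
    maf_min: float = 0.10,
    grid=GRID_W,
    B: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
    pp_threshold: float = 0.5,
) -> tuple[pd.DataFrame, HyperParams, BfTensor]:
    """Full joint cis-eQTL scan: BFs, EM hyperparameters, posteriors and
    permutation-FDR configuration calls."""
    bf = build_bf_tensor(
        expr_acc, gene_ids, gene_table, genotypes, is_I, covariates,
        window, maf_min, grid,
    )
    hyper = em_hyperparams(bf)
    calls = permutation_fdr_classify(
        expr_acc, bf, hyper, genotypes, is_I, covariates,
        B=B, seed=seed, fdr=fdr, pp_threshold=pp_threshold, grid=grid,
    )
    return calls, hyper, bf
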