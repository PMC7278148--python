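"""Broad- and narrow-sense heritability of expression, and the permutation
test for heritability differences between subspecies.

Broad sense: H2 = sigma2_a / (sigma2_a + sigma2_e) from a REML
random-intercept fit on replicate-level expression; significance from a
restricted LRT whose null distribution is simulated per replicate design
(the boundary puts roughly half the null mass at zero, so chi-square
references are wrong here). Narrow sense: h2 from a GRM (VanRaden) REML fit
on accession-level expression, with the usual 0.5*chi2_0 + 0.5*chi2_1
boundary mixture for the LRT. The between-subspecies test permutes
accessions into two label-blind groups of equal size and recomputes the
heritability difference, giving an empirical two-sided p with the add-one
convention (minimum p ~ 1/(B+1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import lmm
from .dataio import GenotypeTable, SampleTable
from .preprocess import SubspeciesAssignment

__all__ = [
    "Grm",
    "build_grm",
    "fit_broad_h2",
    "rlrt_pvalues",
    "run_broad_h2",
    "run_narrow_h2",
    "within_subspecies_scopes",
    "delta_h_permutation",
]


@dataclass
class Grm:
    accessions: list
    G: np.ndarray
    m: int  # markers used

    def __post_init__(self):
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


def build_grm(genotypes: GenotypeTable, rows=None) -> Grm:
    """VanRaden GRM: G = Zcs Zcs' / m from centered, unit-variance dosages.

    Monomorphic columns are dropped; missing dosages are imputed to the
    column mean. Scaling uses the population (denominator n) variance, so
    the mean diagonal is exactly 1.
    """
    if rows is None:
        rows = np.arange(genotypes.n_accessions)
    rows = np.asarray(rows)
    Z = genotypes.dosages[rows].copy()
    col_mean = np.nanmean(Z, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(Z))
    Z[nan_r, nan_c] = col_mean[nan_c]
    sd = Z.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("all markers monomorphic")
    Z = (Z[:, poly] - Z[:, poly].mean(axis=0)) / sd[poly]
    m = int(poly.sum())
    G = Z @ Z.T / m
    return Grm([genotypes.accessions[i] for i in rows], G, m)


def fit_broad_h2(y: np.ndarray, group_idx: np.ndarray):
    """REML variance components and restricted LRT for one gene.

    Requires at least one accession with >= 2 replicates, otherwise the
    components are not separable.
    """
    group_idx = np.asarray(group_idx)
    sizes = np.bincount(group_idx)
    if sizes.max() < 2:
        raise ValueError("single replicate per accession: H2 not estimable")
    stat, fit = lmm.rlrt_broad(y, group_idx)
    return stat, fit


def rlrt_pvalues(stats_obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Empirical p = (1 + #{null >= obs}) / (B + 1) against a simulated null."""
    null = np.sort(null)
    B = len(null)
    ge = B - np.searchsorted(null, np.asarray(stats_obs), side="left")
    return (1.0 + ge) / (B + 1.0)


def run_broad_h2(
    expr_values: np.ndarray,
    gene_ids,
    samples: SampleTable,
    columns=None,
    B: int = 10_000,
    seed: int = 0,
    fdr: float = 0.001,
) -> pd.DataFrame:
    """Broad-sense H2 per gene with simulated-null RLRT p-values.

    All genes share the replicate design, so one simulated null serves the
    whole table.
    """
    columns = samples.sample_ids if columns is None else columns
    accs = samples.accessions()
    acc_index = {a: i for i, a in enumerate(accs)}
    col_of = samples.accession_of
    group_idx = np.array([acc_index[col_of[s]] for s in columns])
    used = np.unique(group_idx)
    remap = {g: i for i, g in enumerate(used)}
    group_idx = np.array([remap[g] for g in group_idx])
    sizes = np.bincount(group_idx)
    null = lmm.rlrt_null_distribution(sizes, B=B, seed=seed)

    if np.all(sizes == sizes[0]) and sizes[0] >= 2:
        s2a, s2e, h2, rlrt = lmm.balanced_one_way_reml_many(
            np.asarray(expr_values), group_idx
        )
        df = pd.DataFrame(
            {"gene_id": list(gene_ids), "sigma2_a": s2a, "sigma2_e": s2e,
             "H2": h2, "rlrt": rlrt}
        )
    else:
        rows = []
        for gid, y in zip(gene_ids, expr_values):
            stat, fit = fit_broad_h2(y, group_idx)
            rows.append((gid, fit.sigma2_a, fit.sigma2_e, fit.h2, stat))
        df = pd.DataFrame(
            rows, columns=["gene_id", "sigma2_a", "sigma2_e", "H2", "rlrt"]
        )
    df["p"] = rlrt_pvalues(df["rlrt"].to_numpy(), null)
    from .divergence import bh_adjust

    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] <= fdr
    return df


def run_narrow_h2(
    expr_values: np.ndarray,
    gene_ids,
    grm: Grm,
    fdr: float = 0.001,
) -> pd.DataFrame:
    """Narrow-sense h2 per gene from one GRM eigendecomposition.

    The LRT of sigma2_g = 0 uses the 0.5*chi2_0 + 0.5*chi2_1 boundary
    mixture.
    """
    eig = lmm.GrmEigen(grm.G)
    h2, s2g, s2e, lrt = eig.fit_many(np.asarray(expr_values))
    p = np.where(lrt > 0, 0.5 * stats.chi2.sf(lrt, df=1), 1.0)
    df = pd.DataFrame(
        {"gene_id": list(gene_ids), "sigma2_g": s2g, "sigma2_e": s2e,
         "h2": h2, "lrt": lrt, "p": p}
    )
    from .divergence import bh_adjust

    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] <= fdr
    return df


def within_subspecies_scopes(
    samples: SampleTable,
    assignment: SubspeciesAssignment,
    seed: int = 0,
) -> dict:
    """Accession subsets per scope, the larger subspecies subsampled
    (seeded) to the smaller's size so estimates are comparable."""
    accs = samples.accessions()
    rng = np.random.default_rng(seed)
    by = {"I": [a for a in accs if assignment.labels[a] == "I"],
          "J": [a for a in accs if assignment.labels[a] == "J"]}
    n_min = min(len(by["I"]), len(by["J"]))
    out = {}
    for scope, members in by.items():
        if len(members) > n_min:
            members = list(rng.choice(members, size=n_min, replace=False))
        out[scope] = members
    return out


def _h2_for_accession_set(
    kind: str,
    members: list,
    gene_rows: np.ndarray,
    *,
    expr_rep: np.ndarray | None = None,
    rep_group_of: np.ndarray | None = None,
    accessions: list | None = None,
    expr_acc: np.ndarray | None = None,
    genotypes: GenotypeTable | None = None,
) -> np.ndarray:
    """Heritability per gene for one accession subset (broad or narrow)."""
    acc_index = {a: i for i, a in enumerate(accessions)}
    rows = np.array([acc_index[a] for a in members])
    if kind == "broad":
        keep = np.isin(rep_group_of, rows)
        sub_groups = rep_group_of[keep]
        remap = {g: i for i, g in enumerate(np.unique(sub_groups))}
        gidx = np.array([remap[g] for g in sub_groups])
        sizes = np.bincount(gidx)
        Y = expr_rep[np.ix_(gene_rows, np.flatnonzero(keep))]
        if np.all(sizes == sizes[0]) and sizes[0] >= 2:
            return lmm.balanced_one_way_reml_many(Y, gidx)[2]
        return np.array(
            [lmm.fit_one_way(y, gidx, reml=True).h2 for y in Y]
        )
    grm = build_grm(genotypes, rows=rows)
    eig = lmm.GrmEigen(grm.G)
    return eig.fit_many(expr_acc[gene_rows][:, rows])[0]


def delta_h_permutation(
    gene_ids,
    delta_obs: np.ndarray,
    kind: str,
    accessions: list,
    B: int = 100,
    seed: int = 0,
    group_size: int | None = None,
    expr_rep: np.ndarray | None = None,
    rep_group_of: np.ndarray | None = None,
    expr_acc: np.ndarray | None = None,
    genotypes: GenotypeTable | None = None,
) -> pd.DataFrame:
    """Permutation null for the between-subspecies heritability difference.

    Every permutation partitions the pooled accessions, ignoring subspecies
    labels, into two disjoint groups of ``group_size`` (default: half the
    panel, capped at the smaller subspecies size by the caller), recomputes
    heritability in each and takes the difference. Two-sided empirical p
    with the add-one convention.

    Parameters mirror the two estimators: broad needs replicate-level
    expression (``expr_rep``, genes x samples) and the accession index per
    sample (``rep_group_of``); narrow needs accession-level expression
    (``expr_acc``) and genotypes for per-group GRMs.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if kind not in ("broad", "narrow"):
        raise ValueError("kind must be 'broad' or 'narrow'")
    rng = np.random.default_rng(seed)
    n_acc = len(accessions)
    m = group_size or n_acc // 2
    if 2 * m > n_acc:
        raise ValueError("group_size too large for the panel")
    gene_rows = np.arange(len(gene_ids))
    kw = dict(
        expr_rep=expr_rep,
        rep_group_of=rep_group_of,
        accessions=accessions,
        expr_acc=expr_acc,
        genotypes=genotypes,
    )
    delta_null = np.empty((B, len(gene_ids)))
    for b in range(B):
        perm = rng.permutation(n_acc)
        g1 = [accessions[i] for i in perm[:m]]
        g2 = [accessions[i] for i in perm[m : 2 * m]]
        h1 = _h2_for_accession_set(kind, g1, gene_rows, **kw)
        h2 = _h2_for_accession_set(kind, g2, gene_rows, **kw)
        delta_null[b] = h2 - h1
    delta_obs = np.asarray(delta_obs, dtype=float)
    ge = (np.abs(delta_null) >= np.abs(delta_obs)[None, :]).sum(axis=0)
    p = (1.0 + ge) / (B + 1.0)
    return pd.DataFrame(
        {"gene_id": gene_ids, "kind": kind, "delta": delta_obs, "p": p, "B": B}
    )
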