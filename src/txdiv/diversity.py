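"""Expression diversity (CV) and nucleotide diversity (site and window pi).

Site pi follows the VCFtools site-pi definition: for a biallelic site with
a reference and b alternate alleles observed, pi = a*b / C(a+b, 2) — the
fraction of discordant pairs. Missing alleles are excluded site-wise.
Expression diversity is the per-gene coefficient of variation of
size-factor-normalized counts at the accession level (unlogged scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GenotypeTable

__all__ = [
    "site_pi",
    "site_pi_counts",
    "group_pi",
    "window_mean_pi",
    "tile_windows",
    "expression_cv",
    "compare_group_pi",
]


def site_pi(n_ref, n_alt) -> float:
    """Nucleotide diversity at one biallelic site from allele counts."""
    n = n_ref + n_alt
    if n < 2:
        return np.nan
    return (n_ref * n_alt) / (n * (n - 1) / 2.0)


def site_pi_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized site pi over SNP columns of a haploid dosage matrix.

    Returns (pi, n_alleles) per SNP; pi is NaN where fewer than two
    alleles were observed.
    """
    obs = ~np.isnan(dosages)
    n = obs.sum(axis=0).astype(float)
    alt = np.nansum(dosages, axis=0)
    ref = n - alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n >= 2, ref * alt / (n * (n - 1) / 2.0), np.nan)
    return pi, n


def group_pi(
    genotypes: GenotypeTable,
    groups: dict,
    maf_min: float = 0.05,
    equalize: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group site-pi table after a within-group MAF filter.

    ``groups`` maps group name -> accession-index array. With ``equalize``
    every group is subsampled (seeded) to the smallest group's size before
    computing frequencies, as when comparing subspecies of unequal size.
    """
    rng = np.random.default_rng(seed)
    sizes = {g: len(rows) for g, rows in groups.items()}
    if min(sizes.values()) < 2:
        raise ValueError("every group needs at least two accessions")
    n_min = min(sizes.values())
    out = []
    snps = genotypes.snps
    for g, rows in groups.items():
        rows = np.asarray(rows)
        if equalize and len(rows) > n_min:
            rows = rng.choice(rows, size=n_min, replace=False)
        sub = genotypes.dosages[rows]
        pi, n = site_pi_counts(sub)
        p = np.nansum(sub, axis=0) / np.maximum(n, 1)
        maf = np.minimum(p, 1 - p)
        keep = (maf >= maf_min) & (n >= 2)
        out.append(
            pd.DataFrame(
                {
                    "snp_id": snps["snp_id"][keep].to_numpy(),
                    "chrom": snps["chrom"][keep].to_numpy(),
                    "pos": snps["pos"][keep].to_numpy(),
                    "group": g,
                    "n": n[keep].astype(int),
                    "pi": pi[keep],
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def tile_windows(chromosome_lengths: dict, size: int = 100_000) -> pd.DataFrame:
    """Consecutive 1-based closed windows tiling each chromosome."""
    rows = []
    for chrom, L in chromosome_lengths.items():
        starts = np.arange(1, L + 1, size)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + size - 1, L))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_mean_pi(sites: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Mean site pi per (window, group); NaN where a window has no SNPs."""
    rows = []
    for win in windows.itertuples(index=False):
        sel = sites[
            (sites["chrom"] == win.chrom)
            & (sites["pos"] >= win.start)
            & (sites["pos"] <= win.end)
        ]
        for g, sub in sel.groupby("group"):
            rows.append((win.chrom, win.start, win.end, g, sub["pi"].mean(), len(sub)))
        for g in sites["group"].unique():
            if len(sel) == 0 or g not in set(sel["group"]):
                rows.append((win.chrom, win.start, win.end, g, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "group", "mean_pi", "n_sites"]
    )


def expression_cv(
    values: np.ndarray, gene_ids, groups: dict
) -> pd.DataFrame:
    """Coefficient of variation (sd/mean) per gene per group.

    ``values`` is accession-level normalized (unlogged) expression;
    ``groups`` maps group name -> column-index array. CV is NaN where the
    group mean is <= 0.
    """
    rows = []
    for g, cols in groups.items():
        sub = values[:, np.asarray(cols)]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
        for gid, c in zip(gene_ids, cv):
            rows.append((gid, g, c))
    return pd.DataFrame(rows, columns=["gene_id", "group", "cv"])


def compare_group_pi(sites: pd.DataFrame, group_a: str, group_b: str) -> dict:
    """Wilcoxon rank-sum comparison of site-pi distributions between groups."""
    a = sites.loc[sites["group"] == group_a, "pi"].dropna()
    b = sites.loc[sites["group"] == group_b, "pi"].dropna()
    stat, p = stats.ranksums(a, b)
    return {
        "group_a": group_a,
        "group_b": group_b,
        "mean_pi_a": float(a.mean()),
        "mean_pi_b": float(b.mean()),
        "statistic": float(stat),
        "p": float(p),
    }
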