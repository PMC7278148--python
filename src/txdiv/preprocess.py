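"""Expression filtering, normalization, genotype PCA and subspecies calls.

Normalization uses median-of-ratios size factors followed by log2(x/s + 1),
a monotone variance-stabilizing transform for overdispersed counts.
Per-gene rank-based inverse normal transformation (ties broken randomly)
prepares expression for Gaussian mixed models. The subspecies classifier is
a PCA + 2-means stand-in anchored by accessions of known label: on panels as
divergent as Indica/Japonica, PC1 of the SNP matrix separates the groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .dataio import CountTable, GenotypeTable, SampleTable
from . import lmm

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PcaResult",
    "SubspeciesAssignment",
    "filter_expressed",
    "normalize_vst",
    "inverse_normal_transform",
    "genotype_pca",
    "classify_subspecies",
    "accession_blup",
]


@dataclass
class ExpressionMatrix:
    """Real-valued gene x column matrix with a transform tag."""

    genes: list
    columns: list
    values: np.ndarray
    transform: str = "vst"
    size_factors: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.size_factors is not None and np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.columns)


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, k)
    pve: np.ndarray  # proportion of variance explained, non-increasing
    ids: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(np.diff(self.pve) > 1e-12):
            raise ValueError("PVE must be non-increasing")


@dataclass
class SubspeciesAssignment:
    labels: dict  # accession -> "I" | "J"
    method: str = "pca_kmeans"

    def mask(self, accessions, label) -> np.ndarray:
        return np.array([self.labels[a] == label for a in accessions])


def filter_expressed(
    counts: CountTable, min_count: int = 10, min_frac: float = 0.20
) -> np.ndarray:
    """Boolean keep-mask: gene is expressed in >= ceil(min_frac * n) samples.

    A sample "expresses" a gene when its count is >= min_count.
    """
    if not 0.0 < min_frac <= 1.0:
        raise ValueError("min_frac must be in (0, 1]")
    n = len(counts.samples)
    need = int(np.ceil(min_frac * n))
    return (counts.counts >= min_count).sum(axis=1) >= need


def size_factors_median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (reference: per-gene geometric mean
    over genes observed in every sample). Falls back to total-count ratios
    when no zero-free gene exists."""
    zero_free = (counts > 0).all(axis=1)
    if not zero_free.any():
        logger.warning("no zero-free genes; using total-count size factors")
        tot = counts.sum(axis=0).astype(float)
        return tot / stats.gmean(tot)
    sub = counts[zero_free].astype(float)
    log_ref = np.log(sub).mean(axis=1)
    log_s = np.median(np.log(sub) - log_ref[:, None], axis=0)
    return np.exp(log_s)


def normalize_vst(counts: CountTable) -> ExpressionMatrix:
    """Size-factor normalization followed by log2(x/s + 1)."""
    if len(counts.samples) < 2:
        raise ValueError("need at least two samples")
    s = size_factors_median_of_ratios(counts.counts)
    vals = np.log2(counts.counts / s[None, :] + 1.0)
    return ExpressionMatrix(counts.genes, counts.samples, vals, "vst", s)


def inverse_normal_transform(values: np.ndarray, rng=None) -> np.ndarray:
    """Map values to quantiles of N(0,1): Phi^-1((rank - 0.5)/n).

    Ties are broken by random permutation under ``rng``. Works on a vector
    or row-wise on a matrix.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        return np.vstack([inverse_normal_transform(row, rng) for row in values])
    n = values.size
    if n < 2:
        raise ValueError("need at least two values")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if np.all(values == values[0]):
        warnings.warn("all values identical; ranks assigned at random")
    jitter = rng.permutation(n)  # decides ties, leaves distinct values alone
    order = np.lexsort((jitter, values))
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return stats.norm.ppf((ranks - 0.5) / n)


def genotype_pca(
    genotypes: GenotypeTable, maf_min: float = 0.10, k: int = 4
) -> PcaResult:
    """PCA of MAF-filtered, column-centered dosages (missing -> column mean)."""
    keep = genotypes.maf() >= maf_min
    if not keep.any():
        raise ValueError("all SNPs removed by the MAF filter")
    Z = genotypes.dosages[:, keep].copy()
    col_mean = np.nanmean(Z, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(Z))
    Z[nan_r, nan_c] = col_mean[nan_c]
    Z -= Z.mean(axis=0)
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    total = float(np.sum(S**2))
    k = min(k, len(S))
    scores = U[:, :k] * S[:k]
    pve = S[:k] ** 2 / total
    return PcaResult(scores=scores, pve=pve, ids=list(genotypes.accessions))


def classify_subspecies(pca: PcaResult, anchors: dict) -> SubspeciesAssignment:
    """2-means on PC1; clusters named by anchor majority.

    ``anchors`` maps at least one accession id per subspecies to its known
    label ("I" or "J").
    """
    if len(pca.ids) < 2:
        raise ValueError("need at least two accessions")
    pc1 = pca.scores[:, [0]]
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(pc1)
    cl = km.labels_
    if len(set(cl)) < 2:
        raise ValueError("degenerate clustering: one cluster is empty")
    votes = {0: {"I": 0, "J": 0}, 1: {"I": 0, "J": 0}}
    idx = {a: i for i, a in enumerate(pca.ids)}
    for acc, lab in anchors.items():
        if acc in idx:
            votes[cl[idx[acc]]][lab] += 1
    name = {}
    for c in (0, 1):
        vi, vj = votes[c]["I"], votes[c]["J"]
        if vi == vj:
            continue
        name[c] = "I" if vi > vj else "J"
    if len(name) == 1:
        (c0,) = name
        name[1 - c0] = "J" if name[c0] == "I" else "I"
    if len(name) != 2 or name[0] == name[1]:
        raise ValueError("anchors conflict: clusters cannot be named")
    return SubspeciesAssignment({a: name[cl[idx[a]]] for a in pca.ids})


def accession_blup(
    expr: ExpressionMatrix, samples: SampleTable
) -> ExpressionMatrix:
    """Shrink replicate-level expression to accession BLUPs, per gene.

    Fits y_ij = mu + u_i + e_ij by REML and returns
    mu + (s2a / (s2a + s2e / r_i)) * (ybar_i - mu). With replicate noise
    absent the BLUP is the accession mean; with no accession variance it
    collapses to mu.
    """
    accs = samples.accessions()
    acc_index = {a: i for i, a in enumerate(accs)}
    col_of = samples.accession_of
    group_idx = np.array([acc_index[col_of[s]] for s in expr.columns])
    k = len(accs)
    n_i = np.bincount(group_idx, minlength=k).astype(float)
    if np.all(n_i <= 1):
        warnings.warn("single replicate everywhere; BLUPs equal observed values")
        out = np.full((len(expr.genes), k), np.nan)
        for j, g in enumerate(group_idx):
            out[:, g] = expr.values[:, j]
        return ExpressionMatrix(expr.genes, accs, out, "blup")

    if np.all(n_i == n_i[0]) and n_i[0] >= 2:
        # balanced: closed-form REML components, fully vectorized
        Y = expr.values
        s2a, s2e, _, _ = lmm.balanced_one_way_reml_many(Y, group_idx)
        sums = np.zeros((Y.shape[0], k))
        np.add.at(sums.T, group_idx, Y.T)
        ybar = sums / n_i[None, :]
        mu = Y.mean(axis=1)
        denom = s2a + s2e / n_i[0]
        w = np.divide(s2a, denom, out=np.zeros_like(s2a), where=denom > 0)
        out = mu[:, None] + w[:, None] * (ybar - mu[:, None])
        return ExpressionMatrix(expr.genes, accs, out, "blup")

    out = np.empty((len(expr.genes), k))
    for gi in range(len(expr.genes)):
        y = expr.values[gi]
        fit = lmm.fit_one_way(y, group_idx, reml=True)
        mu = fit.beta[0]
        ybar = np.bincount(group_idx, weights=y, minlength=k) / n_i
        denom = fit.sigma2_a + fit.sigma2_e / n_i
        w = np.divide(fit.sigma2_a, denom, out=np.zeros(k), where=denom > 0)
        out[gi] = mu + w * (ybar - mu)
    return ExpressionMatrix(expr.genes, accs, out, "blup")
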