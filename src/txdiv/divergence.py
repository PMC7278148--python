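"""Differential expression and presence-absence variation between subspecies.

DE: per gene, a Gaussian mixed model on inverse-normal-transformed
replicate-level expression with subspecies as fixed effect and accession as
random intercept; maximum-likelihood LRT (df = 1) of the subspecies term
(ML, not REML: REML likelihoods are not comparable across fixed-effect
structures). PAV: a penalized random-intercept logistic model on the
expressed/not-expressed coding, same LRT. Both control FDR by
Benjamini-Hochberg, with the conventional significance cut q <= 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import glmm, lmm
from .dataio import CountTable, SampleTable
from .preprocess import SubspeciesAssignment

__all__ = [
    "DivergenceResult",
    "bh_adjust",
    "fit_de_gene",
    "encode_pav",
    "fit_pav_gene",
    "run_de",
    "run_pav",
]


@dataclass
class DivergenceResult:
    gene_id: str
    test: str  # "DE" or "PAV"
    beta: float  # subspecies contrast (J - I)
    intercept: float
    lrt: float
    p: float
    direction: str  # "higher_in_J" / "higher_in_I" / "none"


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(q, 1.0)
    out[ok] = adj
    return out


def _design(samples: SampleTable, assignment: SubspeciesAssignment, columns):
    """Accession grouping and subspecies design shared by DE and PAV fits."""
    accs = samples.accessions()
    acc_index = {a: i for i, a in enumerate(accs)}
    col_of = samples.accession_of
    group_idx = np.array([acc_index[col_of[s]] for s in columns])
    is_J = np.array([assignment.labels[a] == "J" for a in accs], dtype=float)
    # +-1/2 coding keeps the penalized PAV fit symmetric under label swap;
    # beta stays the J - I contrast
    X_full = np.column_stack([np.ones(len(accs)), is_J - 0.5])
    X_red = np.ones((len(accs), 1))
    return group_idx, X_full, X_red


def fit_de_gene(
    y: np.ndarray,
    samples: SampleTable,
    assignment: SubspeciesAssignment,
    columns=None,
) -> DivergenceResult:
    """ML mixed-model LRT of the subspecies effect for one gene."""
    columns = samples.sample_ids if columns is None else columns
    group_idx, X_full, X_red = _design(samples, assignment, columns)
    try:
        full = lmm.fit_one_way(y, group_idx, X_full, reml=False)
        red = lmm.fit_one_way(y, group_idx, X_red, reml=False)
        stat = max(2.0 * (full.loglik - red.loglik), 0.0)
        p = float(stats.chi2.sf(stat, df=1))
        beta = float(full.beta[1])
    except (np.linalg.LinAlgError, FloatingPointError):
        return DivergenceResult("", "DE", np.nan, np.nan, np.nan, np.nan, "none")
    direction = "higher_in_J" if beta > 0 else ("higher_in_I" if beta < 0 else "none")
    return DivergenceResult("", "DE", beta, float(full.beta[0]), stat, p, direction)


def encode_pav(
    counts: CountTable,
    threshold: int = 10,
    lower: float = 0.20,
    upper: float = 0.80,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary expressed coding and the candidate band filter.

    A sample expresses a gene when its read count >= threshold; candidates
    are genes expressed in a fraction of samples within [lower, upper].
    """
    binary = (counts.counts >= threshold).astype(np.int8)
    frac = binary.mean(axis=1)
    candidates = (frac >= lower) & (frac <= upper)
    return binary, candidates


def fit_pav_gene(
    b: np.ndarray,
    samples: SampleTable,
    assignment: SubspeciesAssignment,
    columns=None,
    n_nodes: int = 9,
) -> DivergenceResult:
    """Penalized logistic mixed-model LRT of subspecies for one PAV gene."""
    columns = samples.sample_ids if columns is None else columns
    group_idx, X_full, X_red = _design(samples, assignment, columns)
    stat, full, _ = glmm.logistic_ri_lrt(
        b, group_idx, X_full, X_red, n_nodes=n_nodes
    )
    p = float(stats.chi2.sf(stat, df=1))
    beta = float(full.beta[1])
    direction = "higher_in_J" if beta > 0 else ("higher_in_I" if beta < 0 else "none")
    return DivergenceResult("", "PAV", beta, float(full.beta[0]), stat, p, direction)


def run_de(
    expr_values: np.ndarray,
    gene_ids,
    samples: SampleTable,
    assignment: SubspeciesAssignment,
    fdr: float = 0.001,
    columns=None,
) -> pd.DataFrame:
    """DE LRT for every row of an INT-transformed expression matrix."""
    rows = []
    for gid, y in zip(gene_ids, expr_values):
        r = fit_de_gene(y, samples, assignment, columns)
        rows.append((gid, r.beta, r.intercept, r.lrt, r.p, r.direction))
    df = pd.DataFrame(
        rows, columns=["gene_id", "beta", "intercept", "lrt", "p", "direction"]
    )
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] <= fdr
    return df


def run_pav(
    counts: CountTable,
    samples: SampleTable,
    assignment: SubspeciesAssignment,
    threshold: int = 10,
    lower: float = 0.20,
    upper: float = 0.80,
    fdr: float = 0.001,
) -> pd.DataFrame:
    """Band-filter and logistic LRT for presence-absence candidates."""
    binary, cand = encode_pav(counts, threshold, lower, upper)
    rows = []
    for gi in np.flatnonzero(cand):
        r = fit_pav_gene(binary[gi], samples, assignment)
        rows.append((counts.genes[gi], r.beta, r.intercept, r.lrt, r.p, r.direction))
    df = pd.DataFrame(
        rows, columns=["gene_id", "beta", "intercept", "lrt", "p", "direction"]
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] <= fdr
    else:
        df["q"] = []
        df["significant"] = []
    return df
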