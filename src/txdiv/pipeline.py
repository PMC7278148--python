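"""End-to-end orchestration: simulate/load -> preprocess -> divergence ->
diversity -> heritability -> delta-h -> eQTL -> selection scan.

Every stage is also callable on its own; this module just wires the
default path and writes the result tables. All randomness derives from one
seed, so a fixed seed reproduces every table bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import divergence, diversity, eqtl, heritability, preprocess, selection
from .dataio import Dataset, write_results

__all__ = ["run_pipeline"]


def _anchor_labels(dataset: Dataset) -> dict:
    """One anchor accession per subspecies from sample metadata."""
    t = dataset.samples.table
    if "subspecies" not in t.columns:
        raise ValueError("sample metadata has no subspecies column; pass anchors")
    anchors = {}
    for lab in ("I", "J"):
        sub = t[t["subspecies"] == lab]
        if len(sub) == 0:
            raise ValueError(f"no anchor available for subspecies {lab}")
        anchors[sub["accession_id"].iloc[0]] = lab
    return anchors


def run_pipeline(
    dataset: Dataset,
    seed: int = 0,
    out_dir=None,
    anchors: dict | None = None,
    min_count: int = 10,
    min_frac: float = 0.20,
    pca_maf: float = 0.10,
    n_pcs: int = 4,
    fdr_divergence: float = 0.001,
    fdr_h2: float = 0.001,
    fdr_eqtl: float = 0.05,
    rlrt_B: int = 10_000,
    delta_B: int = 100,
    eqtl_B: int = 1000,
    eqtl_window: int = 100_000,
    eqtl_maf: float = 0.10,
    eqtl_prefilter: bool = True,
    pp_threshold: float = 0.5,
    scan_radius: int = 100_000,
    chromosome_lengths: dict | None = None,
    force: bool = False,
) -> dict:
    """Run the full analysis; returns a dict of result DataFrames.

    With ``eqtl_prefilter`` the cis scan is restricted to genes whose
    broad-sense H2 is significant in at least one subspecies.
    """
    rng_seed = np.random.default_rng(seed)
    counts, samples, genes, genotypes = (
        dataset.counts, dataset.samples, dataset.genes, dataset.genotypes,
    )
    # canonical accession order = genotype order
    sampled = set(samples.table["accession_id"])
    accs = [a for a in genotypes.accessions if a in sampled]
    results: dict = {}

    # --- preprocess ---------------------------------------------------
    keep = preprocess.filter_expressed(counts, min_count, min_frac)
    counts_f = counts.subset_genes(keep)
    expr = preprocess.normalize_vst(counts_f)
    int_rng = np.random.default_rng([seed, 101])
    expr_int = preprocess.ExpressionMatrix(
        expr.genes, expr.columns,
        preprocess.inverse_normal_transform(expr.values, int_rng),
        "int", expr.size_factors,
    )
    pca = preprocess.genotype_pca(genotypes, maf_min=pca_maf, k=n_pcs)
    assignment = preprocess.classify_subspecies(
        pca, anchors or _anchor_labels(dataset)
    )
    is_I = assignment.mask(genotypes.accessions, "I")
    results["assignment"] = pd.DataFrame(
        {"accession_id": list(assignment.labels),
         "subspecies": list(assignment.labels.values())}
    )

    # --- divergence ---------------------------------------------------
    results["de"] = divergence.run_de(
        expr_int.values, expr_int.genes, samples, assignment, fdr_divergence
    )
    results["pav"] = divergence.run_pav(
        counts, samples, assignment, min_count, fdr=fdr_divergence
    )

    # --- diversity ----------------------------------------------------
    group_rows = {
        "I": np.flatnonzero(is_I),
        "J": np.flatnonzero(~is_I),
    }
    sites = diversity.group_pi(
        genotypes, group_rows, maf_min=0.05, equalize=True, seed=seed
    )
    results["site_pi"] = sites
    results["pi_comparison"] = pd.DataFrame(
        [diversity.compare_group_pi(sites, "I", "J")]
    )
    # CV on accession-averaged normalized counts (unlogged scale)
    norm = counts_f.counts / expr.size_factors[None, :]
    acc_index = {a: i for i, a in enumerate(accs)}
    col_group = np.array([acc_index[samples.accession_of[s]] for s in counts_f.samples])
    acc_norm = np.zeros((norm.shape[0], len(accs)))
    for g in range(len(accs)):
        acc_norm[:, g] = norm[:, col_group == g].mean(axis=1)
    acc_is_I = assignment.mask(accs, "I")
    results["cv"] = diversity.expression_cv(
        acc_norm, counts_f.genes,
        {"I": np.flatnonzero(acc_is_I), "J": np.flatnonzero(~acc_is_I)},
    )

    # --- heritability -------------------------------------------------
    results["h2_broad"] = heritability.run_broad_h2(
        expr_int.values, expr_int.genes, samples,
        B=rlrt_B, seed=int(rng_seed.integers(2**31)), fdr=fdr_h2,
    )
    blup = preprocess.accession_blup(expr_int, samples)
    blup_int = preprocess.inverse_normal_transform(
        blup.values, np.random.default_rng([seed, 102])
    )
    blup_cols = [blup.columns.index(a) for a in genotypes.accessions]
    expr_acc = blup_int[:, blup_cols]  # aligned to genotype accession order
    grm = heritability.build_grm(genotypes)
    results["h2_narrow"] = heritability.run_narrow_h2(
        expr_acc, expr_int.genes, grm, fdr=fdr_h2
    )

    # --- within-subspecies heritability + permutation delta ------------
    scopes = heritability.within_subspecies_scopes(samples, assignment, seed=seed)
    rep_group_of = np.array(
        [acc_index[samples.accession_of[s]] for s in expr_int.columns]
    )
    within = {}
    gt_acc_index = {a: i for i, a in enumerate(genotypes.accessions)}
    for scope, members in scopes.items():
        member_set = set(members)
        scol = np.array(
            [samples.accession_of[s] in member_set for s in expr_int.columns]
        )
        # per-subspecies expression re-filter
        keep_s = (counts_f.counts[:, scol] >= min_count).sum(axis=1) >= np.ceil(
            min_frac * scol.sum()
        )
        h_broad = np.full(len(expr_int.genes), np.nan)
        sub_groups = rep_group_of[scol]
        remap = {g: i for i, g in enumerate(np.unique(sub_groups))}
        gidx = np.array([remap[g] for g in sub_groups])
        rows_keep = np.flatnonzero(keep_s)
        sizes = np.bincount(gidx)
        if rows_keep.size:
            Yb = expr_int.values[np.ix_(rows_keep, np.flatnonzero(scol))]
            if np.all(sizes == sizes[0]) and sizes[0] >= 2:
                h_broad[rows_keep] = heritability.lmm.balanced_one_way_reml_many(
                    Yb, gidx
                )[2]
            else:
                h_broad[rows_keep] = [
                    heritability.lmm.fit_one_way(y, gidx, reml=True).h2 for y in Yb
                ]
        rows_g = np.array([gt_acc_index[a] for a in members])
        grm_s = heritability.build_grm(genotypes, rows=rows_g)
        eig = heritability.lmm.GrmEigen(grm_s.G)
        h_narrow = np.full(len(expr_int.genes), np.nan)
        if rows_keep.size:
            h_narrow[rows_keep] = eig.fit_many(
                expr_acc[np.ix_(rows_keep, rows_g)]
            )[0]
        within[scope] = pd.DataFrame(
            {"gene_id": expr_int.genes, "scope": scope,
             "H2": h_broad, "h2": h_narrow}
        )
    results["h2_within"] = pd.concat(within.values(), ignore_index=True)

    both = ~(np.isnan(within["I"]["H2"]) | np.isnan(within["J"]["H2"]))
    gene_sub = np.flatnonzero(both.to_numpy())
    m = min(len(scopes["I"]), len(scopes["J"]))
    delta_broad = (
        within["J"]["H2"].to_numpy()[gene_sub]
        - within["I"]["H2"].to_numpy()[gene_sub]
    )
    results["delta_h_broad"] = heritability.delta_h_permutation(
        [expr_int.genes[i] for i in gene_sub], delta_broad, "broad",
        accessions=accs, B=delta_B, seed=int(rng_seed.integers(2**31)),
        group_size=m,
        expr_rep=expr_int.values[gene_sub], rep_group_of=rep_group_of,
    )
    delta_narrow = (
        within["J"]["h2"].to_numpy()[gene_sub]
        - within["I"]["h2"].to_numpy()[gene_sub]
    )
    results["delta_h_narrow"] = heritability.delta_h_permutation(
        [expr_int.genes[i] for i in gene_sub], delta_narrow, "narrow",
        accessions=genotypes.accessions, B=delta_B,
        seed=int(rng_seed.integers(2**31)), group_size=m,
        expr_acc=expr_acc[gene_sub], genotypes=genotypes,
    )

    # --- joint cis-eQTL -----------------------------------------------
    if eqtl_prefilter:
        q_b = results["h2_broad"]["q"].to_numpy()
        # significant across-panel H2 as the heritability pre-filter
        eqtl_rows = np.flatnonzero(q_b <= fdr_h2)
        if eqtl_rows.size == 0:
            eqtl_rows = np.arange(len(expr_int.genes))
    else:
        eqtl_rows = np.arange(len(expr_int.genes))
    covariates = pca.scores[:, :n_pcs]
    calls, hyper, bf = eqtl.run_eqtl(
        expr_acc[eqtl_rows],
        [expr_int.genes[i] for i in eqtl_rows],
        genes, genotypes, is_I, covariates,
        window=eqtl_window, maf_min=eqtl_maf, B=eqtl_B,
        seed=int(rng_seed.integers(2**31)), fdr=fdr_eqtl,
        pp_threshold=pp_threshold,
    )
    results["eqtl_calls"] = calls
    results["eqtl_hyperparams"] = pd.DataFrame(
        {"pi0": [hyper.pi0],
         "w_indica_specific": [hyper.w[0]],
         "w_japonica_specific": [hyper.w[1]],
         "w_shared": [hyper.w[2]]}
    )

    # --- selection scan -----------------------------------------------
    if (calls["call"] != "none").sum() >= 2:
        summary, flagged, background = selection.run_selection_scan(
            calls, genotypes, group_rows, chromosome_lengths,
            radius=scan_radius,
        )
        results["selection_summary"] = summary
        results["selection_flags"] = flagged
        results["background_window_pi"] = background
    else:
        results["selection_summary"] = pd.DataFrame()
        results["selection_flags"] = pd.DataFrame()

    if out_dir is not None:
        write_results(results, out_dir, force=force)
    return results
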