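"""Cis candidates, association stats, Bayes factors, EM, posteriors,
permutation FDR and configuration calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import logsumexp

from txdiv import eqtl, preprocess, simulate
from txdiv.dataio import GeneTable

from conftest import toy_genotypes


class TestCisCandidates:
    def _setup(self):
        pos = np.array([1_000, 50_000, 101_000, 150_000, 201_001, 250_000])
        d = np.random.default_rng(0).binomial(1, 0.5, size=(30, 6)).astype(float)
        gt = toy_genotypes(d)
        gt.snps["pos"] = pos
        gene = pd.Series({"gene_id": "g", "chrom": "chr1", "tss": 101_000})
        return gt, gene

    def test_closed_boundary(self):
        gt, gene = self._setup()
        idx = eqtl.cis_candidates(gene, gt, window=100_000, maf_min=0.0)
        # 201_001 - 101_000 = 100_001 > window -> out; 1_000 at 100_000 -> in
        assert 0 in idx and 4 not in idx

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(1, rng.uniform(0.02, 0.5, 80), size=(40, 80)).astype(float)
        gt = toy_genotypes(d)
        gt.snps["pos"] = np.sort(rng.choice(2_000_000, 80, replace=False)) + 1
        gene = pd.Series({"gene_id": "g", "chrom": "chr1", "tss": 900_000})
        idx = eqtl.cis_candidates(gene, gt, window=100_000, maf_min=0.1)
        maf = gt.maf()
        want = [j for j in range(80)
                if abs(gt.snps["pos"][j] - 900_000) <= 100_000 and maf[j] >= 0.1]
        assert idx.tolist() == want


class TestAssoc:
    def test_null_z_standard_normal(self):
        rng = np.random.default_rng(2)
        zs = []
        C = np.ones((60, 1))
        for _ in range(500):
            y = rng.normal(size=60)
            x = rng.binomial(1, 0.4, size=(60, 1)).astype(float)
            _, _, z, ok = eqtl.subspecies_assoc(y, x, C)
            if ok[0]:
                zs.append(z[0])
        assert stats.kstest(zs, "norm").pvalue > 0.01

    def test_duplication_scales_se(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        x = rng.binomial(1, 0.5, size=(40, 1)).astype(float)
        C = np.ones((40, 1))
        _, se1, _, _ = eqtl.subspecies_assoc(y, x, C)
        y2, x2 = np.tile(y, 2), np.tile(x, (2, 1))
        _, se2, _, _ = eqtl.subspecies_assoc(y2, x2, np.ones((80, 1)))
        assert se2[0] / se1[0] == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_degenerate_exact_fit_flagged(self):
        x = np.arange(20, dtype=float)[:, None]
        y = x[:, 0].copy()
        _, _, _, ok = eqtl.subspecies_assoc(y, x, np.ones((20, 0)))
        assert not ok[0]

    def test_constant_snp_flagged(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=30)
        x = np.ones((30, 1))
        _, _, _, ok = eqtl.subspecies_assoc(y, x, np.ones((30, 1)))
        assert not ok[0]


class TestAbf:
    def test_point_null_prior_gives_unit_bf(self):
        assert eqtl.log_abf(3.7, 1.0, 0.0) == pytest.approx(0.0)

    def test_closed_form_matches_numerical_integration(self):
        # BF = m1(beta_hat)/m0(beta_hat) with beta_hat ~ N(b, V), b ~ N(0, W)
        for z, V, W in [(0.0, 1.0, 1.0), (3.0, 1.0, 1.0), (2.0, 0.25, 0.64)]:
            beta_hat = z * np.sqrt(V)
            m1 = quad(
                lambda b: stats.norm.pdf(beta_hat, b, np.sqrt(V))
                * stats.norm.pdf(b, 0, np.sqrt(W)),
                -30, 30,
            )[0]
            m0 = stats.norm.pdf(beta_hat, 0, np.sqrt(V))
            want = np.log(m1 / m0)
            assert eqtl.log_abf(z, V, W) == pytest.approx(want, abs=1e-8)

    def test_worked_values(self):
        assert np.exp(eqtl.log_abf(0.0, 1.0, 1.0)) == pytest.approx(
            np.sqrt(0.5), abs=1e-12
        )
        assert np.exp(eqtl.log_abf(3.0, 1.0, 1.0)) == pytest.approx(
            np.sqrt(0.5) * np.exp(2.25), rel=1e-12
        )

    def test_log_space_agrees_with_direct(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 2, 100)
        V = rng.uniform(0.05, 2, 100)
        lb = eqtl.log_abf_grid(z, V)
        direct = np.log(
            np.mean(
                [np.sqrt(V / (V + W)) * np.exp(z**2 * W / (2 * (V + W)))
                 for W in eqtl.GRID_W],
                axis=0,
            )
        )
        np.testing.assert_allclose(lb, direct, rtol=1e-10)

    def test_config_bf_products(self):
        lb = eqtl.config_log_bf(np.log(5.0), np.log(2.0))
        np.testing.assert_allclose(np.exp(lb), [5.0, 2.0, 10.0])
        lb1 = eqtl.config_log_bf(np.log(5.0), 0.0)
        assert np.exp(lb1)[2] == pytest.approx(np.exp(lb1)[0])
        np.testing.assert_allclose(eqtl.config_log_bf(0.0, 0.0), 0.0)


def _toy_bf_tensor(rng, n_genes=300, n_snps=5, signal=None):
    """BF tensor with optional per-gene signal ('I', 'J', 'both', None)."""
    gene_ids, snp_idx, log_bf = [], [], []
    for g in range(n_genes):
        gene_ids.append(f"g{g}")
        snp_idx.append(np.arange(n_snps))
        zI = rng.normal(size=n_snps)
        zJ = rng.normal(size=n_snps)
        kind = signal(g) if signal else None
        s = rng.integers(n_snps)
        if kind in ("I", "both"):
            zI[s] = rng.normal(5, 1)
        if kind in ("J", "both"):
            zJ[s] = rng.normal(5, 1)
        lbI = eqtl.log_abf_grid(zI, np.full(n_snps, 1.0))
        lbJ = eqtl.log_abf_grid(zJ, np.full(n_snps, 1.0))
        log_bf.append(eqtl.config_log_bf(lbI, lbJ))
    return eqtl.BfTensor(gene_ids, snp_idx, log_bf)


class TestEm:
    def test_loglik_monotone(self):
        rng = np.random.default_rng(6)
        bf = _toy_bf_tensor(rng, signal=lambda g: "I" if g % 3 == 0 else None)
        hyper = eqtl.em_hyperparams(bf)
        assert np.all(np.diff(hyper.loglik_trace) >= -1e-8)
        assert hyper.w.sum() == pytest.approx(1.0)

    def test_all_null_recovers_high_pi0(self):
        rng = np.random.default_rng(7)
        bf = _toy_bf_tensor(rng, signal=None)
        hyper = eqtl.em_hyperparams(bf)
        assert hyper.pi0 >= 0.8

    def test_config_weight_recovery(self):
        rng = np.random.default_rng(8)
        bf = _toy_bf_tensor(rng, signal=lambda g: "I" if g % 2 == 0 else None)
        hyper = eqtl.em_hyperparams(bf)
        assert np.argmax(hyper.w) == 0  # indica-specific dominates

    def test_flat_bfs_flagged_nonidentifiable(self):
        bf = eqtl.BfTensor(["g0"], [np.arange(3)], [np.zeros((3, 3))])
        hyper = eqtl.em_hyperparams(bf)
        assert not hyper.identifiable


class TestPosteriors:
    def test_config_pps_sum_to_one(self):
        rng = np.random.default_rng(9)
        bf = _toy_bf_tensor(rng, n_genes=20, signal=lambda g: "both")
        hyper = eqtl.em_hyperparams(bf)
        post = eqtl.compute_posteriors(bf, hyper)
        s = post[["pp_indica_specific", "pp_japonica_specific", "pp_shared"]].sum(axis=1)
        np.testing.assert_allclose(s, 1.0, atol=1e-8)

    def test_pi0_to_one_kills_pp(self):
        rng = np.random.default_rng(10)
        bf = _toy_bf_tensor(rng, n_genes=10, signal=lambda g: "I")
        hyper = eqtl.HyperParams(1.0 - 1e-12, np.full(3, 1 / 3), np.array([]))
        post = eqtl.compute_posteriors(bf, hyper)
        assert (post["pp_gene"] < 1e-3).all()

    def test_single_snp_shared_toy_hand_evaluation(self):
        lb = eqtl.config_log_bf(np.log(50.0), np.log(40.0))[None, :]
        bf = eqtl.BfTensor(["g"], [np.array([0])], [lb])
        w = np.array([0.2, 0.2, 0.6])
        hyper = eqtl.HyperParams(0.5, w, np.array([]))
        post = eqtl.compute_posteriors(bf, hyper)
        want = w * np.array([50.0, 40.0, 2000.0])
        want = want / want.sum()
        assert post["pp_shared"].iloc[0] == pytest.approx(want[2], abs=1e-10)
        assert post["pp_shared"].iloc[0] > 0.5
        # PP_gene = (1-pi0)A / (pi0 + (1-pi0)A), A = sum_c w_c BF_c
        A = float(np.sum(w * np.array([50.0, 40.0, 2000.0])))
        assert post["pp_gene"].iloc[0] == pytest.approx(
            0.5 * A / (0.5 + 0.5 * A), abs=1e-10
        )


def _joint_panel(seed=42, n_genes=120, mix=None):
    mix = mix or {"null": 0.25, "eqtl_I": 0.25, "eqtl_J": 0.25, "eqtl_both": 0.25}
    cfg = simulate.SimulationConfig(
        n_accessions_per_pop=(35, 56), n_snps=6000, n_genes=n_genes,
        chromosome_lengths={f"chr{i}": 4_000_000 for i in (1, 2, 3)},
        architecture_mix=mix, seed=seed,
    )
    ds, archs = simulate.simulate_dataset(cfg)
    expr = preprocess.normalize_vst(ds.counts)
    y_int = preprocess.inverse_normal_transform(expr.values, 1)
    em = preprocess.ExpressionMatrix(expr.genes, expr.columns, y_int, "int")
    blup = preprocess.accession_blup(em, ds.samples)
    expr_acc = preprocess.inverse_normal_transform(blup.values, 2)
    pca = preprocess.genotype_pca(ds.genotypes)
    is_I = cfg.pop_labels() == "I"
    return ds, archs, expr_acc, pca.scores[:, :4], is_I


class TestJointScan:
    def test_configuration_recovery(self):
        ds, archs, expr_acc, covs, is_I = _joint_panel()
        calls, hyper, bf = eqtl.run_eqtl(
            expr_acc, [a.gene_id for a in archs], ds.genes, ds.genotypes,
            is_I, covs, B=300, seed=3,
        )
        truth = {a.gene_id: a.gene_class for a in archs}
        name = {"eqtl_I": "indica_specific", "eqtl_J": "japonica_specific",
                "eqtl_both": "shared"}
        called = calls[calls["call"] != "none"]
        correct = sum(
            name.get(truth[r.gene_id]) == r.call
            for r in called.itertuples(index=False)
        )
        assert len(called) >= 10
        assert correct / len(called) >= 0.8
        # EM monotone and pi0 near the simulated null fraction
        assert np.all(np.diff(hyper.loglik_trace) >= -1e-8)

    def test_null_panel_fdr_and_negative_control(self):
        ds, archs, expr_acc, covs, is_I = _joint_panel(
            seed=43, n_genes=100, mix={"null": 1.0}
        )
        calls, hyper, _ = eqtl.run_eqtl(
            expr_acc, [a.gene_id for a in archs], ds.genes, ds.genotypes,
            is_I, covs, B=200, seed=4,
        )
        assert (calls["call"] != "none").mean() <= 0.07
        assert hyper.pi0 >= 0.7

    def test_single_subspecies_degrades_gracefully(self):
        ds, archs, expr_acc, covs, is_I = _joint_panel(
            seed=44, n_genes=30, mix={"eqtl_both": 1.0}
        )
        calls, hyper, bf = eqtl.run_eqtl(
            expr_acc, [a.gene_id for a in archs], ds.genes, ds.genotypes,
            np.ones_like(is_I, dtype=bool), covs, B=100, seed=5,
        )
        # J side carries no data: BF_J = 1, so calls reduce to a
        # single-population cis scan (no japonica-specific evidence)
        assert (calls["call"] != "japonica_specific").all()

    def test_permutation_pvalues_reproducible(self):
        ds, archs, expr_acc, covs, is_I = _joint_panel(seed=45, n_genes=20)
        args = (expr_acc, [a.gene_id for a in archs], ds.genes, ds.genotypes,
                is_I, covs)
        c1, _, _ = eqtl.run_eqtl(*args, B=100, seed=6)
        c2, _, _ = eqtl.run_eqtl(*args, B=100, seed=6)
        pd.testing.assert_frame_equal(c1, c2)
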