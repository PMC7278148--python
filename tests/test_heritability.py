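"""GRM construction, variance components, RLRT null, permutation delta."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txdiv import heritability, lmm, simulate
from txdiv.dataio import GenotypeTable, SampleTable


from conftest import toy_genotypes


class TestGrm:
    def test_two_accession_worked_example(self):
        gt = toy_genotypes([[0], [1]])
        grm = heritability.build_grm(gt)
        np.testing.assert_allclose(grm.G, [[1, -1], [-1, 1]], atol=1e-12)

    def test_mean_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        gt = toy_genotypes(rng.binomial(1, 0.3, size=(12, 200)))
        grm = heritability.build_grm(gt)
        assert np.mean(np.diag(grm.G)) == pytest.approx(1.0, abs=1e-10)

    def test_allele_coding_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(1, 0.4, size=(10, 50)).astype(float)
        flip = d.copy()
        flip[:, ::2] = 1 - flip[:, ::2]
        g1 = heritability.build_grm(toy_genotypes(d)).G
        g2 = heritability.build_grm(toy_genotypes(flip)).G
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValueError):
            heritability.build_grm(toy_genotypes(np.ones((5, 10))))


class TestBroadH2:
    def test_no_residual_variance_gives_h2_one(self):
        stat, fit = heritability.fit_broad_h2(
            np.array([0.0, 0.0, 10.0, 10.0]), np.array([0, 0, 1, 1])
        )
        assert fit.h2 > 0.999

    def test_null_mean_h2_small(self):
        rng = np.random.default_rng(2)
        gidx = np.repeat(np.arange(40), 2)
        Y = rng.normal(size=(200, 80))
        h2 = lmm.balanced_one_way_reml_many(Y, gidx)[2]
        assert h2.mean() < 0.15

    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        gidx = np.repeat(np.arange(40), 2)
        u = rng.normal(0, 1, size=(200, 40))
        Y = np.repeat(u, 2, axis=1) + rng.normal(0, 1, size=(200, 80))
        h2 = lmm.balanced_one_way_reml_many(Y, gidx)[2]
        assert h2.mean() == pytest.approx(0.5, abs=0.05)

    def test_single_replicate_errors(self):
        with pytest.raises(ValueError):
            heritability.fit_broad_h2(np.array([1.0, 2.0]), np.array([0, 1]))


class TestRlrtNull:
    def test_zero_statistic_p_near_one(self):
        null = lmm.rlrt_null_distribution(np.full(30, 2), B=500, seed=0)
        p = heritability.rlrt_pvalues(np.array([0.0]), null)
        assert p[0] > 0.4  # boundary point mass makes p large

    def test_point_mass_at_zero_about_half(self):
        null = lmm.rlrt_null_distribution(np.full(40, 2), B=5000, seed=1)
        frac0 = np.mean(null < 1e-10)
        assert 0.35 <= frac0 <= 0.65

    def test_calibration(self):
        null = lmm.rlrt_null_distribution(np.full(35, 2), B=10_000, seed=2)
        rng = np.random.default_rng(3)
        gidx = np.repeat(np.arange(35), 2)
        Y = rng.normal(size=(600, 70))
        obs = lmm.balanced_one_way_reml_many(Y, gidx)[3]
        p = heritability.rlrt_pvalues(obs, null)
        assert 0.03 <= np.mean(p < 0.05) <= 0.07

    def test_unbalanced_design_falls_back(self):
        null = lmm.rlrt_null_distribution(np.array([2, 2, 3, 2, 4]), B=50, seed=4)
        assert null.shape == (50,) and np.all(null >= 0)


def simulated_grm(n=200, m=2000, seed=5):
    """GRM from a structured two-subspecies panel (the estimator needs
    eigenvalue dispersion, which real panels supply via population and
    subpopulation structure)."""
    cfg = simulate.SimulationConfig(
        n_accessions_per_pop=(n // 2, n - n // 2), n_snps=m, n_genes=1,
        seed=seed,
    )
    gt = simulate.simulate_genotypes(cfg)
    return heritability.build_grm(gt), gt


class TestNarrowH2:
    def test_reml_matches_dense_gls_oracle(self):
        """Brute-force dense profiled likelihood on a small toy."""
        rng = np.random.default_rng(6)
        n = 10
        Z = rng.binomial(1, 0.5, size=(n, 30)).astype(float)
        grm = heritability.build_grm(toy_genotypes(Z))
        eig = lmm.GrmEigen(grm.G)
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        for lam in [0.01, 0.5, 2.0, 10.0]:
            V = lam * grm.G + np.eye(n)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            Q = float(r @ Vi @ r)
            df = n - 1
            s2 = Q / df
            m2_dense = (
                df * (np.log(2 * np.pi * s2) + 1.0)
                + np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XtViX / s2)[1] + np.log(s2)
            )
            m2_ours = eig._m2ll(np.log(lam), eig.U.T @ y, reml=True)[0]
            assert m2_ours == pytest.approx(m2_dense, abs=1e-6)

    def test_h2_recovery(self):
        grm, _ = simulated_grm()
        rng = np.random.default_rng(7)
        eig_vals, eig_vecs = np.linalg.eigh(grm.G)
        eig_vals = np.maximum(eig_vals, 0)
        n = grm.G.shape[0]
        eig = lmm.GrmEigen(grm.G)
        for true_h2 in (0.2, 0.5, 0.8):
            # exact model draw: y ~ N(0, h2*G + (1-h2)*I)
            g = eig_vecs @ (
                np.sqrt(eig_vals)[:, None] * rng.normal(size=(n, 50))
            )
            Y = (np.sqrt(true_h2) * g
                 + rng.normal(0, np.sqrt(1 - true_h2), size=(n, 50))).T
            h2 = eig.fit_many(Y)[0]
            assert h2.mean() == pytest.approx(true_h2, abs=0.08)

    def test_null_calibration(self):
        grm, _ = simulated_grm(n=150, m=1000, seed=8)
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(200, 150))
        h2, _, _, lrt = lmm.GrmEigen(grm.G).fit_many(Y)
        p = np.where(lrt > 0, 0.5 * stats.chi2.sf(lrt, df=1), 1.0)
        assert h2.mean() < 0.15
        assert np.mean(p < 0.05) <= 0.07

    def test_top_eigenvector_boundary(self):
        grm, _ = simulated_grm(n=80, m=500, seed=10)
        vals, vecs = np.linalg.eigh(grm.G)
        y = vecs[:, -1] * np.sqrt(vals[-1])
        fit = lmm.GrmEigen(grm.G).fit(y)
        assert fit.h2 >= 0.99


class TestWithinSubspecies:
    def test_equal_sizes_no_subsampling(self):
        st = SampleTable(pd.DataFrame({
            "sample_id": [f"a{i}_r{j}" for i in range(6) for j in range(2)],
            "accession_id": [f"a{i}" for i in range(6) for _ in range(2)],
            "replicate": [1, 2] * 6,
        }))
        from txdiv.preprocess import SubspeciesAssignment

        asg = SubspeciesAssignment({f"a{i}": ("I" if i < 3 else "J") for i in range(6)})
        scopes = heritability.within_subspecies_scopes(st, asg, seed=0)
        assert sorted(scopes["I"]) == ["a0", "a1", "a2"]
        assert sorted(scopes["J"]) == ["a3", "a4", "a5"]

    def test_seeded_subsampling_repeats(self):
        st = SampleTable(pd.DataFrame({
            "sample_id": [f"a{i}_r1" for i in range(10)],
            "accession_id": [f"a{i}" for i in range(10)],
            "replicate": [1] * 10,
        }))
        from txdiv.preprocess import SubspeciesAssignment

        asg = SubspeciesAssignment({f"a{i}": ("I" if i < 3 else "J") for i in range(10)})
        s1 = heritability.within_subspecies_scopes(st, asg, seed=5)
        s2 = heritability.within_subspecies_scopes(st, asg, seed=5)
        assert s1 == s2
        assert len(s1["J"]) == 3

    def test_subspecies_specific_heritability_recovered(self):
        """Genes with a cis effect active in I only are significant (broad
        sense, simulated-null RLRT) within I and not within J."""
        from txdiv import preprocess

        n = 35
        cfg = simulate.SimulationConfig(
            n_accessions_per_pop=(n, n), n_snps=3000, n_genes=50,
            architecture_mix={"eqtl_I": 1.0}, seed=31,
        )
        ds, archs = simulate.simulate_dataset(cfg)
        expr = preprocess.normalize_vst(ds.counts)
        y = preprocess.inverse_normal_transform(expr.values, 0)
        labels = np.repeat(cfg.pop_labels(), cfg.n_replicates)
        gidx = np.repeat(np.arange(n), cfg.n_replicates)
        null = lmm.rlrt_null_distribution(np.full(n, 2), B=2000, seed=1)
        ok = 0
        for gi in range(len(archs)):
            ps = {}
            for scope in ("I", "J"):
                stat = lmm.balanced_one_way_reml_many(
                    y[gi, labels == scope][None, :], gidx
                )[3][0]
                ps[scope] = heritability.rlrt_pvalues(np.array([stat]), null)[0]
            ok += (ps["I"] < 0.05) and (ps["J"] >= 0.05)
        assert ok / len(archs) >= 0.8


class TestDeltaPermutation:
    def test_zero_delta_p_one(self):
        rng = np.random.default_rng(12)
        gidx = np.repeat(np.arange(20), 2)
        Y = rng.normal(size=(3, 40))
        out = heritability.delta_h_permutation(
            ["g0", "g1", "g2"], np.zeros(3), "broad",
            accessions=[f"a{i}" for i in range(20)], B=20, seed=0,
            group_size=10, expr_rep=Y, rep_group_of=gidx,
        )
        assert (out["p"] == 1.0).all()

    def test_null_calibration(self):
        rng = np.random.default_rng(13)
        n_acc, G = 40, 150
        gidx = np.repeat(np.arange(n_acc), 2)
        u = rng.normal(0, 0.7, size=(G, n_acc))
        Y = np.repeat(u, 2, axis=1) + rng.normal(0, 1, size=(G, 2 * n_acc))
        accs = [f"a{i}" for i in range(n_acc)]
        h_I = heritability._h2_for_accession_set(
            "broad", accs[:20], np.arange(G),
            expr_rep=Y, rep_group_of=gidx, accessions=accs,
        )
        h_J = heritability._h2_for_accession_set(
            "broad", accs[20:], np.arange(G),
            expr_rep=Y, rep_group_of=gidx, accessions=accs,
        )
        out = heritability.delta_h_permutation(
            [f"g{i}" for i in range(G)], h_J - h_I, "broad",
            accessions=accs, B=100, seed=1, group_size=20,
            expr_rep=Y, rep_group_of=gidx,
        )
        rate = np.mean(out["p"] < 0.05)
        assert 0.02 <= rate <= 0.08

    def test_power_for_large_difference(self):
        rng = np.random.default_rng(14)
        n = 35
        accs = [f"a{i}" for i in range(2 * n)]
        gidx = np.repeat(np.arange(2 * n), 2)
        hits, runs = 0, 20
        for run in range(runs):
            u = np.concatenate([rng.normal(0, 2, n), np.zeros(n)])
            Y = (np.repeat(u, 2) + rng.normal(0, 1, 4 * n))[None, :]
            h_I = heritability._h2_for_accession_set(
                "broad", accs[:n], np.array([0]),
                expr_rep=Y, rep_group_of=gidx, accessions=accs)
            h_J = heritability._h2_for_accession_set(
                "broad", accs[n:], np.array([0]),
                expr_rep=Y, rep_group_of=gidx, accessions=accs)
            out = heritability.delta_h_permutation(
                ["g0"], h_J - h_I, "broad", accessions=accs, B=100,
                seed=run, group_size=n, expr_rep=Y, rep_group_of=gidx,
            )
            hits += out["p"].iloc[0] <= 0.02
        assert hits / runs >= 0.8

    def test_invalid_B(self):
        with pytest.raises(ValueError):
            heritability.delta_h_permutation(
                ["g"], np.zeros(1), "broad", accessions=["a", "b"], B=0,
            )
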