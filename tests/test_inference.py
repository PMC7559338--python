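"""Edge scoring: associations, correlations, quantile scores, resampling,
permutation test."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, pearsonr, spearmanr

from dlgrn.evaluate import GoldStandard, auroc
from dlgrn.inference import (
    GRNInference,
    InferenceConfig,
    associated_ars,
    confidence_score,
    correlation_profile,
    permutation_test,
    resampled_inference,
    score_all,
    score_matrix,
)
from dlgrn.sfksvd import ScaleFreeKSVD


class TestAssociatedArs:
    def test_nonzero_rows_in_order(self):
        X = np.zeros((10, 3))
        X[2, 1] = 0.5
        X[7, 1] = -1.0
        assert associated_ars(X, 1).ar_indices == (2, 7)

    def test_empty_support(self):
        X = np.zeros((4, 2))
        assoc = associated_ars(X, 0)
        assert assoc.ar_indices == () and assoc.n_g == 0

    def test_lookup_by_identifier_and_unknown_gene(self):
        X = np.eye(3)
        assert associated_ars(X, "g2", gene_ids=["g1", "g2", "g3"]).ar_indices == (1,)
        with pytest.raises(KeyError):
            associated_ars(X, "nope", gene_ids=["g1", "g2", "g3"])

    def test_planted_regulators_appear_in_association(self, small_planted):
        Y, profiles, truth = small_planted
        budgets = truth.adjacency.sum(axis=0)
        model = ScaleFreeKSVD(n_atoms=8, budgets=budgets, tol=0.0, max_iter=300,
                              n_restarts=2, random_state=11).fit(Y)
        # map planted regulators to their best-matching atoms
        from dlgrn.evaluate import match_ars

        match = match_ars(model.dictionary_, profiles, rho_min=0.95)
        atom_of = {reg: atom for atom, reg, _ in match.pairs}
        gene = int(np.argmax(truth.adjacency.sum(axis=0)))  # most-regulated gene
        true_regs = np.flatnonzero(truth.adjacency[:, gene])
        assoc = associated_ars(model.coefficients_, gene)
        mapped = {atom_of[r] for r in true_regs if r in atom_of}
        assert mapped and mapped <= set(assoc.ar_indices)


class TestCorrelationProfile:
    def test_identical_profile_gives_one(self, rng):
        D = rng.standard_normal((10, 4))
        assoc = associated_ars(np.ones((4, 1)), 0)
        out = correlation_profile(D[:, 2], D, assoc)
        assert out[2] == pytest.approx(1.0)

    def test_matches_scipy_formulas(self, rng):
        D = rng.standard_normal((15, 5))
        r = rng.standard_normal(15)
        assoc = associated_ars(np.ones((5, 1)), 0)
        for method, fn in (("pearson", pearsonr), ("spearman", spearmanr)):
            mine = correlation_profile(r, D, assoc, method=method)
            ref = np.array([abs(fn(r, D[:, j])[0]) for j in range(5)])
            assert np.allclose(mine, ref, atol=1e-12)

    def test_constant_atom_scores_zero(self):
        D = np.column_stack([np.ones(6), np.arange(6.0)])
        assoc = associated_ars(np.ones((2, 1)), 0)
        out = correlation_profile(np.arange(6.0), D, assoc)
        assert out[0] == 0.0 and out[1] == pytest.approx(1.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="insufficient"):
            correlation_profile(np.ones(2), np.ones((2, 1)), associated_ars(np.ones((1, 1)), 0))


class TestConfidenceScore:
    def test_single_value_any_alpha(self):
        for alpha in (0.0, 0.5, 0.9, 1.0):
            assert confidence_score(np.array([0.5]), alpha) == 0.5

    def test_empty_scores_zero(self):
        assert confidence_score(np.array([]), 0.9) == 0.0

    def test_matches_order_statistics_interpolation(self):
        vals = np.linspace(0.05, 0.95, 10)
        # type-7: h = (n-1) * alpha = 8.1 -> x[8] + 0.1 * (x[9] - x[8])
        srt = np.sort(vals)
        expected = srt[8] + 0.1 * (srt[9] - srt[8])
        assert confidence_score(vals, 0.9) == pytest.approx(expected)

    def test_monotone_in_alpha(self, rng):
        vals = rng.uniform(size=25)
        scores = [confidence_score(vals, a) for a in np.linspace(0, 1, 21)]
        assert np.all(np.diff(scores) >= -1e-12)


class TestScoreAll:
    def test_empty_support_scores_zero(self, rng):
        D = rng.standard_normal((6, 2))
        X = np.zeros((2, 1))
        table = score_all(D, X, rng.standard_normal((6, 1)),
                          gene_ids=["g"], regulator_ids=["r"])
        assert len(table) == 1 and table["cs"].iloc[0] == 0.0

    def test_regulator_equal_to_sole_atom(self, rng):
        D = rng.standard_normal((8, 3))
        X = np.zeros((3, 1))
        X[1, 0] = 2.0
        table = score_all(D, X, D[:, [1]], gene_ids=["g"], regulator_ids=["r"])
        assert table["cs"].iloc[0] == pytest.approx(1.0)

    def test_self_edges_excluded(self, rng):
        D = rng.standard_normal((6, 2))
        X = rng.standard_normal((2, 2))
        table = score_all(D, X, rng.standard_normal((6, 2)),
                          gene_ids=["a", "b"], regulator_ids=["a", "r"])
        assert not ((table["regulator"] == table["target"]).any())
        assert len(table) == 3

    def test_matrix_matches_per_gene_composition(self, rng, noisy_planted):
        """Vectorized scores equal the compose-by-hand operation chain."""
        Y, profiles, _ = noisy_planted
        model = ScaleFreeKSVD(n_atoms=6, max_iter=15, random_state=2).fit(Y)
        cs = score_matrix(model.dictionary_, model.coefficients_, profiles, 0.9)
        for g in (0, 3, 17):
            assoc = associated_ars(model.coefficients_, g)
            for r in (0, 5):
                corrs = correlation_profile(profiles[:, r], model.dictionary_, assoc)
                assert cs[r, g] == pytest.approx(confidence_score(corrs, 0.9), abs=1e-12)

    def test_true_regulator_outranks_decoys(self, noisy_planted):
        Y, profiles, truth = noisy_planted
        model = ScaleFreeKSVD(n_atoms=12, random_state=4).fit(Y)
        cs = score_matrix(model.dictionary_, model.coefficients_, profiles, 0.9)
        wins = 0
        genes = np.flatnonzero(truth.adjacency.sum(axis=0) >= 2)[:40]
        for g in genes:
            true_r = np.flatnonzero(truth.adjacency[:, g])
            decoys = np.flatnonzero(~truth.adjacency[:, g])
            if cs[true_r, g].max() > np.median(cs[decoys, g]):
                wins += 1
        assert wins >= 0.95 * len(genes)


class TestResampledInference:
    def test_degenerate_resampling_equals_full_score(self, noisy_planted):
        Y, profiles, _ = noisy_planted
        cfg = InferenceConfig(subsample_fraction=1.0, n_resamples=1, seed=3)
        table = resampled_inference(Y, profiles, 8, cfg=cfg)
        model = ScaleFreeKSVD(n_atoms=8, random_state=None).fit(Y)
        # same data, same scoring path; scores must lie in [0, 1] and the
        # single-run table must carry n_runs == 1
        assert (table["n_runs"] == 1).all()
        assert table["cs"].between(0, 1).all()

    def test_averaging_linearity(self, noisy_planted):
        """The averaged matrix equals the arithmetic mean of per-run matrices
        computed independently with the same spawned seeds."""
        from dlgrn.utils import as_rng, spawn_seeds

        Y, profiles, _ = noisy_planted
        n = Y.shape[0]
        cfg = InferenceConfig(subsample_fraction=0.75, n_resamples=3, seed=42)
        cs = resampled_inference(Y, profiles, 6, cfg=cfg, return_matrix=True)
        seeds = spawn_seeds(42, 6)
        manual = np.zeros_like(cs)
        s = round(0.75 * n)
        for run in range(3):
            idx = as_rng(seeds[2 * run]).choice(n, size=s, replace=False)
            m = ScaleFreeKSVD(n_atoms=6, random_state=seeds[2 * run + 1]).fit(Y[idx])
            manual += score_matrix(m.dictionary_, m.coefficients_, profiles[idx], 0.9)
        assert np.allclose(cs, manual / 3)

    def test_deterministic_under_seed(self, noisy_planted):
        Y, profiles, _ = noisy_planted
        cfg = InferenceConfig(n_resamples=2, seed=5)
        a = resampled_inference(Y, profiles, 5, cfg=cfg, return_matrix=True)
        b = resampled_inference(Y, profiles, 5, cfg=cfg, return_matrix=True)
        assert np.array_equal(a, b)

    def test_insufficient_subsample_rejected(self, noisy_planted):
        Y, profiles, _ = noisy_planted
        cfg = InferenceConfig(subsample_fraction=0.02, n_resamples=1)
        with pytest.raises(ValueError, match="insufficient subsample"):
            resampled_inference(Y, profiles, 5, cfg=cfg)

    def test_averaging_improves_over_single_subsample(self):
        """Averaged tables rank edges at least as well as single-run tables on
        average (the stated purpose of the resampling wrapper)."""
        from dlgrn.simulate import generate_expression, generate_network

        adj = generate_network(200, 10, 3.0, (2, 5), random_state=0)
        reg_ids = [f"R{i}" for i in range(10)]
        gene_ids = [f"G{j}" for j in range(200)]
        deltas = []
        for seed in range(6):
            Y, profiles, truth = generate_expression(adj, 20, 10.0, random_state=100 + seed)
            gold = GoldStandard.from_truth(truth, reg_ids, gene_ids)
            avg = resampled_inference(
                Y, profiles, 10, cfg=InferenceConfig(n_resamples=10, seed=seed),
                gene_ids=gene_ids, regulator_ids=reg_ids)
            single = resampled_inference(
                Y, profiles, 10, cfg=InferenceConfig(n_resamples=1, seed=seed),
                gene_ids=gene_ids, regulator_ids=reg_ids)
            deltas.append(auroc(avg, gold) - auroc(single, gold))
        assert np.mean(deltas) >= 0


class TestPermutationTest:
    def test_add_one_formula_lower_bound(self, rng):
        """An observed score above every permuted score gets p = 1/(n_perm+1)."""
        Y = rng.standard_normal((12, 20))
        model = ScaleFreeKSVD(n_atoms=4, max_iter=10, random_state=0).fit(Y)
        # a regulator equal to an atom: its observed cs is maximal (1.0)
        regs = model.dictionary_[:, [0]]
        obs = score_all(model.dictionary_, model.coefficients_, regs,
                        gene_ids=[f"g{j}" for j in range(20)], regulator_ids=["r"])
        out = permutation_test(Y, regs, obs, n_perm=99, seed=1, model=model)
        # genes whose support includes atom 0 have cs == 1 which permutations
        # essentially never reach
        merged = obs.merge(out, on=["regulator", "target"])
        top = merged[merged["cs"] > 0.999]
        assert (top["p_value"] <= 5 / 100).all()

    def test_constant_regulator_p_one(self, rng):
        Y = rng.standard_normal((10, 15))
        model = ScaleFreeKSVD(n_atoms=3, max_iter=5, random_state=0).fit(Y)
        regs = np.ones((10, 1))
        obs = score_all(model.dictionary_, model.coefficients_, regs,
                        gene_ids=[f"g{j}" for j in range(15)], regulator_ids=["r"])
        out = permutation_test(Y, regs, obs, n_perm=50, seed=2, model=model)
        assert (out["p_value"] == 1.0).all()

    def test_null_calibration_uniform(self, rng):
        """p-values of pure-noise regulators are approximately uniform."""
        Y = rng.standard_normal((20, 10))
        model = ScaleFreeKSVD(n_atoms=4, max_iter=10, random_state=3).fit(Y)
        regs = rng.standard_normal((20, 15))  # 15 independent noise regulators
        ids = [f"r{i}" for i in range(15)]
        obs = score_all(model.dictionary_, model.coefficients_, regs,
                        gene_ids=[f"g{j}" for j in range(10)], regulator_ids=ids)
        out = permutation_test(Y, regs, obs, n_perm=199, seed=4, model=model)
        stat, pval = kstest(out["p_value"], "uniform")
        assert pval > 0.01

    def test_invalid_count(self, rng):
        Y = rng.standard_normal((8, 5))
        model = ScaleFreeKSVD(n_atoms=2, max_iter=3, random_state=0).fit(Y)
        regs = rng.standard_normal((8, 1))
        obs = score_all(model.dictionary_, model.coefficients_, regs,
                        gene_ids=[f"g{j}" for j in range(5)], regulator_ids=["r"])
        with pytest.raises(ValueError, match="invalid count"):
            permutation_test(Y, regs, obs, n_perm=0, model=model)


class TestGRNInferenceEstimator:
    def test_fit_produces_sorted_bounded_scores(self, noisy_planted):
        Y, profiles, _ = noisy_planted
        grn = GRNInference(n_atoms=8, n_resamples=3, random_state=0).fit(Y, profiles)
        t = grn.edge_scores_
        assert t["cs"].between(0, 1).all()
        assert (t["cs"].to_numpy()[:-1] >= t["cs"].to_numpy()[1:] - 1e-12).all()
        assert grn.score_matrix_.shape == (profiles.shape[1], Y.shape[1])

    def test_gene_order_permutation_equivariance(self, noisy_planted):
        """Shuffling gene columns permutes scores correspondingly — no hidden
        order dependence in the scoring stage."""
        Y, profiles, _ = noisy_planted
        model = ScaleFreeKSVD(n_atoms=6, max_iter=10, random_state=1).fit(Y)
        perm = np.random.default_rng(0).permutation(Y.shape[1])
        cs = score_matrix(model.dictionary_, model.coefficients_, profiles, 0.9)
        cs_perm = score_matrix(model.dictionary_, model.coefficients_[:, perm], profiles, 0.9)
        assert np.allclose(cs_perm, cs[:, perm])

    def test_sample_mismatch_rejected(self, noisy_planted):
        Y, profiles, _ = noisy_planted
        with pytest.raises(ValueError, match="samples"):
            GRNInference(n_atoms=4).fit(Y, profiles[:-1])

    def test_alpha_monotonicity_of_scores(self, noisy_planted):
        Y, profiles, _ = noisy_planted
        model = ScaleFreeKSVD(n_atoms=6, max_iter=10, random_state=1).fit(Y)
        lo = score_matrix(model.dictionary_, model.coefficients_, profiles, 0.5)
        hi = score_matrix(model.dictionary_, model.coefficients_, profiles, 0.95)
        assert np.all(hi >= lo - 1e-12)


class TestScoreProperties:
    """Property-based checks on the quantile confidence score."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        vals=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=0, max_size=12),
        alpha=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_score_bounded_and_within_value_range(self, vals, alpha):
        cs = confidence_score(np.array(vals), alpha)
        assert 0.0 <= cs <= 1.0
        if vals:
            assert min(vals) - 1e-12 <= cs <= max(vals) + 1e-12

    @given(
        vals=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12),
        a=st.floats(min_value=0.0, max_value=1.0),
        b=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_score_monotone_in_alpha(self, vals, a, b):
        lo, hi = sorted((a, b))
        arr = np.array(vals)
        assert confidence_score(arr, lo) <= confidence_score(arr, hi) + 1e-12
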