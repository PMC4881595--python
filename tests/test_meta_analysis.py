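import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xmeta.manifest_io import ValidationError
from xmeta.meta_analysis import (
    METHODS,
    fisher_combine,
    fixed_effect_combine,
    hedges_g,
    moderated_variance,
    random_effect_combine,
    rank_product,
    run_meta,
    stouffer_combine,
    vote_count,
)


class TestHedgesG:
    def test_hand_example(self):
        # n=3+3, mean diff 1, s_pooled=1: J = 1 - 3/15 = 0.8
        g, var_g = hedges_g(3, 1.0, 1.0, 3, 0.0, 1.0)
        assert g == pytest.approx(0.8)
        assert var_g == pytest.approx(6 / 9 + 0.64 / 12)

    def test_equal_means_zero(self):
        g, _ = hedges_g(4, 2.0, 1.0, 4, 2.0, 1.5)
        assert g == 0.0

    def test_larger_groups_shrink_variance(self):
        _, v1 = hedges_g(3, 1.0, 1.0, 3, 0.0, 1.0)
        _, v2 = hedges_g(6, 1.0, 1.0, 6, 0.0, 1.0)
        assert v2 < v1

    def test_zero_sd_unequal_means_rejected(self):
        with pytest.raises(ValidationError):
            hedges_g(3, 1.0, 0.0, 3, 0.0, 0.0)

    def test_zero_sd_equal_means_gives_zero(self):
        g, var_g = hedges_g(3, 1.0, 0.0, 3, 1.0, 0.0)
        assert g == 0.0 and var_g > 0


class TestModeratedVariance:
    def test_identical_variances_fully_shrunk(self):
        s2 = np.full(50, 2.5)
        shrunk, d0, s0 = moderated_variance(s2, df=6)
        assert math.isinf(d0)
        np.testing.assert_allclose(shrunk, s0)
        assert s0 == pytest.approx(2.5)

    def test_shrinkage_blend_formula(self):
        rng = np.random.default_rng(4)
        df = 8
        s2 = stats.f.rvs(df, 10, size=500, random_state=rng) * 1.3
        shrunk, d0, s0 = moderated_variance(s2, df=df)
        np.testing.assert_allclose(shrunk, (d0 * s0 + df * s2) / (d0 + df), rtol=1e-12)
        # shrunken values lie between the sample variance and the prior
        assert (np.minimum(s2, s0) - 1e-12 <= shrunk).all()
        assert (shrunk <= np.maximum(s2, s0) + 1e-12).all()

    def test_hyperparameter_recovery(self):
        """Method of moments recovers (d0=4, s0^2=1) from 5000 simulated genes."""
        rng = np.random.default_rng(99)
        df, d0_true, s0_true = 8, 4.0, 1.0
        s2 = s0_true * stats.f.rvs(df, d0_true, size=5000, random_state=rng)
        _, d0, s0 = moderated_variance(s2, df=df)
        assert 2.5 <= d0 <= 6.0
        assert 0.8 <= s0 <= 1.25

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError):
            moderated_variance(np.ones(5), df=4)


class TestFisherCombine:
    def test_hand_example(self):
        s, p = fisher_combine([0.01, 0.02, 0.03, 0.04])
        assert s == pytest.approx(30.485, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(s, 8), rel=1e-12)
        assert p == pytest.approx(1.734e-4, abs=2e-6)

    def test_all_ones(self):
        s, p = fisher_combine([1.0, 1.0, 1.0])
        assert s == 0.0 and p == 1.0

    def test_single_study_identity(self):
        _, p = fisher_combine([0.37])
        assert p == pytest.approx(0.37)

    def test_zero_p_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            _, p = fisher_combine([0.0, 0.5])
        assert 0.0 < p < 1e-100

    def test_monotone_in_each_input(self):
        rng = np.random.default_rng(11)
        base = rng.uniform(0.01, 0.99, size=4)
        _, p0 = fisher_combine(base)
        for i in range(4):
            worse = base.copy()
            worse[i] = min(1.0, worse[i] + 0.3)
            _, p1 = fisher_combine(worse)
            assert p1 >= p0


class TestStoufferCombine:
    def test_hand_example(self):
        z, p_one, _ = stouffer_combine([0.05, 0.05], [1.0, 1.0])
        assert z == pytest.approx(2 * 1.6449 / math.sqrt(2), abs=1e-3)
        assert p_one == pytest.approx(0.0100, abs=2e-4)

    def test_single_positive_weight_returns_that_study(self):
        z, _, p_two = stouffer_combine([0.03, 0.8], [1.0, 0.0])
        assert p_two == pytest.approx(2 * 0.03)
        assert z == pytest.approx(stats.norm.isf(0.03))

    def test_opposite_evidence_cancels(self):
        z, _, p_two = stouffer_combine([0.05, 0.95], [1.0, 1.0])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p_two == pytest.approx(1.0, rel=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError):
            stouffer_combine([0.1, 0.2], [0.0, 0.0])


class TestFixedEffect:
    def test_hand_example(self):
        out = fixed_effect_combine([0.5, 0.5], [0.1, 0.1])
        assert out["pooled"][0] == pytest.approx(0.5)
        assert out["se"][0] == pytest.approx(math.sqrt(0.05))
        assert out["z"][0] == pytest.approx(2.236, abs=1e-3)

    def test_precise_study_dominates(self):
        out = fixed_effect_combine([0.5, -2.0], [1e-6, 1.0])
        assert out["pooled"][0] == pytest.approx(0.5, abs=1e-4)

    def test_permutation_invariant(self):
        a = fixed_effect_combine([0.1, 0.4, -0.3], [0.2, 0.1, 0.3])
        b = fixed_effect_combine([-0.3, 0.1, 0.4], [0.3, 0.2, 0.1])
        assert a["pooled"][0] == pytest.approx(b["pooled"][0])
        assert a["p"][0] == pytest.approx(b["p"][0])

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValidationError):
            fixed_effect_combine([0.5, 0.5], [0.1, 0.0])


class TestRandomEffect:
    def test_homogeneous_reduces_to_fixed(self):
        re = random_effect_combine([0.5, 0.5], [0.1, 0.1])
        fe = fixed_effect_combine([0.5, 0.5], [0.1, 0.1])
        assert re["tau2"][0] == 0.0 and re["Q"][0] == 0.0
        assert re["pooled"][0] == pytest.approx(fe["pooled"][0])
        assert re["se"][0] == pytest.approx(fe["se"][0])

    def test_dersimonian_laird_closed_form(self):
        # g=(0,2), var=(0.1,0.1): w=10 each, Q=20, c=20-200/20=10, tau2=19/10
        re = random_effect_combine([0.0, 2.0], [0.1, 0.1])
        assert re["Q"][0] == pytest.approx(20.0)
        assert re["tau2"][0] == pytest.approx(1.9)
        assert re["pooled"][0] == pytest.approx(1.0)

    def test_tau2_recovery_on_simulation(self):
        """Mean DL estimate near the true tau2=0.5 for k=50 precise studies."""
        rng = np.random.default_rng(17)
        k, tau2_true = 50, 0.5
        estimates = []
        for _ in range(200):
            v = rng.uniform(0.01, 0.02, size=k)
            g = 0.3 + rng.normal(0.0, math.sqrt(tau2_true), size=k) \
                + rng.normal(0.0, np.sqrt(v))
            estimates.append(random_effect_combine(g, v)["tau2"][0])
        assert 0.35 <= np.mean(estimates) <= 0.65

    def test_single_study_rejected(self):
        with pytest.raises(ValidationError):
            random_effect_combine([0.5], [0.1])


def exhaustive_pair_p(rp_values, n):
    """P(RP <= rp) when each of two ranks is uniform on {1..n} (independent)."""
    pairs = [(a * b) ** 0.5 for a in range(1, n + 1) for b in range(1, n + 1)]
    return np.array([np.mean([q <= rp + 1e-9 for q in pairs]) for rp in rp_values])


class TestRankProduct:
    def test_top_gene_matches_exhaustive_oracle(self):
        # 5 genes, one gene ranked 1 in both studies: P(RP <= 1) = 1/25
        fc = pd.DataFrame(
            {"s1": [5.0, 1.0, 0.5, -1.0, -2.0], "s2": [4.0, 0.3, 1.2, -0.5, -3.0]},
            index=list("ABCDE"),
        )
        out = rank_product(fc, "up", B=2000, seed=3)
        assert out.loc["A", "rp"] == 1.0
        assert out.loc["A", "p_perm"] == pytest.approx(1 / 25, abs=0.01)

    def test_permutation_p_matches_oracle_on_six_genes(self):
        rng = np.random.default_rng(23)
        fc = pd.DataFrame(rng.normal(size=(6, 2)), columns=["s1", "s2"],
                          index=[f"G{i}" for i in range(6)])
        out = rank_product(fc, "up", B=2000, seed=5)
        oracle = exhaustive_pair_p(out["rp"].to_numpy(), 6)
        np.testing.assert_allclose(out["p_perm"], oracle, atol=0.01)

    def test_bottom_gene_p_near_one(self):
        fc = pd.DataFrame(
            {"s1": [3.0, 2.0, 1.0, -9.0], "s2": [1.0, 3.0, 2.0, -9.0]},
            index=list("ABCD"),
        )
        out = rank_product(fc, "up", B=500, seed=1)
        assert out.loc["D", "p_perm"] > 0.9

    def test_directions_mirror_each_other(self):
        rng = np.random.default_rng(2)
        fc = pd.DataFrame(rng.normal(size=(8, 3)))
        up = rank_product(fc, "up", B=200, seed=9)
        down = rank_product(-fc, "down", B=200, seed=9)
        np.testing.assert_allclose(up["rp"], down["rp"])

    def test_invalid_B_rejected(self):
        with pytest.raises(ValidationError):
            rank_product(pd.DataFrame(np.ones((3, 2))), "up", B=0, seed=0)


class TestVoteCount:
    def _p(self, row):
        return pd.DataFrame([row], columns=list(METHODS), index=["G1"])

    def test_four_votes_is_meta_deg(self):
        out = vote_count(self._p([0.01, 0.02, 0.03, 0.04, 0.9]))
        assert out["votes"].iloc[0] == 4 and bool(out["is_meta_deg"].iloc[0])

    def test_three_votes_is_not(self):
        out = vote_count(self._p([0.01, 0.02, 0.03, 0.06, 0.9]))
        assert out["votes"].iloc[0] == 3 and not bool(out["is_meta_deg"].iloc[0])

    def test_alpha_zero_selects_nothing(self):
        out = vote_count(self._p([1e-10] * 5), alpha=0.0)
        assert out["votes"].iloc[0] == 0

    def test_min_methods_validated(self):
        with pytest.raises(ValidationError):
            vote_count(self._p([0.5] * 5), min_methods=6)


class TestRunMeta:
    def test_all_p_columns_in_unit_interval(self, small_preprocessed):
        preprocessed, genes, truth = small_preprocessed
        meta = run_meta(preprocessed, B=200, seed=1)
        for m in METHODS:
            col = meta.table[m]
            assert ((col >= 0) & (col <= 1)).all()
        assert meta.table["votes"].between(0, 5).all()

    def test_vote_rule_recovers_true_degs(self):
        """>= 80% (within 5 points) of true DEGs win the 4-of-5 vote."""
        from xmeta.preprocess import preprocess_collection
        from xmeta.synthetic_data import SimulationConfig, simulate_collection

        cfg = SimulationConfig(n_genes=1000, k_studies=4, n_mcao=5, n_sham=5,
                               frac_deg=0.05, delta=2.0, tau2=0.1,
                               missing_rate=0.0, platform_dropout=0.0,
                               probes_per_gene=1, seed=31)
        studies, truth = simulate_collection(cfg)
        pre, genes = preprocess_collection(studies)
        meta = run_meta(pre, B=1000, seed=31)
        recovered = meta.meta_degs & set(truth.deg_all)
        assert len(recovered) / len(truth.deg_all) >= 0.75

    def test_mismatched_gene_indices_rejected(self, small_preprocessed):
        preprocessed, genes, truth = small_preprocessed
        import copy

        broken = copy.copy(preprocessed[1])
        broken.standardized = broken.standardized.iloc[::-1]
        with pytest.raises(ValidationError):
            run_meta([preprocessed[0], broken], B=10, seed=0)
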