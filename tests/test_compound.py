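import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmapscreen import (
    CompoundSummary,
    EnrichmentResult,
    GeneSetCollection,
    bh_fdr,
    non_null_ratio,
    permutation_pvalue,
    rank_compounds,
    reliability_score,
    specificity_score,
    summarize_compound,
)
from cmapscreen.compound import build_surrogate_queries
from cmapscreen.simulate import SyntheticConfig, simulate_compendium

from oracles import bh_oracle, exhaustive_resample_pvalue


def results(scaled, compound="drugA"):
    return [
        EnrichmentResult(f"i{k}", 0, 0, s, scaled_score=s, is_null=(s == 0), compound=compound)
        for k, s in enumerate(scaled)
    ]


class TestSummarize:
    def test_mean_and_count(self):
        s = summarize_compound(results([0.9, 0.8, 0.7]))
        assert s.mean_score == pytest.approx(0.8)
        assert s.instance_count == 3
        assert s.sd_score == pytest.approx(0.1)

    def test_singleton_has_zero_sd(self):
        s = summarize_compound(results([0.5]))
        assert (s.mean_score, s.sd_score, s.instance_count) == (0.5, 0.0, 1)

    def test_symmetric_scores_give_zero_direction(self):
        s = summarize_compound(results([0.6, -0.6]))
        assert s.mean_score == pytest.approx(0.0)
        assert s.direction == 0

    def test_mixed_compounds_rejected(self):
        mixed = results([0.5]) + results([0.4], compound="drugB")
        with pytest.raises(ValueError, match="mix"):
            summarize_compound(mixed)


class TestNonNullRatio:
    def test_majority_sign_over_all_instances(self):
        assert non_null_ratio(results([0.8, 0.6, -0.1, 0.0])) == pytest.approx(0.5)

    def test_unanimous(self):
        assert non_null_ratio(results([0.3, 0.4, 0.5])) == 1.0

    def test_all_null(self):
        assert non_null_ratio(results([0.0, 0.0])) == 0.0

    def test_negative_majority(self):
        assert non_null_ratio(results([-0.8, -0.6, 0.1])) == pytest.approx(2 / 3)


class TestPermutationPvalue:
    def test_pseudo_count_floor(self):
        pool = np.concatenate([[5.0], np.zeros(99)])
        p = permutation_pvalue(100.0, 2, pool, B=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_zero_mean_gives_p_one(self):
        pool = np.linspace(-1, 1, 50)
        assert permutation_pvalue(0.0, 3, pool, B=200, seed=0) == 1.0

    def test_single_possible_resample_matches_enumeration(self):
        pool = np.array([-1.0, 1.0])
        p = permutation_pvalue(0.0, 2, pool, B=100, seed=1)
        assert p == exhaustive_resample_pvalue(0.0, 2, [-1.0, 1.0])

    def test_converges_to_exhaustive_exceedance_fraction(self):
        # at large B the pseudo-count vanishes and p estimates the exact
        # exceedance fraction over all n-subsets of the pool
        from itertools import combinations

        pool = [-0.9, -0.2, 0.1, 0.5, 0.8]
        means = [sum(c) / 2 for c in combinations(pool, 2)]
        exact_fraction = sum(1 for m in means if abs(m) >= 0.45) / len(means)
        approx = permutation_pvalue(0.45, 2, np.array(pool), B=20000, seed=3)
        assert approx == pytest.approx(exact_fraction, abs=0.02)

    def test_pool_too_small_is_error(self):
        with pytest.raises(ValueError, match="pool"):
            permutation_pvalue(0.1, 5, np.zeros(3), B=100, seed=0)

    def test_deterministic_given_seed(self):
        pool = np.random.default_rng(0).normal(size=40)
        a = permutation_pvalue(0.3, 4, pool, B=500, seed=9)
        b = permutation_pvalue(0.3, 4, pool, B=500, seed=9)
        assert a == b


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=5))
    def test_matches_step_up_oracle_on_random_vectors(self, ps):
        assert bh_fdr(ps) == pytest.approx(bh_oracle(ps))

    def test_matches_oracle_on_all_permutations_of_a_vector(self):
        base = [0.004, 0.03, 0.03, 0.2, 0.9]
        for perm in itertools.permutations(base):
            assert bh_fdr(list(perm)) == pytest.approx(bh_oracle(list(perm)))

    def test_monotone_in_sorted_input(self):
        rng = np.random.default_rng(5)
        ps = rng.uniform(1e-6, 1, 30)
        q = bh_fdr(ps)
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def synthetic():
    cfg = SyntheticConfig(
        n_genes=300, n_compounds=10, instances_per_compound=2,
        n_background_sets=25, background_set_size=40, seed=4,
    )
    return simulate_compendium(cfg)


class TestSpecificity:
    def test_extreme_compound_mean_is_maximally_specific(self, synthetic):
        matrix, sig, background, _ = synthetic
        sub = matrix.subset(list(matrix.ranks.columns[:2]))
        # |mean| = 2 exceeds any achievable background mean
        assert specificity_score(2.0, sig.sizes, background, sub, seed=0) == 1.0

    def test_zero_compound_mean_has_zero_specificity(self, synthetic):
        matrix, sig, background, _ = synthetic
        sub = matrix.subset(list(matrix.ranks.columns[:2]))
        assert specificity_score(0.0, sig.sizes, background, sub, seed=0) == 0.0

    def test_exceedance_counting(self):
        # 10 background sets, 3 with |mean| >= |compound mean| -> 0.7
        surrogate_raw = np.array([[1.0], [0.9], [0.8], [0.1], [0.2], [0.1], [0.0], [0.3], [0.2], [0.1]])
        spec = specificity_score(
            0.75, (1, 1), None, None, seed=0, surrogate_raw=surrogate_raw
        )
        assert spec == pytest.approx(0.7)

    def test_too_few_usable_sets_is_error(self, synthetic):
        matrix, sig, _, _ = synthetic
        small = GeneSetCollection({f"S{i}": [f"G{i:05d}"] for i in range(1, 30)})
        with pytest.raises(ValueError, match="usable background sets"):
            build_surrogate_queries(small, matrix.universe, sig.sizes, np.random.default_rng(0))

    def test_surrogate_sizes_match_query(self, synthetic):
        matrix, sig, background, _ = synthetic
        surrogates = build_surrogate_queries(
            background, matrix.universe, (15, 15), np.random.default_rng(0)
        )
        for up, down in surrogates.values():
            assert len(up) == 15 and len(down) == 15
            assert not set(up) & set(down)


class TestReliability:
    def summary(self, **kw):
        base = dict(
            compound="d", mean_score=1.0, sd_score=0.0, instance_count=4,
            p_value=1e-9, fdr=1e-9, non_null_ratio=1.0, specificity=1.0,
        )
        base.update(kw)
        return CompoundSummary(**base)

    def test_all_components_one(self):
        assert reliability_score(self.summary()) == pytest.approx(1.0, abs=1e-6)

    def test_equal_weight_arithmetic(self):
        s = self.summary(mean_score=0.8, p_value=1e-12, fdr=1e-12)
        assert reliability_score(s) == pytest.approx(29 / 30, abs=1e-6)

    def test_all_zero(self):
        s = self.summary(mean_score=0.0, p_value=1.0, fdr=1.0, non_null_ratio=0.0,
                         specificity=0.0, instance_count=4)
        # instance-count component is 4/4 = 1; zero it out via weights
        w = [0.2, 0.2, 0.2, 0.0, 0.2, 0.2]
        assert reliability_score(s, weights=w) == 0.0

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            reliability_score(self.summary(), weights=[0.5, 0.5, 0.5, 0, 0, 0])

    def test_instance_count_saturates_at_cap(self):
        s4 = self.summary(instance_count=4)
        s9 = self.summary(instance_count=9)
        assert reliability_score(s4) == reliability_score(s9)

    def test_monotone_in_each_component(self):
        base = self.summary(mean_score=0.5, p_value=0.2, fdr=0.3, instance_count=2,
                            non_null_ratio=0.5, specificity=0.5)
        r0 = reliability_score(base)
        better = dict(
            mean_score=0.7, p_value=0.1, fdr=0.1, instance_count=3,
            non_null_ratio=0.8, specificity=0.9,
        )
        for fieldname, value in better.items():
            r1 = reliability_score(self.summary(**{
                "mean_score": 0.5, "p_value": 0.2, "fdr": 0.3, "instance_count": 2,
                "non_null_ratio": 0.5, "specificity": 0.5, fieldname: value,
            }))
            assert r1 >= r0


class TestRankCompounds:
    def summaries(self, rows):
        return [
            CompoundSummary(
                compound=name, mean_score=m, sd_score=0.0, instance_count=1,
                p_value=0.5, fdr=0.5, non_null_ratio=1.0, specificity=1.0, reliability=r,
            )
            for name, r, m in rows
        ]

    def test_sorted_by_reliability(self):
        rep = rank_compounds(self.summaries([("a", 0.3, 0.1), ("b", 0.9, 0.1)]))
        assert list(rep.table["compound"]) == ["b", "a"]

    def test_tie_breaks_by_abs_mean_then_name(self):
        rep = rank_compounds(
            self.summaries([("a", 0.9, 0.5), ("b", 0.9, -0.8), ("c", 0.9, 0.5)])
        )
        assert list(rep.table["compound"]) == ["b", "a", "c"]

    def test_singleton(self):
        rep = rank_compounds(self.summaries([("only", 0.5, 0.2)]))
        assert len(rep) == 1
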