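"""Bootstrap machinery: counts, null resampling, p-values, oracle checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhf import (
    AnalysisRegion,
    BootstrapConfig,
    DomainAnnotation,
    DomainMap,
    adjust_bonferroni,
    bootstrap_null,
    empirical_pvalue,
    exact_binomial_pvalue,
    hotspot_test,
    observed_counts,
    stars,
)
from mhf.errors import CoordinateError, EmptySetError
from .conftest import mutation_set


def binomial_tail_by_enumeration(observed, n, p):
    """Independent oracle: direct summation of the binomial pmf."""
    return sum(
        math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(observed, n + 1)
    )


class TestObservedCounts:
    def test_tally_with_multiplicity(self, toy_map, toy_region):
        D = observed_counts(mutation_set([3, 3, 7], toy_region), toy_map)
        assert list(D) == [2, 1]

    def test_empty_set_gives_zero_vector(self, toy_map, toy_region):
        D = observed_counts(mutation_set([], toy_region), toy_map)
        assert list(D) == [0, 0]

    def test_interdomain_positions_counted_nowhere(self):
        region = AnalysisRegion(1, 100)
        dmap = DomainMap(region, [DomainAnnotation("A", 10, 19)])
        D = observed_counts(mutation_set([5, 15, 50], region), dmap)
        assert list(D) == [1]

    def test_position_outside_region_rejected(self, toy_map):
        wide = AnalysisRegion(1, 50)
        with pytest.raises(CoordinateError):
            observed_counts(mutation_set([30], wide), toy_map)


class TestBootstrapNull:
    def test_rows_sum_to_n_when_domains_tile_region(self, toy_region, toy_map):
        null = bootstrap_null(toy_region, toy_map, 4, BootstrapConfig(K=200, seed=1))
        assert (null.counts.sum(axis=1) == 4).all()

    def test_rows_sum_at_most_n_otherwise(self):
        region = AnalysisRegion(1, 100)
        dmap = DomainMap(region, [DomainAnnotation("A", 1, 20)])
        null = bootstrap_null(region, dmap, 10, BootstrapConfig(K=500, seed=2))
        assert (null.counts.sum(axis=1) <= 10).all()
        assert (null.counts >= 0).all()

    def test_mean_matches_binomial_expectation(self):
        # E[count] = n * L_j / L_X = 10 * 0.2 = 2.0
        region = AnalysisRegion(1, 100)
        dmap = DomainMap(region, [DomainAnnotation("A", 1, 20)])
        K = 10_000
        null = bootstrap_null(region, dmap, 10, BootstrapConfig(K=K, seed=3))
        se = math.sqrt(10 * 0.2 * 0.8 / K)
        assert abs(null.counts[:, 0].mean() - 2.0) < 3 * se

    def test_seed_determinism(self, toy_region, toy_map):
        cfg = BootstrapConfig(K=100, seed=42)
        a = bootstrap_null(toy_region, toy_map, 5, cfg)
        b = bootstrap_null(toy_region, toy_map, 5, cfg)
        c = bootstrap_null(toy_region, toy_map, 5, BootstrapConfig(K=100, seed=43))
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_empty_set_refused(self, toy_region, toy_map):
        with pytest.raises(EmptySetError):
            bootstrap_null(toy_region, toy_map, 0, BootstrapConfig(K=10))

    def test_without_replacement_variant(self, toy_region, toy_map):
        null = bootstrap_null(
            toy_region, toy_map, 10, BootstrapConfig(K=50, seed=1), replace=False
        )
        # drawing all 10 residues without replacement fills both domains exactly
        assert (null.counts == 5).all()

    @pytest.mark.parametrize("K", [100, 1_000, 10_000])
    def test_empirical_expectation_converges(self, K):
        region = AnalysisRegion(1, 200)
        dmap = DomainMap(region, [DomainAnnotation("A", 51, 100)])
        n = 40
        null = bootstrap_null(region, dmap, n, BootstrapConfig(K=K, seed=7))
        expected = n * 50 / 200
        se = math.sqrt(n * 0.25 * 0.75 / K)
        assert abs(null.counts[:, 0].mean() - expected) < 4 * se


class TestEmpiricalPvalue:
    def test_zero_observed_forces_p_one(self):
        assert empirical_pvalue(0, np.array([0, 1, 2])) == 1.0

    def test_unreachable_observed_forces_minimum(self):
        col = np.array([3, 1, 2, 0])
        assert empirical_pvalue(4, col) == 1 / 5

    def test_matches_exact_binomial_tail(self):
        # region 100, domain 1-20, n = 10, observed 6; oracle by enumeration
        region = AnalysisRegion(1, 100)
        dmap = DomainMap(region, [DomainAnnotation("A", 1, 20)])
        K = 10_000
        null = bootstrap_null(region, dmap, 10, BootstrapConfig(K=K, seed=11))
        p_hat = empirical_pvalue(6, null.counts[:, 0])
        b = binomial_tail_by_enumeration(6, 10, 0.2)
        mc_se = math.sqrt(b * (1 - b) * K) / (K + 1)
        assert abs(p_hat - (1 + K * b) / (K + 1)) <= 3 * mc_se

    @settings(derandomize=True, max_examples=40)
    @given(st.data())
    def test_monotone_nonincreasing_in_observed_count(self, data):
        col = np.array(
            data.draw(st.lists(st.integers(0, 20), min_size=5, max_size=50))
        )
        ps = [empirical_pvalue(d, col) for d in range(0, 22)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(1 / (len(col) + 1) <= p <= 1 for p in ps)


class TestAdjustments:
    def test_bonferroni_arithmetic(self):
        assert adjust_bonferroni([0.004], 14)[0] == pytest.approx(0.056)
        assert adjust_bonferroni([0.2], 9)[0] == 1.0
        assert adjust_bonferroni([1 / 10_001], 14)[0] == pytest.approx(14 / 10_001)

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            adjust_bonferroni([0.0], 3)

    def test_star_thresholds(self):
        assert stars(0.004) == "***"
        assert stars(0.009) == "**"
        assert stars(0.049) == "*"
        assert stars(0.05) == ""


class TestExactBinomial:
    def test_zero_observed(self):
        assert exact_binomial_pvalue(0, 10, 5, 100) == 1.0

    def test_half_length_all_hits(self):
        assert exact_binomial_pvalue(4, 4, 50, 100) == pytest.approx(1 / 16)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        L_X = int(rng.integers(10, 500))
        L_j = int(rng.integers(1, L_X + 1))
        D = int(rng.integers(0, n + 1))
        assert exact_binomial_pvalue(D, n, L_j, L_X) == pytest.approx(
            binomial_tail_by_enumeration(D, n, L_j / L_X), rel=1e-10
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_pvalue(5, 4, 10, 100)


class TestHotspotTest:
    def test_flags_an_obvious_cluster(self, toy_region, toy_map):
        S = mutation_set([2, 3, 3, 4, 4, 5, 1, 2], toy_region)
        res = hotspot_test(S, toy_map, BootstrapConfig(K=2_000, seed=5))
        assert res.significant_domains == ["A"]
        row = res.table.set_index("domain").loc["A"]
        assert row["D"] == 8
        assert row["p_bonferroni"] <= 0.05

    def test_refuses_empty_set(self, toy_region, toy_map):
        with pytest.raises(EmptySetError):
            hotspot_test(mutation_set([], toy_region), toy_map)

    def test_result_provenance(self, toy_region, toy_map):
        S = mutation_set([1, 6], toy_region)
        res = hotspot_test(S, toy_map, BootstrapConfig(K=500, seed=9))
        assert (res.n, res.K, res.seed) == (2, 500, 9)
        assert res.table["p_raw"].between(1 / 501, 1).all()
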