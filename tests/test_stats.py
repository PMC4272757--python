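"""Binomial tests, Holm-Bonferroni, and the prediction-noise bootstrap."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from mmpamp.config import AnalysisConfig
from mmpamp.index import PairDelta
from mmpamp.stats import (
    bootstrap_significance,
    holm_bonferroni,
    null_fwer_simulation,
    pvalue_classification,
    pvalue_regression,
    significance_level,
    significant_transformations,
)

from helpers import make_pair, make_transformation


def enumeration_oracle(n_pos: int, n_neg: int) -> float:
    """Independent oracle: enumerate all 2^N equally likely sign outcomes and
    count those with at most min(n_pos, n_neg) successes."""
    n = n_pos + n_neg
    m = min(n_pos, n_neg)
    hits = sum(1 for mask in range(1 << n) if bin(mask).count("1") <= m)
    return hits / (1 << n)


class TestPvalueRegression:
    @pytest.mark.parametrize(
        "n_pos,n_neg,expected",
        [
            (2, 2, 11 / 16),      # all 2^4 outcomes with <= 2 heads
            (0, 10, 0.5**10),
            (0, 1, 0.5),
            (1, 0, 0.5),
        ],
    )
    def test_exact_values(self, n_pos, n_neg, expected):
        assert pvalue_regression(n_pos, n_neg) == pytest.approx(expected, abs=1e-15)

    def test_matches_enumeration_oracle_small_n(self):
        for n in range(1, 13):
            for n_pos in range(n + 1):
                assert pvalue_regression(n_pos, n - n_pos) == pytest.approx(
                    enumeration_oracle(n_pos, n - n_pos), abs=1e-12
                )

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            pvalue_regression(0, 0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60))
    def test_symmetric(self, a, b):
        if a + b == 0:
            return
        assert pvalue_regression(a, b) == pvalue_regression(b, a)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 80))
    def test_monotone_in_imbalance(self, n):
        ps = [pvalue_regression(m, n - m) for m in range(n // 2 + 1)]
        assert ps == sorted(ps)  # more imbalance (smaller m) -> smaller p

    def test_extreme_n_does_not_underflow_to_zero(self):
        assert pvalue_regression(0, 10000) > 0.0


class TestPvalueClassification:
    def test_no_effect_degenerate_rates(self):
        assert pvalue_classification(10, 0, 10, 0) == 1.0

    def test_total_flip(self):
        assert pvalue_classification(5, 5, 0, 10) == pytest.approx(0.5**10, rel=1e-12)

    def test_printed_formula_example(self):
        # min(P[Bin(4,0.75) <= 1], P[Bin(4,0.25) <= 3]) by direct enumeration
        assert pvalue_classification(3, 1, 1, 3) == pytest.approx(0.05078125, abs=1e-12)

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError):
            pvalue_classification(3, 1, 1, 2)


class TestSignificanceLevel:
    @pytest.mark.parametrize("p,expected", [(0.01, 2.0), (0.001, 3.0), (1.0, 0.0)])
    def test_log_conversion(self, p, expected):
        assert significance_level(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_enforced(self, bad):
        with pytest.raises(ValueError):
            significance_level(bad)


class TestHolmBonferroni:
    def test_step_down_example(self):
        # 0.01 <= 0.05/3 rejects; 0.03 > 0.05/2 stops the procedure
        assert holm_bonferroni([0.01, 0.04, 0.03], 0.05) == [True, False, False]

    def test_all_ones_no_rejections(self):
        assert holm_bonferroni([1.0] * 5, 0.05) == [False] * 5

    def test_single_test_reduces_to_plain_threshold(self):
        assert holm_bonferroni([0.04], 0.05) == [True]

    def test_empty(self):
        assert holm_bonferroni([], 0.05) == []

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_agrees_with_statsmodels(self, pvalues):
        ours = holm_bonferroni(pvalues, 0.05)
        reference = multipletests(pvalues, alpha=0.05, method="holm")[0]
        assert ours == list(reference)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_at_least_as_powerful_as_bonferroni(self, pvalues):
        holm = holm_bonferroni(pvalues, 0.05)
        bonf = [p <= 0.05 / len(pvalues) for p in pvalues]
        assert all(h or not b for h, b in zip(holm, bonf))


def continuous_delta(delta, u_a=0.0, u_b=0.0, provenance="predicted"):
    return PairDelta(
        kind="continuous", value_a=0.0, value_b=delta, provenance=provenance,
        uncertainty_a=u_a, uncertainty_b=u_b,
    )


class TestBootstrap:
    def test_zero_uncertainty_reproduces_plain_pvalue(self):
        deltas = [continuous_delta(1.0) for _ in range(12)]
        for seed in (0, 1, 99):
            assert bootstrap_significance(deltas, 200, seed) == pvalue_regression(12, 0)

    def test_robust_effect_survives_noise(self):
        # 50 pairs, effect 1.0, per-side sd 0.1: sign-flip probability
        # Phi(-1/(0.1*sqrt(2))) ~ 8e-13, so replicas stay fully concordant
        deltas = [continuous_delta(1.0, 0.1, 0.1) for _ in range(50)]
        assert bootstrap_significance(deltas, 1000, seed=3) < 1e-6

    def test_noise_washes_out_effect(self):
        # per-side sd 10 makes each pair's sign nearly a coin flip
        deltas = [continuous_delta(1.0, 10.0, 10.0) for _ in range(50)]
        assert bootstrap_significance(deltas, 1000, seed=3) > 0.05

    def test_bitwise_reproducible_from_seed(self):
        deltas = [continuous_delta(0.4, 0.5, 0.5) for _ in range(20)]
        a = bootstrap_significance(deltas, 500, seed=11)
        b = bootstrap_significance(deltas, 500, seed=11)
        assert a == b

    def test_binary_flip_bootstrap(self):
        flips = [
            PairDelta(kind="binary", value_a="active", value_b="inactive",
                      provenance="predicted", uncertainty_a=0.0, uncertainty_b=0.0)
            for _ in range(20)
        ]
        assert bootstrap_significance(flips, 200, seed=0) == pvalue_classification(20, 0, 0, 20)

    def test_missing_uncertainty_rejected(self):
        bad = [PairDelta(kind="continuous", value_a=0.0, value_b=1.0,
                         provenance="predicted", uncertainty_a=None, uncertainty_b=0.0)]
        with pytest.raises(ValueError, match="uncertainty"):
            bootstrap_significance(bad, 10, 0)


class TestSignificantTransformations:
    def test_planted_effect_flagged(self, stats_by_id):
        co = stats_by_id["C[*:1]>>O[*:1]"]
        assert co.holm_significant
        assert co.n_pos == co.N and co.n_neg == 0
        assert co.provenance_class == "experimental"

    def test_null_control_not_flagged(self, stats_by_id):
        assert not stats_by_id["Br[*:1]>>Cl[*:1]"].holm_significant

    def test_below_min_pairs_reported_untested(self):
        t = make_transformation([make_pair(i, 0.0, 1.0) for i in range(3)])
        (stats,) = significant_transformations([t], "y", AnalysisConfig())
        assert not stats.tested
        assert stats.p_value is None
        assert not stats.holm_significant
        assert stats.N == 3

    def test_zero_deltas_excluded_from_counts(self):
        pairs = [make_pair(i, 0.0, 1.0) for i in range(6)]
        pairs.append(make_pair(99, 0.5, 0.5))
        t = make_transformation(pairs)
        (stats,) = significant_transformations([t], "y", AnalysisConfig())
        assert (stats.n_pos, stats.n_neg, stats.n_zero) == (6, 0, 1)
        assert stats.p_value == pytest.approx(0.5**6)

    def test_mixed_kinds_rejected(self):
        t = make_transformation(
            [make_pair(0, 0.0, 1.0)]
            + [make_pair(1, "active", "inactive", kind="binary")]
        )
        with pytest.raises(ValueError, match="kind"):
            significant_transformations([t], "y", AnalysisConfig(min_pairs=1))

    def test_out_of_domain_predictions_excluded_by_default(self):
        pairs = [make_pair(i, 0.0, 1.0, source="predicted", uncertainty=0.1,
                           in_domain=(i % 2 == 0)) for i in range(10)]
        t = make_transformation(pairs)
        (stats,) = significant_transformations([t], "y", AnalysisConfig(min_pairs=1))
        assert stats.N == 5
        (lenient,) = significant_transformations(
            [t], "y", AnalysisConfig(min_pairs=1, include_out_of_domain=True)
        )
        assert lenient.N == 10

    def test_binary_endpoint_counts(self):
        pairs = [make_pair(i, "active", "inactive", kind="binary") for i in range(4)]
        pairs += [make_pair(10 + i, "inactive", "inactive", kind="binary") for i in range(4)]
        t = make_transformation(pairs)
        (stats,) = significant_transformations([t], "y", AnalysisConfig())
        assert (stats.n_pos, stats.n_neg) == (4, 4)
        assert (stats.after_pos, stats.after_neg) == (0, 8)
        assert stats.n_deactivated == 4
        # min(P[Bin(8,0.5)<=0], P[Bin(8,0.5)<=8]) = 0.5^8
        assert stats.p_value == pytest.approx(0.5**8, rel=1e-9)


def test_null_fwer_simulation_deterministic(fitted):
    cfg = AnalysisConfig()
    a = null_fwer_simulation(fitted.transformations, n_runs=25, seed=5, config=cfg)
    b = null_fwer_simulation(fitted.transformations, n_runs=25, seed=5, config=cfg)
    assert a == b
    assert 0.0 <= a <= 1.0
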