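"""Predictor contract, prediction annotation and amplification classes."""

import sys

import pytest

from mmpamp.amplify import (
    SubprocessPredictor,
    annotate_predictions,
    classify_provenance,
    toy_additive_predictor,
    EvidenceSummary,
)
from mmpamp.chem import EndpointValue, standardize
from mmpamp.config import AnalysisConfig
from mmpamp.stats import significant_transformations

from helpers import make_pair, make_transformation


class TestAdditivePredictor:
    def test_direct_sum(self, phenol, toluene):
        predictor = toy_additive_predictor({"[*:1]O": -1.0}, intercept=5.0)
        values = predictor([phenol, toluene])
        assert values[0].value == pytest.approx(4.0)
        assert values[1].value == pytest.approx(5.0)
        assert all(v.source == "predicted" for v in values)

    def test_deterministic_across_calls_and_order(self, library):
        predictor = library.predictor(noise_sd=0.3, seed=5)
        mols = library.molecules[:10]
        first = [v.value for v in predictor(mols)]
        second = [v.value for v in predictor(mols)]
        assert first == second
        reversed_values = {m.id: v.value for m, v in zip(mols[::-1], predictor(mols[::-1]))}
        assert all(
            reversed_values[m.id] == v.value for m, v in zip(mols, predictor(mols))
        )

    def test_zero_noise_reproduces_planted_pair_deltas(self, library):
        predictor = library.predictor(noise_sd=0.0)
        by_id = {m.id: m for m in library.molecules}
        # methyl (V01) -> hydroxyl (V02) on the same scaffold: planted +1.0
        a = predictor([by_id["S02_V01"]])[0].value
        b = predictor([by_id["S02_V02"]])[0].value
        assert b - a == pytest.approx(1.0, abs=1e-12)

    def test_binary_variant_thresholds_score(self, phenol, toluene):
        predictor = toy_additive_predictor(
            {"[*:1]O": -1.0}, intercept=5.0, kind="binary", threshold=4.5
        )
        labels = [v.value for v in predictor([phenol, toluene])]
        assert labels == ["inactive", "active"]

    def test_uncertainty_defaults_to_noise_sd(self, toluene):
        predictor = toy_additive_predictor({}, noise_sd=0.25)
        assert predictor([toluene])[0].uncertainty == 0.25


class TestAnnotate:
    def test_every_molecule_annotated(self, library):
        mols = [standardize(m.structure, m.id) for m in library.molecules]
        predictor = library.predictor(noise_sd=0.1)
        annotate_predictions(mols, predictor)
        values = [m.endpoint_values["activity"].predicted for m in mols]
        assert len(values) == len(mols)
        assert all(v is not None and v.uncertainty == 0.1 for v in values)

    def test_experimental_values_retained_and_preferred(self, toluene):
        toluene.set_value("activity", EndpointValue(kind="continuous", value=2.5))
        annotate_predictions([toluene], toy_additive_predictor({}, intercept=9.0))
        data = toluene.endpoint_values["activity"]
        assert data.experimental.value == 2.5
        assert data.predicted.value == pytest.approx(9.0)
        assert data.effective().source == "experimental"

    def test_out_of_domain_prediction_excluded_downstream(self, toluene):
        toluene.set_value(
            "activity",
            EndpointValue(kind="continuous", value=1.0, source="predicted",
                          uncertainty=0.2, in_domain=False),
        )
        assert toluene.get_value("activity") is None
        assert toluene.get_value("activity", include_out_of_domain=True) is not None


class TestSubprocessPredictor:
    def test_roundtrip(self, toluene, phenol):
        script = (
            "import sys\n"
            "for line in sys.stdin:\n"
            "    line = line.strip()\n"
            "    if line:\n"
            "        print(f'{len(line) * 0.5}\\t0.1\\t1')\n"
        )
        predictor = SubprocessPredictor(
            command=[sys.executable, "-c", script], endpoint="activity"
        )
        values = predictor([toluene, phenol])
        assert len(values) == 2
        assert values[0].value == pytest.approx(len(toluene.structure) * 0.5)
        assert values[0].uncertainty == 0.1
        assert values[0].in_domain


class TestClassifyProvenance:
    def test_amplified_with_untestable_experimental_subset(self):
        # mirrors the few-measured-pairs scenario: 4 experimental pairs
        # cannot be tested alone, hundreds of predicted pairs carry the test
        assert classify_provenance(None, 1e-7, 4, 362, 0.05) == "amplified"

    def test_experimental_alone(self):
        assert classify_provenance(1e-4, 1e-6, 50, 0, 0.05) == "experimental"

    def test_predicted_only(self):
        assert classify_provenance(None, 1e-4, 0, 200, 0.05) == "predicted"

    def test_none_when_nothing_significant(self):
        assert classify_provenance(0.4, 0.3, 10, 10, 0.05) == "none"


class TestAmplificationEndToEnd:
    def build(self, uncertainty):
        exp = [make_pair(i, 0.0, 1.0) for i in range(4)]
        pred = [
            make_pair(100 + i, 0.0, 1.0, source="predicted", uncertainty=uncertainty)
            for i in range(100)
        ]
        return make_transformation(exp + pred)

    def test_predicted_pairs_amplify_sparse_experimental_evidence(self):
        t = self.build(uncertainty=0.1)
        cfg = AnalysisConfig(seed=7)
        (stats,) = significant_transformations([t], "y", cfg)
        assert stats.n_experimental_pairs == 4
        assert stats.n_predicted_pairs == 100
        assert stats.p_experimental is None  # below min pair count alone
        assert stats.holm_significant
        assert stats.provenance_class == "amplified"
        assert stats.bootstrap_p is not None and stats.bootstrap_p <= cfg.alpha

    def test_unreliable_predictions_removed_by_bootstrap(self):
        t = self.build(uncertainty=10.0)  # 10x the planted effect
        cfg = AnalysisConfig(seed=7)
        (stats,) = significant_transformations([t], "y", cfg)
        assert stats.bootstrap_excluded
        assert not stats.holm_significant
        assert stats.provenance_class == "none"

    def test_experimental_statistics_unaffected_by_predictions(self):
        exp = [make_pair(i, 0.0, 1.0) for i in range(8)]
        alone = make_transformation(exp)
        cfg = AnalysisConfig(seed=1)
        (stats_alone,) = significant_transformations([alone], "y", cfg)
        combined = make_transformation(
            exp + [make_pair(50 + i, 0.0, 1.0, source="predicted", uncertainty=0.1)
                   for i in range(20)]
        )
        (stats_comb,) = significant_transformations([combined], "y", cfg)
        assert stats_comb.p_experimental == stats_alone.p_value
        assert stats_comb.p_value <= stats_alone.p_value

    def test_evidence_summary_mirrors_stats(self):
        (stats,) = significant_transformations(
            [self.build(uncertainty=0.1)], "y", AnalysisConfig(seed=7)
        )
        summary = EvidenceSummary.from_stats(stats)
        assert summary.provenance_class == "amplified"
        assert summary.n_predicted_pairs == 100
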