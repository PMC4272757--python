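"""Transformation application, similarity filtering and hit accounting."""

import pytest

from mmpamp.chem import standardize
from mmpamp.fragment import canonical_pair
from mmpamp.index import Transformation
from mmpamp.optimize import OptimizationConfig, apply_transformation, optimize, select_applicable


def make_t(frag_a, frag_b):
    """Canonical transformation plus the sign applying the a -> b direction."""
    left, right, sign = canonical_pair(frag_a, frag_b)
    t = Transformation(
        id=f"{left.notation}>>{right.notation}", left=left, right=right, n_cuts=1
    )
    return t, sign


C_TO_O, C_TO_O_SIGN = make_t("[*:1]C", "[*:1]O")
H_TO_CL, H_TO_CL_SIGN = make_t("[*:1][H]", "[*:1]Cl")
assert C_TO_O_SIGN == 1


class TestApplyTransformation:
    def test_toluene_to_phenol(self, toluene, phenol):
        products = apply_transformation(toluene, C_TO_O, 1)
        assert [p.unique_key for p in products] == [phenol.unique_key]

    def test_reverse_round_trip(self, toluene, phenol):
        back = apply_transformation(phenol, C_TO_O, -1)
        assert toluene.unique_key in {p.unique_key for p in back}

    def test_symmetric_sites_collapse(self):
        para_xylene = standardize("Cc1ccc(C)cc1")
        products = apply_transformation(para_xylene, C_TO_O, 1)
        assert len(products) == 1
        assert products[0].structure == standardize("Cc1ccc(O)cc1").structure

    def test_hydrogen_replacement_sites(self, benzene):
        products = apply_transformation(benzene, H_TO_CL, H_TO_CL_SIGN)
        assert {p.structure for p in products} == {standardize("Clc1ccccc1").structure}

    def test_no_embedding_gives_empty_list(self, benzene):
        assert apply_transformation(benzene, C_TO_O, 1) == []

    def test_round_trip_across_library(self, library):
        recovered = 0
        for mol in library.molecules[:20]:
            products = apply_transformation(mol, C_TO_O, 1)
            for product in products:
                back = apply_transformation(product, C_TO_O, -1)
                assert mol.unique_key in {p.unique_key for p in back}
                recovered += 1
        assert recovered > 0


class TestSelectApplicable:
    def test_directions_and_threshold(self, fitted):
        # threshold 0.8 keeps the planted +/-1.0 effects in scope regardless of
        # sampling noise in their measured means
        decrease = select_applicable(
            fitted.stats,
            fitted.transformations,
            OptimizationConfig(direction="decrease", practical_threshold=0.8),
        )
        ids = {t.id: sign for t, sign in decrease}
        # planted methyl->carboxyl effect is -1.3: applied forward to decrease
        assert ids.get("C[*:1]>>O=C(O)[*:1]") == 1
        # planted methyl->hydroxyl is +1.0: applied in reverse to decrease
        assert ids.get("C[*:1]>>O[*:1]") == -1
        # sub-threshold effects (|mean delta| < 0.8 log units) are not applied
        assert "C[*:1]>>N[*:1]" not in ids
        increase = select_applicable(
            fitted.stats,
            fitted.transformations,
            OptimizationConfig(direction="increase", practical_threshold=0.8),
        )
        assert {t.id: s for t, s in increase}.get("C[*:1]>>O[*:1]") == 1


class TestOptimize:
    @pytest.fixture()
    def target(self, library):
        return next(m for m in library.molecules if m.id == "S00_V01")  # methyl

    def test_full_similarity_filter_keeps_nothing(self, fitted, library, target):
        res = fitted.optimize(
            target, library.predictor(), OptimizationConfig(direction="decrease", min_similarity=1.0, practical_threshold=0.8)
        )
        assert res.generated > 0
        assert res.kept == 0
        assert res.effectiveness is None

    def test_zero_noise_predictor_perfect_on_planted_transformations(
        self, fitted, library, target
    ):
        res = fitted.optimize(
            target,
            library.predictor(noise_sd=0.0),
            OptimizationConfig(direction="decrease", practical_threshold=0.8)
        )
        per_t = res.per_transformation()
        planted = {"C[*:1]>>O=C(O)[*:1]", "C[*:1]>>O[*:1]"}
        applied_planted = planted & set(per_t)
        assert applied_planted
        for tid in applied_planted:
            assert per_t[tid]["kept"] > 0
            assert per_t[tid]["effectiveness"] == 1.0
        assert res.hits <= res.kept <= res.generated

    def test_raising_similarity_never_increases_kept_or_hits(self, fitted, library, target):
        predictor = library.predictor(noise_sd=0.0)
        kept, hits = [], []
        for threshold in (0.0, 0.3, 0.5, 0.7, 1.0):
            res = fitted.optimize(
                target,
                predictor,
                OptimizationConfig(
                    direction="decrease", min_similarity=threshold, practical_threshold=0.8
                ),
            )
            kept.append(res.kept)
            hits.append(res.hits)
        assert kept == sorted(kept, reverse=True)
        assert hits == sorted(hits, reverse=True)

    def test_adverse_transformation_generates_but_never_hits(self, library, target):
        # applying the +1.0 replacement forward while asking for a decrease
        res = optimize(
            target,
            [(C_TO_O, 1)],
            library.predictor(noise_sd=0.0),
            OptimizationConfig(direction="decrease", min_similarity=0.0),
        )
        assert res.generated > 0 and res.kept > 0
        assert res.hits == 0

    def test_max_products_cap(self, library):
        target = next(m for m in library.molecules if m.id == "S00_V00")  # bare core
        res = optimize(
            target,
            [(H_TO_CL, H_TO_CL_SIGN)],
            library.predictor(noise_sd=0.0),
            OptimizationConfig(
                direction="increase", min_similarity=0.0, max_products_per_transformation=2
            ),
        )
        assert res.generated == 2
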