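"""Diet pipeline: unit conversions, augmentation identities, blending."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agmacap.diet import (
    AugmentationTable,
    CompoundInfo,
    DietError,
    DietSpec,
    FoodRecord,
    adjust_absorption,
    augment_nucleotides,
    augment_polyamines,
    blend_with_reference,
    build_participant_diet,
    mass_to_flux,
    normalize_caloric,
)
from agmacap.simulate import SimulationConfig, make_ffq


class TestMassToFlux:
    def test_reference_conversion(self):
        # 36 g/day at 180 g/mol = 200 mmol/day; over 200 g microbiota = 1.0
        assert mass_to_flux(36.0, 180.0) == pytest.approx(1.0)

    def test_zero_mass(self):
        assert mass_to_flux(0.0, 123.4) == 0.0

    def test_inverse_proportional_to_microbiota_mass(self):
        assert mass_to_flux(36.0, 180.0, microbiota_mass=100.0) == pytest.approx(2.0)

    def test_bad_molecular_weight(self):
        with pytest.raises(DietError):
            mass_to_flux(1.0, 0.0)


class TestCaloricNormalization:
    def test_double_caloric_value_halves_amounts(self):
        diet = DietSpec("p", {"glc": 4.0, "arg": 2.0}, caloric_value_kj=17598.0)
        out = normalize_caloric(diet)
        assert out.amounts == {"glc": 2.0, "arg": 1.0}
        assert out.caloric_value_kj == 8799.0

    def test_already_at_target_unchanged(self):
        diet = DietSpec("p", {"glc": 4.0}, caloric_value_kj=8799.0)
        assert normalize_caloric(diet).amounts == diet.amounts

    def test_idempotent(self):
        diet = DietSpec("p", {"glc": 5.0}, caloric_value_kj=4000.0)
        once = normalize_caloric(diet)
        assert normalize_caloric(once).amounts == once.amounts

    def test_scale_equivariance(self):
        # doubling all masses doubles the caloric value; normalization cancels it
        diet = DietSpec("p", {"glc": 3.0, "arg": 1.5}, caloric_value_kj=5000.0)
        doubled = DietSpec("p", {c: 2 * a for c, a in diet.amounts.items()},
                           caloric_value_kj=10000.0)
        a, b = normalize_caloric(diet), normalize_caloric(doubled)
        for c in a.amounts:
            assert a.amounts[c] == pytest.approx(b.amounts[c])

    def test_zero_caloric_value_is_an_error(self):
        with pytest.raises(DietError):
            normalize_caloric(DietSpec("p", {"glc": 1.0}, caloric_value_kj=0.0))


def _records(*items):
    return [
        FoodRecord("p", item, ("plant", "grain"), grams) for item, grams in items
    ]


class TestNucleotideAugmentation:
    def test_pyrimidine_identities(self):
        # 200 g at 2e-3 mmol/g -> 0.4 / 200 g microbiota... use direct numbers:
        table = AugmentationTable(
            contents={"bread": {"adenosine": 2.0, "guanosine": 1.0}},
            groups={"bread": ("plant", "grain")},
        )
        diet = DietSpec("p", {}, 0.0)
        out = augment_nucleotides(diet, _records(("bread", 200.0)), table)
        # adenosine class total = 2.0 * 200 / 200 = 2.0 mmol/gM/d
        assert out.amounts["adn"] + out.amounts["dad_2"] == pytest.approx(2.0)
        assert out.amounts["thymd"] + out.amounts["ura"] == pytest.approx(2.0)
        assert out.amounts["csn"] == pytest.approx(1.0)

    def test_group_average_imputation(self):
        table = AugmentationTable(
            contents={
                "bread": {"adenosine": 2.0, "guanosine": 1.0},
                "rolls": {"adenosine": 4.0, "guanosine": 3.0},
                "beer": {},  # no data: imputed from the plant/grain group
            },
            groups={"bread": ("plant", "grain"), "rolls": ("plant", "grain"),
                    "beer": ("plant", "grain")},
        )
        out = augment_nucleotides(
            DietSpec("p", {}, 0.0), _records(("beer", 200.0)), table
        )
        assert out.amounts["thymd"] + out.amounts["ura"] == pytest.approx(3.0)

    def test_no_data_anywhere_is_an_error(self):
        table = AugmentationTable(contents={"beer": {}}, groups={"beer": ("x",)})
        with pytest.raises(DietError, match="beer"):
            augment_nucleotides(DietSpec("p", {}, 0.0), _records(("beer", 10.0)), table)

    def test_zero_purines_zero_pyrimidines(self):
        table = AugmentationTable(
            contents={"water": {"adenosine": 0.0, "guanosine": 0.0}},
            groups={"water": ("bev",)},
        )
        out = augment_nucleotides(DietSpec("p", {}, 0.0), _records(("water", 500.0)), table)
        assert out.amounts["thymd"] == 0.0 and out.amounts["csn"] == 0.0


class TestPolyamineAugmentation:
    def test_ornithine_extrapolated_at_factor(self):
        table = AugmentationTable(
            contents={"bread": {"cadaverine": 0.1, "putrescine": 0.2,
                                "spermidine": 0.15, "spermine": 0.05}},
            groups={"bread": ("plant", "grain")},
        )
        out = augment_polyamines(DietSpec("p", {}, 0.0), _records(("bread", 200.0)), table)
        # polyamine total 0.5 mmol/g * 200 g / 200 gM -> ornithine 3.28 * 0.5
        assert out.amounts["orn"] == pytest.approx(3.28 * 0.5)

    def test_measured_ornithine_used_directly(self):
        table = AugmentationTable(
            contents={"beef": {"cadaverine": 0.1, "putrescine": 0.2,
                               "spermidine": 0.15, "spermine": 0.05,
                               "ornithine": 0.2}},
            groups={"beef": ("animal", "meat")},
        )
        out = augment_polyamines(
            DietSpec("p", {}, 0.0),
            [FoodRecord("p", "beef", ("animal", "meat"), 200.0)], table,
        )
        assert out.amounts["orn"] == pytest.approx(0.2)

    def test_zero_polyamines_zero_ornithine(self):
        table = AugmentationTable(
            contents={"water": {c: 0.0 for c in
                                ("cadaverine", "putrescine", "spermidine", "spermine")}},
            groups={"water": ("bev",)},
        )
        out = augment_polyamines(DietSpec("p", {}, 0.0), _records(("water", 100.0)), table)
        assert out.amounts["orn"] == 0.0

    def test_negative_table_entry_rejected(self):
        with pytest.raises(DietError):
            AugmentationTable(contents={"x": {"cadaverine": -0.1}}, groups={"x": ("g",)})


class TestBlending:
    def test_ninety_ten_blend(self):
        diet = DietSpec("p", {"glc": 10.0}, 8799.0)
        out = blend_with_reference(diet, {"glc": 2.0})
        assert out.amounts["glc"] == pytest.approx(0.9 * 10 + 0.1 * 2)

    def test_retained_mineral_takes_reference_value(self):
        diet = DietSpec("p", {"pi": 10.0}, 8799.0)
        out = blend_with_reference(diet, {"pi": 2.0})
        assert out.amounts["pi"] == 2.0

    def test_fraction_one_returns_participant_diet(self):
        diet = DietSpec("p", {"glc": 10.0, "arg": 1.0}, 8799.0)
        out = blend_with_reference(diet, {"glc": 2.0}, participant_fraction=1.0,
                                   retained_compounds=())
        assert out.amounts == diet.amounts

    @given(f=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_blending_a_diet_with_itself_is_identity(self, f):
        diet = DietSpec("p", {"glc": 3.0, "arg": 0.5}, 8799.0)
        out = blend_with_reference(diet, diet, participant_fraction=f,
                                   retained_compounds=())
        for c, a in diet.amounts.items():
            assert out.amounts[c] == pytest.approx(a)

    def test_reference_only_compound_enters_at_reference_fraction(self):
        out = blend_with_reference(DietSpec("p", {}, 8799.0), {"nh4": 1.0})
        assert out.amounts["nh4"] == pytest.approx(0.1)


class TestAbsorption:
    @pytest.mark.parametrize("frac,expect", [(0.8, 2.0), (0.0, 10.0), (1.0, 0.0)])
    def test_absorbed_fraction(self, frac, expect):
        out = adjust_absorption(DietSpec("p", {"glc": 10.0}, 0.0), {"glc": frac})
        assert out.amounts["glc"] == pytest.approx(expect)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(DietError):
            adjust_absorption(DietSpec("p", {"glc": 1.0}, 0.0), {"glc": 1.2})

    def test_unmapped_compound_unchanged(self):
        out = adjust_absorption(DietSpec("p", {"glc": 10.0}, 0.0), {"arg": 0.5})
        assert out.amounts["glc"] == 10.0


class TestFullPipeline:
    def test_matches_independent_recomputation(self):
        """The composed pipeline equals a step-by-step hand recomputation."""
        ffq = make_ffq(SimulationConfig(seed=7, n_participants=2))
        pid = "ffq_000"
        records, intake = ffq["records"][pid], ffq["intakes"][pid]
        got, log = build_participant_diet(
            records, intake, ffq["compound_map"], ffq["purine_table"],
            ffq["polyamine_table"], ffq["reference_diet"],
        )
        # independent recomposition using only the documented step algebra
        amounts = {}
        caloric = 0.0
        for compound, grams in intake.items():
            info = ffq["compound_map"][compound]
            key = info.exchange_metabolite_id
            amounts[key] = amounts.get(key, 0.0) + grams / info.molecular_weight * 5.0
            caloric += grams * info.kj_per_gram
        expect = DietSpec(pid, amounts, caloric)
        expect = augment_nucleotides(expect, records, ffq["purine_table"])
        expect = augment_polyamines(expect, records, ffq["polyamine_table"])
        expect = normalize_caloric(expect)
        expect = blend_with_reference(expect, ffq["reference_diet"])
        assert set(got.amounts) == set(expect.amounts)
        for c in expect.amounts:
            assert got.amounts[c] == pytest.approx(expect.amounts[c], abs=1e-15), c
        assert [s["step"] for s in log] == [
            "mapped", "nucleotides", "polyamines", "caloric_normalized", "blended",
        ]

    def test_identical_participants_identical_diets(self):
        ffq = make_ffq(SimulationConfig(seed=7, n_participants=1))
        pid = "ffq_000"
        args = (ffq["records"][pid], ffq["intakes"][pid], ffq["compound_map"],
                ffq["purine_table"], ffq["polyamine_table"], ffq["reference_diet"])
        a, _ = build_participant_diet(*args)
        b, _ = build_participant_diet(*args)
        assert a.amounts == b.amounts

    def test_all_zero_intake_yields_reference_tail_only(self):
        ffq = make_ffq(SimulationConfig(seed=7, n_participants=1))
        pid = "ffq_000"
        records = [
            FoodRecord(pid, r.food_item, r.group_path, 0.0)
            for r in ffq["records"][pid]
        ]
        with pytest.raises(DietError):
            # zero intake -> zero caloric value: normalization must refuse
            build_participant_diet(
                records, {}, ffq["compound_map"], ffq["purine_table"],
                ffq["polyamine_table"], ffq["reference_diet"],
            )

    def test_every_step_preserves_non_negativity(self):
        ffq = make_ffq(SimulationConfig(seed=13, n_participants=3))
        for pid in ("ffq_000", "ffq_001", "ffq_002"):
            diet, _ = build_participant_diet(
                ffq["records"][pid], ffq["intakes"][pid], ffq["compound_map"],
                ffq["purine_table"], ffq["polyamine_table"], ffq["reference_diet"],
                absorbed_fraction={"glc": 0.9, "arg": 0.5},
            )
            assert all(a >= 0 for a in diet.amounts.values())
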