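"""Biophysical chain: geometry, shedding proportionality, genome accounting."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ctdna_screen import (
    DetectionCriterion,
    DrawSpec,
    ShedModel,
    TumorSpec,
    diameter_to_volume,
    expected_cancer_genomes,
    genome_equivalents_per_ml,
    maf_from_volume,
    total_genome_equivalents,
    volume_from_maf,
    volume_to_cells,
    volume_to_diameter,
)


class TestGeometry:
    @pytest.mark.parametrize(
        "diameter_mm, volume_cm3",
        [
            (12.407, 1.0),       # the canonical 1 cm³ <-> ~1.2 cm nodule
            (0.0, 0.0),
            (27.0, 10.306),      # 10 cm³ at the table's rounding
        ],
    )
    def test_diameter_to_volume(self, diameter_mm, volume_cm3):
        assert diameter_to_volume(diameter_mm) == pytest.approx(volume_cm3, abs=5e-4)

    @pytest.mark.parametrize(
        "volume_cm3, diameter_mm",
        [(1.0, 12.407), (0.0, 0.0), (0.5, 9.847)],
    )
    def test_volume_to_diameter(self, volume_cm3, diameter_mm):
        assert volume_to_diameter(volume_cm3) == pytest.approx(diameter_mm, abs=5e-3)

    def test_one_cm3_is_1_2_cm_at_2sf(self):
        assert round(volume_to_diameter(1.0) / 10, 1) == 1.2

    @given(st.floats(min_value=1e-6, max_value=100.0))
    @settings(deadline=None)
    def test_roundtrip(self, d):
        assert volume_to_diameter(diameter_to_volume(d)) == pytest.approx(
            d, rel=1e-9
        )

    @given(st.floats(min_value=0, max_value=99), st.floats(min_value=1e-9, max_value=1))
    @settings(deadline=None)
    def test_strictly_increasing(self, d, eps):
        assert diameter_to_volume(d + eps) > diameter_to_volume(d)

    @pytest.mark.parametrize("fn", [diameter_to_volume, volume_to_diameter,
                                    volume_to_cells, maf_from_volume])
    def test_negative_input_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(-1.0)


class TestCellsAndShedding:
    @pytest.mark.parametrize(
        "volume_cm3, cells", [(1.0, 1e9), (0.0, 0.0), (0.25, 2.5e8)]
    )
    def test_volume_to_cells(self, volume_cm3, cells):
        assert volume_to_cells(volume_cm3) == pytest.approx(cells)

    @pytest.mark.parametrize(
        "volume_cm3, maf",
        [(10.0, 1e-3), (0.0, 0.0), (0.5, 5e-5), (1.0, 1e-4)],
    )
    def test_maf_from_volume(self, volume_cm3, maf, model):
        assert maf_from_volume(volume_cm3, model) == pytest.approx(maf)

    @pytest.mark.parametrize("maf, volume_cm3", [(1e-4, 1.0), (0.0, 0.0), (1e-3, 10.0)])
    def test_volume_from_maf(self, maf, volume_cm3, model):
        assert volume_from_maf(maf, model) == pytest.approx(volume_cm3)

    def test_maf_out_of_range_rejected(self, model):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                volume_from_maf(bad, model)

    def test_maf_caps_at_one(self, model):
        assert maf_from_volume(1e9, model) == 1.0

    @given(st.floats(min_value=1e-8, max_value=0.99))
    @settings(deadline=None)
    def test_maf_volume_roundtrip(self, maf):
        model = ShedModel()
        assert maf_from_volume(volume_from_maf(maf, model), model) == pytest.approx(
            maf, rel=1e-9
        )


class TestGenomeAccounting:
    def test_default_genome_equivalents_per_ml(self, model):
        ge = genome_equivalents_per_ml(model)
        assert ge == pytest.approx(1505.5, abs=0.1)
        # the familiar round number at two significant figures
        assert round(ge, -2) == 1500

    def test_zero_concentration(self):
        model = ShedModel(cfdna_conc_ng_per_ml=0.0)
        assert genome_equivalents_per_ml(model) == 0.0

    def test_high_concentration_scales_linearly(self, model):
        model10 = ShedModel(cfdna_conc_ng_per_ml=10.0)
        assert genome_equivalents_per_ml(model10) == pytest.approx(
            2 * genome_equivalents_per_ml(model)
        )
        assert genome_equivalents_per_ml(model10) == pytest.approx(3011, abs=1)

    def test_total_per_default_draw(self, model, draw):
        total = total_genome_equivalents(draw, model)
        assert total == pytest.approx(6022, abs=1)
        assert round(total, -3) == 6000

    def test_total_scales_with_blood_volume(self, model):
        assert total_genome_equivalents(DrawSpec(blood_ml=20.0), model) == (
            pytest.approx(12044, abs=2)
        )
        assert total_genome_equivalents(DrawSpec(blood_ml=0.0), model) == 0.0

    def test_explicit_plasma_overrides_fraction(self, model):
        d = DrawSpec(blood_ml=10.0, plasma_ml=4.0)
        assert d.resolve_plasma_ml(model) == 4.0


class TestExpectedCancerGenomes:
    @pytest.mark.parametrize(
        "volume_cm3, genomes",
        [(10.0, 6.0), (0.0, 0.0), (1.0, 0.6), (0.5, 0.3), (0.25, 0.15)],
    )
    def test_table_convention(self, volume_cm3, genomes, model, draw):
        tumor = TumorSpec.from_volume(volume_cm3)
        assert expected_cancer_genomes(
            tumor, draw, model, total_genomes=6000
        ) == pytest.approx(genomes)

    def test_exact_convention_close_to_table(self, model, draw):
        tumor = TumorSpec.from_volume(10.0)
        assert expected_cancer_genomes(tumor, draw, model) == pytest.approx(
            6.022, abs=0.001
        )

    @given(st.floats(min_value=0.5, max_value=2.0))
    @settings(deadline=None)
    def test_linear_in_plasma_and_volume(self, s):
        model, draw = ShedModel(), DrawSpec()
        base = expected_cancer_genomes(TumorSpec.from_volume(1.0), draw, model)
        scaled_draw = expected_cancer_genomes(
            TumorSpec.from_volume(1.0), DrawSpec(blood_ml=10.0 * s), model
        )
        scaled_vol = expected_cancer_genomes(TumorSpec.from_volume(s), draw, model)
        scaled_conc = expected_cancer_genomes(
            TumorSpec.from_volume(1.0),
            draw,
            ShedModel(cfdna_conc_ng_per_ml=5.0 * s),
        )
        for scaled in (scaled_draw, scaled_vol, scaled_conc):
            assert scaled == pytest.approx(s * base, rel=1e-9)


class TestTypes:
    def test_tumor_from_diameter_consistent(self):
        t = TumorSpec.from_diameter(12.407)
        assert t.volume_cm3 == pytest.approx(1.0, abs=1e-3)
        assert t.weight_mg == pytest.approx(1000.0, abs=1)
        assert t.cell_count == pytest.approx(1e9, rel=1e-3)

    def test_tumor_all_zero_allowed(self):
        t = TumorSpec.from_volume(0.0)
        assert t.diameter_mm == t.weight_mg == t.cell_count == 0.0

    def test_tumor_mixed_zero_rejected(self):
        with pytest.raises(ValueError):
            TumorSpec(diameter_mm=10.0, volume_cm3=0.0, weight_mg=500.0,
                      cell_count=5e8)

    def test_tabulated_mode_accepts_printed_values(self):
        # the 5 mm published row: weight 62 mg, not the sphere's 65.4
        t = TumorSpec.tabulated(5.0, 62.0, 0.06, 62_000_000)
        assert t.weight_mg == 62.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf_per_cm3": 0.0},
            {"maf_per_cm3": 1.5},
            {"genome_mass_da": -1.0},
            {"plasma_per_blood": 1.0},
        ],
    )
    def test_shed_model_validation(self, kwargs):
        with pytest.raises(ValueError):
            ShedModel(**kwargs)

    @pytest.mark.parametrize("cls", [ShedModel, DrawSpec, DetectionCriterion])
    def test_json_yaml_roundtrip(self, cls):
        obj = cls()
        assert cls.from_json(obj.to_json()) == obj
        assert cls.from_yaml(obj.to_yaml()) == obj

    def test_shed_model_field_names_in_config(self):
        d = ShedModel().to_dict()
        assert set(d) == {
            "maf_per_cm3",
            "genome_mass_da",
            "cfdna_conc_ng_per_ml",
            "plasma_per_blood",
        }
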