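"""Parallel-tissue algebra: per-tissue resistance, parallel combination,
mixture conductivity, and the default stage geometries."""
import math

import numpy as np
import pytest

import wristbia as wb
from wristbia.dielectrics import DielectricTable, TissueCrossSection, WristComposition
from wristbia.errors import ConfigurationError, FrequencyRangeError
from wristbia.geometry import WristGeometry


def _flat_table(name, sigma):
    f = np.array([1e3, 1e6])
    return DielectricTable(name, f, np.full(2, sigma), np.full(2, 100.0))


def _comp(stage, *sections):
    obj = object.__new__(WristComposition)
    object.__setattr__(obj, "sections", tuple(sections))
    object.__setattr__(obj, "stage", stage)
    return obj


class TestTissueResistance:
    def test_direct_arithmetic(self):
        sec = TissueCrossSection("muscle", 1e-3)
        r = wb.tissue_resistance(sec, _flat_table("muscle", 0.5), 1e4, 0.05)
        assert r == pytest.approx(100.0, rel=1e-12)

    def test_linear_in_length(self):
        sec = TissueCrossSection("fat", 4e-4)
        t = _flat_table("fat", 0.025)
        assert wb.tissue_resistance(sec, t, 1e4, 0.10) == pytest.approx(
            2 * wb.tissue_resistance(sec, t, 1e4, 0.05), rel=1e-12)

    def test_stage1_muscle_matches_hand_computation(self, tables):
        comp = wb.default_composition("model1")
        muscle = next(s for s in comp.sections if s.tissue == "muscle")
        f, l = 1e5, 0.018
        expected = l / (tables["muscle"].conductivity(f) * muscle.area)
        assert wb.tissue_resistance(muscle, tables["muscle"], f, l) == pytest.approx(
            expected, rel=1e-12)

    def test_out_of_range_frequency_rejected(self, tables):
        sec = TissueCrossSection("muscle", 1e-3)
        with pytest.raises(FrequencyRangeError):
            wb.tissue_resistance(sec, tables["muscle"], 10.0, 0.05)

    def test_zero_area_rejected(self):
        with pytest.raises(ConfigurationError):
            TissueCrossSection("muscle", 0.0)


class TestOverallResistance:
    def test_single_tissue_degenerates_to_tissue_resistance(self):
        sec = TissueCrossSection("muscle", 1.5e-3)
        t = _flat_table("muscle", 0.3)
        comp = _comp("model1", sec)
        assert wb.overall_resistance(comp, {"muscle": t}, 1e4, 0.05) == pytest.approx(
            wb.tissue_resistance(sec, t, 1e4, 0.05), rel=1e-12)

    def test_l_pu_proportionality(self, tables):
        comp = wb.default_composition("model1")
        r50 = wb.overall_resistance(comp, tables, 1e5, 0.050)
        r10 = wb.overall_resistance(comp, tables, 1e5, 0.010)
        assert r50 / r10 == pytest.approx(5.0, rel=1e-12)

    def test_conductance_additivity_of_equal_sections(self):
        a, b = TissueCrossSection("fat", 1e-3), TissueCrossSection("muscle", 1e-3)
        tabs = {"fat": _flat_table("fat", 0.1), "muscle": _flat_table("muscle", 0.7)}
        r = wb.overall_resistance(_comp("model1", a, b), tabs, 1e4, 0.05)
        merged = _comp("model1", TissueCrossSection("fat", 2e-3))
        r_merged = wb.overall_resistance(merged, {"fat": _flat_table("fat", 0.4)},
                                         1e4, 0.05)
        assert r == pytest.approx(r_merged, rel=1e-12)

    def test_parallel_combination_of_parts(self, tables):
        comp = wb.default_composition("model2")
        f, l = 2.15e3, 0.018
        g = sum(1.0 / wb.tissue_resistance(s, tables[s.tissue], f, l)
                for s in comp.sections)
        assert wb.overall_resistance(comp, tables, f, l) == pytest.approx(
            1.0 / g, rel=1e-12)

    def test_monotone_in_conductivity_and_area(self, tables):
        comp = wb.default_composition("model1")
        base = wb.overall_resistance(comp, tables, 1e5, 0.018)
        bigger = _comp("model1", *(
            TissueCrossSection(s.tissue, s.area * (1.3 if s.tissue == "blood" else 1.0))
            for s in comp.sections))
        assert wb.overall_resistance(bigger, tables, 1e5, 0.018) < base
        hot = dict(tables)
        t = tables["muscle"]
        hot["muscle"] = DielectricTable("muscle", t.frequencies, t.sigma * 1.2, t.eps_r)
        assert wb.overall_resistance(comp, hot, 1e5, 0.018) < base

    def test_missing_table_rejected(self, tables):
        comp = wb.default_composition("model3")
        tabs = {k: v for k, v in tables.items() if k != "cancellous"}
        with pytest.raises(ConfigurationError, match="cancellous"):
            wb.overall_resistance(comp, tabs, 1e5, 0.018)


class TestMixtureConductivity:
    def test_single_tissue_identity(self):
        comp = _comp("model1", TissueCrossSection("fat", 1e-3))
        got = wb.mixture_conductivity(comp, {"fat": _flat_table("fat", 0.025)}, 1e4)
        assert got == pytest.approx(0.025, rel=1e-12)

    def test_equal_areas_arithmetic_mean(self):
        comp = _comp("model1", TissueCrossSection("a", 1e-3),
                     TissueCrossSection("b", 1e-3))
        tabs = {"a": _flat_table("a", 0.1), "b": _flat_table("b", 0.7)}
        assert wb.mixture_conductivity(comp, tabs, 1e4) == pytest.approx(0.4, rel=1e-12)

    def test_surrounding_conductivity_excludes_blood(self, tables):
        comp = wb.default_composition("model3")
        got = wb.surrounding_conductivity(comp, tables, 1e5)
        manual = wb.mixture_conductivity(comp.without("blood"), tables, 1e5)
        assert got == manual
        # blood dominates conductivity, so excluding it must lower the mixture
        assert got < wb.mixture_conductivity(comp, tables, 1e5)

    def test_stage3_band_is_physically_plausible(self, tables):
        # soft plausibility check: same order of magnitude as a gelatine
        # surrounding-tissue simulant across the band
        vals = [wb.surrounding_conductivity(wb.default_composition("model3"),
                                            tables, f)
                for f in (1e3, 1e4, 1e5, 1e6)]
        assert all(0.02 < v < 0.3 for v in vals)
        assert vals == sorted(vals)  # beta dispersion: rises with frequency


class TestDefaults:
    def test_stage_tissue_sets(self):
        names1 = {s.tissue for s in wb.default_composition("model1").sections}
        assert names1 == {"fat", "muscle", "blood"}
        names2 = {s.tissue for s in wb.default_composition("model2").sections}
        assert names2 == {"fat", "muscle", "blood", "skin"}
        names3 = {s.tissue for s in wb.default_composition("model3").sections}
        assert names3 == {"fat", "muscle", "blood", "skin", "cortical", "cancellous"}

    def test_sections_sum_to_cuboid_area(self):
        geo = WristGeometry()
        for stage in ("model1", "model2", "model3"):
            total = sum(s.area for s in wb.default_composition(stage).sections)
            assert total == pytest.approx(geo.cross_section_area, rel=1e-9)

    def test_printed_anchor_values(self, tables):
        assert tables["skin"].conductivity(1e3) == pytest.approx(0.00065738)
        blood = [tables["blood"].conductivity(f) for f in np.logspace(3, 6, 20)]
        assert all(0.70 <= s <= 0.82 for s in blood)

    def test_bone_block_replaces_68_percent_of_muscle(self):
        geo = WristGeometry()
        areas = geo.section_areas("model3")
        bone = areas["cortical"] + areas["cancellous"]
        assert bone == pytest.approx(0.68 * geo.stage1_muscle_area, rel=0.01)

    def test_table_csv_round_trip(self, tables, tmp_path):
        from wristbia.dielectrics import read_dielectric_csv, write_dielectric_csv
        path = tmp_path / "tables.csv"
        write_dielectric_csv(tables, path)
        back = read_dielectric_csv(path)
        assert set(back) == set(tables)
        for name in tables:
            np.testing.assert_allclose(back[name].sigma, tables[name].sigma)
            np.testing.assert_allclose(back[name].eps_r, tables[name].eps_r)
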