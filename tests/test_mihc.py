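"""mIHC gating, density, proximity and co-localization tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from hexspot import mihc
from hexspot.containers import MARKER_COLUMNS, CellTable
from hexspot.errors import ConfigurationError, InvalidArgumentError
from hexspot.mihc import PhenotypeRule
from hexspot.synthdata import MihcConfig, simulate_mihc_dataset


def _table(cells_spec, um_per_px=1.0, area_px2=1e6):
    """cells_spec: list of (x, y, positive-marker list, compartment)."""
    rows = []
    for x, y, pos, comp in cells_spec:
        row = {"slide": "S1", "subtype": "A", "compartment": comp,
               "x_px": x, "y_px": y}
        for m in MARKER_COLUMNS:
            row[m] = m in pos
        rows.append(row)
    meta = pd.DataFrame({"slide": ["S1"], "subtype": ["A"],
                         "um_per_px": [um_per_px],
                         "area_px2_tumor": [area_px2 / 2],
                         "area_px2_stroma": [area_px2 / 2]}).set_index("slide")
    return CellTable(pd.DataFrame(rows), meta)


class TestPhenotypeRules:
    def test_parse_mixed_signs(self):
        rule = PhenotypeRule.from_string("CD68+CD163+CD206-")
        assert rule.positive == {"CD68", "CD163"}
        assert rule.negative == {"CD206"}

    def test_typographic_minus_accepted(self):
        rule = PhenotypeRule.from_string("CD68+CD206−")
        assert rule.negative == {"CD206"}

    def test_malformed_spec(self):
        with pytest.raises(ConfigurationError):
            PhenotypeRule.from_string("CD68")

    def test_conflicting_markers(self):
        with pytest.raises(ConfigurationError):
            PhenotypeRule("bad", {"CD68"}, {"CD68"})


class TestGating:
    def test_definition_membership(self):
        ct = _table([(0, 0, ["CD68", "CD163"], "tumor")])
        rules = [PhenotypeRule.from_string("CD68+CD163+CD206-"),
                 PhenotypeRule.from_string("CD68+CD163+CD206+")]
        out = mihc.gate_phenotypes(ct, rules)
        assert out["CD68+CD163+CD206-"].iloc[0]
        assert not out["CD68+CD163+CD206+"].iloc[0]

    def test_negative_marker_excludes(self):
        ct = _table([(0, 0, ["PanCK", "CD68"], "tumor")])
        rule = PhenotypeRule("tumor_only", {"PanCK"}, {"CD68"})
        assert not mihc.gate_phenotypes(ct, [rule]).tumor_only.iloc[0]

    def test_unknown_marker_rejected(self):
        ct = _table([(0, 0, ["CD68"], "tumor")])
        with pytest.raises(ConfigurationError):
            mihc.gate_phenotypes(ct, [PhenotypeRule("x", {"CD999"})])


class TestDensities:
    def test_simple_density(self):
        # 100 cells on a 1 mm^2 slide -> 100 cells/mm^2
        cells = [(float(i), 0.0, ["CD68"], "tumor") for i in range(100)]
        ct = _table(cells, um_per_px=1.0, area_px2=1e6)
        out = mihc.densities(ct, [PhenotypeRule("CD68+", {"CD68"})])
        row = out[(out.compartment == "all")].iloc[0]
        assert row.density == pytest.approx(100.0)

    def test_unit_conversion(self):
        # 250 cells over 2,000,000 px^2 at 0.5 um/px -> 0.5 mm^2 -> 500/mm^2
        cells = [(float(i), 0.0, ["CD68"], "tumor") for i in range(250)]
        ct = _table(cells, um_per_px=0.5, area_px2=2_000_000)
        out = mihc.densities(ct, [PhenotypeRule("CD68+", {"CD68"})])
        row = out[(out.compartment == "all")].iloc[0]
        assert row.area_mm2 == pytest.approx(0.5)
        assert row.density == pytest.approx(500.0)

    def test_zero_cells_zero_density(self):
        ct = _table([(0, 0, ["PanCK"], "tumor")])
        out = mihc.densities(ct, [PhenotypeRule("CD68+", {"CD68"})])
        assert (out.density == 0).all()

    def test_compartment_counts_sum_to_total(self):
        cfg = MihcConfig(n_slides=2, width_px=600, height_px=600, seed=8)
        ct, _ = simulate_mihc_dataset(cfg)
        rules = [PhenotypeRule("CD68+", {"CD68"})]
        out = mihc.densities(ct, rules)
        for slide in ct.slides:
            sub = out[out.slide == slide]
            total = sub[sub.compartment == "all"]["count"].iloc[0]
            parts = sub[sub.compartment != "all"]["count"].sum()
            assert parts == total


class TestProximity:
    def test_three_four_five_triangle(self):
        ct = _table([(0.0, 0.0, ["PanCK"], "tumor"),
                     (3.0, 4.0, ["CD68"], "stroma")])
        out = mihc.proximity_to_tumor(ct, [PhenotypeRule("CD68+", {"CD68"})])
        assert out.median_distance_um.iloc[0] == pytest.approx(5.0)

    def test_coincident_cell_distance_zero(self):
        ct = _table([(1.0, 1.0, ["PanCK"], "tumor"),
                     (1.0, 1.0, ["CD68"], "tumor")])
        out = mihc.proximity_to_tumor(ct, [PhenotypeRule("CD68+", {"CD68"})])
        assert out.median_distance_um.iloc[0] == 0.0

    def test_scale_equivariance(self):
        cells = [(0.0, 0.0, ["PanCK"], "tumor"), (6.0, 8.0, ["CD68"], "stroma")]
        d1 = mihc.proximity_to_tumor(_table(cells, um_per_px=1.0),
                                     [PhenotypeRule("CD68+", {"CD68"})])
        d2 = mihc.proximity_to_tumor(_table(cells, um_per_px=2.0),
                                     [PhenotypeRule("CD68+", {"CD68"})])
        assert d2.median_distance_um.iloc[0] == \
            pytest.approx(2 * d1.median_distance_um.iloc[0])

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(30, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + [500, 300]
        rule = PhenotypeRule("CD68+", {"CD68"})
        def build(coords):
            spec = [(x, y, ["PanCK"] if i < 10 else ["CD68"], "tumor")
                    for i, (x, y) in enumerate(coords)]
            return _table(spec)
        d1 = mihc.proximity_to_tumor(build(pts), [rule])
        d2 = mihc.proximity_to_tumor(build(moved), [rule])
        assert d1.median_distance_um.iloc[0] == \
            pytest.approx(d2.median_distance_um.iloc[0])

    def test_kdtree_matches_brute_force(self):
        rng = np.random.default_rng(1)
        tumor = rng.uniform(0, 1000, size=(400, 2))
        other = rng.uniform(0, 1000, size=(600, 2))
        spec = ([(x, y, ["PanCK"], "tumor") for x, y in tumor]
                + [(x, y, ["CD68"], "stroma") for x, y in other])
        ct = _table(spec)
        out = mihc.proximity_to_tumor(ct, [PhenotypeRule("CD68+", {"CD68"})])
        brute = cdist(other, tumor).min(axis=1)
        assert out.median_distance_um.iloc[0] == pytest.approx(np.median(brute))

    def test_slide_without_tumor_skipped(self, caplog):
        ct = _table([(0.0, 0.0, ["CD68"], "stroma")])
        out = mihc.proximity_to_tumor(ct, [PhenotypeRule("CD68+", {"CD68"})])
        assert out.empty


class TestColocalizationAndSubtypes:
    def _density_table(self, values: dict, subtype=None):
        rows = []
        slides = sorted({s for v in values.values() for s in range(len(v))})
        for ph, v in values.items():
            for s, d in enumerate(v):
                rows.append({"slide": f"S{s}", "subtype": (subtype or {}).get(
                    f"S{s}", "A"), "compartment": "all", "phenotype": ph,
                    "count": 0, "area_mm2": 1.0, "density": d})
        return pd.DataFrame(rows)

    def test_identical_densities_correlate_perfectly(self):
        v = [1.0, 3.0, 2.0, 5.0, 4.0]
        table = self._density_table({"X": v, "Y": v})
        out = mihc.colocalization(table, [("X", "Y")])
        assert out.coefficient.iloc[0] == pytest.approx(1.0)

    def test_constant_density_untestable(self):
        table = self._density_table({"X": [1.0] * 5, "Y": [1, 2, 3, 4, 5]})
        out = mihc.colocalization(table, [("X", "Y")])
        assert not out.tested.iloc[0]

    def test_planted_shared_gradient_detected(self):
        cfg = MihcConfig(n_slides=30, width_px=800, height_px=800,
                         shared_gradient=("CD68+IRF8+", "CD68+CD206+"),
                         gradient_sigma=0.8, seed=12)
        ct, _ = simulate_mihc_dataset(cfg)
        rules = [PhenotypeRule.from_string(n) for n in
                 ("CD68+IRF8+", "CD68+CD206+", "CD68+CD163+")]
        dens = mihc.densities(ct, rules, by_compartment=False)
        out = mihc.colocalization(dens, [("CD68+IRF8+", "CD68+CD206+")])
        assert out.coefficient.iloc[0] > 0.5
        assert out.significant.iloc[0]

    def test_subtype_comparison_identical(self):
        table = self._density_table(
            {"X": [2.0] * 9}, subtype={f"S{i}": "ABC"[i % 3] for i in range(9)})
        res = mihc.density_subtype_comparison(table, "X")
        assert res["p"] == pytest.approx(1.0)

    def test_planted_subtype_trend_detected(self):
        scale = {"N": 0.3, "Lep": 0.5, "A": 1.0, "MP": 1.5, "PA": 2.0, "S": 3.0}
        cfg = MihcConfig(n_slides=36, width_px=800, height_px=800,
                         subtype_density_scale=scale, seed=13)
        ct, _ = simulate_mihc_dataset(cfg)
        rules = [PhenotypeRule.from_string("CD68+CD163+")]
        dens = mihc.densities(ct, rules, by_compartment=False)
        res = mihc.density_subtype_comparison(dens, "CD68+CD163+")
        assert res["p"] < 0.05
        assert res["dunn"] is not None

    def test_missing_phenotype_rejected(self):
        table = self._density_table({"X": [1, 2, 3]})
        with pytest.raises(InvalidArgumentError):
            mihc.density_subtype_comparison(table, "NOPE")
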