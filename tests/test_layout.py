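"""Coordinate assignment, the fixed-coordinate property, and overlap resolution."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from cvkmap import (
    LayoutConfig,
    PathwayGraph,
    bounding_circle,
    cartesian_layout,
    parse_formula,
    polar_layout,
    polar_position,
    resolve_overlaps,
)
from cvkmap.fixtures import make_random_graph

TWO_PI = 2 * math.pi


def _graph_of(formulas: dict[str, str]) -> PathwayGraph:
    g = PathwayGraph()
    for cid, formula in formulas.items():
        g.add_compound(cid, parse_formula(formula))
    return g


class TestLayoutConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"hc_max": 0.0},
            {"hc_max": -1.0},
            {"y_ratio": "nc"},
            {"min_sep": -0.1},
            {"direction": 2},
            {"r_max": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LayoutConfig(**kwargs)


class TestCartesian:
    def test_worked_example_coordinates(self):
        lay = cartesian_layout(_graph_of({"ex": "C26H43NO5"}))
        x, y = lay.coordinates("ex")
        assert round(x, 3) == 1.654
        assert round(y, 3) == 0.301

    def test_oc_axis_selection(self):
        lay = cartesian_layout(_graph_of({"ex": "C26H43NO5"}), LayoutConfig(y_ratio="oc"))
        assert round(lay.coordinates("ex")[1], 3) == 0.192

    def test_methane(self):
        lay = cartesian_layout(_graph_of({"m": "CH4"}))
        assert lay.coordinates("m") == (4.0, 0.0)

    def test_no_clipping_no_displacement(self):
        lay = cartesian_layout(_graph_of({"a": "C2H6", "b": "C50H2O40"}), LayoutConfig(r_max=0.5))
        assert not lay.table["clipped"].any()
        assert not lay.table["displaced"].any()


class TestPolar:
    def test_zero_hc_sits_at_origin_angle(self):
        for origin in (0.0, math.pi / 2):
            lay = polar_layout(_graph_of({"c": "C2O"}), LayoutConfig(theta_origin=origin))
            assert lay.table.loc["c", "theta"] == pytest.approx(origin)

    def test_half_scale_maps_to_pi(self):
        lay = polar_layout(_graph_of({"e": "C2H4"}))  # hc = 2 = hc_max/2
        assert lay.table.loc["e", "theta"] == pytest.approx(math.pi)

    def test_worked_example_polar(self):
        lay = polar_layout(_graph_of({"ex": "C26H43NO5"}))
        assert lay.table.loc["ex", "theta"] == pytest.approx(2.598, abs=1e-3)
        assert lay.table.loc["ex", "r"] == pytest.approx(0.301, abs=5e-4)

    def test_clockwise_direction(self):
        lay = polar_layout(_graph_of({"e": "C4H4"}), LayoutConfig(direction=-1))
        # hc=1, ccw angle would be pi/2; cw mirrors to 3*pi/2
        assert lay.table.loc["e", "theta"] == pytest.approx(3 * math.pi / 2)

    def test_radial_clip_flagged(self):
        lay = polar_layout(_graph_of({"h": "CH2O9"}), LayoutConfig(r_max=2.0))
        row = lay.table.loc["h"]
        assert row["clipped"] and row["r"] == 2.0

    def test_hc_saturation_flagged_not_wrapped(self):
        lay = polar_layout(_graph_of({"s": "CH9"}))  # hc = 9 > 4
        row = lay.table.loc["s"]
        assert row["hc_saturated"]
        assert row["theta"] == pytest.approx(0.0)  # full turn reduces to origin

    def test_angles_in_range_radii_nonnegative(self):
        g = make_random_graph(40, 0, seed=11)
        lay = polar_layout(g)
        assert ((lay.table["theta"] >= 0) & (lay.table["theta"] < TWO_PI)).all()
        assert (lay.table["r"] >= 0).all()


class TestFixedCoordinate:
    def test_same_formula_same_coordinate_across_graphs(self):
        config = LayoutConfig()
        rng = np.random.default_rng(42)
        for trial in range(20):
            from cvkmap import ElementCount

            counts = ElementCount(
                {
                    "C": int(rng.integers(1, 40)),
                    "H": int(rng.integers(1, 60)),
                    "O": int(rng.integers(0, 10)),
                    "N": int(rng.integers(0, 6)),
                }
            )
            g1 = make_random_graph(6, 4, seed=int(rng.integers(0, 1000)), id_prefix="A")
            g2 = make_random_graph(9, 2, seed=int(rng.integers(0, 1000)), id_prefix="B")
            g1.add_compound("probe1", counts)
            g2.add_compound("zz_probe2", counts)
            l1 = polar_layout(g1, config)
            l2 = polar_layout(g2, config)
            assert tuple(l1.table.loc["probe1", ["theta", "r", "x", "y"]]) == tuple(
                l2.table.loc["zz_probe2", ["theta", "r", "x", "y"]]
            )

    def test_pure_function_matches_layout(self, caffeine_graph):
        config = LayoutConfig()
        lay = polar_layout(caffeine_graph, config)
        for comp in caffeine_graph.compounds:
            theta, r = polar_position(comp.ratios, config)
            assert lay.table.loc[comp.id, "theta"] == theta
            assert lay.table.loc[comp.id, "r"] == r

    def test_order_invariance_with_resolution(self):
        formulas = {"a": "C8H10N4O2", "b": "C8H10N4O2", "c": "C8H10N4O2", "d": "C5H4N4O2"}
        g1 = _graph_of(formulas)
        g2 = PathwayGraph()
        for cid in reversed(list(formulas)):
            g2.add_compound(cid, parse_formula(formulas[cid]))
        r1 = resolve_overlaps(polar_layout(g1))
        r2 = resolve_overlaps(polar_layout(g2))
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestResolveOverlaps:
    def _threshold(self, layout):
        return layout.config.min_sep * bounding_circle(layout)

    def test_noop_when_already_separated(self):
        lay = polar_layout(_graph_of({"a": "CH4", "b": "C2H2O4"}))
        res = resolve_overlaps(lay)
        pd.testing.assert_frame_equal(res.table, lay.table)
        assert res.residual_collisions == 0

    def test_coincident_pair_contract(self):
        g = _graph_of({"iso1": "C7H8N4O2", "iso2": "C7H8N4O2", "far": "C5H4N4O3"})
        lay = polar_layout(g, LayoutConfig(r_max=2.0, min_sep=0.01))
        res = resolve_overlaps(lay)
        t = 0.01 * 2.0
        p1 = res.table.loc["iso1", ["x", "y"]].to_numpy(dtype=float)
        p2 = res.table.loc["iso2", ["x", "y"]].to_numpy(dtype=float)
        assert np.linalg.norm(p1 - p2) >= t * (1 - 1e-9)
        for cid in ("iso1", "iso2"):
            assert res.table.loc[cid, "displacement"] <= t * (1 + 1e-6)
            # radius untouched
            assert res.table.loc[cid, "r"] == lay.table.loc[cid, "r"]
        # angular midpoint equals the original shared angle
        mid = (res.table.loc["iso1", "theta"] + res.table.loc["iso2", "theta"]) / 2
        assert mid == pytest.approx(lay.table.loc["iso1", "theta"], abs=1e-9)
        # untouched node is bit-identical
        assert tuple(res.table.loc["far"]) == tuple(lay.table.loc["far"])

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_cluster_separated_radius_preserved(self, k):
        g = _graph_of({f"m{i:02d}": "C8H10N4O2" for i in range(k)})
        lay = polar_layout(g, LayoutConfig(r_max=2.0, min_sep=0.01))
        res = resolve_overlaps(lay)
        t = 0.01 * 2.0
        xy = res.table[["x", "y"]].to_numpy(dtype=float)
        assert len(np.unique(xy, axis=0)) == k
        assert pdist(xy).min() >= t * (1 - 1e-9)
        assert (res.table["r"] == lay.table["r"]).all()
        # symmetric fan: worst-case displacement is ceil((k-1)/2) fan gaps
        assert (res.table["displacement"] <= math.ceil((k - 1) / 2) * t * (1 + 1e-6)).all()
        assert res.residual_collisions == 0

    def test_deterministic(self):
        g = _graph_of({f"m{i}": "C6H6N4O2" for i in range(6)})
        lay = polar_layout(g, LayoutConfig(r_max=2.0))
        r1 = resolve_overlaps(lay)
        r2 = resolve_overlaps(polar_layout(g, LayoutConfig(r_max=2.0)))
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_origin_cluster_is_residual(self):
        # hydrocarbons have zero NOPS:C, hence radius 0: angular displacement
        # cannot separate them and they are reported, not moved
        g = _graph_of({"hc1": "C2H2", "hc2": "C2H4"})
        lay = polar_layout(g, LayoutConfig(r_max=1.0))
        res = resolve_overlaps(lay)
        assert res.residual_collisions == 1
        pd.testing.assert_frame_equal(
            res.table[["x", "y", "theta", "r"]], lay.table[["x", "y", "theta", "r"]]
        )

    def test_cartesian_mode_shifts_x_keeps_y(self):
        g = _graph_of({"i1": "C6H12O6", "i2": "C6H12O6"})
        lay = cartesian_layout(g, LayoutConfig(min_sep=0.05, r_max=1.0))
        res = resolve_overlaps(lay)
        assert res.table.loc["i1", "x"] != res.table.loc["i2", "x"]
        assert (res.table["y"] == lay.table["y"]).all()

    def test_random_instances_respect_bound(self):
        # displacement never exceeds the fan bound over random layouts
        for seed in range(5):
            g = make_random_graph(30, 0, carbon_range=(2, 8), seed=seed)
            lay = polar_layout(g, LayoutConfig(r_max=4.0, min_sep=0.02))
            res = resolve_overlaps(lay)
            t = 0.02 * 4.0
            moved = res.table[res.table["displaced"]]
            k_max = len(moved) if len(moved) else 1
            assert (moved["displacement"] <= math.ceil((k_max - 1) / 2 + 1) * t * (1 + 1e-6)).all()
            assert (res.table["r"] == lay.table["r"]).all()


class TestBoundingCircle:
    def test_configured_rmax_wins(self):
        lay = polar_layout(_graph_of({"a": "C2H4O"}), LayoutConfig(r_max=3.0))
        assert bounding_circle(lay) == 3.0

    def test_data_driven_max(self):
        lay = polar_layout(_graph_of({"a": "C26H43NO5", "b": "C10H10O1"}))
        assert bounding_circle(lay) == pytest.approx(max(lay.table["r"]))

    def test_empty_layout_rejected(self):
        lay = polar_layout(PathwayGraph())
        with pytest.raises(ValueError):
            bounding_circle(lay)


def test_layout_export_columns(tmp_path, caffeine_graph):
    lay = resolve_overlaps(polar_layout(caffeine_graph))
    out = tmp_path / "layout.tsv"
    lay.write(out)
    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == [
        "compound_id", "formula", "hc", "selected_ratio", "theta_rad",
        "r", "x", "y", "displaced", "clipped",
    ]
    assert len(df) == 14
    # full floating precision survives the round trip
    assert df.set_index("compound_id").loc["caffeine", "hc"] == 10 / 8
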