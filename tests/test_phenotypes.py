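"""The 17 image-derived phenotypes: unit oracles and end-to-end contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retvasc.graph import OpticDisc, RasterMask, VesselGraph, VesselSegment
from retvasc.phenotypes import (IDP_FIELDS, central_retinal_equivalent,
                                compute_idps, count_bifurcations,
                                diameter_stats, knudtson_pair,
                                median_tortuosity, segment_tortuosity,
                                temporal_angle, vascular_density)
from retvasc.synthetic import (TreeParams, generate_tree,
                               make_half_circle_centerline,
                               make_sinusoidal_centerline, rasterize_polyline)


def _segment(points, diameters=None, cls="artery"):
    return VesselSegment(vessel_class=cls, points=np.asarray(points, float),
                         diameters=None if diameters is None
                         else np.asarray(diameters, float))


def _graph(segments, cls="artery"):
    return VesselGraph(segments=list(segments), vessel_class=cls)


def _trace(mask):
    from retvasc.phenotypes import _extract_graph
    return _extract_graph(mask, spur_px=10, merge_radius=2.0)


class TestVascularDensity:
    def test_trivial_fractions(self):
        roi = RasterMask(np.ones((10, 10), bool))
        empty = RasterMask(np.zeros((10, 10), bool))
        assert vascular_density(empty, roi) == 0.0
        assert vascular_density(roi, roi) == 1.0
        half = np.zeros((10, 10), bool)
        half[:5] = True
        assert vascular_density(RasterMask(half), roi) == 0.5

    def test_empty_roi_rejected(self):
        empty = RasterMask(np.zeros((10, 10), bool))
        with pytest.raises(ValueError):
            vascular_density(empty, empty)


class TestDiameterStats:
    def test_constant_and_hand_computed(self):
        g = _graph([_segment([[0, 0], [0, 9]], [5.0] * 10)])
        assert diameter_stats(g, min_points=5) == (5.0, 0.0)
        g = _graph([_segment([[0, 0], [0, 3]], [4, 4, 6, 6])])
        assert diameter_stats(g, min_points=4) == (5.0, 1.0)

    def test_below_min_points_missing(self):
        g = _graph([_segment([[0, 0], [0, 3]], [4, 4, 6, 6])])
        med, std = diameter_stats(g, min_points=50)
        assert math.isnan(med) and math.isnan(std)


class TestTortuosity:
    def test_straight_segment_is_one(self):
        assert segment_tortuosity(_segment([[0, 0], [0, 50], [0, 100]])) == 1.0

    def test_short_chord_excluded(self):
        assert segment_tortuosity(_segment([[0, 0], [0, 5]]),
                                  min_chord_px=10) is None

    def test_half_circle_traced_matches_analytic(self):
        pts, _ = make_half_circle_centerline(60, center=(150, 150))
        mask = rasterize_polyline(pts, 3, (300, 300))
        g = _trace(mask)
        tort = max(segment_tortuosity(s) for s in g.segments)
        assert tort == pytest.approx(np.pi / 2, rel=0.02)

    def test_sinusoid_traced_matches_quadrature(self):
        pts, arc = make_sinusoidal_centerline(200, 5, 50, start=(100, 20))
        true_ratio = arc / np.hypot(*(pts[-1] - pts[0]))
        mask = rasterize_polyline(pts, 3, (300, 300))
        g = _trace(mask)
        [seg] = g.segments
        assert segment_tortuosity(seg) == pytest.approx(true_ratio, abs=1e-2)

    def test_median_and_exclusion_invariance(self):
        segs = [
            _segment([[0, 0], [0, 20]]),                      # 1.0
            _segment([[10, 0], [14, 10], [10, 20]], None),    # ~1.077
            _segment([[20, 0], [28, 10], [20, 20]], None),    # ~1.28
        ]
        g = _graph(segs)
        base = median_tortuosity(g)
        assert base == pytest.approx(
            segment_tortuosity(segs[1]), abs=1e-12)
        g_extra = _graph(segs + [_segment([[30, 0], [33, 4]])])  # chord 5 < 10
        assert median_tortuosity(g_extra) == base


class TestKnudtson:
    def test_point_values(self):
        assert knudtson_pair(100, 100, "artery") == pytest.approx(124.45, abs=0.01)
        assert knudtson_pair(100, 100, "vein") == pytest.approx(134.35, abs=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            knudtson_pair(0, 5, "artery")

    @settings(derandomize=True, max_examples=50)
    @given(w1=st.floats(0.1, 500), w2=st.floats(0.1, 500),
           c=st.floats(0.01, 10))
    def test_symmetry_and_homogeneity(self, w1, w2, c):
        assert knudtson_pair(w1, w2, "vein") == knudtson_pair(w2, w1, "vein")
        assert knudtson_pair(c * w1, c * w2, "artery") == pytest.approx(
            c * knudtson_pair(w1, w2, "artery"), rel=1e-12)


def _spoke_graph(widths, od, cls="artery"):
    """Radial segments crossing the zone-B annulus with constant widths."""
    segs = []
    for i, w in enumerate(widths):
        ang = np.deg2rad(10 + i * 25)
        u = np.array([np.sin(ang), np.cos(ang)])
        pts = np.asarray(od.center) + np.outer(
            np.linspace(1.2 * od.radius, 3.5 * od.radius, 40), u)
        segs.append(_segment(pts, [w] * 40, cls))
    return _graph(segs, cls)


def _hand_pairing(widths, coef):
    """Independent oracle: explicit recursion of the pairing scheme."""
    vals = sorted(widths, reverse=True)
    while len(vals) > 1:
        out = []
        while len(vals) > 1:
            a, b = vals[0], vals[-1]
            vals = vals[1:-1]
            out.append(coef * math.hypot(a, b))
        out.extend(vals)
        vals = sorted(out, reverse=True)
    return vals[0]


class TestCentralRetinalEquivalent:
    OD = OpticDisc(center=(200.0, 200.0), radius=40.0)

    def test_six_equal_widths_match_hand_iteration(self):
        for cls, coef in (("artery", 0.88), ("vein", 0.95)):
            g = _spoke_graph([10.0] * 6, self.OD, cls)
            value, n = central_retinal_equivalent(g, self.OD)
            assert n == 6
            assert value == pytest.approx(_hand_pairing([10.0] * 6, coef),
                                          abs=1e-9)
            assert value / 10.0 == pytest.approx(
                1.74842 if cls == "artery" else 2.13761, abs=1e-4)

    def test_permutation_invariance_and_homogeneity(self):
        widths = [12.0, 9.0, 15.0, 7.5, 11.0, 8.0]
        v1, _ = central_retinal_equivalent(
            _spoke_graph(widths, self.OD), self.OD)
        rng = np.random.default_rng(0)
        v2, _ = central_retinal_equivalent(
            _spoke_graph(list(rng.permutation(widths)), self.OD), self.OD)
        assert v1 == pytest.approx(v2, rel=1e-12)
        v3, _ = central_retinal_equivalent(
            _spoke_graph([2.5 * w for w in widths], self.OD), self.OD)
        assert v3 == pytest.approx(2.5 * v1, rel=1e-12)
        assert v1 == pytest.approx(_hand_pairing(widths, 0.88), rel=1e-12)

    def test_widest_six_selected_and_flagged_when_fewer(self):
        v_seven, n7 = central_retinal_equivalent(
            _spoke_graph([20, 18, 16, 14, 12, 10, 1.0], self.OD), self.OD)
        v_six, n6 = central_retinal_equivalent(
            _spoke_graph([20, 18, 16, 14, 12, 10], self.OD), self.OD)
        assert (n7, n6) == (6, 6)
        assert v_seven == pytest.approx(v_six, rel=1e-12)
        v_two, n2 = central_retinal_equivalent(
            _spoke_graph([10, 10], self.OD), self.OD)
        assert n2 == 2
        assert v_two == pytest.approx(0.88 * math.hypot(10, 10), rel=1e-12)

    def test_no_od_missing(self):
        value, n = central_retinal_equivalent(
            _spoke_graph([10] * 6, self.OD), None)
        assert math.isnan(value) and n == 0


class TestTemporalAngle:
    def test_synthetic_arcades_recovered(self):
        params = TreeParams(depth=2, arcade_sup_deg=60.0, arcade_inf_deg=60.0,
                            seed=6)
        artery, _, od, _ = generate_tree(params)
        g = _trace(artery)
        angle = temporal_angle(g, od, artery.shape)
        assert angle == pytest.approx(120.0, abs=5.0)

    def test_mirror_symmetry_about_od_horizontal(self):
        params = TreeParams(depth=2, arcade_sup_deg=65.0, arcade_inf_deg=45.0,
                            seed=8)
        artery, _, od, _ = generate_tree(params)
        g = _trace(artery)
        base = temporal_angle(g, od, artery.shape)
        for seg in g.segments:  # reflect the traced geometry exactly
            seg.points[:, 0] = 2 * od.center[0] - seg.points[:, 0]
        mirrored = temporal_angle(g, od, artery.shape)
        assert mirrored == pytest.approx(base, abs=1e-9)

    def test_single_trunk_missing(self):
        artery, _, od, _ = generate_tree(TreeParams(depth=0, seed=2))
        g = _trace(artery)
        assert math.isnan(temporal_angle(g, od, artery.shape))


class TestBifurcationCount:
    def test_one_y_per_class(self):
        def y_mask():
            canvas = np.zeros((120, 120), bool)
            for a, b in [((100, 60), (60, 60)), ((60, 60), (20, 30)),
                         ((60, 60), (20, 90))]:
                rasterize_polyline(np.array([a, b], float), 3, canvas.shape,
                                   out=canvas)
            return RasterMask(canvas)
        ga, gv = _trace(y_mask()), _trace(y_mask())
        assert count_bifurcations(ga, gv) == 2

    def test_cross_class_crossing_not_counted(self):
        a = rasterize_polyline(np.array([[60.0, 10.0], [60.0, 110.0]]), 3,
                               (120, 120))
        v = rasterize_polyline(np.array([[10.0, 60.0], [110.0, 60.0]]), 3,
                               (120, 120))
        assert count_bifurcations(_trace(a), _trace(v)) == 0

    def test_synthetic_trees_depth3(self, tree3):
        artery, vein, _, _ = tree3
        assert count_bifurcations(_trace(artery), _trace(vein)) == 14

    def test_empty_graphs_zero(self):
        assert count_bifurcations(VesselGraph(), VesselGraph()) == 0


class TestComputeIDPs:
    def test_full_fixture_all_17_present(self, tree3_idps):
        assert set(tree3_idps.values) == set(IDP_FIELDS)
        assert len(IDP_FIELDS) == 17
        assert tree3_idps.n_present() == 17

    def test_empty_vein_propagates_missing(self, tree3):
        artery, vein, od, _ = tree3
        empty = RasterMask(np.zeros(vein.shape, bool), vessel_class="vein")
        idp = compute_idps(artery, empty, od)
        for f in IDP_FIELDS:
            if f.startswith(("v_", "ratio_")) or f == "bifurcations":
                assert math.isnan(idp[f]), f
            else:
                assert not math.isnan(idp[f]), f

    def test_ratio_consistency(self, tree3_idps):
        idp = tree3_idps
        assert idp["ratio_vascular_density"] * idp["v_vascular_density"] == \
            pytest.approx(idp["a_vascular_density"], abs=1e-12)
        assert idp["ratio_tortuosity"] == pytest.approx(
            idp["a_tortuosity"] / idp["v_tortuosity"], abs=1e-12)

    def test_shape_mismatch_rejected(self, tree3):
        artery, _, od, _ = tree3
        small = RasterMask(np.zeros((10, 10), bool), vessel_class="vein")
        with pytest.raises(ValueError):
            compute_idps(artery, small, od)

    def test_translation_invariance(self):
        params = TreeParams(depth=2, seed=13, canvas_shape=(640, 640),
                            od_center=(300.0, 160.0))
        artery, vein, od, _ = generate_tree(params)
        shifted = TreeParams(depth=2, seed=13, canvas_shape=(640, 640),
                             od_center=(320.0, 180.0))
        artery2, vein2, od2, _ = generate_tree(shifted)
        roi = RasterMask(np.ones((640, 640), bool))
        idp1 = compute_idps(artery, vein, od, roi=roi)
        idp2 = compute_idps(artery2, vein2, od2, roi=roi)
        assert idp1["bifurcations"] == idp2["bifurcations"]
        assert idp1["a_vascular_density"] == pytest.approx(
            idp2["a_vascular_density"], rel=0.02)
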