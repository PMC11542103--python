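"""Synthetic retinal vasculature with exhaustive ground truth.

Emulates the inputs of the phenotyping pipeline — per-class (artery/vein)
binary vessel rasters rooted near an optic disc — while recording the exact
quantities the pipeline is supposed to recover: bifurcation counts,
per-segment diameters and tortuosities, arcade elevation angles, and vessel
pixel counts.

Geometry: each class is one bifurcating tree.  A trunk enters from the nasal
side and splits exactly at the optic-disc centre into a superior and an
inferior temporal arcade (elevations ``arcade_sup_deg`` / ``arcade_inf_deg``
above/below the horizontal).  Each subsequent level splits symmetrically
about the parent direction, with branch lengths, diameters (Murray-type
caliber law: parent^k = sum child^k) and split angles decaying geometrically.
Centerlines are sinusoidal with controllable amplitude/wavelength, giving an
analytic tortuosity oracle.  The vein tree is the same construction rigidly
rotated by a few degrees about the disc centre (this leaves the sum of the
two arcade elevations — the true temporal angle — unchanged) so that the two
class rasters are distinct and artery–vein crossings arise from overlap.

Pixel conventions: 0-based (row, col), origin top-left, y increases
downward; elevation angles in degrees, positive above the horizontal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, ndimage

from .graph import OpticDisc, RasterMask

__all__ = [
    "TreeParams",
    "SyntheticTruth",
    "generate_tree",
    "rasterize_polyline",
    "make_sinusoidal_centerline",
    "make_half_circle_centerline",
    "random_params",
]


@dataclass
class TreeParams:
    """Parameters of one synthetic artery/vein tree pair.

    ``depth`` is the number of bifurcation levels: 0 gives a single
    unbranched trunk per class; depth d gives a complete binary tree with
    2^d - 1 bifurcations per class.
    """

    depth: int = 3
    root_diameter_px: float = 14.0
    caliber_exponent: float = 3.0  # Murray's law default
    branch_half_angle_deg: float = 32.0
    segment_length_px: float = 100.0
    tortuosity_amplitude: float = 2.0
    tortuosity_wavelength_px: float = 60.0
    arcade_sup_deg: float = 55.0
    arcade_inf_deg: float = 55.0
    seed: int = 0
    canvas_shape: tuple[int, int] = (576, 576)
    od_center: tuple[float, float] = (288.0, 150.0)
    od_radius_px: float = 40.0
    length_decay: float = 0.7
    angle_decay: float = 0.7
    angle_jitter_deg: float = 2.0
    vein_rotation_deg: float = 4.0
    vein_diameter_scale: float = 1.1

    def __post_init__(self) -> None:
        if self.depth < 0 or int(self.depth) != self.depth:
            raise ValueError("depth must be an integer >= 0")
        if not self.root_diameter_px > 0:
            raise ValueError("root_diameter_px must be > 0")
        if not self.caliber_exponent > 0:
            raise ValueError("caliber_exponent must be > 0")
        if not 0 < self.branch_half_angle_deg < 90:
            raise ValueError("branch_half_angle_deg must be in (0, 90)")
        if not self.segment_length_px > 0:
            raise ValueError("segment_length_px must be > 0")
        if self.tortuosity_amplitude < 0:
            raise ValueError("tortuosity_amplitude must be >= 0")
        if not self.tortuosity_wavelength_px > 0:
            raise ValueError("tortuosity_wavelength_px must be > 0")
        for name in ("arcade_sup_deg", "arcade_inf_deg"):
            if not 0 < getattr(self, name) < 90:
                raise ValueError(f"{name} must be in (0, 90)")


@dataclass
class SyntheticTruth:
    """Generator-side ground truth used as the test oracle."""

    n_bifurcations_per_class: int
    segments: pd.DataFrame  # one row per true segment
    true_temporal_angle_deg: dict[str, Optional[float]]
    true_vessel_pixel_count: dict[str, int]
    od_center: tuple[float, float]
    od_radius_px: float
    params: TreeParams = field(repr=False, default=None)

    def segments_of(self, vessel_class: str) -> pd.DataFrame:
        return self.segments[self.segments["vessel_class"] == vessel_class]

    def median_tortuosity(self, vessel_class: str) -> float:
        return float(self.segments_of(vessel_class)["true_tortuosity"].median())

    def to_csv(self, path) -> None:
        self.segments.to_csv(path, index=False)

    def sidecar_json(self) -> str:
        d = asdict(self.params)
        d.update(
            n_bifurcations_per_class=self.n_bifurcations_per_class,
            true_temporal_angle_deg=self.true_temporal_angle_deg,
            true_vessel_pixel_count=self.true_vessel_pixel_count,
            od_center=list(self.od_center),
            od_radius_px=self.od_radius_px,
        )
        d.pop("segments", None)
        return json.dumps(d, indent=2, default=float)


# ---------------------------------------------------------------------------
# centerline primitives

def make_sinusoidal_centerline(
    chord_px: float,
    amplitude: float,
    wavelength: float,
    *,
    start: tuple[float, float] = (0.0, 0.0),
    direction_deg: float = 0.0,
    step_px: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Sinusoidally displaced centerline with quadrature arc length.

    The curve runs a chordwise distance ``chord_px`` from ``start`` along
    elevation ``direction_deg``, displaced perpendicular to the chord by
    ``amplitude * sin(2*pi*s/wavelength)``.  Returns ``(points, arc_length)``
    where ``arc_length`` is computed by dense numerical quadrature of the
    exact speed — the independent tortuosity oracle.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if not chord_px > 0:
        raise ValueError("chord_px must be > 0")
    if wavelength > chord_px:
        raise ValueError("wavelength must be <= chord length")
    k = 2.0 * np.pi / wavelength
    s = np.linspace(0.0, chord_px, max(2, int(np.ceil(chord_px / step_px)) + 1))
    offset = amplitude * np.sin(k * s)
    theta = np.deg2rad(direction_deg)
    u = np.array([-np.sin(theta), np.cos(theta)])  # chord direction (row, col)
    v = np.array([-np.cos(theta), -np.sin(theta)])  # unit perpendicular
    pts = np.asarray(start, dtype=float) + np.outer(s, u) + np.outer(offset, v)
    arc, _ = integrate.quad(
        lambda t: np.sqrt(1.0 + (amplitude * k * np.cos(k * t)) ** 2),
        0.0, chord_px, limit=200)
    return pts, float(arc)


def make_half_circle_centerline(
    radius_px: float,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    n_points: int = 721,
) -> tuple[np.ndarray, float]:
    """Half-circle polyline; arc/chord = pi/2 analytically."""
    if not radius_px > 0:
        raise ValueError("radius_px must be > 0")
    t = np.linspace(0.0, np.pi, n_points)
    pts = np.column_stack([
        np.asarray(center)[0] - radius_px * np.sin(t),
        np.asarray(center)[1] + radius_px * np.cos(t),
    ])
    return pts, float(np.pi * radius_px)


def _densify(points: np.ndarray, max_step: float = 0.5) -> np.ndarray:
    """Resample a polyline so consecutive points are <= max_step apart."""
    pts = np.asarray(points, dtype=float)
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        d = float(np.hypot(*(b - a)))
        n = max(1, int(np.ceil(d / max_step)))
        for i in range(1, n + 1):
            out.append(a + (b - a) * i / n)
    return np.asarray(out)


def rasterize_polyline(
    centerline: np.ndarray,
    diameter_px: float,
    shape: tuple[int, int],
    out: Optional[np.ndarray] = None,
) -> RasterMask:
    """Draw a stroke: union of disks of radius ``diameter_px/2`` centered on
    the densified polyline.  If ``out`` is given, the stroke is OR-ed into it
    in place (and also returned wrapped as a RasterMask)."""
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("rasterize_polyline needs >= 2 centerline points")
    if not diameter_px >= 1:
        raise ValueError("diameter_px must be >= 1")
    canvas = out if out is not None else np.zeros(shape, dtype=bool)
    dense = _densify(pts)
    radius = diameter_px / 2.0
    margin = int(np.ceil(radius)) + 2
    r0 = max(0, int(np.floor(dense[:, 0].min())) - margin)
    r1 = min(shape[0], int(np.ceil(dense[:, 0].max())) + margin + 1)
    c0 = max(0, int(np.floor(dense[:, 1].min())) - margin)
    c1 = min(shape[1], int(np.ceil(dense[:, 1].max())) + margin + 1)
    sub = np.ones((r1 - r0, c1 - c0), dtype=bool)
    rows = np.rint(dense[:, 0]).astype(int) - r0
    cols = np.rint(dense[:, 1]).astype(int) - c0
    keep = (rows >= 0) & (rows < sub.shape[0]) & (cols >= 0) & (cols < sub.shape[1])
    sub[rows[keep], cols[keep]] = False
    dist = ndimage.distance_transform_edt(sub)
    canvas[r0:r1, c0:c1] |= dist <= radius
    return RasterMask(canvas)


# ---------------------------------------------------------------------------
# tree generation

def _check_in_canvas(points: np.ndarray, radius: float,
                     shape: tuple[int, int], level: int, length: float) -> None:
    lo = points.min(axis=0) - radius
    hi = points.max(axis=0) + radius
    if (lo < 0).any() or hi[0] >= shape[0] or hi[1] >= shape[1]:
        raise ValueError(
            f"synthetic tree exceeds the canvas at depth level {level} "
            f"(segment length {length:.1f} px, stroke radius {radius:.1f} px); "
            f"reduce depth/segment_length_px or enlarge canvas_shape")


def _grow_class(params: TreeParams, vessel_class: str,
                rotation_deg: float, diam_scale: float,
                rng: np.random.Generator):
    """Return (list of segment dicts, n_bifurcations) for one class."""
    od = np.asarray(params.od_center, dtype=float)
    rot = np.deg2rad(rotation_deg)

    def place(start, direction_deg, chord, diameter, level):
        """Build one sinusoidal segment; rotation applied to the direction."""
        wavelength = min(params.tortuosity_wavelength_px, chord)
        pts, arc = make_sinusoidal_centerline(
            chord, params.tortuosity_amplitude, wavelength,
            start=start, direction_deg=direction_deg + rotation_deg)
        chord_actual = float(np.hypot(*(pts[-1] - pts[0])))
        return {
            "vessel_class": vessel_class,
            "level": level,
            "points": pts,
            "true_diameter_px": diameter * diam_scale,
            "true_arc_length_px": arc,
            "true_tortuosity": arc / chord_actual,
        }

    segments = []
    n_bif = 0
    shrink = 2.0 ** (-1.0 / params.caliber_exponent)

    # trunk from the nasal edge of the disc; for depth 0 it continues
    # temporally for a full segment length instead of splitting
    trunk_start = od + np.array([0.0, -params.od_radius_px])
    # rotate the trunk start about the OD centre too, so the whole tree is rigid
    if rotation_deg != 0.0:
        rel = trunk_start - od
        cr, sr = np.cos(rot), np.sin(rot)
        # rotation by +deg moves directions to higher elevation (row decreases)
        rel = np.array([rel[0] * cr - rel[1] * sr, rel[0] * sr + rel[1] * cr])
        trunk_start = od + rel
    trunk_chord = params.od_radius_px + (params.segment_length_px
                                         if params.depth == 0 else 0.0)
    segments.append(place(trunk_start, 0.0, trunk_chord,
                          params.root_diameter_px, 0))

    if params.depth >= 1:
        # first level: the superior/inferior arcade split at the OD centre
        d1 = params.root_diameter_px * shrink
        stack = [
            (segments[-1]["points"][-1], params.arcade_sup_deg, 1, d1),
            (segments[-1]["points"][-1], -params.arcade_inf_deg, 1, d1),
        ]
        n_bif += 1
        while stack:
            start, direction, level, diameter = stack.pop()
            jitter = rng.uniform(-params.angle_jitter_deg,
                                 params.angle_jitter_deg)
            chord = params.segment_length_px * params.length_decay ** (level - 1)
            seg = place(start, direction + jitter, chord, diameter, level)
            segments.append(seg)
            if level < params.depth:
                n_bif += 1
                half = (params.branch_half_angle_deg
                        * params.angle_decay ** (level - 1))
                child_d = diameter * shrink
                end = seg["points"][-1]
                stack.append((end, direction + jitter + half, level + 1, child_d))
                stack.append((end, direction + jitter - half, level + 1, child_d))

    return segments, n_bif


def generate_tree(params: TreeParams):
    """Generate artery and vein rasters, the optic disc, and ground truth.

    Deterministic for a fixed ``params.seed``.  Raises if any stroke would
    leave the canvas.
    """
    rng = np.random.default_rng(params.seed)
    rng_a = np.random.default_rng(rng.integers(2**31))
    rng_v = np.random.default_rng(rng.integers(2**31))

    art_segs, n_bif_a = _grow_class(params, "artery", 0.0, 1.0, rng_a)
    vein_segs, n_bif_v = _grow_class(params, "vein", params.vein_rotation_deg,
                                     params.vein_diameter_scale, rng_v)
    if n_bif_a != n_bif_v:
        raise AssertionError("class trees must have identical topology")

    shape = params.canvas_shape
    canvases = {"artery": np.zeros(shape, dtype=bool),
                "vein": np.zeros(shape, dtype=bool)}
    records = []
    for seg in art_segs + vein_segs:
        _check_in_canvas(seg["points"], seg["true_diameter_px"] / 2.0, shape,
                         seg["level"], float(seg["true_arc_length_px"]))
        rasterize_polyline(seg["points"], max(1.0, seg["true_diameter_px"]),
                           shape, out=canvases[seg["vessel_class"]])
        mid = seg["points"][len(seg["points"]) // 2]
        records.append({
            "vessel_class": seg["vessel_class"],
            "level": seg["level"],
            "true_diameter_px": seg["true_diameter_px"],
            "true_tortuosity": seg["true_tortuosity"],
            "true_arc_length_px": seg["true_arc_length_px"],
            "mid_row": float(mid[0]),
            "mid_col": float(mid[1]),
            "start_row": float(seg["points"][0][0]),
            "start_col": float(seg["points"][0][1]),
            "end_row": float(seg["points"][-1][0]),
            "end_col": float(seg["points"][-1][1]),
        })

    od = OpticDisc(center=tuple(params.od_center), radius=params.od_radius_px)
    angle = (params.arcade_sup_deg + params.arcade_inf_deg
             if params.depth >= 1 else None)
    truth = SyntheticTruth(
        n_bifurcations_per_class=n_bif_a,
        segments=pd.DataFrame(records),
        true_temporal_angle_deg={"artery": angle, "vein": angle},
        true_vessel_pixel_count={k: int(v.sum()) for k, v in canvases.items()},
        od_center=tuple(params.od_center),
        od_radius_px=params.od_radius_px,
        params=params,
    )
    artery = RasterMask(canvases["artery"], vessel_class="artery",
                        px_per_disc_diameter=2 * params.od_radius_px)
    vein = RasterMask(canvases["vein"], vessel_class="vein",
                      px_per_disc_diameter=2 * params.od_radius_px)
    return artery, vein, od, truth


def random_params(rng: np.random.Generator, *, max_depth: int = 3,
                  **overrides) -> TreeParams:
    """Sample a realistic parameter set for batch simulations."""
    base = dict(
        depth=int(rng.integers(1, max_depth + 1)),
        root_diameter_px=float(rng.uniform(10.0, 16.0)),
        branch_half_angle_deg=float(rng.uniform(26.0, 36.0)),
        segment_length_px=float(rng.uniform(85.0, 110.0)),
        tortuosity_amplitude=float(rng.uniform(0.0, 4.0)),
        tortuosity_wavelength_px=float(rng.uniform(50.0, 70.0)),
        arcade_sup_deg=float(rng.uniform(45.0, 65.0)),
        arcade_inf_deg=float(rng.uniform(45.0, 65.0)),
        seed=int(rng.integers(2**31)),
    )
    base.update(overrides)
    return TreeParams(**base)
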