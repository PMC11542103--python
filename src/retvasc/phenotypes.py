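"""The 17 image-derived vascular phenotypes (IDPs).

Per image: artery/vein main temporal angle, median tortuosity (+ ratio),
central retinal equivalent (+ ratio), diameter variability (std), vascular
density (+ ratio), median diameter (+ ratio), and the total number of vessel
bifurcations.  Ratios are oriented artery/vein.  Missing values propagate as
NaN, never as silent zeros.

Central retinal equivalents use the revised Knudtson pairing: the six widest
vessels in zone B (an annulus 0.5-1.0 disc diameters from the disc margin)
are combined iteratively, widest with narrowest, with branching coefficients
0.88 (arterioles) and 0.95 (venules).  Tortuosity is the distance factor:
centerline arc length over endpoint chord.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .graph import (OpticDisc, RasterMask, VesselGraph, build_graph,
                    consolidate_junctions, measure_diameters, prune_spurs,
                    skeletonize, smooth_segments)

__all__ = [
    "IDP_FIELDS",
    "IDPVector",
    "vascular_density",
    "diameter_stats",
    "segment_tortuosity",
    "median_tortuosity",
    "knudtson_pair",
    "central_retinal_equivalent",
    "temporal_angle",
    "count_bifurcations",
    "compute_idps",
    "default_roi",
]

#: Default exclusion/stability thresholds (all configurable per call).
MIN_CHORD_PX = 10.0     # tortuosity: segments with shorter chords excluded
MIN_DIAMETER_POINTS = 50  # diameter stats: fewer centerline samples -> missing
SPUR_PX = 10.0          # terminal spur pruning threshold
ZONE_B_DD = (0.5, 1.0)  # CRE annulus, in disc diameters from the disc margin
ANGLE_ANNULUS_R = (1.0, 2.5)  # temporal-angle annulus, in disc radii

KNUDTSON_COEF = {"artery": 0.88, "vein": 0.95}

IDP_FIELDS = (
    "a_temporal_angle", "v_temporal_angle",
    "a_tortuosity", "v_tortuosity", "ratio_tortuosity",
    "a_central_retinal_eq", "v_central_retinal_eq", "ratio_central_retinal_eq",
    "a_std_diameter", "v_std_diameter",
    "bifurcations",
    "a_vascular_density", "v_vascular_density", "ratio_vascular_density",
    "a_median_diameter", "v_median_diameter", "ratio_median_diameter",
)


@dataclass
class IDPVector:
    """The 17 named phenotype values for one image (NaN = missing)."""

    image_id: str = ""
    values: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = {k: float(self.values.get(k, np.nan)) for k in IDP_FIELDS}

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def n_present(self) -> int:
        return sum(0 if math.isnan(v) else 1 for v in self.values.values())

    def as_dict(self) -> dict:
        return dict(self.values)


# ---------------------------------------------------------------------------
# pixel-level phenotypes

def default_roi(shape: tuple[int, int], od: Optional[OpticDisc] = None) -> RasterMask:
    """Density denominator: the disk inscribed in the frame minus the OD disk."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    roi = (rr - cy) ** 2 + (cc - cx) ** 2 <= (min(h, w) / 2.0) ** 2
    if od is not None:
        roi &= (rr - od.center[0]) ** 2 + (cc - od.center[1]) ** 2 > od.radius ** 2
    return RasterMask(roi)


def vascular_density(mask: RasterMask, roi: RasterMask) -> float:
    """Fraction of ROI pixels covered by vessel, in [0, 1]."""
    if mask.shape != roi.shape:
        raise ValueError("mask and roi shapes differ")
    n_roi = roi.pixel_count()
    if n_roi == 0:
        raise ValueError("empty ROI")
    return float((mask.data & roi.data).sum() / n_roi)


# ---------------------------------------------------------------------------
# diameter phenotypes

def diameter_stats(graph: VesselGraph,
                   min_points: int = MIN_DIAMETER_POINTS
                   ) -> tuple[float, float]:
    """Median and population std over all per-point diameters of the class.

    Returns (nan, nan) when fewer than ``min_points`` centerline samples are
    available — a median over a handful of points is not a stable phenotype.
    """
    diams = [s.diameters for s in graph.segments if s.diameters is not None]
    if not diams:
        return (float("nan"), float("nan"))
    all_d = np.concatenate(diams)
    if all_d.size < min_points:
        return (float("nan"), float("nan"))
    return float(np.median(all_d)), float(np.std(all_d))


def knudtson_pair(w1: float, w2: float, vessel_class: str) -> float:
    """Combine two branch calibers into the parent-trunk equivalent
    (revised branching coefficients: 0.88 arteries, 0.95 veins)."""
    if not (w1 > 0 and w2 > 0):
        raise ValueError("branch widths must be positive")
    try:
        coef = KNUDTSON_COEF[vessel_class]
    except KeyError:
        raise ValueError(f"unknown vessel class {vessel_class!r}") from None
    return coef * math.sqrt(w1 * w1 + w2 * w2)


def _iterate_pairing(widths: list[float], vessel_class: str) -> float:
    """Iterative widest-with-narrowest combination until one value remains;
    an odd middle value is carried to the next round unchanged."""
    values = sorted(widths, reverse=True)
    while len(values) > 1:
        nxt = []
        i, j = 0, len(values) - 1
        while i < j:
            nxt.append(knudtson_pair(values[i], values[j], vessel_class))
            i, j = i + 1, j - 1
        if i == j:
            nxt.append(values[i])
        values = sorted(nxt, reverse=True)
    return values[0]


def central_retinal_equivalent(
    graph: VesselGraph,
    od: Optional[OpticDisc],
    zone_dd: tuple[float, float] = ZONE_B_DD,
    n_vessels: int = 6,
) -> tuple[float, int]:
    """Central retinal arteriolar/venular equivalent in zone B.

    Each segment contributes its mean diameter over centerline points inside
    the measurement annulus; the ``n_vessels`` widest are combined by the
    iterative pairing scheme.  Returns ``(value, n_used)``; with fewer than
    ``n_vessels`` eligible segments the equivalent is computed on what is
    available (callers should flag n_used < n_vessels), and is NaN with none.
    """
    if od is None:
        return (float("nan"), 0)
    r_in = od.radius * (1.0 + 2.0 * zone_dd[0])
    r_out = od.radius * (1.0 + 2.0 * zone_dd[1])
    center = np.asarray(od.center)
    widths = []
    for seg in graph.segments:
        if seg.diameters is None:
            continue
        r = np.hypot(*(seg.points - center).T)
        inside = (r >= r_in) & (r <= r_out)
        if inside.any():
            widths.append(float(seg.diameters[inside].mean()))
    if not widths:
        return (float("nan"), 0)
    widths = sorted(widths, reverse=True)[:n_vessels]
    return (_iterate_pairing(widths, graph.vessel_class), len(widths))


# ---------------------------------------------------------------------------
# tortuosity

def segment_tortuosity(segment, min_chord_px: float = MIN_CHORD_PX
                       ) -> Optional[float]:
    """Distance-factor tortuosity: arc length / endpoint chord (>= 1).

    Segments with chord shorter than ``min_chord_px`` are excluded (None):
    the ratio is numerically unstable for near-closed or tiny segments.
    """
    chord = segment.chord_length()
    if chord < min_chord_px:
        return None
    return max(1.0, segment.arc_length() / chord)


def median_tortuosity(graph: VesselGraph,
                      min_chord_px: float = MIN_CHORD_PX) -> float:
    values = [t for s in graph.segments
              if (t := segment_tortuosity(s, min_chord_px)) is not None]
    if not values:
        return float("nan")
    return float(np.median(values))


# ---------------------------------------------------------------------------
# temporal arcade angle

def temporal_angle(
    graph: VesselGraph,
    od: OpticDisc,
    image_shape: tuple[int, int],
    laterality_hint: Optional[str] = None,
    annulus_r: tuple[float, float] = ANGLE_ANNULUS_R,
    min_elevation_deg: float = 5.0,
) -> float:
    """Angle at the OD centre between the superior- and inferior-temporal
    principal arcade directions, in degrees (NaN if a hemifield is empty).

    Principal directions are diameter-weighted mean unit vectors (from the
    OD centre) over centerline points inside the annulus
    ``annulus_r * od.radius`` on the temporal side.  Points within
    ``min_elevation_deg`` of the OD horizontal belong to neither arcade (an
    undulating horizontal trunk must not masquerade as two arcades).  The
    temporal side is the half-plane away from the image's vertical midline
    relative to the OD offset, overridable with ``laterality_hint`` ('L':
    temporal is image right, 'R': temporal is image left — standard fundus
    orientation).
    """
    if laterality_hint is None:
        temporal_dir = 1.0 if od.center[1] <= (image_shape[1] - 1) / 2.0 else -1.0
    elif laterality_hint.upper() == "L":
        temporal_dir = 1.0
    elif laterality_hint.upper() == "R":
        temporal_dir = -1.0
    else:
        raise ValueError("laterality_hint must be 'L', 'R' or None")

    center = np.asarray(od.center)
    sup = np.zeros(2)
    inf = np.zeros(2)
    n_sup = n_inf = 0
    for seg in graph.segments:
        rel = seg.points - center
        r = np.hypot(rel[:, 0], rel[:, 1])
        keep = ((r >= annulus_r[0] * od.radius)
                & (r <= annulus_r[1] * od.radius)
                & (rel[:, 1] * temporal_dir > 0))
        if not keep.any():
            continue
        w = (seg.diameters[keep] if seg.diameters is not None
             else np.ones(int(keep.sum())))
        units = rel[keep] / r[keep, None]
        # elevation above the OD horizontal (y increases downward)
        elevation = np.degrees(np.arctan2(-rel[keep][:, 0],
                                          np.abs(rel[keep][:, 1])))
        above = elevation > min_elevation_deg
        below = elevation < -min_elevation_deg
        if above.any():
            sup += (w[above, None] * units[above]).sum(axis=0)
            n_sup += int(above.sum())
        if below.any():
            inf += (w[below, None] * units[below]).sum(axis=0)
            n_inf += int(below.sum())
    if n_sup == 0 or n_inf == 0:
        return float("nan")
    sup /= np.linalg.norm(sup)
    inf /= np.linalg.norm(inf)
    cosang = float(np.clip(np.dot(sup, inf), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# bifurcations

def count_bifurcations(graph_a: VesselGraph, graph_v: VesselGraph) -> int:
    """Total bifurcation (degree-3) nodes over the two class graphs.

    Degree-4 nodes are crossing candidates (e.g. two vessels of the same
    class passing over each other) and are not counted."""
    return graph_a.n_bifurcations() + graph_v.n_bifurcations()


# ---------------------------------------------------------------------------
# assembly

def _extract_graph(mask: RasterMask, spur_px: float,
                   merge_radius: float, smooth_window: int = 3) -> VesselGraph:
    graph = build_graph(skeletonize(mask), merge_radius=merge_radius)
    graph = prune_spurs(graph, min_spur_px=spur_px)
    graph = consolidate_junctions(graph, min_sep_px=spur_px)
    graph = smooth_segments(graph, window=smooth_window)
    return measure_diameters(graph, mask)


def _ratio(a: float, v: float) -> float:
    if math.isnan(a) or math.isnan(v) or v == 0:
        return float("nan")
    return a / v


def compute_idps(
    artery_mask: RasterMask,
    vein_mask: RasterMask,
    od: Optional[OpticDisc],
    roi: Optional[RasterMask] = None,
    *,
    laterality_hint: Optional[str] = None,
    spur_px: float = SPUR_PX,
    merge_radius: float = 2.0,
    min_chord_px: float = MIN_CHORD_PX,
    min_points: int = MIN_DIAMETER_POINTS,
    zone_dd: tuple[float, float] = ZONE_B_DD,
    annulus_r: tuple[float, float] = ANGLE_ANNULUS_R,
    image_id: str = "",
) -> IDPVector:
    """Run the full per-image measurement chain and assemble all 17 IDPs.

    A class whose mask is empty is unmeasurable: all its fields, the ratios,
    and the (joint) bifurcation count come out NaN rather than zero.
    """
    if artery_mask.shape != vein_mask.shape:
        raise ValueError("artery and vein masks have different shapes")
    if roi is None:
        roi = default_roi(artery_mask.shape, od)

    out: dict[str, float] = {}
    flags: dict[str, str] = {}
    graphs: dict[str, Optional[VesselGraph]] = {}
    for prefix, mask in (("a", artery_mask), ("v", vein_mask)):
        if mask.pixel_count() == 0:
            graphs[prefix] = None
            for f in (f"{prefix}_temporal_angle", f"{prefix}_tortuosity",
                      f"{prefix}_central_retinal_eq", f"{prefix}_std_diameter",
                      f"{prefix}_vascular_density", f"{prefix}_median_diameter"):
                out[f] = float("nan")
            flags[prefix] = "empty_mask"
            continue
        g = _extract_graph(mask, spur_px, merge_radius)
        graphs[prefix] = g
        out[f"{prefix}_vascular_density"] = vascular_density(mask, roi)
        med, std = diameter_stats(g, min_points)
        out[f"{prefix}_median_diameter"] = med
        out[f"{prefix}_std_diameter"] = std
        out[f"{prefix}_tortuosity"] = median_tortuosity(g, min_chord_px)
        if od is not None:
            cre, n_used = central_retinal_equivalent(g, od, zone_dd)
            out[f"{prefix}_central_retinal_eq"] = cre
            if 0 < n_used < 6:
                flags[f"{prefix}_central_retinal_eq"] = f"n_vessels={n_used}"
            out[f"{prefix}_temporal_angle"] = temporal_angle(
                g, od, artery_mask.shape, laterality_hint, annulus_r)
        else:
            out[f"{prefix}_central_retinal_eq"] = float("nan")
            out[f"{prefix}_temporal_angle"] = float("nan")

    if graphs["a"] is not None and graphs["v"] is not None:
        out["bifurcations"] = float(count_bifurcations(graphs["a"], graphs["v"]))
    else:
        out["bifurcations"] = float("nan")

    for name in ("tortuosity", "central_retinal_eq", "vascular_density",
                 "median_diameter"):
        out[f"ratio_{name}"] = _ratio(out[f"a_{name}"], out[f"v_{name}"])

    return IDPVector(image_id=image_id, values=out, flags=flags)
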