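"""Readers/writers for masks, optic-disc records, tables and configuration.

Masks are 8-bit PNG/TIFF (0/255 or 0/1).  All serialized coordinates are
0-based (row, col).  The pipeline configuration gathers every tunable
threshold in one place and round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .graph import OpticDisc, RasterMask

__all__ = [
    "read_mask",
    "read_masks",
    "write_mask",
    "read_od_file",
    "write_od_file",
    "PipelineConfig",
]

#: fraction of pixels allowed to hold intermediate gray values (anti-aliasing)
NONBINARY_TOLERANCE = 0.01


def read_mask(path, vessel_class: str = "artery",
              image_id: str = "") -> RasterMask:
    """Load a binary class mask from PNG/TIFF (values {0,1} or {0,255})."""
    img = Image.open(path)
    if img.mode == "P":
        img = img.convert("L")
    elif img.mode not in ("L", "1", "I", "I;16"):
        img = img.convert("L")
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image")
    lo, hi = arr.min(), arr.max()
    binary = (arr == lo) | (arr == hi)
    if (~binary).mean() > NONBINARY_TOLERANCE:
        raise ValueError(
            f"{path}: more than {NONBINARY_TOLERANCE:.0%} of pixels hold "
            f"intermediate values; not a binary mask")
    threshold = (int(lo) + int(hi)) / 2.0 if hi > lo else 0.5
    return RasterMask(arr > threshold, image_id=image_id or Path(path).stem,
                      vessel_class=vessel_class)


def read_masks(artery_path, vein_path, image_id: str = ""
               ) -> tuple[RasterMask, RasterMask]:
    artery = read_mask(artery_path, "artery", image_id)
    vein = read_mask(vein_path, "vein", image_id)
    if artery.shape != vein.shape:
        raise ValueError(
            f"artery/vein mask shape mismatch: {artery.shape} vs {vein.shape} "
            f"({artery_path} / {vein_path})")
    return artery, vein


def write_mask(mask: RasterMask, path) -> None:
    """Write as 8-bit PNG with values 0/255."""
    Image.fromarray((mask.data.astype(np.uint8)) * 255, mode="L").save(path)


def read_od_file(path) -> dict[str, OpticDisc]:
    """Optic-disc records: CSV with columns image_id, row, col, radius_px."""
    df = pd.read_csv(path)
    required = {"image_id", "row", "col", "radius_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"OD file needs columns {sorted(required)}")
    return {str(r.image_id): OpticDisc(center=(float(r.row), float(r.col)),
                                       radius=float(r.radius_px))
            for r in df.itertuples()}


def write_od_file(ods: dict[str, OpticDisc], path) -> None:
    rows = [{"image_id": k, "row": od.center[0], "col": od.center[1],
             "radius_px": od.radius} for k, od in ods.items()]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its default, in one record."""

    mask_dir: str = ""
    od_file: str = ""
    qc_scores: str = ""          # optional CSV image_id,score; empty = proxy
    subjects_file: str = ""      # optional CSV image_id,subject_id,eye,visit
    out_dir: str = "retvasc_out"
    seed: int = 0
    spur_px: float = 10.0
    merge_radius: float = 2.0
    min_chord_px: float = 10.0
    min_points: int = 50
    zone_b_dd: tuple[float, float] = (0.5, 1.0)
    angle_annulus_r: tuple[float, float] = (1.0, 2.5)
    qc_quantile: float = 0.25
    rank_int_offset: float = 0.375  # Blom constant
    n_permutations: int = 10_000
    covariate_spec: Optional[dict] = None
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["zone_b_dd"] = list(self.zone_b_dd)
        d["angle_annulus_r"] = list(self.angle_annulus_r)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("zone_b_dd", "angle_annulus_r"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
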