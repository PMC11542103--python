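"""End-to-end pipeline stages: simulate / extract / aggregate / correlate /
associate, plus ``run_pipeline`` chaining them.

Each stage reads and writes plain CSV/PNG files so the stages compose on
disk exactly as ``run_pipeline`` composes them in memory.  Per-image
failures are logged and isolated; the run is considered failed only if more
than half of the images fail.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as rio
from .graph import OpticDisc
from .phenotypes import IDP_FIELDS, compute_idps
from .qc import QCRecord, aggregate_subject, quartile_filter
from .stats import compare_correlation_sets, correlation_matrix
from .synthetic import generate_tree, random_params

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def simulate(out_dir, n_subjects: int = 10, seed: int = 0,
             max_depth: int = 3, **param_overrides) -> pd.DataFrame:
    """Write a synthetic cohort: two eyes per subject, one visit.

    Produces ``<image>_artery.png`` / ``<image>_vein.png`` mask pairs,
    ``od.csv``, ``subjects.csv``, per-segment ground truth ``truth.csv`` and
    a JSON sidecar of per-image parameters.  Returns the subjects table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ods: dict[str, OpticDisc] = {}
    subjects, truth_frames, sidecars = [], [], {}
    for s in range(n_subjects):
        sid = f"S{s:04d}"
        for eye in ("L", "R"):
            image_id = f"{sid}_{eye}_v0"
            params = random_params(rng, max_depth=max_depth, **param_overrides)
            artery, vein, od, truth = generate_tree(params)
            rio.write_mask(artery, out / f"{image_id}_artery.png")
            rio.write_mask(vein, out / f"{image_id}_vein.png")
            ods[image_id] = od
            tf = truth.segments.copy()
            tf.insert(0, "image_id", image_id)
            truth_frames.append(tf)
            sidecars[image_id] = json.loads(truth.sidecar_json())
            subjects.append({"image_id": image_id, "subject_id": sid,
                             "eye": eye, "visit": 0})
    rio.write_od_file(ods, out / "od.csv")
    subjects_df = pd.DataFrame(subjects)
    subjects_df.to_csv(out / "subjects.csv", index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out / "truth.csv", index=False, float_format=FLOAT_FMT)
    with open(out / "truth_params.json", "w") as fh:
        json.dump(sidecars, fh, indent=2, sort_keys=True)
    return subjects_df


def extract(mask_dir, od_file, out_csv, config: Optional[rio.PipelineConfig] = None
            ) -> pd.DataFrame:
    """Measure the 17 IDPs for every ``*_artery.png``/``*_vein.png`` pair."""
    cfg = config or rio.PipelineConfig()
    mask_dir = Path(mask_dir)
    artery_files = sorted(mask_dir.glob("*_artery.png"))
    if not artery_files:
        raise FileNotFoundError(f"no '*_artery.png' masks under {mask_dir}")
    ods = rio.read_od_file(od_file)
    rows, failures = [], 0
    for af in artery_files:
        image_id = af.name[: -len("_artery.png")]
        vf = mask_dir / f"{image_id}_vein.png"
        try:
            artery, vein = rio.read_masks(af, vf, image_id)
            idp = compute_idps(
                artery, vein, ods.get(image_id),
                spur_px=cfg.spur_px, merge_radius=cfg.merge_radius,
                min_chord_px=cfg.min_chord_px, min_points=cfg.min_points,
                zone_dd=cfg.zone_b_dd, annulus_r=cfg.angle_annulus_r,
                image_id=image_id)
            row = {"image_id": image_id, **idp.as_dict(),
                   "qc_flags": ";".join(f"{k}={v}" for k, v in
                                        sorted(idp.flags.items()))}
            rows.append(row)
        except Exception as exc:
            failures += 1
            log.error("image %s failed: %s", image_id, exc)
            rows.append({"image_id": image_id,
                         **{f: np.nan for f in IDP_FIELDS},
                         "qc_flags": "extraction_failed"})
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False, float_format=FLOAT_FMT)
    if failures > len(artery_files) / 2:
        raise RuntimeError(
            f"{failures}/{len(artery_files)} images failed extraction")
    return df


def aggregate(idp_csv, subjects_csv, out_csv,
              qc_scores_csv: Optional[str] = None,
              qc_quantile: float = 0.25) -> pd.DataFrame:
    """QC-gate images and collapse to one phenotype row per subject.

    Without an external QC score file, total vascular density serves as the
    quality proxy."""
    idps = pd.read_csv(idp_csv, dtype={"image_id": str})
    subjects = pd.read_csv(subjects_csv, dtype={"image_id": str,
                                                "subject_id": str})
    if qc_scores_csv:
        sc = pd.read_csv(qc_scores_csv, dtype={"image_id": str})
        scores = dict(zip(sc["image_id"], sc["score"]))
    else:
        dens = (idps["a_vascular_density"].fillna(0)
                + idps["v_vascular_density"].fillna(0))
        scores = dict(zip(idps["image_id"], dens))
    records = [QCRecord(image_id=i, score=float(scores.get(i, 0.0)))
               for i in idps["image_id"]]
    flagged = {r.image_id: r.passed
               for r in quartile_filter(records, qc_quantile)}
    merged = subjects.merge(idps, on="image_id", how="inner")
    merged["qc_pass"] = merged["image_id"].map(flagged).fillna(False)
    per_subject = aggregate_subject(merged)
    if out_csv is not None:
        per_subject.to_csv(out_csv, index=False, float_format=FLOAT_FMT)
    return per_subject


def correlate(subject_csv, out_csv, genetic_csv: Optional[str] = None,
              n_perm: int = 10_000, seed: int = 0):
    """Phenotypic correlation matrix; optionally compare against a genetic
    correlation matrix (input table, e.g. from LD-score regression)."""
    df = pd.read_csv(subject_csv)
    cols = [c for c in IDP_FIELDS if c in df.columns]
    rp = correlation_matrix(df, columns=cols, kind="phenotypic")
    if out_csv is not None:
        rp.values.to_csv(out_csv, float_format=FLOAT_FMT)
    comparison = None
    if genetic_csv:
        gmat = pd.read_csv(genetic_csv, index_col=0)
        from .stats import CorrelationMatrix
        rg = CorrelationMatrix(values=gmat.loc[rp.labels, rp.labels],
                               kind="genetic")
        comparison = compare_correlation_sets(rg, rp, n_perm=n_perm, seed=seed)
    return rp, comparison


def run_pipeline(config: rio.PipelineConfig) -> Path:
    """Chain extract -> aggregate -> correlate; returns the output directory.

    Deterministic given the seed; the log records the config hash, seed and
    per-image QC decisions."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("retvasc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        cfg_yaml = out / "config.yaml"
        config.to_yaml(cfg_yaml)
        digest = hashlib.sha256(cfg_yaml.read_bytes()).hexdigest()[:16]
        log.info("config hash %s, seed %d", digest, config.seed)

        idp_csv = out / "idps_per_image.csv"
        extract(config.mask_dir, config.od_file, idp_csv, config)
        subj_csv = out / "idps_per_subject.csv"
        subjects_file = config.subjects_file or str(
            Path(config.mask_dir) / "subjects.csv")
        agg = aggregate(idp_csv, subjects_file, subj_csv,
                        config.qc_scores or None, config.qc_quantile)
        log.info("aggregated %d subjects", len(agg))
        correlate(subj_csv, out / "phenotypic_correlations.csv",
                  seed=config.seed)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
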