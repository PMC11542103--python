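"""Image-level QC gating and subject-level phenotype preparation.

Images in the lowest quartile of a quality score are discarded.  Per
subject, phenotypes from the earliest visit are used, averaging the two eyes
when both pass QC and falling back to the single passing eye otherwise.
Before association analyses, phenotypes are rank-inverse-normal transformed
(Blom offset) and residualized on the covariate battery (age, sex and their
interactions, refraction terms, batch/centre indicators, genomic PCs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phenotypes import IDP_FIELDS

__all__ = [
    "QCRecord",
    "quartile_filter",
    "density_proxy_scores",
    "aggregate_subject",
    "spherical_equivalent",
    "rank_inverse_normal",
    "residualize",
    "build_covariates",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCRecord:
    image_id: str
    score: float
    passed: Optional[bool] = None


def quartile_filter(records: Sequence[QCRecord],
                    quantile: float = 0.25) -> list[QCRecord]:
    """Flag records passing QC: score >= the 25th percentile.

    Percentile uses linear interpolation between order statistics, so on n
    distinct scores exactly the top 75% pass; ties at the threshold pass.
    With fewer than 4 records the quartile is meaningless: all pass, with a
    warning.
    """
    scores = []
    for rec in records:
        s = rec.score
        if s is None or isinstance(s, (bool, str)) or not np.isfinite(float(s)):
            raise ValueError(f"non-numeric QC score for image {rec.image_id!r}")
        scores.append(float(s))
    if len(records) < 4:
        warnings.warn("fewer than 4 QC scores: quartile undefined, all pass")
        return [replace(r, passed=True) for r in records]
    threshold = float(np.percentile(scores, 100.0 * quantile,
                                    method="linear"))
    return [replace(r, passed=r.score >= threshold) for r in records]


def density_proxy_scores(densities: dict[str, float]) -> list[QCRecord]:
    """Fallback QC score when no external quality scores are supplied:
    total vascular density, a good proxy for image quality."""
    return [QCRecord(image_id=k, score=float(v)) for k, v in densities.items()]


# ---------------------------------------------------------------------------
# subject aggregation

def aggregate_subject(rows: pd.DataFrame,
                      idp_columns: Iterable[str] = IDP_FIELDS) -> pd.DataFrame:
    """Collapse QC-flagged per-image rows to one phenotype row per subject.

    Expects columns ``subject_id``, ``eye`` (L/R), ``visit`` (ordered) and
    ``qc_pass`` plus the phenotype columns.  Only the earliest visit with at
    least one passing eye is used; the two eyes are averaged field-wise when
    both pass (mean over non-missing values), otherwise the single passing
    eye is taken.  Subjects with no passing image are absent from the output.
    """
    required = {"subject_id", "eye", "visit", "qc_pass"}
    if not required.issubset(rows.columns):
        raise ValueError(f"subject table needs columns {sorted(required)}")
    idp_columns = [c for c in idp_columns if c in rows.columns]
    passing = rows[rows["qc_pass"].astype(bool)]
    out = []
    for sid, grp in passing.groupby("subject_id", sort=True):
        first_visit = grp["visit"].min()
        eyes = grp[grp["visit"] == first_visit]
        vals = eyes[idp_columns].mean(axis=0, skipna=True)
        rec = {"subject_id": sid, "visit": first_visit,
               "n_eyes": int(len(eyes))}
        rec.update(vals.to_dict())
        out.append(rec)
    return pd.DataFrame(out)


def spherical_equivalent(spherical, cylindrical):
    """Spherical equivalent refraction: spherical + cylindrical/2 (diopters).
    Missing input gives missing output (works elementwise on arrays)."""
    return np.asarray(spherical, dtype=float) + np.asarray(cylindrical,
                                                           dtype=float) / 2.0


# ---------------------------------------------------------------------------
# phenotype preparation

def rank_inverse_normal(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transformation (Blom offset by default).

    value -> Phi^{-1}((rank - c) / (n - 2c + 1)); ties get average ranks;
    NaN preserved.  All-identical input maps to zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 2:
        return out
    xs = x[ok]
    if np.all(xs == xs[0]):
        warnings.warn("all values identical: rank-INT maps everything to 0")
        out[ok] = 0.0
        return out
    ranks = sps.rankdata(xs, method="average")
    out[ok] = sps.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))
    return out


def residualize(y, covariates: pd.DataFrame, zscore: bool = False) -> np.ndarray:
    """OLS residuals of ``y`` on the covariate table (plus intercept).

    Categorical/string columns are expanded to drop-one indicator columns.
    Rank-deficient designs are handled by least squares on the column space
    (collinear columns effectively dropped) with a logged warning.  Rows with
    missing y or covariates come back NaN.  With ``zscore`` the residuals are
    standardized to mean 0, sd 1.
    """
    y = np.asarray(y, dtype=float)
    X = _design_matrix(covariates)
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and covariates have different lengths")
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    n = int(ok.sum())
    if n <= X.shape[1]:
        raise ValueError("need more observations than covariate columns")
    Xo = X[ok]
    rank = np.linalg.matrix_rank(Xo)
    if rank < Xo.shape[1]:
        log.warning("rank-deficient covariate design (rank %d < %d columns); "
                    "collinear columns dropped", rank, Xo.shape[1])
    beta, *_ = np.linalg.lstsq(Xo, y[ok], rcond=None)
    res = np.full(y.shape, np.nan)
    res[ok] = y[ok] - Xo @ beta
    if zscore:
        sd = np.nanstd(res)
        if sd > 0:
            res = (res - np.nanmean(res)) / sd
    return res


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    cov = pd.DataFrame(covariates).copy()
    num = cov.select_dtypes(include=[np.number])
    cat = cov.drop(columns=num.columns)
    parts = [pd.Series(1.0, index=cov.index, name="intercept"), num]
    if len(cat.columns):
        parts.append(pd.get_dummies(cat.astype(str), drop_first=True,
                                    dtype=float))
    return pd.concat(parts, axis=1).to_numpy(dtype=float)


#: Covariate battery applied before association analyses.
DEFAULT_COVARIATE_SPEC = {
    "numeric": ["age", "sex", "spherical", "cylindrical"],
    "squares": ["age", "spherical", "cylindrical"],
    "sex_by": ["age", "age_sq"],
    "categorical": ["centre", "batch"],
    "pc_prefix": "pc",
    "n_pcs": 20,
}


def build_covariates(df: pd.DataFrame, spec: Optional[dict] = None
                     ) -> pd.DataFrame:
    """Assemble the covariate table from base columns.

    Derived terms (age^2, sex*age, sex*age^2, spherical^2, cylindrical^2)
    are built internally; batch/centre become categorical columns; genomic
    PC columns are passed through.  Base columns absent from ``df`` are
    skipped silently so the same spec works on reduced tables.
    """
    spec = {**DEFAULT_COVARIATE_SPEC, **(spec or {})}
    out = pd.DataFrame(index=df.index)
    for col in spec["numeric"]:
        if col in df.columns:
            out[col] = pd.to_numeric(df[col])
    for col in spec["squares"]:
        if col in out.columns:
            out[f"{col}_sq"] = out[col] ** 2
    if "sex" in out.columns:
        for col in spec["sex_by"]:
            if col in out.columns:
                out[f"sex_by_{col}"] = out["sex"] * out[col]
    for col in spec["categorical"]:
        if col in df.columns:
            out[col] = df[col].astype(str)
    prefix, n_pcs = spec["pc_prefix"], spec["n_pcs"]
    for i in range(1, n_pcs + 1):
        col = f"{prefix}{i}"
        if col in df.columns:
            out[col] = pd.to_numeric(df[col])
    return out
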