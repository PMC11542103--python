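"""Correlation structure and association statistics.

Two jobs: (1) compare a phenotypic correlation matrix with a genetic one
(e.g. from LD-score regression, consumed as an input table) over the
unordered phenotype pairs — standardized mean difference (Cohen's d with
pooled SD), paired t-test, correlation-of-correlations with a permutation
p-value; (2) the disease-association battery: per (phenotype, trait) pair an
OLS linear regression (standardized effects) or a logistic regression
(odds ratios per SD), with two Bonferroni significance tiers
p < 0.05/N_tests and p < 0.001/N_tests, N_tests = N_phenotypes x N_traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationMatrix",
    "CorrelationComparison",
    "correlation_matrix",
    "compare_correlation_sets",
    "association_battery",
]

log = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with labels."""

    values: pd.DataFrame
    kind: str = "phenotypic"  # phenotypic | genetic

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v)) > 1 + 1e-9:
                raise ValueError("correlations must lie in [-1, 1]")

    @property
    def labels(self) -> list[str]:
        return list(self.values.columns)

    def upper_triangle(self) -> np.ndarray:
        v = self.values.to_numpy(dtype=float)
        iu = np.triu_indices(v.shape[0], k=1)
        return v[iu]


@dataclass
class CorrelationComparison:
    """Paired statistics between genetic and phenotypic correlations."""

    n_pairs: int
    d: float
    t: float
    df: int
    p: float
    corr_of_corr: float
    permutation_p: float
    n_permutations: int
    seed: int


def correlation_matrix(table: pd.DataFrame, columns: Optional[list] = None,
                       min_pairs: int = 3,
                       kind: str = "phenotypic") -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between phenotype columns.

    Cells with fewer than ``min_pairs`` complete observations are NaN."""
    df = table[columns] if columns is not None else table
    df = df.select_dtypes(include=[np.number])
    if df.shape[1] < 2:
        raise ValueError("need at least 2 numeric phenotype columns")
    corr = df.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationMatrix(values=corr, kind=kind)


def compare_correlation_sets(
    rg: CorrelationMatrix,
    rp: CorrelationMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    denominator: str = "pooled",
) -> CorrelationComparison:
    """Paired comparison of two correlation matrices over unordered pairs.

    ``d`` is the standardized mean difference (mean(r_g) - mean(r_p)) over a
    pooled SD, sqrt((SD_g^2 + SD_p^2)/2); ``denominator='printed'`` uses the
    difference-of-variances form instead (undefined when SD_p > SD_g, kept
    only for auditability).  The permutation p-value shuffles which entries
    of the two pair vectors correspond, testing corr-of-corr against the
    no-correspondence null.
    """
    if rg.labels != rp.labels:
        raise ValueError("matrices have mismatching labels")
    g = rg.upper_triangle()
    p_vec = rp.upper_triangle()
    ok = np.isfinite(g) & np.isfinite(p_vec)
    g, p_vec = g[ok], p_vec[ok]
    n_pairs = g.size
    if n_pairs < 3:
        raise ValueError("need at least 3 complete correlation pairs")

    sd_g, sd_p = np.std(g, ddof=1), np.std(p_vec, ddof=1)
    if denominator == "pooled":
        denom = np.sqrt((sd_g**2 + sd_p**2) / 2.0)
    elif denominator == "printed":
        denom = np.sqrt((sd_g**2 - sd_p**2) / 2.0)  # NaN when SD_p > SD_g
    else:
        raise ValueError("denominator must be 'pooled' or 'printed'")
    d = float((g.mean() - p_vec.mean()) / denom)

    if np.allclose(g, p_vec):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = sps.ttest_rel(g, p_vec)
    r_obs = float(sps.pearsonr(g, p_vec).statistic)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_pairs)
        r_perm = np.corrcoef(g, p_vec[perm])[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    perm_p = (1.0 + count) / (n_perm + 1.0)

    return CorrelationComparison(
        n_pairs=int(n_pairs), d=d, t=float(t_stat), df=int(n_pairs - 1),
        p=float(p_val), corr_of_corr=r_obs, permutation_p=float(perm_p),
        n_permutations=int(n_perm), seed=int(seed))


# ---------------------------------------------------------------------------
# disease-association battery

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def association_battery(
    idps: pd.DataFrame,
    traits: pd.DataFrame,
    model: str = "linear",
    alpha_tiers: tuple[float, float] = (0.05, 0.001),
) -> pd.DataFrame:
    """Regress each trait on each phenotype, one pair at a time.

    ``model='linear'``: OLS of the z-scored trait on the z-scored phenotype;
    the slope is the standardized effect.  ``model='logistic'``: logit of the
    binary trait on the z-scored phenotype; effect reported as odds ratio per
    1 SD (log-odds in ``beta``).  Significance tiers use Bonferroni
    thresholds alpha / (N_phenotypes * N_traits).  Returns a tidy frame with
    columns idp, trait, model, beta, effect, se, p, tier.
    """
    if model not in ("linear", "logistic"):
        raise ValueError("model must be 'linear' or 'logistic'")
    n_tests = idps.shape[1] * traits.shape[1]
    thr1, thr2 = alpha_tiers[0] / n_tests, alpha_tiers[1] / n_tests
    idp_arrays = {c: pd.to_numeric(idps[c], errors="coerce").to_numpy(float)
                  for c in idps.columns}
    trait_arrays = {c: pd.to_numeric(traits[c], errors="coerce").to_numpy(float)
                    for c in traits.columns}
    rows = []
    for trait_name in traits.columns:
        t_full = trait_arrays[trait_name]
        for idp_name in idps.columns:
            x_full = idp_arrays[idp_name]
            ok = np.isfinite(t_full) & np.isfinite(x_full)
            y, x = t_full[ok], x_full[ok]
            rec = {"idp": idp_name, "trait": trait_name, "model": model,
                   "n": int(ok.sum()), "beta": np.nan, "effect": np.nan,
                   "se": np.nan, "p": np.nan, "tier": "ns"}
            if ok.sum() >= 10 and x.std() > 0:
                X = sm.add_constant(_zscore(x))
                try:
                    if model == "linear":
                        fit = sm.OLS(_zscore(y), X).fit()
                        rec.update(beta=fit.params[1], effect=fit.params[1],
                                   se=fit.bse[1], p=fit.pvalues[1])
                    else:
                        classes = np.unique(y)
                        if classes.size != 2:
                            log.warning("trait %r is not binary with two "
                                        "classes; result missing", trait_name)
                            rows.append(rec)
                            continue
                        yb = (y == classes.max()).astype(float)
                        fit = sm.Logit(yb, X).fit(disp=0)
                        rec.update(beta=fit.params[1],
                                   effect=float(np.exp(fit.params[1])),
                                   se=fit.bse[1], p=fit.pvalues[1])
                except Exception as exc:  # separation, non-convergence
                    log.warning("association %s ~ %s failed: %s",
                                trait_name, idp_name, exc)
                if np.isfinite(rec["p"]):
                    if rec["p"] < thr2:
                        rec["tier"] = "**"
                    elif rec["p"] < thr1:
                        rec["tier"] = "*"
            rows.append(rec)
    return pd.DataFrame(rows)
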