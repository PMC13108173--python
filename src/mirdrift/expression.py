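"""Per-miRNA age trends in expression from raw counts.

Each retained miRNA is fit with a negative-binomial log-linear model of
counts on mean-centered age (plus optional clinical covariates), with a
library-size offset from median-of-ratios normalization. The age
coefficient, rescaled to log2 units, is the per-year log2 fold change
``b``; ``(2**b - 1) * 100`` is the interpretable percent change per year.
Wald p-values are adjusted across features with Benjamini–Hochberg, and a
two-stage selection first takes an exploratory FDR cut and then a stricter
FDR plus minimum-effect-size cut.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._stats import bh_adjust
from .harmonize import harmonize

__all__ = [
    "filter_low_expression",
    "size_factors",
    "estimate_dispersions",
    "fit_age_model",
    "log2fc_to_pct_per_year",
    "select_age_associated",
]

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

RESULT_COLUMNS = [
    "mirna_id",
    "base_id",
    "log2fc_per_year",
    "std_error",
    "p_value",
    "fdr",
    "pct_per_year",
    "direction",
]


def filter_low_expression(
    counts: pd.DataFrame, min_count: int = 5, min_fraction: float = 0.2
) -> pd.DataFrame:
    """Drop weakly expressed features.

    Keeps features (rows) with ``count >= min_count`` in at least
    ``min_fraction`` of samples; the sample set is unchanged.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    frac = (counts >= min_count).mean(axis=1)
    kept = counts.loc[frac >= min_fraction]
    if kept.empty:
        warnings.warn("no features pass the low-expression filter", stacklevel=2)
    return kept


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (one per sample).

    The reference is the geometric mean profile over features expressed in
    every sample; each sample's factor is the median ratio to it. Falls
    back to relative total counts when no feature is all-positive.
    """
    arr = counts.to_numpy(dtype=float)
    pos = (arr > 0).all(axis=1)
    if pos.sum() == 0:
        totals = arr.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    else:
        logref = np.log(arr[pos]).mean(axis=1)
        sf = np.exp(np.median(np.log(arr[pos]) - logref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame, sf: pd.Series, shrink: float = 0.5, floor: float = 1e-8
) -> pd.Series:
    """Per-feature NB dispersion by method of moments, shrunk to the median.

    On size-factor-normalized counts the moment estimator is
    ``alpha = (var - mean) / mean**2`` floored at ``floor``; each estimate
    is then pulled ``shrink`` of the way toward the across-feature median
    on the log scale, stabilizing noisy per-feature moments.
    """
    q = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, floor)
    raw = np.maximum(raw, floor)
    med = np.median(raw)
    alpha = np.exp((1 - shrink) * np.log(raw) + shrink * np.log(max(med, floor)))
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _design(clinical: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Intercept + centered age (+ numeric-coded, centered covariates)."""
    age_c = clinical["age_years"].to_numpy(dtype=float)
    age_c = age_c - age_c.mean()
    cols = [np.ones_like(age_c), age_c]
    for name in covariates:
        col = clinical[name]
        codes = (
            col.astype("category").cat.codes.to_numpy(dtype=float)
            if not np.issubdtype(col.dtype, np.number)
            else col.to_numpy(dtype=float)
        )
        if np.ptp(codes) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=3)
            continue
        cols.append(codes - codes.mean())
    return np.column_stack(cols)


def fit_age_model(
    counts: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: Sequence[str] = (),
    dispersion_mode: str = "moment",
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Fit a per-feature NB GLM of counts on mean-centered age.

    Parameters
    ----------
    counts
        Features x samples integer matrix; columns must match
        ``clinical['sample_id']`` order (reindexed otherwise).
    clinical
        Table with ``sample_id`` and ``age_years`` plus any covariates.
    covariates
        Clinical column names entered as numeric-coded linear terms.
    dispersion_mode
        ``"moment"`` (per-feature, shrunk to the median) or ``"fixed"``
        with ``dispersion`` giving a shared alpha.

    Returns
    -------
    DataFrame with one row per fitted feature: raw and harmonized id,
    per-year log2 fold change and its standard error, Wald p, BH-adjusted
    fdr, percent change per year, and direction (``Up``/``Down``).
    Constant features are dropped before fitting and non-convergent fits
    are excluded from the BH family; both counts are logged.
    """
    counts = counts[clinical["sample_id"].tolist()]
    if len(clinical) < 3:
        raise ValueError("need at least 3 samples")

    const = counts.nunique(axis=1) <= 1
    n_const = int(const.sum())
    if n_const:
        logger.info("dropping %d constant features before fitting", n_const)
        counts = counts.loc[~const]

    X = _design(clinical, covariates)
    offset = np.log(size_factors(counts).to_numpy())
    if dispersion_mode == "fixed":
        if dispersion is None or dispersion <= 0:
            raise ValueError("fixed dispersion mode requires a positive dispersion")
        alphas = pd.Series(dispersion, index=counts.index)
    elif dispersion_mode == "moment":
        alphas = estimate_dispersions(counts, size_factors(counts))
    else:
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")

    rows = []
    n_failed = 0
    for fid, y in counts.iterrows():
        fam = sm.families.NegativeBinomial(alpha=float(alphas[fid]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y.to_numpy(dtype=float), X, family=fam, offset=offset).fit()
            b_nat, se_nat, p = res.params[1], res.bse[1], res.pvalues[1]
            if not (np.isfinite(b_nat) and np.isfinite(p)):
                raise ValueError("non-finite estimate")
        except Exception:
            n_failed += 1
            rows.append((fid, harmonize(fid), np.nan, np.nan, np.nan))
            continue
        rows.append((fid, harmonize(fid), b_nat / LN2, se_nat / LN2, p))
    if n_failed:
        logger.warning("%d features failed to converge; excluded from FDR", n_failed)

    out = pd.DataFrame(
        rows, columns=["mirna_id", "base_id", "log2fc_per_year", "std_error", "p_value"]
    )
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["pct_per_year"] = log2fc_to_pct_per_year(out["log2fc_per_year"])
    out["direction"] = np.where(out["log2fc_per_year"] > 0, "Up", "Down")
    out.loc[out["log2fc_per_year"].isna(), "direction"] = pd.NA
    return out[RESULT_COLUMNS]


def log2fc_to_pct_per_year(b):
    """Convert a per-year log2 fold change to percent change per year.

    ``b = 0.015`` gives ~1.04%/year; ``b = 1`` is a doubling, 100%/year.
    """
    return (np.exp2(b) - 1.0) * 100.0


def select_age_associated(
    results: pd.DataFrame,
    fdr_exploratory: float = 0.10,
    fdr_final: float = 0.015,
    min_abs_log2fc: float = 0.015,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage selection of age-associated miRNAs.

    The exploratory set takes ``fdr <= fdr_exploratory``; the final set
    additionally requires ``fdr <= fdr_final`` and
    ``|log2fc_per_year| >= min_abs_log2fc``. With ``fdr_final <=
    fdr_exploratory`` the final set is a subset of the exploratory one.
    """
    for t in (fdr_exploratory, fdr_final):
        if not 0 < t <= 1:
            raise ValueError("FDR thresholds must be in (0, 1]")
    if results.empty:
        return results.copy(), results.copy()
    fdr = results["fdr"]
    exploratory = results[fdr <= fdr_exploratory]
    final = results[
        (fdr <= fdr_final) & (results["log2fc_per_year"].abs() >= min_abs_log2fc)
    ]
    return exploratory, final
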