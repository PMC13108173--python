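"""Joining expression and methylation layers, concordance, scoring, ranking.

A miRNA whose promoter gains methylation with age while its expression
falls (or loses methylation while expression rises) fits the canonical
model of methylation-mediated repression and is *concordant*; any other
sign combination is *discordant*. Concordant miRNAs are prioritized by a
concordance score — the product of the absolute per-year expression and
methylation coefficients, either on the percent-per-year scale (``raw``)
or after z-standardizing both coefficient sets (``znorm``, the default
ranking scale, which removes the units mismatch between the two layers).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "integrate",
    "classify_concordance",
    "concordance_score",
    "rank_candidates",
    "sensitivity_reanalysis",
]

logger = logging.getLogger(__name__)


def classify_concordance(expr_direction: str, meth_status: str) -> str:
    """Classify one (expression direction, methylation status) pair.

    ``(Up, Hypo)`` and ``(Down, Hyper)`` are concordant — canonical
    epigenetic repression/derepression; the other two combinations are
    discordant. Undefined inputs are rejected (zero-effect records never
    reach classification: selection requires a nonzero minimum effect).
    """
    if expr_direction not in ("Up", "Down"):
        raise ValueError(f"undefined expression direction {expr_direction!r}")
    if meth_status not in ("Hyper", "Hypo"):
        raise ValueError(f"undefined methylation status {meth_status!r}")
    concordant = (expr_direction == "Up") == (meth_status == "Hypo")
    return "concordant" if concordant else "discordant"


def _dedup_expression(expr_results: pd.DataFrame, policy: str = "min_fdr") -> pd.DataFrame:
    """Resolve multiple expression records (e.g. both arms) per base id.

    ``min_fdr`` keeps the record with the smallest adjusted p — the
    strongest evidence for the locus; ties break on the raw id for
    determinism.
    """
    if policy != "min_fdr":
        raise ValueError(f"unknown dedup policy {policy!r}")
    df = expr_results.sort_values(["fdr", "mirna_id"], kind="mergesort")
    return df.drop_duplicates("base_id", keep="first")


def integrate(
    expr_results: pd.DataFrame,
    meth_summaries: pd.DataFrame,
    dedup: str = "min_fdr",
) -> pd.DataFrame:
    """Inner-join the expression and methylation layers per miRNA.

    ``expr_results`` rows are expression association records (one per raw
    feature; arm duplicates per base id are resolved by ``dedup``);
    ``meth_summaries`` are promoter methylation summaries keyed by
    ``base_id``. miRNAs lacking either layer are excluded and counted in
    the log. Each joined record is classified for concordance.
    """
    if expr_results.empty or meth_summaries.empty:
        logger.info("integration: one layer empty, no joined records")
        return pd.DataFrame(
            columns=[
                "base_id",
                "expr_b",
                "expr_pct_per_year",
                "expr_direction",
                "expr_fdr",
                "meth_b",
                "meth_pct_per_year",
                "meth_status",
                "meth_min_fdr",
                "n_cpgs",
                "concordance_class",
            ]
        )
    expr = _dedup_expression(expr_results, dedup)
    merged = expr.merge(meth_summaries, on="base_id", how="inner")
    n_dropped = (len(expr) - len(merged)) + (len(meth_summaries) - len(merged))
    logger.info(
        "integration: %d joined, %d records lacked the other layer",
        len(merged),
        n_dropped,
    )
    out = pd.DataFrame(
        {
            "base_id": merged["base_id"],
            "expr_b": merged["log2fc_per_year"],
            "expr_pct_per_year": merged["pct_per_year_x"]
            if "pct_per_year_x" in merged
            else merged["pct_per_year"],
            "expr_direction": merged["direction"],
            "expr_fdr": merged["fdr"],
            "meth_b": merged["mean_slope_per_year"],
            "meth_pct_per_year": merged["pct_per_year_y"]
            if "pct_per_year_y" in merged
            else 100.0 * merged["mean_slope_per_year"],
            "meth_status": merged["status"],
            "meth_min_fdr": merged["min_fdr"],
            "n_cpgs": merged["n_cpgs"],
        }
    )
    out["concordance_class"] = [
        classify_concordance(d, s)
        for d, s in zip(out["expr_direction"], out["meth_status"])
    ]
    return out.sort_values("base_id", ignore_index=True)


def concordance_score(records: pd.DataFrame, mode: str = "znorm") -> pd.DataFrame:
    """Attach concordance scores to integrated records.

    ``raw_score`` is always computed: ``|expr %/yr| * |meth %/yr|``. In
    ``znorm`` mode both coefficient columns are standardized (mean 0,
    sd 1, computed over the full record set) before taking the product of
    absolute values, giving ``z_score``; the mode's score lands in the
    ``score`` column used for ranking.
    """
    if records.empty:
        raise ValueError("no records to score")
    if mode not in ("raw", "znorm"):
        raise ValueError(f"unknown score mode {mode!r}")
    out = records.copy()
    e = out["expr_pct_per_year"].to_numpy(dtype=float)
    m = out["meth_pct_per_year"].to_numpy(dtype=float)
    out["raw_score"] = np.abs(e) * np.abs(m)
    if mode == "znorm":
        if len(out) < 2:
            raise ValueError("znorm scoring needs at least 2 records")
        e_sd, m_sd = e.std(ddof=1), m.std(ddof=1)
        if e_sd == 0 or m_sd == 0:
            raise ValueError("znorm scoring needs nonzero coefficient spread")
        out["z_score"] = np.abs((e - e.mean()) / e_sd) * np.abs((m - m.mean()) / m_sd)
        out["score"] = out["z_score"]
    else:
        out["z_score"] = np.nan
        out["score"] = out["raw_score"]
    return out


def rank_candidates(scored: pd.DataFrame) -> pd.DataFrame:
    """Rank concordant records by descending score.

    Ties break on ``base_id`` lexicographically, so the ranking is a
    deterministic permutation invariant to input order.
    """
    conc = scored[scored["concordance_class"] == "concordant"].copy()
    conc = conc.sort_values(
        ["score", "base_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    conc["rank"] = np.arange(1, len(conc) + 1)
    return conc


def sensitivity_reanalysis(
    counts: pd.DataFrame,
    betas: pd.DataFrame,
    clinical: pd.DataFrame,
    loci: pd.DataFrame,
    probes: pd.DataFrame,
    covariates: Sequence[str],
    fdr_exploratory: float = 0.10,
    fdr_final: float = 0.015,
    min_abs_log2fc: float = 0.015,
    half_width: int = 2000,
) -> set[str]:
    """Re-fit both layers with clinical covariates and return robust miRNAs.

    Samples missing any covariate are dropped listwise (counted in the
    log); constant covariates are dropped from the design with a warning
    inside the fitters. Both the expression NB model and the CpG OLS model
    are re-fit with the covariates, the final age-associated set is
    re-selected, and integration re-classified. The returned base ids are
    the miRNAs concordant in this adjusted analysis; a primary-analysis
    concordant miRNA is covariate-robust iff its base id is in this set.
    """
    from .expression import fit_age_model, select_age_associated
    from .methylation import (
        define_promoters,
        fit_cpg_age_model,
        map_cpgs_to_promoters,
        summarize_promoter_methylation,
    )

    complete = clinical.dropna(subset=list(covariates))
    n_dropped = len(clinical) - len(complete)
    if n_dropped:
        logger.info("sensitivity: dropped %d samples with missing covariates", n_dropped)

    expr = fit_age_model(counts[complete["sample_id"].tolist()], complete, covariates)
    _, final = select_age_associated(expr, fdr_exploratory, fdr_final, min_abs_log2fc)

    cpg = fit_cpg_age_model(betas[complete["sample_id"].tolist()], complete, covariates)
    windows = define_promoters(loci, half_width)
    mapping = map_cpgs_to_promoters(probes, windows)
    meth = summarize_promoter_methylation(mapping, cpg)

    joined = integrate(final, meth)
    return set(joined.loc[joined["concordance_class"] == "concordant", "base_id"])
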