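"""Per-CpG age trends in methylation and promoter-level summarization.

CpG beta values are regressed on mean-centered age (ordinary least
squares, optional covariates) probe by probe, with BH adjustment applied
once genome-wide. Probes are then assigned to strand-aware promoter
windows — the TSS is the locus start on the ``+`` strand and the end on
the ``-`` strand, with a closed interval of +/- the half-width (default
2 kb) floored at position 1 — and each miRNA's promoter drift is the
arithmetic mean slope over its mapped, fitted CpGs, retaining the minimum
adjusted p. All coordinates are 1-based inclusive, the manifest
convention for point CpG positions.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "fit_cpg_age_model",
    "define_promoters",
    "map_cpgs_to_promoters",
    "summarize_promoter_methylation",
]


def fit_cpg_age_model(
    betas: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """OLS of beta on mean-centered age, one fit per probe.

    All probes share one design matrix, so the fits are solved in a single
    vectorized least-squares call. Zero-variance probes get slope 0 with a
    missing p-value and are excluded from the BH family.

    Returns a DataFrame with ``probe_id, slope_per_year, std_error,
    p_value, fdr``.
    """
    from .expression import _design

    betas = betas[clinical["sample_id"].tolist()]
    if len(clinical) < 3:
        raise ValueError("need at least 3 samples")
    X = _design(clinical, covariates)
    Y = betas.to_numpy(dtype=float).T  # samples x probes
    n, p = X.shape
    if n <= p:
        raise ValueError("more design columns than samples")

    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    slope = coef[1]

    zero_var = Y.var(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slope / se
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    slope = np.where(zero_var, 0.0, slope)
    se = np.where(zero_var, np.nan, se)
    pvals = np.where(zero_var, np.nan, pvals)

    return pd.DataFrame(
        {
            "probe_id": betas.index.to_numpy(),
            "slope_per_year": slope,
            "std_error": se,
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
        }
    )


def define_promoters(loci: pd.DataFrame, half_width: int = 2000) -> pd.DataFrame:
    """Strand-aware promoter windows of +/- ``half_width`` around each TSS.

    Expects loci columns ``locus_id`` or ``base_id``, ``chrom``, ``start``,
    ``end``, ``strand``. Windows are closed intervals floored at 1.
    """
    from .harmonize import harmonize

    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if loci["strand"].isna().any() or (~loci["strand"].isin(["+", "-"])).any():
        raise ValueError("every locus must have strand '+' or '-'")
    base = (
        loci["base_id"]
        if "base_id" in loci.columns
        else loci["locus_id"].map(harmonize)
    )
    tss = np.where(loci["strand"] == "+", loci["start"], loci["end"]).astype(int)
    return pd.DataFrame(
        {
            "base_id": base.to_numpy(),
            "chrom": loci["chrom"].to_numpy(),
            "window_start": np.maximum(1, tss - half_width),
            "window_end": tss + half_width,
            "tss": tss,
            "strand": loci["strand"].to_numpy(),
        }
    )


def map_cpgs_to_promoters(
    probes: pd.DataFrame, windows: pd.DataFrame
) -> dict[str, set[str]]:
    """Assign each probe to every promoter window containing its position.

    Intervals are closed on both ends; a probe inside two overlapping
    promoters is assigned to both (many-to-many). Probes falling in no
    window are left unassigned. Implemented with per-chromosome interval
    trees.
    """
    probe_chroms = set(probes["chrom"].unique())
    window_chroms = set(windows["chrom"].unique())
    if probe_chroms and window_chroms and not (probe_chroms & window_chroms):
        warnings.warn(
            f"no shared chromosome names: {len(probe_chroms)} probe vs "
            f"{len(window_chroms)} window chromosomes",
            stacklevel=2,
        )

    trees: dict[str, IntervalTree] = {}
    for w in windows.itertuples():
        # +1 because IntervalTree intervals are half-open
        trees.setdefault(w.chrom, IntervalTree()).addi(
            int(w.window_start), int(w.window_end) + 1, w.base_id
        )

    mapping: dict[str, set[str]] = {}
    for pr in probes.itertuples():
        tree = trees.get(pr.chrom)
        if tree is None:
            continue
        for hit in tree.at(int(pr.position)):
            mapping.setdefault(hit.data, set()).add(pr.probe_id)
    return mapping


def summarize_promoter_methylation(
    mapping: dict[str, set[str]], cpg_results: pd.DataFrame
) -> pd.DataFrame:
    """Summarize CpG-level fits to one methylation drift record per miRNA.

    Per base id: arithmetic mean of the mapped CpGs' slopes, the minimum
    adjusted p, and the CpG count. Probes whose fit was excluded (missing
    p) do not contribute; miRNAs left with zero fitted CpGs are omitted
    and surface downstream as missing-methylation cases. ``pct_per_year``
    is ``100 * mean_slope`` (beta is already a fraction) and status is
    ``Hyper`` for positive drift, ``Hypo`` otherwise.
    """
    fits = cpg_results.set_index("probe_id")
    rows = []
    for base_id in sorted(mapping):
        ids = [
            p
            for p in mapping[base_id]
            if p in fits.index and np.isfinite(fits.at[p, "p_value"])
        ]
        if not ids:
            continue
        slopes = fits.loc[ids, "slope_per_year"]
        mean_slope = float(slopes.mean())
        rows.append(
            {
                "base_id": base_id,
                "mean_slope_per_year": mean_slope,
                "min_fdr": float(fits.loc[ids, "fdr"].min()),
                "n_cpgs": len(ids),
                "pct_per_year": 100.0 * mean_slope,
                "status": "Hyper" if mean_slope > 0 else "Hypo",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "base_id",
            "mean_slope_per_year",
            "min_fdr",
            "n_cpgs",
            "pct_per_year",
            "status",
        ],
    )
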