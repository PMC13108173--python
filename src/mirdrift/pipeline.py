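"""End-to-end orchestration: one config in, a report bundle out.

Stages run in order — identifier harmonization happens inside each stage's
joins — expression association, methylation association with promoter
summarization, integration (plus covariate sensitivity when covariates are
configured), then optional cross-cohort validation and target-network
analysis. Every stage's table is written to the output directory so a run
can be resumed or audited mid-way, together with a run log (seed, versions,
filter counts) and a summary of the headline funnel counts.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as mio
from ._stats import round_half_away
from .expression import fit_age_model, filter_low_expression, select_age_associated
from .integration import (
    concordance_score,
    integrate,
    rank_candidates,
    sensitivity_reanalysis,
)
from .methylation import (
    define_promoters,
    fit_cpg_age_model,
    map_cpgs_to_promoters,
    summarize_promoter_methylation,
)
from .network import build_bipartite, degree_filter, hub_genes
from .validation import call_direction, compare_directions, summarize_validation

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "make_report",
    "summarize_concordance",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Either ``simulate`` (overrides for the synthetic study generator) or
    ``inputs`` (paths: clinical, counts, betas, loci, probes) must be set.
    Thresholds default to the two-stage selection used throughout:
    exploratory FDR 0.10, final FDR 0.015 with ``|log2FC| >= 0.015``
    per year; promoters span +/-2 kb; network hubs need gene degree >= 5.
    """

    outdir: str = "mirdrift_run"
    seed: int = 0
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    min_count: int = 5
    min_fraction: float = 0.2
    fdr_exploratory: float = 0.10
    fdr_final: float = 0.015
    min_abs_log2fc: float = 0.015
    promoter_half_width: int = 2000
    min_gene_degree: int = 5
    score_mode: str = "znorm"
    covariates: list[str] = field(default_factory=list)
    external_calls: str | None = None
    network_edges: str | None = None
    plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        for name in ("fdr_exploratory", "fdr_final"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be non-negative")
        if self.promoter_half_width <= 0:
            raise ValueError("promoter_half_width must be positive")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either 'simulate' or 'inputs'")


@dataclass
class PipelineResult:
    """In-memory view of one run's stage outputs."""

    expr_results: pd.DataFrame
    exploratory: pd.DataFrame
    final: pd.DataFrame
    cpg_results: pd.DataFrame
    meth_summaries: pd.DataFrame
    integrated: pd.DataFrame
    ranked: pd.DataFrame
    validation_records: pd.DataFrame | None
    validation_summary: pd.DataFrame | None
    hub_table: pd.DataFrame | None
    summary: dict[str, Any]
    truth: pd.DataFrame | None = None


def summarize_concordance(n_concordant: int, n_discordant: int) -> dict[str, Any]:
    """Headline concordance split with half-away-from-zero percentage."""
    total = n_concordant + n_discordant
    pct = round_half_away(100.0 * n_concordant / total) if total else 0
    return {
        "n_concordant": int(n_concordant),
        "n_discordant": int(n_discordant),
        "n_integrated": int(total),
        "pct_concordant": pct,
    }


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        from .synthetic import simulate_study

        study = simulate_study(seed=config.seed, **config.simulate)
        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        mio.write_clinical(study.clinical, inputs / "clinical.tsv")
        mio.write_matrix(study.counts, inputs / "counts.tsv")
        mio.write_matrix(study.betas, inputs / "betas.tsv")
        mio.write_loci_gff3(study.loci, inputs / "loci.gff3")
        mio.write_probes(
            study.probes[["probe_id", "chrom", "position"]], inputs / "probes.tsv"
        )
        mio.write_truth(study.truth, inputs / "truth.tsv")
        mio.write_params(study.params, inputs / "params.yaml")
        return study.clinical, study.counts, study.betas, study.loci, study.probes, study.truth

    paths = config.inputs
    clinical = mio.read_clinical(paths["clinical"])
    counts = mio.read_matrix(paths["counts"])
    betas = mio.read_matrix(paths["betas"])
    loci_path = str(paths["loci"])
    loci = (
        mio.read_loci_bed(loci_path)
        if loci_path.endswith(".bed")
        else mio.read_loci_gff3(loci_path)
    )
    probes = mio.read_probes(paths["probes"])
    return clinical, counts, betas, loci, probes, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Writes all stage TSVs, the report tables, a ``run_log.yaml`` and a
    ``summary.yaml`` under ``config.outdir`` and returns the in-memory
    stage outputs. Deterministic under a fixed config and seed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    clinical, counts, betas, loci, probes, truth = _load_inputs(config, outdir)
    log: dict[str, Any] = {"seed": config.seed, "n_samples": len(clinical)}

    # expression layer
    counts_f = filter_low_expression(counts, config.min_count, config.min_fraction)
    log["n_features_in"] = len(counts)
    log["n_features_after_filter"] = len(counts_f)
    expr_results = fit_age_model(counts_f, clinical)
    expr_results.to_csv(outdir / "expression_association.tsv", sep="\t", index=False)
    exploratory, final = select_age_associated(
        expr_results, config.fdr_exploratory, config.fdr_final, config.min_abs_log2fc
    )
    log["n_exploratory"] = len(exploratory)
    log["n_final"] = len(final)

    # methylation layer
    cpg_results = fit_cpg_age_model(betas, clinical)
    cpg_results.to_csv(outdir / "cpg_association.tsv", sep="\t", index=False)
    windows = define_promoters(loci, config.promoter_half_width)
    mapping = map_cpgs_to_promoters(probes, windows)
    meth_summaries = summarize_promoter_methylation(mapping, cpg_results)
    meth_summaries.to_csv(outdir / "promoter_methylation.tsv", sep="\t", index=False)
    log["n_cpgs_mapped"] = int(sum(len(v) for v in mapping.values()))
    log["n_mirnas_with_methylation"] = len(meth_summaries)

    # integration
    integrated = integrate(final, meth_summaries)
    n_conc = int((integrated["concordance_class"] == "concordant").sum())
    n_disc = len(integrated) - n_conc
    if not integrated.empty:
        try:
            integrated = concordance_score(integrated, config.score_mode)
        except ValueError:
            logger.warning("score mode %r not applicable; using raw", config.score_mode)
            integrated = concordance_score(integrated, "raw")
        ranked = rank_candidates(integrated)
    else:
        ranked = integrated.copy()

    # covariate sensitivity
    if config.covariates and not integrated.empty:
        robust = sensitivity_reanalysis(
            counts_f,
            betas,
            clinical,
            loci,
            probes,
            config.covariates,
            config.fdr_exploratory,
            config.fdr_final,
            config.min_abs_log2fc,
            config.promoter_half_width,
        )
        integrated["covariate_robust"] = [
            (b in robust) and (c == "concordant")
            for b, c in zip(integrated["base_id"], integrated["concordance_class"])
        ]
        ranked = ranked.merge(
            integrated[["base_id", "covariate_robust"]], on="base_id", how="left"
        )
        log["n_covariate_robust"] = int(integrated["covariate_robust"].sum())
    integrated.to_csv(outdir / "integrated.tsv", sep="\t", index=False)

    # optional validation against an external cohort's direction calls
    validation_records = validation_summary = None
    if config.external_calls:
        primary_calls = _primary_calls(integrated)
        external = pd.read_csv(config.external_calls, sep="\t", keep_default_na=False)
        validation_records = compare_directions(primary_calls, external)
        validation_summary = summarize_validation(validation_records)
        validation_records.to_csv(outdir / "validation_records.tsv", sep="\t", index=False)
        validation_summary.to_csv(outdir / "validation_summary.tsv", sep="\t", index=False)

    # optional convergent-target network
    hub_table = None
    if config.network_edges:
        edges = pd.read_csv(config.network_edges, sep="\t")
        net = build_bipartite(edges)
        hub_table = hub_genes(net)
        filtered = degree_filter(net, config.min_gene_degree)
        hub_table.to_csv(outdir / "hub_genes.tsv", sep="\t", index=False)
        _write_network(filtered, outdir)
        log["n_hub_genes"] = int((hub_table["degree"] >= config.min_gene_degree).sum())

    summary = {
        **summarize_concordance(n_conc, n_disc),
        "n_exploratory": len(exploratory),
        "n_final": len(final),
    }
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    log["versions"] = _versions()
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)

    make_report(ranked, validation_records, hub_table, outdir)
    if config.plot and not integrated.empty:
        _plot_scatter(integrated, outdir / "methylation_vs_expression.png")

    return PipelineResult(
        expr_results, exploratory, final, cpg_results, meth_summaries,
        integrated, ranked, validation_records, validation_summary,
        hub_table, summary, truth,
    )


def _primary_calls(integrated: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for rec in integrated.itertuples():
        rows.append(
            {"base_id": rec.base_id, "layer": "expression",
             "call": call_direction(rec.expr_b, "expression")}
        )
        rows.append(
            {"base_id": rec.base_id, "layer": "methylation",
             "call": call_direction(rec.meth_b, "methylation")}
        )
    return pd.DataFrame(rows, columns=["base_id", "layer", "call"])


def make_report(
    ranked: pd.DataFrame,
    validation_records: pd.DataFrame | None,
    hub_table: pd.DataFrame | None,
    outdir,
) -> None:
    """Write the fixed-format report tables (3-decimal %/year columns)."""
    outdir = Path(outdir)
    cols = ["rank", "base_id", "expr_pct_per_year", "expr_direction",
            "meth_pct_per_year", "meth_status", "raw_score", "z_score"]
    if "covariate_robust" in ranked.columns:
        cols.append("covariate_robust")
    table = ranked.reindex(columns=cols).copy()
    for c in ("expr_pct_per_year", "meth_pct_per_year", "raw_score", "z_score"):
        table[c] = table[c].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
    table.to_csv(outdir / "report_candidates.tsv", sep="\t", index=False)
    if validation_records is not None:
        validation_records.to_csv(outdir / "report_validation.tsv", sep="\t", index=False)
    if hub_table is not None:
        hub_table.to_csv(outdir / "report_hubs.tsv", sep="\t", index=False)


def _write_network(net, outdir: Path) -> None:
    import networkx as nx

    nx.write_graphml(net.graph, outdir / "network_filtered.graphml")
    nodes = pd.DataFrame(
        [(n, k) for n, k in net.graph.nodes(data="kind")], columns=["node", "kind"]
    ).sort_values(["kind", "node"])
    nodes.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(sorted(net.edges), columns=["mirna", "gene"])
    edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)


def _plot_scatter(integrated: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, color in (("concordant", "tab:blue"), ("discordant", "tab:orange")):
        sub = integrated[integrated["concordance_class"] == cls]
        ax.scatter(sub["meth_pct_per_year"], sub["expr_pct_per_year"],
                   s=14, label=cls, color=color, alpha=0.8)
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel("promoter methylation change (%/year)")
    ax.set_ylabel("expression change (%/year)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _versions() -> dict[str, str]:
    import numpy, pandas, scipy, statsmodels

    from . import __version__

    return {
        "mirdrift": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
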