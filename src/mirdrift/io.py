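"""Readers and writers for the pipeline's tabular and genomic formats.

Matrices travel as TSV with features (or probes) as rows and a header row
of sample ids; loci as GFF3 (type ``miRNA``) or 6-column BED; probe
annotation, truth tables, edge lists and report tables as plain TSV.
Generation parameters are echoed to a YAML sidecar so any run can be
reproduced from its output directory alone.

Also exposes the bundled reference tables: the TCGA-PRAD discovery
cohort's ranked concordant-miRNA table, the GEO-cohort direction calls
used for validation, the validated miRNA–target edge list, and the
discovery cohort's headline funnel counts.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_clinical",
    "write_clinical",
    "read_matrix",
    "write_matrix",
    "read_loci_gff3",
    "write_loci_gff3",
    "read_loci_bed",
    "write_loci_bed",
    "read_probes",
    "write_probes",
    "read_truth",
    "write_truth",
    "write_params",
    "read_params",
    "load_reference_candidates",
    "load_reference_validation",
    "load_reference_edges",
    "load_reference_counts",
]

_GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df or "age_years" not in df:
        raise ValueError("clinical table needs sample_id and age_years columns")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a features-x-samples TSV matrix (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def write_loci_gff3(loci: pd.DataFrame, path) -> None:
    """Write miRNA loci as GFF3 records of type ``miRNA``."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in loci.itertuples():
            attrs = f"ID={row.locus_id}"
            fh.write(
                f"{row.chrom}\tmirdrift\tmiRNA\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_loci_gff3(path) -> pd.DataFrame:
    """Read miRNA loci from a GFF3 file (records of type ``miRNA``)."""
    from .harmonize import harmonize

    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF3_COLUMNS, dtype={"seqid": str}
    )
    df = df[df["type"] == "miRNA"].copy()
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    out = pd.DataFrame(
        {
            "locus_id": ids.to_numpy(),
            "chrom": df["seqid"].to_numpy(),
            "start": df["start"].astype(int).to_numpy(),
            "end": df["end"].astype(int).to_numpy(),
            "strand": df["strand"].to_numpy(),
        }
    )
    out["base_id"] = out["locus_id"].map(harmonize)
    return out


def write_loci_bed(loci: pd.DataFrame, path) -> None:
    """Write loci as 6-column BED (0-based half-open starts)."""
    bed = pd.DataFrame(
        {
            "chrom": loci["chrom"],
            "start": loci["start"] - 1,
            "end": loci["end"],
            "name": loci["locus_id"],
            "score": 0,
            "strand": loci["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_loci_bed(path) -> pd.DataFrame:
    from .harmonize import harmonize

    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"], dtype={"chrom": str},
    )
    out = pd.DataFrame(
        {
            "locus_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int) + 1,
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
        }
    )
    out["base_id"] = out["locus_id"].map(harmonize)
    return out


def read_probes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    for col in ("probe_id", "chrom", "position"):
        if col not in df:
            raise ValueError(f"probe annotation missing column {col!r}")
    return df


def write_probes(probes: pd.DataFrame, path) -> None:
    probes.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_params(params: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_yaml_safe(params), fh, sort_keys=True)


def read_params(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _yaml_safe(obj):
    """Recursively coerce numpy scalars / tuples for YAML round-tripping."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _data_path(name: str) -> Path:
    return Path(resources.files("mirdrift.data") / name)


def load_reference_candidates() -> pd.DataFrame:
    """Ranked concordant-miRNA table from the TCGA-PRAD discovery cohort.

    Columns: rank, mirna, expr_pct_per_year, expr_direction,
    meth_pct_per_year, meth_status, conc_score (z-normalized),
    covariate_robust (stable to Gleason / T-stage adjustment).
    """
    df = pd.read_csv(_data_path("tcga_prad_concordant_mirnas.tsv"), sep="\t")
    df["covariate_robust"] = df["covariate_robust"].astype(bool)
    return df


def load_reference_validation() -> pd.DataFrame:
    """GEO-cohort direction calls and concordance flags per candidate miRNA."""
    return pd.read_csv(
        _data_path("geo_validation_directions.tsv"), sep="\t", keep_default_na=False
    )


def load_reference_edges() -> pd.DataFrame:
    """Validated miRNA–target interactions for the candidate set (TSV edge list)."""
    return pd.read_csv(_data_path("mirna_target_edges.tsv"), sep="\t")


def load_reference_counts() -> dict:
    """Discovery-cohort funnel counts (exploratory → final → integrated → classes)."""
    with open(_data_path("cohort_counts.yaml")) as fh:
        return yaml.safe_load(fh)
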