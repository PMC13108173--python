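import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mirdrift as md
from mirdrift.io import (
    load_reference_candidates,
    load_reference_counts,
    load_reference_edges,
    load_reference_validation,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_candidates() -> pd.DataFrame:
    """Bundled ranked concordant-miRNA table from the discovery cohort."""
    return load_reference_candidates()


@pytest.fixture(scope="session")
def reference_validation() -> pd.DataFrame:
    return load_reference_validation()


@pytest.fixture(scope="session")
def reference_edges() -> pd.DataFrame:
    return load_reference_edges()


@pytest.fixture(scope="session")
def reference_counts() -> dict:
    return load_reference_counts()


@pytest.fixture(scope="session")
def small_study() -> md.SimulatedStudy:
    """A compact planted-truth study shared across tests."""
    return md.simulate_study(
        seed=7, n_samples=120, n_mirna=60, n_concordant=8, n_discordant=8
    )


def direction_calls(table: pd.DataFrame, layer: str, column: str) -> pd.DataFrame:
    """Build (base_id, layer, call) records from a reference table column."""
    return pd.DataFrame(
        {
            "base_id": table["mirna"].map(md.harmonize),
            "layer": layer,
            "call": table[column],
        }
    )


def brute_force_mapping(probes: pd.DataFrame, windows: pd.DataFrame) -> dict:
    """Exhaustive O(n*m) closed-interval overlap check (test oracle)."""
    mapping: dict[str, set[str]] = {}
    for pr in probes.itertuples():
        for w in windows.itertuples():
            if pr.chrom == w.chrom and w.window_start <= pr.position <= w.window_end:
                mapping.setdefault(w.base_id, set()).add(pr.probe_id)
    return mapping
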