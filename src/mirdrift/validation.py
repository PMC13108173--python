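"""Cross-cohort validation by direction of effect only.

Age-associated effects are small, so replication across cohorts profiled
on different platforms is judged on the *sign* of the per-year trend, not
on significance. Expression trends are called Up/Down, methylation trends
Hyper/Hypo, with NA for features the external platform does not cover (or
an exactly-zero coefficient). A primary-cohort call is concordant with
the external cohort only when both calls are defined and identical; the
summary tallies matches, opposite calls, and NAs separately so true
disagreement is distinguishable from missingness.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["call_direction", "compare_directions", "summarize_validation"]

logger = logging.getLogger(__name__)

_CALLS = {
    "expression": ("Up", "Down"),
    "methylation": ("Hyper", "Hypo"),
}


def call_direction(coefficient: float | None, layer: str) -> str:
    """Sign-only direction call for one feature on one layer.

    Positive coefficients give Up (expression) or Hyper (methylation),
    negative give Down/Hypo; a missing or exactly-zero coefficient gives
    NA (an exact zero carries no direction and is logged).
    """
    if layer not in _CALLS:
        raise ValueError(f"unknown layer {layer!r}")
    pos, neg = _CALLS[layer]
    if coefficient is None or (isinstance(coefficient, float) and np.isnan(coefficient)):
        return "NA"
    if coefficient == 0:
        logger.info("exactly-zero coefficient on layer %s: called NA", layer)
        return "NA"
    return pos if coefficient > 0 else neg


def compare_directions(
    primary: pd.DataFrame, external: pd.DataFrame
) -> pd.DataFrame:
    """Match primary-cohort calls against external-cohort calls.

    Both inputs carry columns ``base_id, layer, call``. One record is
    produced per primary call; the external call defaults to NA when the
    feature is absent. ``concordant`` is ``"Yes"`` only when both calls
    are defined and equal — any NA yields ``"No"``.
    """
    ext = external.set_index(["base_id", "layer"])["call"]
    rows = []
    for rec in primary.itertuples():
        external_call = ext.get((rec.base_id, rec.layer), "NA")
        concordant = (
            "Yes"
            if rec.call != "NA" and external_call != "NA" and rec.call == external_call
            else "No"
        )
        rows.append(
            {
                "base_id": rec.base_id,
                "layer": rec.layer,
                "primary_call": rec.call,
                "external_call": external_call,
                "concordant": concordant,
            }
        )
    return pd.DataFrame(
        rows, columns=["base_id", "layer", "primary_call", "external_call", "concordant"]
    )


def summarize_validation(records: pd.DataFrame) -> pd.DataFrame:
    """Per-layer tallies of direction matches.

    Splits records into ``n_yes`` (both defined, equal), ``n_no_opposite``
    (both defined, different) and ``n_na`` (either call NA); the three sum
    to the record count, and percentages of the total are reported
    alongside.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["layer", "n_yes", "n_no_opposite", "n_na", "n_total",
                     "pct_yes", "pct_no_opposite", "pct_na"]
        )
    rows = []
    for layer, grp in records.groupby("layer", sort=True):
        has_na = (grp["primary_call"] == "NA") | (grp["external_call"] == "NA")
        yes = grp["concordant"] == "Yes"
        n_na = int(has_na.sum())
        n_yes = int(yes.sum())
        n_opp = len(grp) - n_yes - n_na
        total = len(grp)
        rows.append(
            {
                "layer": layer,
                "n_yes": n_yes,
                "n_no_opposite": n_opp,
                "n_na": n_na,
                "n_total": total,
                "pct_yes": 100.0 * n_yes / total,
                "pct_no_opposite": 100.0 * n_opp / total,
                "pct_na": 100.0 * n_na / total,
            }
        )
    return pd.DataFrame(rows)
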