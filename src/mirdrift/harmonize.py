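"""miRNA identifier harmonization.

Expression matrices, methylation annotation, validation panels and target
databases each carry their own flavour of miRNA identifier for the same
locus: species prefixes (``hsa-``, ``mmu-``), case differences (``miR`` vs
``mir``), mature-arm suffixes (``-5p``/``-3p``) and hyphen separators. To
join records across platforms every identifier is reduced to a *base id* —
the core gene name, lowercase, without prefix, arm token or hyphens — while
trailing locus numbers (``-1``, ``-2``) survive as digits so that distinct
loci of one family (e.g. mir-486-1 vs mir-486-2) stay distinct.

Example: ``hsa-miR-129-2-3p`` → ``mir1292``.
"""

from __future__ import annotations

import re
from collections.abc import Iterable

__all__ = ["harmonize", "build_join_index"]

# A species prefix is three letters plus a hyphen, but only when what follows
# is a miRNA stem ("mir"/"let"); a bare guard on length would mangle ids such
# as "let-7a" into "7a".
_SPECIES_PREFIX = re.compile(r"^[a-z]{3}-(?=mir|let)")
# Only a *terminal* arm token is stripped, so interior locus numbers survive
# ("mir-129-2-3p" keeps its "2").
_ARM_SUFFIX = re.compile(r"-(?:5p|3p)$")


def harmonize(raw_id: str) -> str:
    """Reduce a platform miRNA identifier to its base form.

    Applies, in order: lowercase; strip one leading species prefix; strip one
    terminal ``-5p``/``-3p`` arm token; remove remaining hyphens. The result
    is idempotent under re-harmonization.

    Parameters
    ----------
    raw_id
        Platform identifier, e.g. ``"hsa-miR-129-2-3p"``.

    Returns
    -------
    str
        Base identifier, e.g. ``"mir1292"``.

    Raises
    ------
    ValueError
        If the input is empty, or empty after stripping.
    """
    if raw_id is None or not str(raw_id).strip():
        raise ValueError("empty miRNA identifier")
    base = str(raw_id).strip().lower()
    base = _SPECIES_PREFIX.sub("", base)
    base = _ARM_SUFFIX.sub("", base, count=1)
    base = base.replace("-", "")
    if not base:
        raise ValueError(f"identifier {raw_id!r} is empty after harmonization")
    return base


def build_join_index(ids: Iterable[str]) -> dict[str, set[str]]:
    """Group raw identifiers by their shared base id.

    Every raw id lands under exactly one base id; collisions — typically the
    two mature arms of one locus — are grouped rather than dropped, so the
    caller can apply its own de-duplication policy.
    """
    index: dict[str, set[str]] = {}
    for raw in ids:
        index.setdefault(harmonize(raw), set()).add(raw)
    return index
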