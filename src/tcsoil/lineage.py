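"""GreenGenes-style lineage string parsing.

Taxon tables classified against GreenGenes carry lineage strings of the form
``k__Bacteria; p__Proteobacteria; c__; o__; f__; g__Kaistobacter``.  Ranks are
positional: an empty or missing field never shifts the fields below it.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

logger = logging.getLogger(__name__)

__all__ = ["RANKS", "Lineage", "parse_lineage", "format_lineage"]

#: the six ranks carried by the table, kingdom first
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class Lineage(NamedTuple):
    kingdom: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str

    def rank(self, name: str) -> str:
        """Field accessor by rank name ('class' accepted for 'class_')."""
        return self[RANKS.index(name)]


def parse_lineage(lineage_string: str) -> Lineage:
    """Parse a semicolon-separated lineage into six positional rank fields.

    Prefixes ``k__`` .. ``g__`` are accepted and optional; an unknown prefix is
    kept as plain text at its position (with a warning).  A seventh field with
    an ``s__`` prefix (species) is tolerated and dropped; more than seven
    fields are rejected.  Parsing is idempotent: feeding a formatted lineage
    back in reproduces the same fields.
    """
    parts = [p.strip() for p in lineage_string.split(";")]
    if len(parts) > 7:
        raise ValueError(
            f"lineage has {len(parts)} fields, at most 7 allowed: {lineage_string!r}"
        )
    if len(parts) == 7:
        parts = parts[:6]  # species field out of scope
    fields = []
    for i, part in enumerate(parts):
        if part[:3] in _PREFIXES:
            expected = _PREFIXES[i]
            if part[:3] != expected:
                logger.warning(
                    "lineage field %d has prefix %r where %r was expected; "
                    "keeping text as-is: %r",
                    i, part[:3], expected, part,
                )
                fields.append(part)
            else:
                fields.append(part[3:].strip())
        else:
            fields.append(part)
    fields += [""] * (6 - len(fields))
    return Lineage(*fields)


def format_lineage(lin: Lineage) -> str:
    """Render a lineage back to the prefixed GreenGenes dialect."""
    return "; ".join(f"{p}{v}" for p, v in zip(_PREFIXES[:6], lin))
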