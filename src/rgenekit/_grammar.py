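"""Allele-suffixed gene identifier grammar.

Polyploid sugarcane assemblies name each haplotype-resolved gene copy by
appending ``-<digit><letter>`` to a base locus ID, e.g. ``Sspon.05G0015970-2C``
is one allele of base gene ``Sspon.05G0015970``.  The digit is the haplotype
slot (1-based) and the letter is the corresponding slot letter (A for slot 1,
B for slot 2, ...).  The species/origin prefix is the text before the first
dot (``Sspon``, ``Soff``, ...).
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass

ALLELE_SUFFIX_RE = re.compile(r"^(?P<base>.+)-(?P<slot>\d+)(?P<letter>[A-Z])$")


@dataclass(frozen=True)
class ParsedGeneId:
    """A gene identifier decomposed under the allele-suffix grammar."""

    gene_id: str
    base_gene_id: str
    slot: int | None       # 1-based haplotype slot; None when no suffix
    letter: str | None
    has_suffix: bool

    @property
    def prefix(self) -> str:
        """Origin prefix: text before the first '.' of the base gene ID."""
        return self.base_gene_id.split(".", 1)[0]


def parse_gene_id(gene_id: str) -> ParsedGeneId:
    """Parse a gene ID; IDs without an allele suffix are their own base gene."""
    m = ALLELE_SUFFIX_RE.match(gene_id)
    if m is None:
        return ParsedGeneId(gene_id, gene_id, None, None, False)
    return ParsedGeneId(
        gene_id, m.group("base"), int(m.group("slot")), m.group("letter"), True
    )


def allele_suffix(slot: int) -> str:
    """Canonical suffix for a 1-based haplotype slot: 1 -> '1A', 2 -> '2B', ..."""
    if not 1 <= slot <= 26:
        raise ValueError(f"haplotype slot out of range: {slot}")
    return f"{slot}{string.ascii_uppercase[slot - 1]}"
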