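"""Minimal GFF3 reader for gene / mRNA / exon / CDS models.

Coordinates are 1-based inclusive throughout, as in the GFF3 format itself.
Only the feature types this pipeline consumes are modelled; anything else in
the file is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import unquote


class GFFError(ValueError):
    pass


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    seqid: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def sorted_exons(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class Gene:
    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)


def _attributes(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise GFFError(f"malformed attribute field: {part!r}")
        k, v = part.split("=", 1)
        out[k] = unquote(v)
    return out


def parse_gff3(source: str | Path) -> dict[str, Gene]:
    """Parse GFF3 text (or a path to it) into a gene_id -> Gene mapping.

    Exon/CDS lines attach to their mRNA via Parent; mRNAs attach to genes.
    Exon/CDS lines whose Parent is a gene directly (single-transcript styles)
    get an implicit transcript named after the gene.
    """
    text = source
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}

    for lineno, line in enumerate(str(text).splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GFFError(f"line {lineno}: expected 9 columns, got {len(cols)}")
        seqid, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise GFFError(f"line {lineno}: non-integer coordinates") from exc
        if start > end:
            raise GFFError(f"line {lineno}: start > end ({start} > {end})")
        attrs = _attributes(attrs_s)

        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise GFFError(f"line {lineno}: gene without ID")
            genes[gid] = Gene(gid, seqid, start, end, strand)
        elif ftype in ("mRNA", "transcript"):
            tid, parent = attrs.get("ID"), attrs.get("Parent")
            if tid is None or parent is None:
                raise GFFError(f"line {lineno}: mRNA needs ID and Parent")
            tr = Transcript(tid, parent, seqid, strand)
            transcripts[tid] = tr
            if parent in genes:
                genes[parent].transcripts[tid] = tr
        elif ftype in ("exon", "CDS"):
            parent = attrs.get("Parent")
            if parent is None:
                raise GFFError(f"line {lineno}: {ftype} without Parent")
            if parent not in transcripts:
                if parent in genes:  # exon attached straight to a gene
                    tr = Transcript(parent, parent, seqid, strand)
                    transcripts[parent] = tr
                    genes[parent].transcripts[parent] = tr
                else:
                    raise GFFError(f"line {lineno}: unknown Parent {parent!r}")
            target = transcripts[parent]
            (target.exons if ftype == "exon" else target.cds).append((start, end))

    # orphan transcripts (gene line missing) become their own gene records
    for tid, tr in transcripts.items():
        if tr.gene_id not in genes and tid != tr.gene_id:
            lo = min(s for s, _ in tr.exons or tr.cds or [(1, 1)])
            hi = max(e for _, e in tr.exons or tr.cds or [(1, 1)])
            genes.setdefault(
                tr.gene_id, Gene(tr.gene_id, tr.seqid, lo, hi, tr.strand)
            ).transcripts[tid] = tr
    return genes


def gene_chromosomes(genes: dict[str, Gene]) -> dict[str, str]:
    return {gid: g.seqid for gid, g in genes.items()}
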