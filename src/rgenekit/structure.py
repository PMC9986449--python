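"""Gene-composition statistics: GC content, CDS length, exons and introns.

GC is computed over the concatenated CDS of one representative transcript
per gene (the longest CDS), with ambiguity bases (anything outside ACGT)
excluded from both numerator and denominator.  Introns are the genomic gaps
between consecutive exons of that transcript, 1-based inclusive arithmetic:
exons at 1-100 and 201-300 flank an intron of length 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .gff import Gene, parse_gff3


class AnnotationError(ValueError):
    pass


class MissingSequenceError(KeyError):
    pass


@dataclass
class GeneStructure:
    gene_id: str
    transcript_id: str
    gc_percent: float
    cds_length_bp: int
    n_exons: int
    exon_lengths_bp: list[int]
    intron_lengths_bp: list[int]

    @property
    def n_introns(self) -> int:
        return len(self.intron_lengths_bp)

    @property
    def total_intron_bp(self) -> int:
        return sum(self.intron_lengths_bp)

    @property
    def mean_intron_bp(self) -> float:
        return float(np.mean(self.intron_lengths_bp)) if self.intron_lengths_bp else 0.0

    @property
    def mean_exon_bp(self) -> float:
        return float(np.mean(self.exon_lengths_bp))


def gc_percent(seq: str) -> float:
    """GC percentage over unambiguous bases only; 0.0 for an empty count."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    total = gc + at
    return 100.0 * gc / total if total else 0.0


def _representative(gene: Gene):
    """Longest-CDS transcript (ties broken by transcript ID for determinism)."""
    if not gene.transcripts:
        return None
    return max(
        gene.transcripts.values(),
        key=lambda t: (t.cds_length or sum(e - s + 1 for s, e in t.exons),
                       t.transcript_id),
    )


def compute_structures(
    gff: str | Path | dict[str, Gene],
    cds_fasta: str | Path,
) -> list[GeneStructure]:
    """Per-gene structure statistics from a GFF3 and a CDS FASTA.

    FASTA records are matched by transcript ID, falling back to the gene ID.
    Overlapping exons within a transcript are an annotation error.
    """
    genes = gff if isinstance(gff, dict) else parse_gff3(gff)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(cds_fasta), "fasta")}

    out: list[GeneStructure] = []
    for gid in sorted(genes):
        tr = _representative(genes[gid])
        if tr is None:
            continue
        exons = tr.sorted_exons() or sorted(tr.cds)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"{tr.transcript_id}: overlapping exons "
                    f"({s1}-{e1}, {s2}-{e2})"
                )
        seq = seqs.get(tr.transcript_id, seqs.get(gid))
        if seq is None:
            raise MissingSequenceError(
                f"no CDS sequence for {tr.transcript_id} (gene {gid})"
            )
        introns = [s2 - e1 - 1 for (s1, e1), (s2, e2) in zip(exons, exons[1:])]
        out.append(
            GeneStructure(
                gene_id=gid,
                transcript_id=tr.transcript_id,
                gc_percent=gc_percent(seq),
                cds_length_bp=len(seq),
                n_exons=len(exons),
                exon_lengths_bp=[e - s + 1 for s, e in exons],
                intron_lengths_bp=introns,
            )
        )
    return out


def structures_frame(structures: list[GeneStructure]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in structures],
            "gc_percent": [s.gc_percent for s in structures],
            "cds_length_bp": [s.cds_length_bp for s in structures],
            "n_exons": [s.n_exons for s in structures],
            "total_intron_bp": [s.total_intron_bp for s in structures],
            "mean_intron_bp": [s.mean_intron_bp for s in structures],
            "mean_exon_bp": [s.mean_exon_bp for s in structures],
        }
    )


@dataclass
class GroupComparison:
    field: str
    test: str
    statistic: float
    p_value: float
    group_means: dict[str, float]
    group_n: dict[str, int]


class DegenerateVarianceError(ValueError):
    pass


def compare_groups(
    structures: list[GeneStructure],
    grouping: dict[str, str],
    field: str,
    test: str = "auto",
) -> GroupComparison:
    """Compare a structure field across groups (species or subfamily).

    ``test="auto"`` runs one-way ANOVA for >2 groups and a Welch t test for
    exactly two; ``"mannwhitney"`` forces the rank test.  Groups with fewer
    than 2 members are rejected.
    """
    values: dict[str, list[float]] = {}
    for s in structures:
        g = grouping.get(s.gene_id)
        if g is None:
            continue
        values.setdefault(g, []).append(float(getattr(s, field)))
    if len(values) < 2:
        raise ValueError("need at least two groups")
    for g, v in values.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")

    labels = sorted(values)
    arrays = [np.asarray(values[g]) for g in labels]
    if all(a.std() == 0 for a in arrays) and test != "mannwhitney":
        if len({a[0] for a in arrays}) == 1:
            raise DegenerateVarianceError(f"{field} constant within all groups")

    if test == "auto":
        test = "welch" if len(labels) == 2 else "anova"
    if test == "anova":
        res = stats.f_oneway(*arrays)
    elif test == "welch":
        if len(labels) != 2:
            raise ValueError("Welch t test requires exactly two groups")
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
    elif test == "mannwhitney":
        if len(labels) != 2:
            raise ValueError("Mann-Whitney requires exactly two groups")
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")

    return GroupComparison(
        field=field,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_means={g: float(np.mean(values[g])) for g in labels},
        group_n={g: len(values[g]) for g in labels},
    )
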