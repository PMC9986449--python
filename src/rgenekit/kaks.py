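"""Nei-Gojobori (1986) Ka/Ks estimation on pairwise codon alignments.

The method counts, for each codon, the expected numbers of synonymous (S)
and nonsynonymous (N) sites — per position, the fraction of one-step
nucleotide changes that are synonymous, among changes that do not create a
stop codon — and the observed synonymous/nonsynonymous differences (Sd, Nd)
between the two codons, averaged with equal weight over all orderings of
the differing positions (pathways through stop codons are excluded).
Proportions pN = Nd/N and pS = Sd/S are corrected for multiple hits with
the Jukes-Cantor formula d = -(3/4)·ln(1 - 4p/3); the ratio Ka/Ks > 1
indicates positive selection.

Codon alignments are built by protein-guided global alignment (BLOSUM62,
affine gaps) back-translated to codons; columns containing a gap or an
ambiguity base are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations, product

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

BASES = "TCAG"
LOW_CONFIDENCE_MIN_CODONS = 30


class SequenceQualityError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class GeneticCode:
    """Codon -> amino-acid mapping for one NCBI translation table."""

    def __init__(self, table_id: int = 1):
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.stops = frozenset(tbl.stop_codons)
        self.aa = dict(tbl.forward_table)
        for c in self.stops:
            self.aa[c] = "*"

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def translate(self, codon: str) -> str:
        return self.aa[codon]


STANDARD_CODE = GeneticCode(1)


@lru_cache(maxsize=None)
def _code(table_id: int) -> GeneticCode:
    return GeneticCode(table_id)


@lru_cache(maxsize=None)
def syn_sites(codon: str, table_id: int = 1) -> float:
    """Expected synonymous sites in one codon.

    Per position: (# synonymous one-step changes) / (# one-step changes not
    creating a stop).  Nonsynonymous sites are 3 minus this, so every codon
    contributes exactly 3 sites.
    """
    code = _code(table_id)
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no defined site counts")
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if code.is_stop(alt):
                continue
            valid += 1
            if code.translate(alt) == code.translate(codon):
                syn += 1
        total += syn / valid if valid else 0.0
    return total


@lru_cache(maxsize=None)
def pair_differences(c1: str, c2: str, table_id: int = 1) -> tuple[float, float]:
    """(Nd, Sd) between two codons, equal-weight pathway averaging.

    Codons differing at k positions have k! substitution orderings; each
    single step is classified synonymous or nonsynonymous, orderings that
    pass through a stop codon are discarded, and the per-step tallies are
    averaged over the surviving orderings.  If every ordering is blocked by
    stops, each differing position is classified by the direct one-step
    change in the context of whichever codon keeps it stop-free.
    """
    code = _code(table_id)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    nd_list, sd_list = [], []
    for order in permutations(diff):
        cur, nd, sd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate(nxt) == code.translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            nd_list.append(nd)
            sd_list.append(sd)
    if nd_list:
        return float(np.mean(nd_list)), float(np.mean(sd_list))
    # every ordering blocked: classify each position by a direct swap
    nd = sd = 0.0
    for pos in diff:
        alt1 = c1[:pos] + c2[pos] + c1[pos + 1:]
        alt2 = c2[:pos] + c1[pos] + c2[pos + 1:]
        if not code.is_stop(alt1):
            syn = code.translate(alt1) == code.translate(c1)
        elif not code.is_stop(alt2):
            syn = code.translate(alt2) == code.translate(c2)
        else:
            syn = False
        sd, nd = (sd + 1, nd) if syn else (sd, nd + 1)
    return nd, sd


@dataclass
class CodonAlignment:
    codons_a: list[str]
    codons_b: list[str]
    n_dropped_gap: int = 0
    n_dropped_ambiguous: int = 0

    def __len__(self) -> int:
        return len(self.codons_a)

    @property
    def low_confidence(self) -> bool:
        return len(self) < LOW_CONFIDENCE_MIN_CODONS


_AA_OK = set("ACGT")


def _codons(seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    n = len(seq) - len(seq) % 3        # trim incomplete tail
    return [seq[i:i + 3] for i in range(0, n, 3)]


def _protein(codons: list[str], code: GeneticCode, max_internal_stops: int):
    if codons and code.is_stop(codons[-1]):
        codons = codons[:-1]            # trailing stop is not part of the ORF
    aas, stops = [], 0
    for c in codons:
        if any(b not in _AA_OK for b in c):
            aas.append("X")
        elif code.is_stop(c):
            stops += 1
            aas.append("X")             # align through it; column dropped later
        else:
            aas.append(code.translate(c))
    if stops > max_internal_stops:
        raise SequenceQualityError(
            f"{stops} internal stop codons (max {max_internal_stops})"
        )
    return codons, "".join(aas)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


def align_codons(
    cds_a: str,
    cds_b: str,
    max_internal_stops: int = 0,
    table_id: int = 1,
) -> CodonAlignment:
    """Protein-guided codon alignment of two coding sequences.

    Sequences are trimmed to full codons, translated, globally aligned
    (BLOSUM62, gap open 10 / extend 0.5) and back-translated; codon columns
    with a gap or ambiguity base are dropped.
    """
    code = _code(table_id)
    cod_a, prot_a = _protein(_codons(cds_a), code, max_internal_stops)
    cod_b, prot_b = _protein(_codons(cds_b), code, max_internal_stops)
    if not prot_a or not prot_b:
        raise AlignmentError("empty coding sequence after trimming")

    # X (ambiguity/stop placeholder) is not in BLOSUM62's alphabet subset we
    # feed; substitute a neutral residue for scoring, original kept for masks
    sub = str.maketrans({"X": "A"})
    aln = _aligner().align(prot_a.translate(sub), prot_b.translate(sub))[0]

    keep_a, keep_b = [], []
    n_gap = n_amb = 0
    blocks_a, blocks_b = aln.aligned
    prev_a = prev_b = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        n_gap += (sa - prev_a) + (sb - prev_b)
        prev_a, prev_b = ea, eb
        for i, j in zip(range(sa, ea), range(sb, eb)):
            ca, cb = cod_a[i], cod_b[j]
            if any(b not in _AA_OK for b in ca + cb) or code.is_stop(ca) or code.is_stop(cb):
                n_amb += 1
                continue
            keep_a.append(ca)
            keep_b.append(cb)
    n_gap += (len(cod_a) - prev_a) + (len(cod_b) - prev_b)
    if not keep_a:
        raise AlignmentError("no aligned codon columns survive filtering")
    return CodonAlignment(keep_a, keep_b, n_gap, n_amb)


@dataclass
class KaKsResult:
    pair_id: tuple[str, str]
    n_codons_used: int
    N: float
    S: float
    Nd: float
    Sd: float
    pn: float
    ps: float
    ka: float | None
    ks: float | None
    ratio: float | None
    saturated: bool = False
    low_confidence: bool = False

    def as_dict(self) -> dict:
        return {
            "gene_a": self.pair_id[0], "gene_b": self.pair_id[1],
            "n_codons": self.n_codons_used,
            "N": self.N, "S": self.S, "Nd": self.Nd, "Sd": self.Sd,
            "pN": self.pn, "pS": self.ps,
            "Ka": self.ka if self.ka is not None else "NA",
            "Ks": self.ks if self.ks is not None else "NA",
            "KaKs": self.ratio if self.ratio is not None else "NA",
            "saturated": self.saturated,
            "low_confidence": self.low_confidence,
        }


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(
    alignment: CodonAlignment,
    pair_id: tuple[str, str] = ("A", "B"),
    table_id: int = 1,
) -> KaKsResult:
    """NG86 Ka/Ks for one codon alignment.

    Site counts are averaged over the two sequences; N + S = 3·codons.
    The ratio is undefined (None) when Ks is 0 or either Jukes-Cantor
    correction is undefined (proportion >= 3/4, reported as saturated).
    """
    L = len(alignment)
    if L == 0:
        raise ValueError("empty codon alignment")
    s_a = sum(syn_sites(c, table_id) for c in alignment.codons_a)
    s_b = sum(syn_sites(c, table_id) for c in alignment.codons_b)
    S = (s_a + s_b) / 2.0
    N = 3.0 * L - S
    nd = sd = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        d_n, d_s = pair_differences(ca, cb, table_id)
        nd += d_n
        sd += d_s
    pn = nd / N if N > 0 else 0.0
    ps = sd / S if S > 0 else 0.0
    ka, ks = _jukes_cantor(pn), _jukes_cantor(ps)
    saturated = (pn >= 0.75) or (ps >= 0.75)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(
        pair_id=pair_id, n_codons_used=L, N=N, S=S, Nd=nd, Sd=sd,
        pn=pn, ps=ps, ka=ka, ks=ks, ratio=ratio,
        saturated=saturated, low_confidence=alignment.low_confidence,
    )


def kaks_pair(cds_a: str, cds_b: str, pair_id=("A", "B"), **kw) -> KaKsResult:
    return ng86(align_codons(cds_a, cds_b, **kw), pair_id=pair_id)


DEFAULT_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 1.0, 1.1, math.inf)


def bin_ratios(results: list[KaKsResult], edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Histogram of defined Ka/Ks ratios; undefined (NA) counted separately.

    Returns a frame with one row per bin (left-closed, right-open) plus a
    trailing "undefined" row; percentages are over defined ratios only.
    """
    edges = list(edges)
    defined = [r.ratio for r in results if r.ratio is not None]
    n_def = len(defined)
    counts, _ = np.histogram(defined, bins=edges) if defined else (
        np.zeros(len(edges) - 1, int), None)
    rows = []
    for i, c in enumerate(counts):
        hi = edges[i + 1]
        label = f"[{edges[i]:g}, {hi:g})" if math.isfinite(hi) else f">={edges[i]:g}"
        rows.append({
            "bin": label, "count": int(c),
            "percent": 100.0 * c / n_def if n_def else 0.0,
        })
    rows.append({
        "bin": "undefined",
        "count": sum(1 for r in results if r.ratio is None),
        "percent": float("nan"),
    })
    return pd.DataFrame(rows)


def shared_pairs(pair_sets: dict[str, set]) -> set:
    """Pairs present in every comparison (e.g. one wild-species anchor gene
    matched in all three other species)."""
    sets = list(pair_sets.values())
    if not sets:
        return set()
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def pairs_from_fasta(path) -> list[tuple[tuple[str, str], str, str]]:
    """Consecutive-record pairing of a paired CDS FASTA."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) % 2:
        raise ValueError("paired FASTA has an odd number of records")
    out = []
    for i in range(0, len(recs), 2):
        a, b = recs[i], recs[i + 1]
        out.append(((a.id, b.id), str(a.seq), str(b.seq)))
    return out
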