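"""NBS-LRR identification and subfamily classification from domain annotations.

A gene is an NBS-LRR (R-gene) candidate when its protein products carry both
a nucleotide-binding NB-ARC domain and leucine-rich repeats (LRR).  The
N-terminal domain then determines the subfamily:

* TIR present                      -> TNL
* coiled-coil present (no TIR)     -> CNL
* RPW8 present (no TIR/CC)         -> RNL
* none of the three                -> NL ("truncated CNL" in monocots)
* TIR and CC both present          -> flagged TNL+CNL (rare dual-domain genes)

Domain evidence arrives as an InterProScan-style TSV; raw signature
accessions (Pfam/InterPro/COILS) are mapped to canonical labels through an
editable signature map so the classification rule itself stays fixed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

CANONICAL_LABELS = ("NB-ARC", "LRR", "TIR", "RPW8", "CC", "OTHER")

_ROUND = 1  # report percentages to one decimal place


class DomainParseError(ValueError):
    pass


@dataclass(frozen=True)
class DomainRecord:
    """One protein-domain hit with 1-based inclusive protein coordinates."""

    protein_id: str
    raw_signature: str
    canonical_label: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}: domain start {self.start} > end {self.end}"
            )
        if self.canonical_label not in CANONICAL_LABELS:
            raise ValueError(f"unknown canonical label {self.canonical_label!r}")


@dataclass(frozen=True)
class Classification:
    gene_id: str
    is_nbs_lrr: bool
    subfamily: str | None          # CNL / TNL / RNL / NL / TNL+CNL
    domain_set: frozenset[str]


@dataclass
class SpeciesSummary:
    species: str
    n_genes_total: int
    genome_size_mb: float
    n_nbs: int
    n_cnl: int
    n_tnl: int
    n_rnl: int
    n_nl: int
    n_multi: int = 0               # dual TIR+CC genes, counted once in n_nbs

    @property
    def nbs_fraction(self) -> float:
        return self.n_nbs / self.n_genes_total if self.n_genes_total else 0.0

    def percent(self, count: int) -> float:
        """A subfamily count as percent of all NBS-LRR genes, 1 decimal."""
        if self.n_nbs == 0:
            return 0.0
        return round(100.0 * count / self.n_nbs, _ROUND)

    @property
    def cnl_percent(self) -> float:
        return self.percent(self.n_cnl)


def default_signature_map() -> dict[str, str]:
    """Signature -> canonical label map shipped with the package.

    Covers the NB-ARC, TIR, RPW8 and LRR-superfamily Pfam/InterPro
    accessions plus COILS coiled-coil predictor hits.
    """
    path = resources.files("rgenekit.data").joinpath("signature_map.tsv")
    return load_signature_map(str(path))


def load_signature_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            label = row["label"].strip()
            if label not in CANONICAL_LABELS:
                raise DomainParseError(f"signature map label {label!r} not canonical")
            out[row["signature"].strip()] = label
    return out


def load_domains(
    path: str | Path,
    signature_map: dict[str, str] | None = None,
    columns: tuple[int, int, int, int] = (0, 1, 2, 3),
) -> list[DomainRecord]:
    """Read an InterProScan-style domain TSV into DomainRecords.

    ``columns`` gives the indices of (protein_id, signature, start, end) so
    wider InterProScan exports can be consumed without reshaping.  Unmapped
    signatures become OTHER; row order is preserved.
    """
    if signature_map is None:
        signature_map = default_signature_map()
    pi, si, sti, eni = columns
    records: list[DomainRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return records
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            try:
                protein_id = cols[pi]
                sig = cols[si]
                start, end = int(cols[sti]), int(cols[eni])
            except (IndexError, ValueError) as exc:
                raise DomainParseError(f"line {lineno}: malformed row") from exc
            records.append(
                DomainRecord(protein_id, sig, signature_map.get(sig, "OTHER"),
                             start, end)
            )
    return records


def classify_gene(gene_id: str, domain_set: frozenset[str] | set[str]) -> Classification:
    """Classify one gene from the union of canonical labels over its proteins.

    Pure function of the domain set; genes lacking either NB-ARC or LRR are
    not NBS-LRR and get no subfamily.
    """
    ds = frozenset(domain_set)
    is_nbs = "NB-ARC" in ds and "LRR" in ds
    subfamily = None
    if is_nbs:
        has_tir, has_cc, has_rpw8 = "TIR" in ds, "CC" in ds, "RPW8" in ds
        if has_tir and has_cc:
            subfamily = "TNL+CNL"
        elif has_tir:
            subfamily = "TNL"
        elif has_cc:
            subfamily = "CNL"
        elif has_rpw8:
            subfamily = "RNL"
        else:
            subfamily = "NL"
    return Classification(gene_id, is_nbs, subfamily, ds)


def classify_genes(
    domains: list[DomainRecord],
    protein_to_gene=None,
) -> dict[str, Classification]:
    """Classify every gene seen in a domain table.

    ``protein_to_gene`` maps protein/transcript IDs to gene IDs (defaults to
    identity); domain sets are unioned over all products of a gene.
    """
    sets: dict[str, set[str]] = {}
    for rec in domains:
        gid = protein_to_gene(rec.protein_id) if protein_to_gene else rec.protein_id
        sets.setdefault(gid, set()).add(rec.canonical_label)
    return {gid: classify_gene(gid, ds) for gid, ds in sets.items()}


def summarize_species(
    classifications,
    gene_total: int,
    genome_size_mb: float,
    species: str = "",
) -> SpeciesSummary:
    """Per-species NBS-LRR subfamily counts with 1-decimal percentages."""
    if isinstance(classifications, dict):
        classifications = classifications.values()
    nbs = [c for c in classifications if c.is_nbs_lrr]
    counts = {"CNL": 0, "TNL": 0, "RNL": 0, "NL": 0, "TNL+CNL": 0}
    for c in nbs:
        counts[c.subfamily] += 1
    if not nbs:
        warnings.warn(f"{species or 'species'}: no NBS-LRR genes; fractions are 0")
    return SpeciesSummary(
        species=species,
        n_genes_total=gene_total,
        genome_size_mb=genome_size_mb,
        n_nbs=len(nbs),
        n_cnl=counts["CNL"],
        n_tnl=counts["TNL"],
        n_rnl=counts["RNL"],
        n_nl=counts["NL"],
        n_multi=counts["TNL+CNL"],
    )


class UndefinedCorrelationError(ValueError):
    pass


def correlate(summaries, x_field: str, y_field: str, method: str = "pearson"):
    """Bivariate correlation across species summaries.

    Pearson product-moment r with a two-sided p from the t transform on
    n-2 df (Spearman available via ``method="spearman"``).  Accepts a list
    of SpeciesSummary or any objects/records exposing the two fields.
    """
    def get(obj, f):
        if isinstance(obj, dict):
            return float(obj[f])
        return float(getattr(obj, f))

    x = np.array([get(s, x_field) for s in summaries], dtype=float)
    y = np.array([get(s, y_field) for s in summaries], dtype=float)
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {x_field if np.ptp(x) == 0 else y_field}"
        )
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue), len(x)
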