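"""Polyploid allele grouping and allele-retention statistics.

In haplotype-resolved polyploid assemblies (tetraploid *S. spontaneum*,
octoploid *S. officinarum*) each base gene may be annotated as up to
`ploidy` allele entries distinguished by an ID suffix.  Grouping those
entries recovers per-gene allele retention; most R genes have lost one or
more alleles, and coiled-coil (CNL) genes retain alleles better than
truncated (NL) genes.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._grammar import parse_gene_id

log = logging.getLogger(__name__)


class DuplicateGeneIdError(ValueError):
    pass


class UnknownGeneError(KeyError):
    pass


@dataclass
class AlleleGroup:
    base_gene_id: str
    allele_ids: list[str]
    ploidy: int
    subfamily: str | None = None
    origin_prefix: str = ""

    def __post_init__(self):
        if not 1 <= self.n_retained <= self.ploidy:
            raise ValueError(
                f"{self.base_gene_id}: {self.n_retained} alleles exceeds "
                f"ploidy {self.ploidy}"
            )

    @property
    def n_retained(self) -> int:
        return len(set(self.allele_ids))

    @property
    def n_lost(self) -> int:
        return self.ploidy - self.n_retained


def group_alleles(
    gene_ids,
    ploidy: int,
    subfamilies: dict[str, str] | None = None,
) -> list[AlleleGroup]:
    """Group allele-suffixed gene IDs into base genes.

    IDs without a parseable allele suffix become singleton groups (logged).
    ``subfamilies`` may be keyed by allele ID or base gene ID; the group
    takes the first subfamily seen among its members.
    """
    gene_ids = list(gene_ids)
    dupes = [g for g, c in Counter(gene_ids).items() if c > 1]
    if dupes:
        raise DuplicateGeneIdError(f"duplicate gene IDs: {dupes[:5]}")

    members: dict[str, list[str]] = {}
    for gid in gene_ids:
        parsed = parse_gene_id(gid)
        if not parsed.has_suffix:
            log.info("ID %s lacks an allele suffix; kept as singleton", gid)
        members.setdefault(parsed.base_gene_id, []).append(gid)

    groups = []
    for base, ids in members.items():
        sub = None
        if subfamilies:
            for key in (base, *ids):
                if key in subfamilies:
                    sub = subfamilies[key]
                    break
        groups.append(
            AlleleGroup(base, sorted(ids), ploidy, sub,
                        parse_gene_id(base).prefix)
        )
    return groups


@dataclass
class RetentionTable:
    """Distribution of alleles retained per base gene at one ploidy."""

    ploidy: int
    table: pd.DataFrame          # columns: n_retained, count, percent
    n_groups: int
    percent_retained_all: float
    percent_lost_some: float


def retention_summary(groups: list[AlleleGroup]) -> RetentionTable:
    """Tabulate n_retained -> (count, percent of groups), 1-decimal percents.

    Also reports the headline split: percent of base genes retaining the
    full allele complement vs losing at least one allele.
    """
    if not groups:
        return RetentionTable(0, pd.DataFrame(
            columns=["n_retained", "count", "percent"]), 0, 0.0, 0.0)
    ploidies = {g.ploidy for g in groups}
    if len(ploidies) > 1:
        raise ValueError(f"groups mix ploidies: {sorted(ploidies)}")
    ploidy = ploidies.pop()
    n = len(groups)
    counts = Counter(g.n_retained for g in groups)
    rows = [
        {"n_retained": k, "count": counts.get(k, 0),
         "percent": round(100.0 * counts.get(k, 0) / n, 1)}
        for k in range(1, ploidy + 1)
    ]
    full = counts.get(ploidy, 0)
    return RetentionTable(
        ploidy=ploidy,
        table=pd.DataFrame(rows),
        n_groups=n,
        percent_retained_all=round(100.0 * full / n, 1),
        percent_lost_some=round(100.0 * (n - full) / n, 1),
    )


@dataclass
class LossComparison:
    statistic: float
    p_value: float
    medians: dict[str, float]
    means: dict[str, float]
    n: dict[str, int]


def compare_loss_by_subfamily(
    groups: list[AlleleGroup],
    class_a: str = "CNL",
    class_b: str = "NL",
) -> LossComparison:
    """Mann-Whitney U on alleles lost, CNL vs truncated-CNL (NL) groups.

    Two-sided rank test on ``n_lost = ploidy - n_retained``; small discrete
    counts make a rank test the robust default.
    """
    a = np.array([g.n_lost for g in groups if g.subfamily == class_a])
    b = np.array([g.n_lost for g in groups if g.subfamily == class_b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >=2 groups in each class ({class_a}: {len(a)}, "
            f"{class_b}: {len(b)})"
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return LossComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        medians={class_a: float(np.median(a)), class_b: float(np.median(b))},
        means={class_a: float(a.mean()), class_b: float(b.mean())},
        n={class_a: len(a), class_b: len(b)},
    )


@dataclass
class DuplicateSummary:
    n_pairs: int
    n_genes: int
    per_chromosome: dict[str, int]
    dropped_allele_pairs: int = 0


def summarize_duplicates(
    pairs,
    known_genes,
    chromosomes: dict[str, str] | None = None,
) -> DuplicateSummary:
    """Summarise an externally supplied duplicated-gene pair list.

    ``pairs`` is an iterable of (gene_a, gene_b).  Pairs whose members are
    alleles of the same base gene are dropped (duplication within a gene's
    own allele set is allele retention, not gene expansion).  Chromosome
    tallies count distinct genes per chromosome when a mapping is given.
    """
    known = set(known_genes)
    unknown = sorted(
        {g for p in pairs for g in p if g not in known}
    )
    if unknown:
        raise UnknownGeneError(f"pair list references unknown genes: {unknown[:10]}")

    kept, dropped = [], 0
    for a, b in pairs:
        if parse_gene_id(a).base_gene_id == parse_gene_id(b).base_gene_id:
            dropped += 1
        else:
            kept.append((a, b))
    genes = sorted({g for p in kept for g in p})
    per_chrom: Counter = Counter()
    if chromosomes:
        for g in genes:
            per_chrom[chromosomes.get(g, "?")] += 1
    return DuplicateSummary(len(kept), len(genes), dict(per_chrom), dropped)


def read_pair_list(path) -> list[tuple[str, str]]:
    """Plain two-column TSV of gene pairs (no header detection magic:
    a first line whose cells repeat as gene IDs nowhere is kept as data)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"pair list line has <2 columns: {line!r}")
            out.append((cols[0], cols[1]))
    return out


def read_mcscanx_collinearity(path) -> list[tuple[str, str]]:
    """Extract gene pairs from an MCScanX ``.collinearity`` file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or ":" not in line:
                continue
            try:
                _idx, rest = line.split(":", 1)
                cols = rest.split()
                out.append((cols[0], cols[1]))
            except (ValueError, IndexError):
                warnings.warn(f"skipping unparseable collinearity line: {line!r}")
    return out
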