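"""Subgenome origin attribution of differentially expressed genes.

Modern sugarcane cultivars derive roughly 80% of their genome from the
noble parent *S. officinarum* and 10-20% from the wild parent
*S. spontaneum*.  After collapsing allele-level DE calls to base genes,
each gene is attributed to a parental subgenome by its ID prefix and the
wild-parent share among DE genes is tested against the expected genome
contribution (default 0.2) with an exact one-sided binomial test.  Alleles
of one base gene significantly regulated in opposite directions constitute
allele-specific expression (ASE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._grammar import parse_gene_id


class AttributionError(ValueError):
    pass


@dataclass
class GeneDE:
    """Base-gene-level DE call aggregated over alleles."""

    base_gene_id: str
    is_de: bool
    direction: str                       # up / down / mixed / none
    alleles: list[dict] = field(default_factory=list)

    @property
    def de_alleles(self) -> list[dict]:
        return [a for a in self.alleles if a["is_de"]]


def collapse_to_genes(de_table: pd.DataFrame) -> list[GeneDE]:
    """Collapse allele-level DE records to base genes.

    A base gene is DE iff at least one allele is DE; its direction is the
    shared direction of its DE alleles, or "mixed" when they disagree.
    Expects columns feature_id, log2fc, fdr, is_de, direction.
    """
    groups: dict[str, list[dict]] = {}
    for rec in de_table.to_dict("records"):
        base = parse_gene_id(str(rec["feature_id"])).base_gene_id
        groups.setdefault(base, []).append(
            {
                "allele_id": rec["feature_id"],
                "log2fc": float(rec["log2fc"]),
                "fdr": float(rec["fdr"]),
                "is_de": bool(rec["is_de"]),
                "direction": rec["direction"],
            }
        )
    out = []
    for base in sorted(groups):
        alleles = groups[base]
        de = [a for a in alleles if a["is_de"]]
        if not de:
            direction = "none"
        else:
            dirs = {a["direction"] for a in de}
            direction = dirs.pop() if len(dirs) == 1 else "mixed"
        out.append(GeneDE(base, bool(de), direction, alleles))
    return out


@dataclass
class OriginTest:
    n_total: int
    n_wild: int
    expected_p: float
    proportion: float
    p_value: float
    alternative: str = "greater"
    per_origin: dict[str, dict] = field(default_factory=dict)


def binomial_tail_greater(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct pmf summation."""
    if k <= 0:
        return 1.0
    ks = np.arange(k, n + 1)
    return float(np.sum(stats.binom.pmf(ks, n, p)))


def origin_test(
    genes: list[GeneDE] | pd.DataFrame,
    prefix_map: dict[str, str],
    expected_p: float = 0.2,
    wild_label: str = "wild",
    alternative: str = "greater",
    de_only: bool = True,
    method: str = "binomial",
) -> OriginTest:
    """Test the wild-parent share of DE genes against its expected value.

    Each base gene must match exactly one prefix in ``prefix_map``
    (e.g. {"Sspon": "wild", "Soff": "noble"}).  The default test is the
    exact binomial tail P(X >= n_wild), the direction of the claim that the
    wild parent contributes more resistance genes than its genome share;
    ``method="chi2"`` gives the one-df goodness-of-fit alternative and
    ``alternative="two-sided"`` doubles the smaller tail.
    """
    if isinstance(genes, pd.DataFrame):
        genes = collapse_to_genes(genes)
    pool = [g for g in genes if g.is_de] if de_only else list(genes)

    unmapped = sorted(
        {parse_gene_id(g.base_gene_id).prefix for g in pool}
        - set(prefix_map)
    )
    if unmapped:
        raise AttributionError(f"unmapped gene prefixes: {unmapped}")

    per_origin: dict[str, dict] = {}
    n_wild = 0
    for g in pool:
        label = prefix_map[parse_gene_id(g.base_gene_id).prefix]
        slot = per_origin.setdefault(
            label, {"n": 0, "up": 0, "down": 0, "mixed": 0}
        )
        slot["n"] += 1
        if g.direction in ("up", "down", "mixed"):
            slot[g.direction] += 1
        if label == wild_label:
            n_wild += 1

    n = len(pool)
    prop = n_wild / n if n else 0.0
    if n == 0:
        pval = 1.0
    elif method == "binomial":
        upper = binomial_tail_greater(n_wild, n, expected_p)
        if alternative == "greater":
            pval = upper
        elif alternative == "two-sided":
            lower = float(np.sum(stats.binom.pmf(np.arange(0, n_wild + 1), n,
                                                 expected_p)))
            pval = min(1.0, 2.0 * min(lower, upper))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    elif method == "chi2":
        exp = np.array([n * expected_p, n * (1 - expected_p)])
        obs = np.array([n_wild, n - n_wild])
        pval = float(stats.chisquare(obs, exp).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    return OriginTest(
        n_total=n, n_wild=n_wild, expected_p=expected_p,
        proportion=prop, p_value=pval, alternative=alternative,
        per_origin=per_origin,
    )


@dataclass
class ASECall:
    base_gene_id: str
    allele_up: list[str]
    allele_down: list[str]
    diseases: list[str] = field(default_factory=list)


def detect_ase(genes: list[GeneDE], disease: str | None = None) -> list[ASECall]:
    """Allele-specific expression: >=2 individually DE alleles of one base
    gene with opposite directions in the same comparison."""
    out = []
    for g in genes:
        up = [a["allele_id"] for a in g.de_alleles if a["direction"] == "up"]
        down = [a["allele_id"] for a in g.de_alleles if a["direction"] == "down"]
        if up and down:
            out.append(
                ASECall(g.base_gene_id, sorted(up), sorted(down),
                        [disease] if disease else [])
            )
    return out


@dataclass
class IntersectionReport:
    min_diseases: int
    strict_lfc: float
    genes: pd.DataFrame          # base_gene_id, n_diseases, diseases, in_strict
    n_multi_disease: int
    n_strict_common: int


def intersect_diseases(
    tables: dict[str, list[GeneDE]],
    min_diseases: int = 2,
    strict_lfc: float = 2.0,
    strict_diseases: list[str] | None = None,
) -> IntersectionReport:
    """Genes DE in multiple disease comparisons.

    ``tables`` maps disease label to collapsed gene tables.  The strict
    subset re-thresholds each gene at |log2fc| >= strict_lfc (on its DE
    alleles) and requires membership in every disease of
    ``strict_diseases`` (default: all of them).
    """
    if len(tables) < 2:
        raise ValueError("need at least two disease tables")
    if len(set(tables)) != len(tables):
        raise ValueError("duplicated disease labels")
    strict_in = strict_diseases if strict_diseases is not None else list(tables)

    membership: dict[str, set[str]] = {}
    strict_membership: dict[str, set[str]] = {}
    for disease, genes in tables.items():
        for g in genes:
            if not g.is_de:
                continue
            membership.setdefault(g.base_gene_id, set()).add(disease)
            if any(abs(a["log2fc"]) >= strict_lfc for a in g.de_alleles):
                strict_membership.setdefault(g.base_gene_id, set()).add(disease)

    rows = []
    for gene in sorted(membership):
        ds = sorted(membership[gene])
        if len(ds) < min_diseases:
            continue
        strict = set(strict_in) <= strict_membership.get(gene, set())
        rows.append(
            {"base_gene_id": gene, "n_diseases": len(ds),
             "diseases": ",".join(ds), "in_strict": strict}
        )
    frame = pd.DataFrame(
        rows, columns=["base_gene_id", "n_diseases", "diseases", "in_strict"]
    )
    return IntersectionReport(
        min_diseases=min_diseases,
        strict_lfc=strict_lfc,
        genes=frame,
        n_multi_disease=len(frame),
        n_strict_common=int(frame["in_strict"].sum()) if len(frame) else 0,
    )
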