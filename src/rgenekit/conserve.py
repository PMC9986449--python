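"""Conserved-gene identification from orthogroup membership tables.

A gene counts as "conserved" when its orthogroup contains at least one
member from every species under comparison (the strict all-species reading;
``min_species`` relaxes it).  Input follows the OrthoFinder
``Orthogroups.tsv`` dialect: first column the orthogroup ID, one column per
species, comma-separated gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd


class OrthogroupConfigError(ValueError):
    pass


@dataclass
class Orthogroup:
    og_id: str
    members: dict[str, list[str]]   # species -> gene IDs

    def species_present(self) -> set[str]:
        return {sp for sp, genes in self.members.items() if genes}


def read_orthogroups(path: str | Path) -> list[Orthogroup]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    species = list(df.columns[1:])
    out = []
    for _, row in df.iterrows():
        members = {
            sp: [g.strip() for g in row[sp].split(",") if g.strip()]
            for sp in species
        }
        out.append(Orthogroup(row[og_col], members))
    return out


def conserved_genes(
    orthogroups: list[Orthogroup],
    species_list: list[str],
    min_species: int | None = None,
) -> dict[str, set[str]]:
    """Per-species sets of conserved genes.

    Default ``min_species`` is all of ``species_list``; an orthogroup
    qualifies when it has members in at least that many of the listed
    species, and then all its member genes in those species are conserved.
    """
    if min_species is None:
        min_species = len(species_list)
    if orthogroups:
        header = set(orthogroups[0].members)
        missing = [sp for sp in species_list if sp not in header]
        if missing:
            raise OrthogroupConfigError(
                f"species absent from orthogroup table: {missing}"
            )
    out: dict[str, set[str]] = {sp: set() for sp in species_list}
    for og in orthogroups:
        present = og.species_present() & set(species_list)
        if len(present) >= min_species:
            for sp in species_list:
                out[sp].update(og.members.get(sp, []))
    return out


@dataclass
class ConservationRow:
    species: str
    n_nbs: int
    n_conserved: int
    percent_conserved: float            # of collapsed NBS-LRR gene count
    n_conserved_cnl: int
    percent_conserved_cnl: float        # of conserved genes
    percent_conserved_allele_denom: float | None = None


def conservation_summary(
    conserved: dict[str, set[str]],
    classifications: dict[str, "object"],
    nbs_totals: dict[str, int],
    allele_totals: dict[str, int] | None = None,
) -> list[ConservationRow]:
    """Per-species conserved-gene counts and CNL shares, 1-decimal percents.

    ``nbs_totals`` is the allele-collapsed NBS-LRR gene count per species.
    When ``allele_totals`` (counts before allele collapsing) is given, the
    conserved percentage is additionally reported against that denominator,
    since published polyploid summaries sometimes mix the two.
    """
    rows = []
    for sp in sorted(conserved):
        genes = conserved[sp]
        n_cons = len(genes)
        n_cnl = sum(
            1 for g in genes
            if g in classifications and getattr(classifications[g], "subfamily", None) == "CNL"
        )
        total = nbs_totals.get(sp, 0)
        alt = None
        if allele_totals and allele_totals.get(sp):
            alt = round(100.0 * n_cons / allele_totals[sp], 1)
        rows.append(
            ConservationRow(
                species=sp,
                n_nbs=total,
                n_conserved=n_cons,
                percent_conserved=round(100.0 * n_cons / total, 1) if total else 0.0,
                n_conserved_cnl=n_cnl,
                percent_conserved_cnl=(
                    round(100.0 * n_cnl / n_cons, 1) if n_cons else 0.0
                ),
                percent_conserved_allele_denom=alt,
            )
        )
    return rows
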