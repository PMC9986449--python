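"""Synthetic polyploid R-gene data with known ground truth.

Generates the three inputs the pipeline consumes — allele-suffixed gene
annotations (GFF3 + domain TSV + CDS FASTA), negative-binomially
distributed RNA-seq counts with planted differential expression and
antagonistic allele pairs, and codon-sequence pairs diverged under a
controlled nonsynonymous/synonymous rate ratio — each with a complete
truth table, so every downstream stage can be tested for exact or
statistical recovery without any external data.

Defaults mirror the sugarcane study system: a tetraploid wild-parent-style
genome where ~6% of R genes retain all four alleles, a CNL :
truncated-CNL mix of roughly 46:54 among NBS-LRR genes, three replicates
per group, NB dispersion 0.1 around a mean of ~100 counts, planted effects
of |log2FC| = 3, and a wild-parent prefix on ~55% of genes (the share
observed among disease-responsive genes, against a 20% genome-contribution
null).

Determinism: one RNG stream per output, derived from the master seed by a
fixed label, so regenerating one artifact never perturbs another.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._grammar import allele_suffix

CLASS_LABELS = ("CNL", "NL", "OTHER")    # coiled-coil, truncated, non-NBS

_DEFAULT_RETENTION = {
    2: (0.60, 0.40),
    4: (0.25, 0.35, 0.34, 0.06),
    8: (0.18, 0.20, 0.18, 0.15, 0.12, 0.09, 0.07, 0.01),
}

# domain rows emitted per planted class (signature, canonical meaning)
_CLASS_DOMAINS = {
    "CNL": (("Coil", 1, 120), ("PF00931", 160, 440), ("PF00560", 480, 900)),
    "NL": (("PF00931", 40, 320), ("PF13855", 360, 780)),
    "OTHER": (("PF00069", 30, 290),),    # protein kinase: not an R-gene domain
}

_CLASS_GC = {"CNL": 0.44, "NL": 0.46, "OTHER": 0.45}


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; every run is a pure function of this object."""

    seed: int = 0
    n_base_genes: int = 300
    ploidy: int = 4
    retention_probs: tuple[float, ...] | None = None
    class_mix: tuple[float, float, float] = (0.28, 0.32, 0.40)
    n_samples_per_group: int = 3
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 3.0
    ase_pairs: int = 7
    wild_fraction: float = 0.55
    omega_true: float = 0.2
    t_branch: float = 0.4
    n_codon_pairs: int = 50
    n_codons: int = 300
    base_mean: float = 100.0
    n_chromosomes: int = 8
    allow_any_ploidy: bool = False

    def __post_init__(self):
        if self.ploidy not in (2, 4, 8) and not self.allow_any_ploidy:
            raise SimConfigError(
                f"ploidy {self.ploidy} not in (2, 4, 8); set allow_any_ploidy"
            )
        probs = self.effective_retention_probs()
        if len(probs) != self.ploidy:
            raise SimConfigError("retention_probs must have one entry per "
                                 "possible allele count 1..ploidy")
        if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise SimConfigError("retention_probs must be a probability vector")
        for name in ("n_base_genes", "n_samples_per_group", "ase_pairs",
                     "n_codon_pairs", "n_codons"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or min(self.class_mix) < 0:
            raise SimConfigError("class_mix must be a probability vector")
        for name in ("nb_dispersion", "omega_true", "t_branch"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")
        if not 0 <= self.de_fraction <= 1 or not 0 <= self.wild_fraction <= 1:
            raise SimConfigError("fractions must lie in [0, 1]")

    def effective_retention_probs(self) -> tuple[float, ...]:
        if self.retention_probs is not None:
            return tuple(self.retention_probs)
        if self.ploidy in _DEFAULT_RETENTION:
            return _DEFAULT_RETENTION[self.ploidy]
        return tuple([1.0 / self.ploidy] * self.ploidy)

    def rng(self, label: str) -> np.random.Generator:
        """Independent, reproducible stream for one named output."""
        return np.random.default_rng(
            [self.seed % (2**31), zlib.crc32(label.encode())]
        )

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimulatedAnnotation:
    gff3: str
    domain_tsv: str
    cds_fasta: str
    truth: pd.DataFrame          # one row per allele entry


@dataclass
class SimulatedCounts:
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame

    @property
    def counts_tsv(self) -> str:
        return self.counts.to_csv(sep="\t", index_label="feature_id")

    @property
    def samples_tsv(self) -> str:
        return self.samples.to_csv(sep="\t", index=False)

    @property
    def truth_tsv(self) -> str:
        return self.truth.to_csv(sep="\t", index=False)


def _random_cds(rng: np.random.Generator, n_bp: int, gc: float) -> str:
    p_gc, p_at = gc / 2.0, (1.0 - gc) / 2.0
    return "".join(
        rng.choice(list("ACGT"), size=n_bp, p=[p_at, p_gc, p_gc, p_at])
    )


def simulate_annotation(cfg: SimConfig) -> SimulatedAnnotation:
    """Polyploid gene annotation: GFF3, domain TSV, CDS FASTA and truth.

    Each base gene appears as k allele entries (k ~ retention_probs) named
    ``<prefix>.<chr>G<locus>-<slot><letter>``; domain rows match the
    planted class exactly (no annotation noise), so classification recovery
    is testable against truth with zero mismatches.
    """
    rng = cfg.rng("annotation")
    probs = cfg.effective_retention_probs()
    letters = string.ascii_uppercase[: cfg.ploidy]

    gff = ["##gff-version 3"]
    dom = ["protein_id\tsignature\tstart\tend"]
    fasta = []
    truth_rows = []
    cursor = {c: 1000 for c in range(1, cfg.n_chromosomes + 1)}

    for i in range(cfg.n_base_genes):
        chrom = i % cfg.n_chromosomes + 1
        prefix = "Sspon" if rng.random() < cfg.wild_fraction else "Soff"
        base_id = f"{prefix}.{chrom:02d}G{(i + 1) * 10:07d}"
        klass = CLASS_LABELS[rng.choice(3, p=cfg.class_mix)]
        k = int(rng.choice(np.arange(1, cfg.ploidy + 1), p=probs))
        slots = sorted(rng.choice(cfg.ploidy, size=k, replace=False) + 1)

        n_exons = int(rng.integers(1, 5))
        cds_len = 3 * int(rng.integers(300, 1200))
        cuts = sorted(rng.choice(np.arange(1, cds_len // 3), size=n_exons - 1,
                                 replace=False)) if n_exons > 1 else []
        bounds = [0, *[3 * c for c in cuts], cds_len]
        exon_lens = [bounds[j + 1] - bounds[j] for j in range(n_exons)]
        intron_lens = [int(rng.integers(80, 1000)) for _ in range(n_exons - 1)]
        seq = _random_cds(rng, cds_len, _CLASS_GC[klass])

        for slot in slots:
            allele_id = f"{base_id}-{allele_suffix(slot)}"
            mrna_id = f"{allele_id}.1"
            start = cursor[chrom]
            pos, exons = start, []
            for j, el in enumerate(exon_lens):
                exons.append((pos, pos + el - 1))
                pos += el + (intron_lens[j] if j < len(intron_lens) else 0)
            end = exons[-1][1]
            cursor[chrom] = end + int(rng.integers(2000, 5000))

            gff.append("\t".join(
                [f"Chr{chrom}", "rgenekit_sim", "gene", str(start), str(end),
                 ".", "+", ".", f"ID={allele_id}"]))
            gff.append("\t".join(
                [f"Chr{chrom}", "rgenekit_sim", "mRNA", str(start), str(end),
                 ".", "+", ".", f"ID={mrna_id};Parent={allele_id}"]))
            for es, ee in exons:
                gff.append("\t".join(
                    [f"Chr{chrom}", "rgenekit_sim", "exon", str(es), str(ee),
                     ".", "+", ".", f"Parent={mrna_id}"]))
                gff.append("\t".join(
                    [f"Chr{chrom}", "rgenekit_sim", "CDS", str(es), str(ee),
                     ".", "+", "0", f"Parent={mrna_id}"]))
            for sig, ds, de_ in _CLASS_DOMAINS[klass]:
                dom.append(f"{allele_id}\t{sig}\t{ds}\t{de_}")
            fasta.append(f">{mrna_id}\n{seq}")

            truth_rows.append({
                "allele_id": allele_id,
                "base_gene_id": base_id,
                "class_label": klass,
                "origin_prefix": prefix,
                "n_retained": k,
                "chromosome": f"Chr{chrom}",
                "cds_length_bp": cds_len,
                "n_exons": n_exons,
            })

    return SimulatedAnnotation(
        gff3="\n".join(gff) + "\n",
        domain_tsv="\n".join(dom) + "\n",
        cds_fasta="\n".join(fasta) + "\n",
        truth=pd.DataFrame(truth_rows),
    )


def simulate_counts(cfg: SimConfig, annotation: SimulatedAnnotation) -> SimulatedCounts:
    """NB count matrix over allele-level features with planted DE and ASE.

    Group means of planted DE alleles differ by 2^de_log2fc (direction
    random per gene, shared by its alleles); ASE pairs are two alleles of
    one multi-allele base gene planted with opposite directions.  The truth
    table labels every feature.
    """
    if cfg.n_samples_per_group < 1:
        raise SimConfigError("n_samples_per_group must be >= 1")
    rng = cfg.rng("counts")
    truth = annotation.truth
    base_genes = truth["base_gene_id"].drop_duplicates().tolist()
    alleles_of = truth.groupby("base_gene_id")["allele_id"].apply(list).to_dict()

    multi = [b for b in base_genes if len(alleles_of[b]) >= 2]
    if cfg.ase_pairs > len(multi):
        raise SimConfigError(
            f"ase_pairs={cfg.ase_pairs} exceeds the {len(multi)} base genes "
            "with >=2 alleles"
        )
    ase_genes = set(
        rng.choice(multi, size=cfg.ase_pairs, replace=False).tolist()
    ) if cfg.ase_pairs else set()

    eligible = [b for b in base_genes if b not in ase_genes]
    n_de = int(round(cfg.de_fraction * len(base_genes)))
    n_de = min(n_de, len(eligible))
    de_genes = set(
        rng.choice(eligible, size=n_de, replace=False).tolist()
    ) if n_de else set()

    fc = 2.0 ** cfg.de_log2fc
    feature_rows = []
    for base in base_genes:
        base_mu = cfg.base_mean * rng.lognormal(0.0, 0.5)
        gene_dir = rng.choice(["up", "down"]) if base in de_genes else "none"
        ids = alleles_of[base]
        for idx, allele in enumerate(ids):
            mu1 = mu2 = base_mu
            direction, is_de, is_ase = "none", False, False
            if base in de_genes:
                direction, is_de = gene_dir, True
                mu2 = mu1 * fc if direction == "up" else mu1 / fc
            elif base in ase_genes and idx < 2:
                is_de, is_ase = True, True
                direction = "up" if idx == 0 else "down"
                mu2 = mu1 * fc if direction == "up" else mu1 / fc
            feature_rows.append({
                "allele_id": allele, "base_gene_id": base,
                "mean_group1": mu1, "mean_group2": mu2,
                "is_de": is_de, "direction": direction, "is_ase": is_ase,
            })

    ftruth = pd.DataFrame(feature_rows)
    n, g = len(ftruth), cfg.n_samples_per_group
    phi = cfg.nb_dispersion

    def draw(mu_col: np.ndarray) -> np.ndarray:
        mu = np.repeat(mu_col[:, None], g, axis=1)
        if phi == 0:
            return rng.poisson(mu)
        r = 1.0 / phi
        return rng.negative_binomial(r, r / (r + mu))

    c1 = draw(ftruth["mean_group1"].to_numpy())
    c2 = draw(ftruth["mean_group2"].to_numpy())
    samples = [f"g1_s{j + 1}" for j in range(g)] + [f"g2_s{j + 1}" for j in range(g)]
    counts = pd.DataFrame(
        np.hstack([c1, c2]), index=ftruth["allele_id"], columns=samples
    )
    sheet = pd.DataFrame({
        "sample": samples,
        "group": ["group1"] * g + ["group2"] * g,
    })
    return SimulatedCounts(counts=counts, samples=sheet, truth=ftruth)


# --- codon-pair evolution ---------------------------------------------------

from .kaks import BASES, GeneticCode, _code  # noqa: E402


def _random_sense_codons(rng, n_codons: int, code: GeneticCode) -> list[str]:
    sense = [a + b + c for a in BASES for b in BASES for c in BASES
             if not code.is_stop(a + b + c)]
    return [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]


def _evolve(rng, codons: list[str], t: float, omega: float,
            code: GeneticCode) -> list[str]:
    """One lineage of a per-site substitution process.

    Mutation events arrive at rate ``t`` proposals per nucleotide site:
    uniform target base; proposals creating stops are rejected, synonymous
    changes always fix, nonsynonymous changes fix with probability omega.
    The uniform proposal kernel with symmetric acceptance keeps the sense
    codons' stationary distribution uniform, so the realized
    nonsynonymous/synonymous rate ratio equals omega.
    """
    seq = list(codons)
    n_sites = 3 * len(seq)
    for _ in range(rng.poisson(t * n_sites)):
        site = int(rng.integers(n_sites))
        ci, pos = divmod(site, 3)
        cur = seq[ci]
        alt_base = BASES[int(rng.integers(4))]
        if alt_base == cur[pos]:
            continue
        alt = cur[:pos] + alt_base + cur[pos + 1:]
        if code.is_stop(alt):
            continue
        if code.translate(alt) == code.translate(cur) or rng.random() < omega:
            seq[ci] = alt
    return seq


def simulate_codon_pairs(
    cfg: SimConfig,
    n_pairs: int | None = None,
    n_codons: int | None = None,
) -> tuple[list[tuple[str, str]], str]:
    """Codon-sequence pairs diverged with rate ratio omega_true.

    Each pair descends from a random sense-codon ancestor along two
    independent lineages of total length t_branch (proposals per
    nucleotide site, split evenly).  Returns (pairs, paired FASTA text);
    headers record the pair index, omega and branch length.
    """
    n_pairs = cfg.n_codon_pairs if n_pairs is None else n_pairs
    n_codons = cfg.n_codons if n_codons is None else n_codons
    if n_codons <= 0:
        raise SimConfigError("n_codons must be positive")
    if cfg.omega_true < 0 or cfg.t_branch < 0:
        raise SimConfigError("omega_true and t_branch must be non-negative")
    code = _code(1)
    rng = cfg.rng("codon_pairs")
    pairs, fasta = [], []
    for p in range(n_pairs):
        anc = _random_sense_codons(rng, n_codons, code)
        a = "".join(_evolve(rng, anc, cfg.t_branch / 2, cfg.omega_true, code))
        b = "".join(_evolve(rng, anc, cfg.t_branch / 2, cfg.omega_true, code))
        pairs.append((a, b))
        hdr = f"pair{p:04d} omega={cfg.omega_true:g} t={cfg.t_branch:g}"
        fasta.append(f">{hdr} seq=A\n{a}\n>{hdr} seq=B\n{b}")
    return pairs, "\n".join(fasta) + ("\n" if fasta else "")
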