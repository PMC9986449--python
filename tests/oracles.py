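"""Independent brute-force oracles used only by the test suite.

These re-derive the quantities under test from first principles (recursive
pathway enumeration, exact rational arithmetic) without sharing code with
the implementation.
"""

from __future__ import annotations

from fractions import Fraction

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _is_stop(codon: str) -> bool:
    return _aa(codon) == "*"


def oracle_syn_sites(codon: str) -> float:
    """Synonymous site count: per position, synonymous one-step changes as a
    fraction of one-step changes that avoid stop codons."""
    total = Fraction(0)
    for pos in range(3):
        syn, valid = 0, 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _is_stop(alt):
                continue
            valid += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if valid:
            total += Fraction(syn, valid)
    return float(total)


def _enumerate_paths(cur: str, target: str):
    """All stop-free substitution paths from cur to target, as (nd, sd)."""
    diff = [i for i in range(3) if cur[i] != target[i]]
    if not diff:
        yield (0, 0)
        return
    for pos in diff:
        nxt = cur[:pos] + target[pos] + cur[pos + 1:]
        if _is_stop(nxt):
            continue
        step = (0, 1) if _aa(nxt) == _aa(cur) else (1, 0)
        for nd, sd in _enumerate_paths(nxt, target):
            yield (nd + step[0], sd + step[1])


def oracle_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Equal-weight pathway-averaged (Nd, Sd) between two sense codons."""
    paths = list(_enumerate_paths(c1, c2))
    if paths:
        n = len(paths)
        nd = Fraction(sum(p[0] for p in paths), n)
        sd = Fraction(sum(p[1] for p in paths), n)
        return float(nd), float(sd)
    # all paths blocked by stops: direct one-step classification per position
    nd = sd = 0
    for pos in range(3):
        if c1[pos] == c2[pos]:
            continue
        alt1 = c1[:pos] + c2[pos] + c1[pos + 1:]
        alt2 = c2[:pos] + c1[pos] + c2[pos + 1:]
        if not _is_stop(alt1):
            syn = _aa(alt1) == _aa(c1)
        elif not _is_stop(alt2):
            syn = _aa(alt2) == _aa(c2)
        else:
            syn = False
        if syn:
            sd += 1
        else:
            nd += 1
    return float(nd), float(sd)


def oracle_ng86_counts(codons_a, codons_b):
    """(N, S, Nd, Sd) for an aligned codon pair list."""
    sa = sum(oracle_syn_sites(c) for c in codons_a)
    sb = sum(oracle_syn_sites(c) for c in codons_b)
    S = (sa + sb) / 2.0
    N = 3.0 * len(codons_a) - S
    nd = sd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d_n, d_s = oracle_pair_differences(ca, cb)
        nd += d_n
        sd += d_s
    return N, S, nd, sd


def oracle_binomial_tail_greater(k: int, n: int, p: Fraction) -> Fraction:
    """Exact P(X >= k) for Binomial(n, p) in rational arithmetic."""
    p = Fraction(p)
    q = 1 - p
    total = Fraction(0)
    # C(n, j) p^j q^(n-j) accumulated from j = k upward
    from math import comb

    for j in range(k, n + 1):
        total += comb(n, j) * p**j * q**(n - j)
    return total


def random_sense_codons(rng, n: int) -> list[str]:
    sense = [a + b + c for a in BASES for b in BASES for c in BASES
             if not _is_stop(a + b + c)]
    return [sense[i] for i in rng.integers(0, len(sense), size=n)]
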