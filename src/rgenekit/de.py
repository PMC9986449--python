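"""Differential expression on RNA-seq count matrices.

Implements the classic two-group workflow for count data: TPM summaries,
TMM (trimmed mean of M-values) between-sample normalization, and an exact
conditional negative-binomial test.  Conditional on a feature's total count
(after scaling libraries to a common size), the group-2 sum follows a
distribution that depends only on the per-group NB shape parameters
r_g = n_g / dispersion — a negative hypergeometric that reduces to a
binomial when the dispersion is 0.  Two-sided p-values double the smaller
tail (capped at 1); Benjamini-Hochberg FDR is applied across all features
of one comparison.  A feature is called differentially expressed when
FDR < 0.05 and |log2 fold change| >= 1 (defaults).

With no replicates the dispersion cannot be estimated and must be supplied;
the conventional default for such designs is BCV 0.4 (dispersion 0.16).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

NO_REPLICATE_BCV = 0.4


class UndefinedTPMError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Integer count matrix with sample groups and feature lengths."""

    counts: pd.DataFrame                       # features x samples
    groups: dict[str, str]                     # sample -> group label
    lengths: pd.Series | None = None           # feature length, bp

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled so each
    sample column sums to 1e6."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise KeyError(
            f"missing lengths for {list(lengths[lengths.isna()].index[:5])}"
        )
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    rate = counts.div(lengths / 1e3, axis=0)
    denom = rate.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise UndefinedTPMError(f"all-zero samples: {list(zero.index)}")
    return rate.div(denom, axis=1) * 1e6


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM scaling factors, geometric-mean centred to 1.

    Reference sample = the one whose 75th percentile of library-scaled
    counts is closest to the mean 75th percentile.  For each sample, log
    ratios (M) vs the reference are trimmed 30% from each tail and A values
    5% from each tail; the factor is 2 to the precision-weighted trimmed
    mean of M.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    uq = np.array([
        np.quantile(col[col > 0], 0.75) / n if (col > 0).any() else 0.0
        for col, n in zip(mat.T, lib)
    ])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref, ref_lib = mat[:, ref_idx], lib[ref_idx]

    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        obs, obs_lib = mat[:, j], lib[j]
        ok = (obs > 0) & (ref > 0)
        if not ok.any():
            warnings.warn(f"sample {counts.columns[j]}: no co-expressed "
                          "features with reference; factor set to 1")
            continue
        p_obs, p_ref = obs[ok] / obs_lib, ref[ok] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) inverse variance of M
        with np.errstate(divide="ignore"):
            w = 1.0 / ((obs_lib - obs[ok]) / (obs_lib * obs[ok])
                       + (ref_lib - ref[ok]) / (ref_lib * ref[ok]))
        fin = np.isfinite(m) & np.isfinite(a) & np.isfinite(w) & (w > 0)
        if not fin.any():
            continue                       # degenerate; factor stays 1
        m, a, w = m[fin], a[fin], w[fin]
        keep = np.ones(len(m), bool)
        for vals, frac in ((m, trim_m), (a, trim_a)):
            lo, hi = np.quantile(vals, [frac, 1 - frac])
            keep &= (vals >= lo) & (vals <= hi)
        if not keep.any():
            keep[:] = True
        log_factors[j] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    log_factors -= log_factors.mean()          # geometric-mean centre
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]       # monotone
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def estimate_common_dispersion(norm: np.ndarray, group_cols: list[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion on normalized counts.

    Aggregates the per-feature, per-group moment identity
    Var = mu + phi·mu^2 into a ratio-of-sums estimator (the mu^2 term is
    debiased by Var/n); clipped at 0.
    """
    num = den = 0.0
    for cols in group_cols:
        sub = norm[:, cols]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        keep = m > 0
        num += float(np.sum(v[keep] - m[keep]))
        den += float(np.sum(np.maximum(m[keep] ** 2 - v[keep] / sub.shape[1], 0)))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _conditional_pvalue(s2: int, t: int, r1: float, r2: float) -> float:
    """Two-sided exact p for the group-2 sum given the total.

    P(X = x | total t) ∝ C(x+r2-1, x)·C(t-x+r1-1, t-x); the NB mean drops
    out because both groups share the null mean per sample.
    """
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    logp = (gammaln(x + r2) - gammaln(x + 1)
            + gammaln(t - x + r1) - gammaln(t - x + 1))
    logp -= logsumexp(logp)
    pmf = np.exp(logp)
    lower = float(pmf[: s2 + 1].sum())
    upper = float(pmf[s2:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def _binomial_pvalue(s2: int, t: int, frac2: float) -> float:
    if t == 0:
        return 1.0
    lower = float(stats.binom.cdf(s2, t, frac2))
    upper = float(stats.binom.sf(s2 - 1, t, frac2))
    return min(1.0, 2.0 * min(lower, upper))


@dataclass
class DERecord:
    feature_id: str
    log2fc: float
    p_value: float
    fdr: float = float("nan")
    is_de: bool = False
    direction: str = "none"


def exact_test(
    cm: CountMatrix,
    contrast: tuple[str, str],
    dispersion: float | str = "auto",
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Exact conditional NB test of group2 vs group1.

    log2fc is group2 over group1 on normalized means with a 0.5 pseudo-count.
    ``dispersion="auto"`` estimates a common dispersion by method of moments
    (requires replicates in at least one group); a numeric value is used as
    given, 0 meaning Poisson counts (binomial conditional test).
    """
    g1, g2 = contrast
    s1_cols = cm.samples_in(g1)
    s2_cols = cm.samples_in(g2)
    n1, n2 = len(s1_cols), len(s2_cols)
    if n1 + n2 < 2 or n1 == 0 or n2 == 0:
        raise ValueError("need at least one sample per group, two in total")

    raw = cm.counts[s1_cols + s2_cols].to_numpy(dtype=float)
    if not np.allclose(raw, np.round(raw)):
        warnings.warn("fractional counts rounded to integers")
    raw = np.round(raw)

    if normalize:
        lib = raw.sum(axis=0)
        factors = tmm_factors(cm.counts[s1_cols + s2_cols]).to_numpy()
        eff = lib * factors
        common = float(np.exp(np.mean(np.log(eff))))
        norm = raw * (common / eff)            # counts at a common library size
    else:
        norm = raw                             # caller asserts equal libraries

    if dispersion == "auto":
        if max(n1, n2) < 2:
            raise ValueError(
                "no replicates: supply a numeric dispersion "
                f"(convention: BCV {NO_REPLICATE_BCV} -> "
                f"{NO_REPLICATE_BCV ** 2:.2f})"
            )
        phi = estimate_common_dispersion(
            norm, [np.arange(n1), np.arange(n1, n1 + n2)]
        )
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("dispersion must be non-negative")

    pseudo = np.round(norm).astype(np.int64)
    s1 = pseudo[:, :n1].sum(axis=1)
    s2 = pseudo[:, n1:].sum(axis=1)
    m1 = norm[:, :n1].mean(axis=1)
    m2 = norm[:, n1:].mean(axis=1)
    log2fc = np.log2((m2 + 0.5) / (m1 + 0.5))

    pvals = np.ones(len(raw))
    if phi == 0.0:
        frac2 = n2 / (n1 + n2)
        for i in range(len(raw)):
            pvals[i] = _binomial_pvalue(int(s2[i]), int(s1[i] + s2[i]), frac2)
    else:
        r1, r2 = n1 / phi, n2 / phi
        for i in range(len(raw)):
            pvals[i] = _conditional_pvalue(int(s2[i]), int(s1[i] + s2[i]), r1, r2)

    fdr = bh_fdr(pvals)
    is_de = (fdr < alpha) & (np.abs(log2fc) >= lfc_min)
    direction = np.where(is_de, np.where(log2fc > 0, "up", "down"), "none")
    return pd.DataFrame(
        {
            "feature_id": cm.counts.index,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "is_de": is_de,
            "direction": direction,
            "mean_norm_g1": m1,
            "mean_norm_g2": m2,
            "dispersion": phi,
        }
    ).set_index("feature_id", drop=False)
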