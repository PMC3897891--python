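"""Diploid genotype calling from allelic read counts.

Two callers over the same quality-passing (ref, alt) read counts:

* ``hard_filter`` — fixed cut-offs on the alternative-allele read fraction f:
  f < 15% homozygous reference, 20–80% heterozygous, > 85% homozygous
  alternative, and the borderline bands 15–20% and 80–85% conservatively
  missing ('N').  No genotype quality is produced.

* ``likelihood`` — binomial genotype likelihoods L(g) = B(alt; depth, p_g)
  with p = ε, 1/2, 1−ε for the three diploid genotypes, combined with either
  a heterozygosity prior {1−θ−θ², θ, θ²} (the single-sample null: an
  arbitrary site is a priori almost certainly reference) or per-site
  Hardy–Weinberg priors {q², 2pq, p²} derived from a population allele
  frequency (emulating multi-sample calling at an ascertained SNP site).
  The call is the maximum-posterior genotype; GQ is the phred-scaled
  probability that the call is wrong, capped at 99.

Both callers apply the same depth band (default 10–1000) and, where a GQ
exists, a minimum GQ (default 10); failing entries are missing.

Band-edge arithmetic is exact: thresholds are rationals compared by integer
cross-multiplication, so e.g. 3 alt reads of 20 (f = 0.15 exactly) lands in
the borderline band, never on the wrong side of a float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .core import HET, HOMALT, HOMREF, MISSING, CallSet, SiteCounts

__all__ = [
    "CallerThresholds",
    "DEFAULT_THRESHOLDS",
    "hard_filter_call",
    "genotype_posteriors",
    "likelihood_call",
    "hwe_priors",
    "estimate_site_frequencies",
    "call_population",
]


def _as_fraction(x) -> Fraction:
    # str() round-trips a decimal literal exactly (0.15 -> Fraction(3, 20))
    return x if isinstance(x, Fraction) else Fraction(str(x))


@dataclass(frozen=True)
class CallerThresholds:
    """Depth/quality filters and the hard-filter allele-fraction bands."""

    min_depth: int = 10
    max_depth: int = 1000
    min_gq: int = 10
    homref_max: Fraction = Fraction(15, 100)   # f <  homref_max        -> homref
    het_low: Fraction = Fraction(20, 100)      # het_low <= f <= het_high -> het
    het_high: Fraction = Fraction(80, 100)
    homalt_min: Fraction = Fraction(85, 100)   # f >  homalt_min        -> homalt

    def __post_init__(self) -> None:
        for name in ("homref_max", "het_low", "het_high", "homalt_min"):
            object.__setattr__(self, name, _as_fraction(getattr(self, name)))
        if not (0 <= self.homref_max <= self.het_low <= self.het_high <= self.homalt_min <= 1):
            raise ValueError("hard-filter bands must be ordered within [0, 1]")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth > max_depth")


DEFAULT_THRESHOLDS = CallerThresholds()


def _frac_lt(alt, depth, frac: Fraction):
    """Elementwise alt/depth < frac, exactly."""
    return alt * frac.denominator < frac.numerator * depth


def _frac_le(alt, depth, frac: Fraction):
    return alt * frac.denominator <= frac.numerator * depth


def hard_filter_call(
    ref,
    alt,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Hard-filter genotype calls from (ref, alt) read counts.

    Accepts scalars or arrays; returns genotype codes (same shape).  Zero
    depth and out-of-band depths are missing, not errors.
    """
    ref = np.asarray(ref, dtype=np.int64)
    alt = np.asarray(alt, dtype=np.int64)
    depth = ref + alt
    gt = np.full(depth.shape, MISSING, dtype=np.int8)
    ok = (depth >= thresholds.min_depth) & (depth <= thresholds.max_depth)
    homref = _frac_lt(alt, depth, thresholds.homref_max)
    het = ~_frac_lt(alt, depth, thresholds.het_low) & _frac_le(alt, depth, thresholds.het_high)
    homalt = ~_frac_le(alt, depth, thresholds.homalt_min)
    gt[ok & homref] = HOMREF
    gt[ok & het] = HET
    gt[ok & homalt] = HOMALT
    # remaining passing-depth entries sit in the borderline bands -> missing
    return gt if gt.shape else np.int8(gt)


def hwe_priors(freq) -> np.ndarray:
    """Hardy–Weinberg genotype priors {q², 2pq, p²} for alt frequency p.

    Frequencies are clipped away from 0/1 so that an observed allele can
    never be assigned a strictly-zero prior.
    """
    p = np.clip(np.asarray(freq, dtype=float), 1e-4, 1 - 1e-4)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)


def estimate_site_frequencies(counts: SiteCounts) -> np.ndarray:
    """Pooled-read alt-allele frequency per site (the multi-sample caller's
    internal frequency estimate)."""
    alt = counts.alt.sum(axis=1).astype(float)
    depth = (counts.ref + counts.alt).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    return p


def genotype_posteriors(
    ref,
    alt,
    error_rate: float = 0.001,
    het_prior: float = 0.001,
    site_priors: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior probabilities of (homref, het, homalt); last axis length 3.

    ``site_priors`` (shape (..., 3), broadcastable against the counts)
    overrides the θ-derived priors when given.
    """
    if not 0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    if not 0 < het_prior < 1:
        raise ValueError("het_prior must lie in (0, 1)")
    ref = np.asarray(ref, dtype=np.int64)
    alt = np.asarray(alt, dtype=np.int64)
    depth = ref + alt
    p_alt = np.array([error_rate, 0.5, 1 - error_rate])
    loglik = stats.binom.logpmf(alt[..., None], depth[..., None], p_alt)
    if site_priors is None:
        priors = np.array([1 - het_prior - het_prior**2, het_prior, het_prior**2])
    else:
        priors = np.asarray(site_priors, dtype=float)
        if priors.shape[-1] != 3:
            raise ValueError("site_priors must have length 3 on the last axis")
    with np.errstate(divide="ignore"):
        logpost = loglik + np.log(priors)
    return np.exp(logpost - logsumexp(logpost, axis=-1, keepdims=True))


def likelihood_call(
    ref,
    alt,
    error_rate: float = 0.001,
    het_prior: float = 0.001,
    site_priors: np.ndarray | None = None,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-posterior genotype calls with phred-scaled GQ.

    Returns ``(gt, gq)``; entries failing the depth band or ``min_gq`` are
    missing (their GQ is reported as computed, 0 where no data).
    """
    post = genotype_posteriors(ref, alt, error_rate, het_prior, site_priors)
    ref = np.asarray(ref, dtype=np.int64)
    alt = np.asarray(alt, dtype=np.int64)
    depth = ref + alt
    call = np.argmax(post, axis=-1).astype(np.int8)
    p_call = np.take_along_axis(post, call[..., None].astype(int), axis=-1)[..., 0]
    with np.errstate(divide="ignore"):
        gq = -10.0 * np.log10(np.maximum(1.0 - p_call, 1e-300))
    gq = np.minimum(np.rint(gq), 99).astype(np.int16)
    gt = call.copy()
    bad = (
        (depth < thresholds.min_depth)
        | (depth > thresholds.max_depth)
        | (gq < thresholds.min_gq)
    )
    gt = np.where(bad, np.int8(MISSING), gt).astype(np.int8)
    if gt.shape == ():
        return np.int8(gt), np.int16(gq)
    return gt, gq


def call_population(
    counts: SiteCounts,
    caller: str = "hard_filter",
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    error_rate: float = 0.001,
    het_prior: float = 0.001,
    population_prior: bool = False,
    label: str | None = None,
    multiallelic_min_reads: int = 2,
) -> CallSet:
    """Apply a caller to every (site, individual) of a count table.

    ``population_prior=True`` switches the likelihood caller to per-site
    Hardy–Weinberg priors computed from the pooled-read allele frequency.
    Sites whose third-allele read total reaches ``multiallelic_min_reads``
    are flagged multi-allelic; sites where no called individual carries the
    alternative allele are flagged non-variant.  Both flags are consumed by
    the population filter downstream.
    """
    if caller == "hard_filter":
        gt = hard_filter_call(counts.ref, counts.alt, thresholds)
        gq = None
    elif caller == "likelihood":
        site_priors = None
        if population_prior:
            site_priors = hwe_priors(estimate_site_frequencies(counts))[:, None, :]
        gt, gq = likelihood_call(
            counts.ref, counts.alt, error_rate, het_prior, site_priors, thresholds
        )
    else:
        raise ValueError(f"unknown caller {caller!r}")
    sites = counts.sites[["chrom", "pos", "ref", "alt"]].copy()
    sites["multiallelic"] = counts.other.sum(axis=1) >= multiallelic_min_reads
    sites["variant"] = ((gt == HET) | (gt == HOMALT)).any(axis=1)
    return CallSet(
        label=label or caller,
        sites=sites,
        individuals=list(counts.individuals),
        gt=gt,
        dp=counts.ref + counts.alt,
        gq=gq,
    )
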