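"""Overlap, concordance and validation arithmetic between genotype call sets.

Site identity is chrom + pos + allele pair, irrespective of the genotypes
called, so "overlapping SNPs" means the same variant was discovered, not that
any individual agrees.  Genotype concordance is assessed per individual over
sites where both callers made a call; discordant pairs are classified into
het-versus-hom (one caller heterozygous, the other homozygous for either
allele) and homref-versus-homalt (opposite homozygotes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd

from .core import HET, HOMALT, HOMREF, MISSING, CallSet

__all__ = [
    "site_overlap",
    "ConcordanceReport",
    "genotype_concordance",
    "intersect_callsets",
    "score_validation",
    "outlier_overlap",
]


def _venn(sets: dict[str, set]) -> dict[frozenset, int]:
    union = set().union(*sets.values())
    partition: dict[frozenset, int] = {}
    for item in union:
        key = frozenset(label for label, s in sets.items() if item in s)
        partition[key] = partition.get(key, 0) + 1
    return partition


def site_overlap(callsets: list[CallSet], variant_only: bool = True) -> dict:
    """Venn partition of SNP sites across call sets.

    Returns region counts keyed by the frozenset of caller labels, plus
    per-caller private percentages (denominator: that caller's own total, as
    overlap figures conventionally report them).  Sites sharing chrom+pos but
    with different allele pairs are distinct (and an error, since one pileup
    cannot yield both).
    """
    if len(callsets) < 2:
        raise ValueError("need at least two call sets")
    labels = [cs.label for cs in callsets]
    if len(set(labels)) != len(labels):
        raise ValueError("call sets must have distinct labels")
    sets = {}
    for cs in callsets:
        sites = cs.variant_sites() if variant_only else cs.sites
        sets[cs.label] = set(zip(sites["chrom"], sites["pos"], sites["ref"], sites["alt"]))
    by_locus: dict[tuple, tuple] = {}
    for label, s in sets.items():
        for chrom, pos, ref, alt in s:
            prev = by_locus.setdefault((chrom, pos), (ref, alt))
            if prev != (ref, alt):
                raise ValueError(
                    f"conflicting allele pairs at {chrom}:{pos}: {prev} vs {(ref, alt)}"
                )
    partition = _venn(sets)
    private_pct = {}
    for label in labels:
        n_total = len(sets[label])
        n_private = partition.get(frozenset([label]), 0)
        private_pct[label] = 100.0 * n_private / n_total if n_total else np.nan
    return {
        "counts": partition,
        "totals": {label: len(s) for label, s in sets.items()},
        "private_pct": private_pct,
        "n_union": sum(partition.values()),
        "n_all": partition.get(frozenset(labels), 0),
    }


@dataclass
class ConcordanceReport:
    """Per-individual genotype concordance between two callers, with the
    discordance classification and the het-direction bias."""

    label_a: str
    label_b: str
    per_individual: pd.DataFrame  # individual, n_compared, n_identical, pct_identical
    classification: dict[str, int] = field(default_factory=dict)
    # classification keys: het_a_hom_b, hom_a_het_b, homref_homalt, other

    @property
    def median_pct(self) -> float:
        return float(self.per_individual["pct_identical"].median())

    @property
    def n_discordant(self) -> int:
        return sum(self.classification.values())

    @property
    def het_vs_hom_fraction(self) -> float:
        """Fraction of discordant pairs that are het-versus-hom type."""
        n = self.n_discordant
        if n == 0:
            return np.nan
        return (self.classification["het_a_hom_b"] + self.classification["hom_a_het_b"]) / n

    def het_bias(self, which: str = "a") -> float:
        """Of het-vs-hom discordances, the fraction where the given caller
        is the heterozygous one."""
        h = self.classification["het_a_hom_b"] + self.classification["hom_a_het_b"]
        if h == 0:
            return np.nan
        frac_a = self.classification["het_a_hom_b"] / h
        return frac_a if which == "a" else 1.0 - frac_a


def _aligned_genotypes(a: CallSet, b: CallSet):
    shared_inds = [i for i in a.individuals if i in set(b.individuals)]
    if not shared_inds:
        raise ValueError("no shared individuals between call sets")
    keys_a, keys_b = a.site_keys, b.site_keys
    shared_sites = keys_a.intersection(keys_b)
    ia = keys_a.get_indexer(shared_sites)
    ib = keys_b.get_indexer(shared_sites)
    ca = [a.individuals.index(i) for i in shared_inds]
    cb = [b.individuals.index(i) for i in shared_inds]
    return shared_inds, shared_sites, a.gt[np.ix_(ia, ca)], b.gt[np.ix_(ib, cb)]


def genotype_concordance(a: CallSet, b: CallSet, variant_only: bool = False) -> ConcordanceReport:
    """Compare genotypes per individual over sites present in both call sets.

    Entries missing in either call set are excluded from ``n_compared``.
    ``variant_only`` restricts to sites flagged variant in both sets.
    """
    aa, bb = a, b
    if variant_only:
        aa = a.subset_sites(a.sites["variant"].to_numpy())
        bb = b.subset_sites(b.sites["variant"].to_numpy())
    inds, _, gta, gtb = _aligned_genotypes(aa, bb)
    both = (gta != MISSING) & (gtb != MISSING)
    same = both & (gta == gtb)
    n_compared = both.sum(axis=0)
    n_identical = same.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pct = np.where(n_compared > 0, 100.0 * n_identical / np.maximum(n_compared, 1), np.nan)
    per_ind = pd.DataFrame(
        {
            "individual": inds,
            "n_compared": n_compared,
            "n_identical": n_identical,
            "pct_identical": pct,
        }
    )
    disc = both & (gta != gtb)
    het_a = disc & (gta == HET)
    het_b = disc & (gtb == HET)
    classification = {
        "het_a_hom_b": int((het_a & ~het_b).sum()),
        "hom_a_het_b": int((het_b & ~het_a).sum()),
        "homref_homalt": int((disc & ~het_a & ~het_b).sum()),
        "other": 0,
    }
    return ConcordanceReport(a.label, b.label, per_ind, classification)


def intersect_callsets(a: CallSet, b: CallSet, label: str | None = None) -> CallSet:
    """Keep a genotype only where both callers made the same non-missing
    call; all other entries are missing.  Applied before population-based
    filtering, which is then re-run on the intersect set downstream."""
    inds, shared_sites, gta, gtb = _aligned_genotypes(a, b)
    agree = (gta != MISSING) & (gta == gtb)
    gt = np.where(agree, gta, MISSING).astype(np.int8)
    sites = pd.DataFrame(list(shared_sites), columns=["chrom", "pos", "ref", "alt"])
    ia = a.site_keys.get_indexer(shared_sites)
    ib = b.site_keys.get_indexer(shared_sites)
    multi = (
        a.sites["multiallelic"].to_numpy()[ia] | b.sites["multiallelic"].to_numpy()[ib]
    )
    sites["multiallelic"] = multi
    dp = None
    if a.dp is not None and b.dp is not None:
        ca = [a.individuals.index(i) for i in inds]
        cb = [b.individuals.index(i) for i in inds]
        dp = np.minimum(a.dp[np.ix_(ia, ca)], b.dp[np.ix_(ib, cb)])
    return CallSet(
        label=label or f"{a.label}-{b.label}_intersect",
        sites=sites,
        individuals=inds,
        gt=gt,
        dp=dp,
    )


def _pct(n: int, total: int) -> float:
    """Percentage rounded half-up to two decimals, computed exactly."""
    if total == 0:
        return float("nan")
    return float(
        (Decimal(n) * 100 / Decimal(total)).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


def score_validation(
    discordant: pd.DataFrame,
    concordant: tuple[int, int, int] | None = None,
) -> dict:
    """Score a genotype-validation contingency table.

    ``discordant`` rows are validation categories with columns ``category,
    n_snps, n_genotypes, n_true_a, n_true_b`` (per discordant row,
    n_true_a + n_true_b must equal n_genotypes).  ``concordant`` is
    (n_snps, n_genotypes, n_correct) for the identically-called genotypes.
    Returns the per-category and total percentage splits and the concordant
    accuracy, all rounded half-up to two decimals.
    """
    req = {"category", "n_snps", "n_genotypes", "n_true_a", "n_true_b"}
    if not req <= set(discordant.columns):
        raise ValueError(f"validation table needs columns {sorted(req)}")
    bad = discordant["n_true_a"] + discordant["n_true_b"] != discordant["n_genotypes"]
    if bad.any():
        raise ValueError("n_true_a + n_true_b != n_genotypes in some rows")
    table = discordant.copy()
    table["pct_true_a"] = [
        _pct(na, ng) for na, ng in zip(table["n_true_a"], table["n_genotypes"])
    ]
    table["pct_true_b"] = [
        _pct(nb, ng) for nb, ng in zip(table["n_true_b"], table["n_genotypes"])
    ]
    totals = {
        "n_snps": int(table["n_snps"].sum()),
        "n_genotypes": int(table["n_genotypes"].sum()),
        "n_true_a": int(table["n_true_a"].sum()),
        "n_true_b": int(table["n_true_b"].sum()),
    }
    totals["pct_true_a"] = _pct(totals["n_true_a"], totals["n_genotypes"])
    totals["pct_true_b"] = _pct(totals["n_true_b"], totals["n_genotypes"])
    out = {"table": table, "totals": totals}
    if concordant is not None:
        n_snps, n_genotypes, n_correct = concordant
        out["concordant"] = {
            "n_snps": n_snps,
            "n_genotypes": n_genotypes,
            "n_correct": n_correct,
            "accuracy_pct": _pct(n_correct, n_genotypes),
        }
    return out


def outlier_overlap(scans: list) -> dict:
    """Venn partition of outlier windows across window scans (identical
    window grids required); reports the percentage of outlier windows shared
    by all scans, relative to the union of outliers."""
    if len(scans) < 2:
        raise ValueError("need at least two scans")
    grids = {(s.window, s.step) for s in scans}
    if len(grids) != 1:
        raise ValueError(f"window grids differ: {grids}")
    sets = {}
    for s in scans:
        if s.label in sets:
            raise ValueError("scans must have distinct labels")
        out = s.windows[s.windows["outlier"]]
        sets[s.label] = set(zip(out["chrom"], out["start"]))
    partition = _venn(sets)
    union = sum(partition.values())
    full = partition.get(frozenset(sets), 0)
    return {
        "counts": partition,
        "totals": {label: len(s) for label, s in sets.items()},
        "n_union": union,
        "n_all": full,
        "pct_identical": 100.0 * full / union if union else np.nan,
    }
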