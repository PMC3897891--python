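"""Shared in-memory containers for the genotyping pipeline.

Genotypes are encoded as small integers: 0 = homozygous reference, 1 =
heterozygous, 2 = homozygous alternative, -1 = missing (no passing call).
Sites are rows of a DataFrame with columns ``chrom, pos, ref, alt`` (1-based
positions, as in VCF); matrices are sites x individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOMREF, HET, HOMALT, MISSING = 0, 1, 2, -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


def site_index(sites: pd.DataFrame) -> pd.Index:
    """Site identity: chrom + pos + allele pair (genotype-agnostic)."""
    return pd.Index(
        list(zip(sites["chrom"], sites["pos"], sites["ref"], sites["alt"]))
    )


def _check_sites(sites: pd.DataFrame) -> None:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table lacks columns {missing}")
    if site_index(sites).has_duplicates:
        raise ValueError("duplicate site definitions (chrom, pos, ref, alt)")


@dataclass
class SiteCounts:
    """Quality-passing allelic read counts per (site, individual).

    ``ref`` / ``alt`` are integer matrices of reads supporting the reference
    and alternative allele; ``other`` counts reads supporting any third
    allele (used to flag multi-allelic sites downstream).
    """

    sites: pd.DataFrame
    individuals: list[str]
    ref: np.ndarray
    alt: np.ndarray
    other: np.ndarray | None = None

    def __post_init__(self) -> None:
        _check_sites(self.sites)
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual identifiers")
        shape = (len(self.sites), len(self.individuals))
        for name in ("ref", "alt"):
            mat = getattr(self, name)
            if mat.shape != shape:
                raise ValueError(f"{name} counts have shape {mat.shape}, expected {shape}")
            if (mat < 0).any():
                raise ValueError(f"negative {name} counts")
        if self.other is None:
            self.other = np.zeros(shape, dtype=int)

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt + self.other


@dataclass
class CallSet:
    """A caller-labelled matrix of diploid genotype calls.

    ``gt`` holds genotype codes; ``dp`` read depths; ``gq`` phred-scaled
    genotype qualities (None for callers that do not produce one, e.g. the
    hard-filter caller).  The per-site ``variant`` column marks sites where at
    least one called individual carries the alternative allele; non-variant
    sites are retained for genotype lookup but excluded from SNP reports.
    ``multiallelic`` flags sites with more than two observed alleles.
    """

    label: str
    sites: pd.DataFrame
    individuals: list[str]
    gt: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        _check_sites(self.sites)
        shape = (len(self.sites), len(self.individuals))
        if self.gt.shape != shape:
            raise ValueError(f"genotype matrix has shape {self.gt.shape}, expected {shape}")
        self.sites = self.sites.reset_index(drop=True)
        if "variant" not in self.sites.columns:
            self.sites["variant"] = ((self.gt == HET) | (self.gt == HOMALT)).any(axis=1)
        if "multiallelic" not in self.sites.columns:
            self.sites["multiallelic"] = False
        order = np.lexsort((self.sites["pos"].values, self.sites["chrom"].values))
        if not np.array_equal(order, np.arange(len(order))):
            self.sites = self.sites.iloc[order].reset_index(drop=True)
            self.gt = self.gt[order]
            if self.dp is not None:
                self.dp = self.dp[order]
            if self.gq is not None:
                self.gq = self.gq[order]

    @property
    def site_keys(self) -> pd.Index:
        return site_index(self.sites)

    def variant_sites(self) -> pd.DataFrame:
        return self.sites[self.sites["variant"]]

    def subset_sites(self, mask: np.ndarray) -> "CallSet":
        return CallSet(
            label=self.label,
            sites=self.sites.loc[mask].reset_index(drop=True).copy(),
            individuals=list(self.individuals),
            gt=self.gt[np.asarray(mask)],
            dp=None if self.dp is None else self.dp[np.asarray(mask)],
            gq=None if self.gq is None else self.gq[np.asarray(mask)],
        )


@dataclass
class TruthSet:
    """Ground-truth genotypes and per-population allele frequencies for a
    simulated cohort."""

    sites: pd.DataFrame
    individuals: list[str]
    gt: np.ndarray
    populations: pd.Series  # individual -> population label
    freqs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_sites(self.sites)
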