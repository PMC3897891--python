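"""Population-genomic summary statistics and the differentiation scan.

Per-site statistics: observed site heterozygosity (individuals carrying both
alleles / called individuals), minor-allele frequency, singleton and
private-SNP flags.  Between two populations the allele-frequency
differential of a biallelic site is

    D = (|p1 - p2| + |q1 - q2|) / 2,   q = 1 - p,

which algebraically equals |p1 - p2|; it ranges from 0 (identical
frequencies) to 1 (alternatively fixed).  The selection scan slides 100 kb
windows in 25 kb steps along each chromosome and flags windows whose mean D
exceeds 0.95 with at least 2 SNPs as candidate selective-sweep outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .filtering import SNPTable

__all__ = [
    "site_heterozygosity",
    "allele_freq_differential",
    "WindowScan",
    "sliding_window_scan",
    "singleton_and_private",
    "maf_spectrum",
]


def site_heterozygosity(snps: SNPTable, pop: str) -> np.ndarray:
    """Observed heterozygosity per site: het individuals / called individuals."""
    het = snps.table[f"{pop}:het"].to_numpy(dtype=float)
    called = snps.table[f"{pop}:called"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / np.maximum(called, 1), np.nan)


def allele_freq_differential(p1, p2):
    """D = (|p1 - p2| + |q1 - q2|)/2 for biallelic frequencies in [0, 1]."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if ((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    d = (np.abs(p1 - p2) + np.abs((1 - p1) - (1 - p2))) / 2
    return d if d.shape else float(d)


@dataclass
class WindowScan:
    """Sliding-window mean allele-frequency differential with outlier flags."""

    label: str
    windows: pd.DataFrame  # chrom, start, end (1-based inclusive), n_snps, mean_d, outlier
    window: int
    step: int
    threshold: float
    min_snps: int

    def outliers(self) -> pd.DataFrame:
        return self.windows[self.windows["outlier"]]


def sliding_window_scan(
    snps: SNPTable,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    step: int = 25_000,
    threshold: float = 0.95,
    min_snps: int = 2,
    exclude_pattern: str | None = "_random",
    label: str | None = None,
) -> WindowScan:
    """Scan chromosomes for windows of extreme mean population differentiation.

    Windows are anchored at position 1 of every chromosome and advance by
    ``step``; trailing partial windows are included.  A window's mean D
    averages the per-SNP differentials of all SNPs whose position falls in
    [start, end] (equal weight per SNP); windows without SNPs have missing
    mean D.  Outlier: n_snps >= min_snps and mean D > threshold.
    Chromosome names matching ``exclude_pattern`` (unplaced scaffolds) are
    skipped.
    """
    if len(snps.populations) != 2:
        raise ValueError("the differentiation scan requires exactly two populations")
    pop1, pop2 = snps.populations
    d = allele_freq_differential(snps.freq(pop1), snps.freq(pop2))
    d = np.atleast_1d(d)
    rows = []
    for chrom, length in chrom_lengths.items():
        if exclude_pattern and exclude_pattern in chrom:
            continue
        in_chrom = (snps.table["chrom"] == chrom).to_numpy()
        pos = snps.table.loc[in_chrom, "pos"].to_numpy()
        dc = d[in_chrom]
        order = np.argsort(pos)
        pos, dc = pos[order], dc[order]
        cum = np.concatenate([[0.0], np.cumsum(dc)])
        starts = np.arange(1, length + 1, step)
        ends = np.minimum(starts + window - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean_d = np.where(n > 0, (cum[hi] - cum[lo]) / np.maximum(n, 1), np.nan)
        for s, e, k, m in zip(starts, ends, n, mean_d):
            rows.append((chrom, int(s), int(e), int(k), m))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "mean_d"])
    windows["outlier"] = (windows["n_snps"] >= min_snps) & (windows["mean_d"] > threshold)
    return WindowScan(
        label=label or snps.source or "scan",
        windows=windows,
        window=window,
        step=step,
        threshold=threshold,
        min_snps=min_snps,
    )


def singleton_and_private(snps: SNPTable, scope: str = "overall") -> pd.DataFrame:
    """Singleton and private-SNP flags with summary percentages.

    A singleton carries exactly one alternative-allele copy among called
    genotypes in the scope (one population, or the entire dataset).  A SNP is
    private to a population when it is polymorphic there and monomorphic in
    the other.  Returns the per-site flag table; percentages are relative to
    the scope's polymorphic-site count and stored in ``DataFrame.attrs``.
    """
    t = snps.table
    out = t[["chrom", "pos", "ref", "alt"]].copy()
    pops = snps.populations
    copies = {p: t[f"{p}:het"] + 2 * t[f"{p}:homalt"] for p in pops}
    called = {p: t[f"{p}:called"] for p in pops}
    poly = {
        p: (copies[p] > 0) & (copies[p] < 2 * called[p]) for p in pops
    }
    for p in pops:
        others = [q for q in pops if q != p]
        out[f"private:{p}"] = poly[p] & ~pd.concat([poly[q] for q in others], axis=1).any(axis=1)
    summary: dict[str, float] = {}
    if scope == "overall":
        total_copies = sum(copies.values())
        out["singleton"] = total_copies == 1
        n_sites = len(t)
        summary["pct_singletons"] = 100.0 * out["singleton"].mean() if n_sites else np.nan
    elif scope == "population":
        for p in pops:
            out[f"singleton:{p}"] = copies[p] == 1
            n_poly = int(poly[p].sum())
            summary[f"pct_singletons:{p}"] = (
                100.0 * int((out[f"singleton:{p}"] & poly[p]).sum()) / n_poly
                if n_poly
                else np.nan
            )
    else:
        raise ValueError("scope must be 'overall' or 'population'")
    for p in pops:
        summary[f"n_private:{p}"] = int(out[f"private:{p}"].sum())
        summary[f"n_polymorphic:{p}"] = int(poly[p].sum())
    out.attrs["summary"] = summary
    return out


def maf_spectrum(
    snps: SNPTable,
    pop: str,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Minor-allele frequencies min(p, 1-p) per site, with an optional
    Gaussian KDE (Silverman bandwidth) evaluated on ``grid`` for plotting."""
    p = snps.freq(pop)
    maf = np.minimum(p, 1 - p)
    density = None
    if grid is not None:
        kde = sps.gaussian_kde(maf, bw_method="silverman")
        density = pd.DataFrame({"maf": grid, "density": kde(grid)})
    return maf, density
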