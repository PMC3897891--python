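"""Population-based SNP filtering and sequencing-target efficiency.

The population filter keeps biallelic variant sites genotyped in at least a
minimum number of individuals in *every* population (default 8, i.e. >= 16
chromosomes per population) so that allele frequencies can be estimated
directly from called genotypes.  Target efficiency measures what fraction of
an individual's high-quality sequenced bases (bp_hiqual: mapping quality
>= 30, base quality >= 30, depth >= 10) fall inside the in-silico-predicted
restriction fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HET, HOMALT, HOMREF, MISSING, CallSet

__all__ = ["SNPTable", "population_filter", "target_efficiency", "hiqual_from_depth_table"]


@dataclass
class SNPTable:
    """Population-filtered biallelic SNPs with per-population genotype
    tallies and alt-allele frequencies.

    ``table`` has the site columns plus, per population P, columns
    ``P:called``, ``P:het``, ``P:homalt`` and ``P:p`` (alt-allele frequency
    from called genotypes: allele copies / 2x called individuals).
    """

    table: pd.DataFrame
    populations: list[str]
    min_individuals: int
    source: str = ""

    def __len__(self) -> int:
        return len(self.table)

    def freq(self, pop: str) -> np.ndarray:
        return self.table[f"{pop}:p"].to_numpy()


def _pop_columns(callset: CallSet, populations: pd.Series) -> dict[str, np.ndarray]:
    unknown = [i for i in callset.individuals if i not in populations.index]
    if unknown:
        raise ValueError(f"individuals without population assignment: {unknown[:5]}")
    labels = populations.loc[callset.individuals].to_numpy()
    return {pop: np.flatnonzero(labels == pop) for pop in pd.unique(labels)}


def population_filter(
    callset: CallSet,
    populations: pd.Series,
    min_individuals: int = 8,
) -> SNPTable:
    """Apply the population-based filter to a call set.

    Drops multi-allelic and non-variant sites, then sites with fewer than
    ``min_individuals`` non-missing genotypes in any population, and tallies
    per-population genotype counts and allele frequencies.
    """
    cols = _pop_columns(callset, populations)
    pops = sorted(cols)
    keep = (callset.sites["variant"] & ~callset.sites["multiallelic"]).to_numpy()
    stats: dict[str, np.ndarray] = {}
    for pop, idx in cols.items():
        gt = callset.gt[:, idx]
        called = (gt != MISSING).sum(axis=1)
        het = (gt == HET).sum(axis=1)
        homalt = (gt == HOMALT).sum(axis=1)
        keep &= called >= min_individuals
        stats[f"{pop}:called"] = called
        stats[f"{pop}:het"] = het
        stats[f"{pop}:homalt"] = homalt
    table = callset.sites[["chrom", "pos", "ref", "alt"]].copy()
    for key, val in stats.items():
        table[key] = val
    table = table.loc[keep].reset_index(drop=True)
    for pop in pops:
        with np.errstate(invalid="ignore"):
            table[f"{pop}:p"] = (
                table[f"{pop}:het"] + 2 * table[f"{pop}:homalt"]
            ) / (2 * table[f"{pop}:called"])
    return SNPTable(
        table=table,
        populations=pops,
        min_individuals=min_individuals,
        source=callset.label,
    )


def _interval_overlap_bp(query: pd.DataFrame, targets: pd.DataFrame) -> int:
    """Total bp of ``query`` intervals covered by ``targets`` (both BED-style
    0-based half-open; targets non-overlapping)."""
    total = 0
    for chrom, tgt in targets.groupby("chrom"):
        q = query[query["chrom"] == chrom]
        if q.empty:
            continue
        starts = tgt["start"].to_numpy()
        ends = tgt["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        for qs, qe in zip(q["start"].to_numpy(), q["end"].to_numpy()):
            i = np.searchsorted(ends, qs, side="right")
            while i < len(starts) and starts[i] < qe:
                total += min(qe, ends[i]) - max(qs, starts[i])
                i += 1
    return int(total)


def target_efficiency(
    hiqual: dict[str, pd.DataFrame],
    targets: pd.DataFrame,
    populations: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-individual percentage of bp_hiqual positions inside the predicted
    target regions; the per-population median summarizes protocol efficiency.

    ``hiqual`` maps individual -> BED-style interval DataFrame of that
    individual's high-quality positions.  Individuals with zero hiqual bases
    get a missing (NaN) efficiency.
    """
    rows = []
    for ind, intervals in hiqual.items():
        n_bp = int((intervals["end"] - intervals["start"]).sum())
        if n_bp == 0:
            rows.append({"individual": ind, "bp_hiqual": 0, "on_target_bp": 0,
                         "efficiency_pct": np.nan})
            continue
        on_target = _interval_overlap_bp(intervals, targets)
        rows.append({
            "individual": ind,
            "bp_hiqual": n_bp,
            "on_target_bp": on_target,
            "efficiency_pct": 100.0 * on_target / n_bp,
        })
    out = pd.DataFrame(rows)
    if populations is not None:
        out["population"] = populations.reindex(out["individual"]).to_numpy()
    return out


def hiqual_from_depth_table(
    depth_table: pd.DataFrame,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Convert a samtools-depth-style table (chrom, pos [1-based], depth) of
    quality-passing pileup depths into BED intervals of bp_hiqual positions."""
    ok = depth_table[depth_table["depth"] >= min_depth]
    rows = []
    for chrom, grp in ok.groupby("chrom"):
        pos = np.sort(grp["pos"].unique())
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [pos.size - 1]])
        for s, e in zip(starts, ends):
            rows.append({"chrom": chrom, "start": int(pos[s]) - 1, "end": int(pos[e])})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
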