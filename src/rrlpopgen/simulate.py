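"""Synthetic two-population diploid cohorts with known truth.

The generator emulates the statistical structure a reduced-representation
genotyping-by-sequencing experiment assumes: a genome whose restriction-site
placement is controlled (so the digest's output is known a priori), SNP sites
that live only inside the size-selected target fragments, Hardy–Weinberg
genotypes drawn from per-population allele frequencies, and quality-passing
read counts with Poisson coverage and a symmetric per-read allele-flip error.

Defaults mirror the study conditions the pipeline is exercised under: two
populations of 15 (WA) and 16 (SK) unrelated individuals, ~41x mean coverage,
and a post-quality-filter error rate of 1e-3 (phred Q30 reads).  Everything
is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import HET, HOMALT, HOMREF, SiteCounts, TruthSet
from .digest import ENZYMES, RestrictionEnzyme, digest, find_sites, select_fragments

__all__ = [
    "PopulationModel",
    "ReadCountModel",
    "simulate_genome",
    "simulate_genotypes",
    "simulate_counts",
    "plant_sweep",
    "Cohort",
    "build_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class PopulationModel:
    """Per-population sample sizes and site-wise alt-allele frequencies."""

    sites: pd.DataFrame                    # chrom, pos, ref, alt
    n_individuals: dict[str, int]
    freqs: dict[str, np.ndarray]           # population -> per-site alt frequency
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.n_individuals:
            raise ValueError("at least one population is required")
        for pop, f in self.freqs.items():
            f = np.asarray(f, dtype=float)
            if f.shape != (len(self.sites),):
                raise ValueError(f"{pop}: frequency vector length != number of sites")
            if ((f < 0) | (f > 1)).any():
                raise ValueError(f"{pop}: frequencies outside [0, 1]")
            self.freqs[pop] = f

    @property
    def individuals(self) -> list[str]:
        return [
            f"{pop}{i + 1:02d}"
            for pop in self.n_individuals
            for i in range(self.n_individuals[pop])
        ]

    @property
    def populations(self) -> pd.Series:
        return pd.Series(
            {ind: ind[:-2] for ind in self.individuals}, name="population"
        )


@dataclass(frozen=True)
class ReadCountModel:
    """Poisson coverage with a symmetric per-read allele-flip error.

    Counts are quality-passing by construction: base/mapping-quality
    filtering is modelled as already applied, matching what hard-filter and
    likelihood callers actually consume.
    """

    mean_depth: float = 41.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _erase_sites(seq: np.ndarray, site: str, rng: np.random.Generator,
                 protected: set[int] | None = None) -> None:
    """Mutate accidental occurrences of ``site`` away, leaving any occurrence
    whose start is in ``protected`` untouched."""
    protected = protected or set()
    m = len(site)
    for _ in range(50):
        text = seq.tobytes().decode()
        hits = [p for p in find_sites(text, site) if p not in protected]
        if not hits:
            return
        for p in hits:
            # flip one base in the middle of the occurrence; avoid touching
            # protected occurrences that might overlap
            j = p + m // 2
            old = seq[j]
            choices = _BASES[_BASES != old]
            seq[j] = rng.choice(choices)
    raise RuntimeError("could not erase accidental recognition sites")


def simulate_genome(
    n_chrom: int,
    chrom_len: int,
    site_density: float,
    seed: int,
    enzyme: RestrictionEnzyme = ENZYMES["HaeIII"],
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Random A/C/G/T genome with recognition sites planted at a known
    density; returns (genome, planted site starts per chromosome).

    ``site_density`` is sites per bp; a digest of the result yields exactly
    ``n_planted + 1`` fragments per chromosome.
    """
    if n_chrom < 1 or chrom_len < len(enzyme.site):
        raise ValueError("genome dimensions must be positive")
    n_sites = int(round(site_density * chrom_len))
    spacing = len(enzyme.site) + 2
    if n_sites * spacing > chrom_len - spacing:
        raise ValueError("site density so high that planted sites would overlap")
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    planted: dict[str, list[int]] = {}
    site_arr = np.frombuffer(enzyme.site.encode(), dtype="S1")
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        seq = _random_sequence(rng, chrom_len)
        if n_sites:
            # draw non-overlapping starts via the gap construction
            slots = rng.choice(chrom_len - (n_sites + 1) * spacing, size=n_sites, replace=False)
            slots.sort()
            starts = slots + spacing * np.arange(1, n_sites + 1)
            for s in starts:
                seq[s : s + len(site_arr)] = site_arr
            planted[name] = [int(s) for s in starts]
        else:
            planted[name] = []
        _erase_sites(seq, enzyme.site, rng, protected=set(planted[name]))
        genome[name] = seq.tobytes().decode()
    return genome, planted


def simulate_genotypes(model: PopulationModel, seed: int) -> TruthSet:
    """Hardy–Weinberg truth genotypes: two independent Bernoulli(p) allele
    copies per individual."""
    rng = np.random.default_rng(seed)
    n_sites = len(model.sites)
    columns = []
    for pop, n in model.n_individuals.items():
        p = model.freqs[pop][:, None, None]
        copies = rng.random((n_sites, n, 2)) < p
        columns.append(copies.sum(axis=2))
    gt = np.concatenate(columns, axis=1).astype(np.int8)
    return TruthSet(
        sites=model.sites.copy(),
        individuals=model.individuals,
        gt=gt,
        populations=model.populations,
        freqs={pop: f.copy() for pop, f in model.freqs.items()},
    )


def simulate_counts(truth: TruthSet, model: ReadCountModel) -> SiteCounts:
    """Read counts: depth ~ Poisson(mean_depth) per (site, individual); each
    read reports the allele of a uniformly chosen chromosome copy, flipped
    with probability ε — so the alt-read probability is ε, 1/2, 1−ε for the
    three genotypes."""
    rng = np.random.default_rng(model.seed)
    depth = rng.poisson(model.mean_depth, size=truth.gt.shape)
    p_alt = np.array([model.error_rate, 0.5, 1 - model.error_rate])[truth.gt]
    alt = rng.binomial(depth, p_alt)
    return SiteCounts(
        sites=truth.sites.copy(),
        individuals=list(truth.individuals),
        ref=depth - alt,
        alt=alt,
    )


def plant_sweep(
    model: PopulationModel,
    region: tuple[str, int, int],
    differential: float,
) -> PopulationModel:
    """Force |p_A − p_B| = ``differential`` (symmetric around 1/2) at every
    SNP inside ``region`` (chrom, start, end; 1-based inclusive), emulating a
    completed selective sweep in one population.  Requires exactly two
    populations; sites outside the region are untouched."""
    if not 0 <= differential <= 1:
        raise ValueError("differential must lie in [0, 1]")
    if len(model.freqs) != 2:
        raise ValueError("plant_sweep requires exactly two populations")
    chrom, start, end = region
    if model.chrom_lengths:
        if chrom not in model.chrom_lengths:
            raise ValueError(f"region chromosome {chrom!r} not in the genome")
        if start < 1 or end > model.chrom_lengths[chrom] or start > end:
            raise ValueError("region outside genome bounds")
    inside = (
        (model.sites["chrom"] == chrom)
        & (model.sites["pos"] >= start)
        & (model.sites["pos"] <= end)
    ).values
    pop_hi, pop_lo = sorted(model.freqs)
    freqs = {pop: f.copy() for pop, f in model.freqs.items()}
    freqs[pop_hi][inside] = 0.5 + differential / 2
    freqs[pop_lo][inside] = 0.5 - differential / 2
    return replace(model, freqs=freqs)


@dataclass
class Cohort:
    """A complete simulated dataset: genome, targets, truth, and counts."""

    genome: dict[str, str]
    targets: pd.DataFrame          # selected fragments (chrom, start, end, ...)
    model: PopulationModel
    truth: TruthSet
    counts: SiteCounts
    enzyme: RestrictionEnzyme


def build_cohort(
    n_individuals: dict[str, int] | None = None,
    n_snps: int = 500,
    n_chrom: int = 1,
    chrom_len: int = 2_000_000,
    mean_depth: float = 41.0,
    error_rate: float = 0.001,
    seed: int = 0,
    enzyme: RestrictionEnzyme = ENZYMES["HaeIII"],
    size_window: tuple[int, int] = (104, 123),
    freqs: dict[str, np.ndarray] | None = None,
    snp_positions: pd.DataFrame | None = None,
) -> Cohort:
    """End-to-end cohort: each SNP is placed inside its own in-window
    restriction fragment (RRL sequencing yields no data elsewhere), so the
    digest's size selection recovers exactly the fragments carrying SNPs.

    ``snp_positions`` (chrom, pos) fixes SNP coordinates explicitly (e.g. to
    plant a sweep region away from neutral sites); otherwise positions are
    drawn uniformly with spacing that keeps fragments disjoint.  ``freqs``
    defaults to independent Uniform(0.05, 0.95) draws per population.
    """
    if n_individuals is None:
        n_individuals = {"WA": 15, "SK": 16}
    seeds = np.random.SeedSequence(seed).generate_state(4)
    rng = np.random.default_rng(seeds[0])
    frag_len_lo, frag_len_hi = size_window
    # Minimum spacing between SNPs.  Cut positions flank each SNP at at most
    # ceil(hi/2) bp, so a gap of 2*hi + 2 guarantees every spacer fragment
    # (between two SNP fragments, or to a chromosome end) is longer than the
    # selection window and can never be co-selected by accident.
    unit = 2 * frag_len_hi + 2

    # SNP coordinates
    if snp_positions is None:
        per_chrom = np.array_split(np.arange(n_snps), n_chrom)
        rows = []
        for c, idx in enumerate(per_chrom):
            k = len(idx)
            slots = rng.choice(chrom_len - (k + 2) * unit, size=k, replace=False)
            slots.sort()
            pos = slots + unit * np.arange(1, k + 1)
            rows.append(pd.DataFrame({"chrom": f"chr{c + 1}", "pos": pos + 1}))
        snp_positions = pd.concat(rows, ignore_index=True)
    else:
        snp_positions = snp_positions.sort_values(["chrom", "pos"]).reset_index(drop=True)
        gaps = snp_positions.groupby("chrom")["pos"].diff().dropna()
        if (gaps < unit).any():
            raise ValueError(
                f"explicit SNP positions closer than {unit} bp could merge or "
                "co-select neighbouring fragments"
            )
        if (snp_positions["pos"] < unit).any() or (snp_positions["pos"] > chrom_len - unit).any():
            raise ValueError(f"SNP positions must lie within [{unit}, chrom_len - {unit}]")
    n_snps = len(snp_positions)

    # genome with a fragment of in-window length around every SNP
    chrom_names = sorted(snp_positions["chrom"].unique())
    genome: dict[str, str] = {}
    site_arr = np.frombuffer(enzyme.site.encode(), dtype="S1")
    m = len(enzyme.site)
    for name in chrom_names:
        seq = _random_sequence(rng, chrom_len)
        protected: set[int] = set()
        for pos in snp_positions.loc[snp_positions["chrom"] == name, "pos"]:
            frag_len = int(rng.integers(frag_len_lo, frag_len_hi + 1))
            # cut positions flanking the SNP; pos is 1-based, fragment is
            # [cut_left, cut_left + frag_len) in 0-based coordinates
            cut_left = int(pos) - 1 - frag_len // 2
            left_start = cut_left - enzyme.cut_offset
            right_start = cut_left + frag_len - enzyme.cut_offset
            for s in (left_start, right_start):
                seq[s : s + m] = site_arr
                protected.add(s)
        _erase_sites(seq, enzyme.site, rng, protected=protected)
        genome[name] = seq.tobytes().decode()

    fragments = digest(genome, enzyme)
    targets = select_fragments(fragments, frag_len_lo, frag_len_hi)
    if targets.n_fragments != n_snps:
        raise RuntimeError(
            f"expected {n_snps} in-window fragments, digest produced "
            f"{targets.n_fragments}"
        )

    # alleles and frequencies
    ref_alleles = np.array(
        [genome[c][p - 1] for c, p in zip(snp_positions["chrom"], snp_positions["pos"])]
    )
    shift = rng.integers(1, 4, size=n_snps)
    base_order = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    ref_idx = np.searchsorted(base_order, ref_alleles)
    alt_alleles = base_order[(ref_idx + shift) % 4]
    sites = snp_positions.assign(ref=ref_alleles, alt=alt_alleles)[
        ["chrom", "pos", "ref", "alt"]
    ]
    if freqs is None:
        freqs = {
            pop: rng.uniform(0.05, 0.95, size=n_snps) for pop in n_individuals
        }
    model = PopulationModel(
        sites=sites,
        n_individuals=dict(n_individuals),
        freqs=freqs,
        chrom_lengths={name: len(s) for name, s in genome.items()},
    )
    truth = simulate_genotypes(model, seed=int(seeds[1]))
    counts = simulate_counts(
        truth, ReadCountModel(mean_depth=mean_depth, error_rate=error_rate, seed=int(seeds[2]))
    )
    return Cohort(
        genome=genome,
        targets=targets.intervals,
        model=model,
        truth=truth,
        counts=counts,
        enzyme=enzyme,
    )
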