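"""Named simulation experiments over the pipeline.

Each experiment builds its inputs with the synthetic-data generator, runs the
relevant pipeline stages, and returns the measured quantities.  They are the
computational core of the analysis scripts and of the acceptance checks, so
the same code path produces every reported number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import CallerThresholds, call_population
from .comparison import genotype_concordance, score_validation
from .core import HET, HOMALT, MISSING, TruthSet
from .filtering import population_filter
from .popstats import sliding_window_scan
from .simulate import (
    PopulationModel,
    ReadCountModel,
    build_cohort,
    plant_sweep,
    simulate_counts,
    simulate_genotypes,
)

__all__ = [
    "het_bias_experiment",
    "discordance_classification_experiment",
    "sweep_recovery_experiment",
    "allele_frequency_recovery",
    "published_validation_counts",
]


def _site_frame(n_sites: int, spacing: int = 200) -> pd.DataFrame:
    pos = spacing * np.arange(1, n_sites + 1)
    return pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "ref": "A", "alt": "G"}
    )


def het_bias_experiment(
    n_sites: int = 12_000,
    n_individuals: int = 31,
    mean_depth: float = 12.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> dict:
    """Heterozygote-calling rates of the two callers on true heterozygotes.

    Every genotype is a true het sequenced at low coverage; both callers see
    the same read counts.  The hard-filter caller loses hets whose allele
    fraction drifts outside its 20–80% band, a loss a probabilistic caller
    with a population prior does not share — the classic depth-driven
    het-underestimation of fixed cut-off calling.  The likelihood caller
    runs with per-site Hardy–Weinberg priors (emulating multi-sample calling
    at an ascertained SNP) and the data's true error rate.

    Returns het-call rates, the paired disagreement counts (sites where
    exactly one caller called het), and a one-sided exact sign-test p-value
    for "the likelihood caller calls more hets".
    """
    sites = _site_frame(n_sites)
    inds = [f"I{i:03d}" for i in range(n_individuals)]
    truth = TruthSet(
        sites=sites,
        individuals=inds,
        gt=np.full((n_sites, n_individuals), HET, dtype=np.int8),
        populations=pd.Series("P", index=inds),
        freqs={"P": np.full(n_sites, 0.5)},
    )
    counts = simulate_counts(
        truth, ReadCountModel(mean_depth=mean_depth, error_rate=error_rate, seed=seed)
    )
    hard = call_population(counts, "hard_filter")
    lik = call_population(
        counts, "likelihood", error_rate=error_rate, population_prior=True
    )
    hard_het = hard.gt == HET
    lik_het = lik.gt == HET
    n_lik_only = int((lik_het & ~hard_het).sum())
    n_hard_only = int((hard_het & ~lik_het).sum())
    if n_lik_only + n_hard_only:
        p_value = sps.binomtest(
            n_lik_only, n_lik_only + n_hard_only, 0.5, alternative="greater"
        ).pvalue
    else:
        p_value = 1.0
    report = genotype_concordance(hard, lik)
    return {
        "n_genotypes": truth.gt.size,
        "hard_het_rate": float(hard_het.mean()),
        "likelihood_het_rate": float(lik_het.mean()),
        "n_lik_het_only": n_lik_only,
        "n_hard_het_only": n_hard_only,
        "sign_test_p": float(p_value),
        "n_discordant": report.n_discordant,
        "het_vs_hom_fraction": report.het_vs_hom_fraction,
    }


def discordance_classification_experiment(
    n_sites: int = 200_000,
    n_individuals: dict[str, int] | None = None,
    mean_depth: float = 40.0,
    error_rate: float = 0.005,
    seed: int = 0,
    likelihood_population_prior: bool = False,
) -> dict:
    """Classify all hard-filter-vs-likelihood genotype disagreements on a
    two-population cohort.

    Measures the percentage of discordant (site, individual) genotype pairs
    that are het-versus-hom type (one caller heterozygous, the other
    homozygous) rather than opposite homozygotes — the signature direction
    of caller disagreement in genotyping-by-sequencing data.
    """
    if n_individuals is None:
        n_individuals = {"WA": 15, "SK": 16}
    seeds = np.random.SeedSequence(seed).generate_state(3)
    rng = np.random.default_rng(seeds[0])
    sites = _site_frame(n_sites)
    model = PopulationModel(
        sites=sites,
        n_individuals=dict(n_individuals),
        freqs={pop: rng.uniform(0.05, 0.95, n_sites) for pop in n_individuals},
    )
    truth = simulate_genotypes(model, seed=int(seeds[1]))
    counts = simulate_counts(
        truth, ReadCountModel(mean_depth=mean_depth, error_rate=error_rate, seed=int(seeds[2]))
    )
    hard = call_population(counts, "hard_filter")
    lik = call_population(
        counts,
        "likelihood",
        error_rate=error_rate,
        population_prior=likelihood_population_prior,
    )
    report = genotype_concordance(hard, lik)
    cls = report.classification
    n_disc = report.n_discordant
    return {
        "n_sites": n_sites,
        "n_genotypes": truth.gt.size,
        "n_discordant": n_disc,
        "classification": cls,
        "het_vs_hom_pct": 100.0 * report.het_vs_hom_fraction if n_disc else float("nan"),
        "median_pct_identical": report.median_pct,
    }


def sweep_recovery_experiment(
    seed: int = 0,
    chrom_len: int = 2_000_000,
    n_sweep_snps: int = 50,
    mean_depth: float = 40.0,
    error_rate: float = 0.001,
    caller: str = "hard_filter",
) -> dict:
    """Plant a fixed-difference sweep region and recover it with the full
    pipeline: simulate -> call -> population filter -> window scan.

    The swept region carries ``n_sweep_snps`` SNPs at |p_SK − p_WA| = 1;
    neutral SNPs (shared Uniform frequencies) populate the rest of the
    chromosome, kept one window-length clear of the region so the set of
    windows that should fire is unambiguous.  Returns the flagged and the
    expected outlier windows.
    """
    region = ("chr1", 1_000_001, 1_050_000)
    sweep_pos = np.arange(1_000_501, 1_000_501 + 1000 * n_sweep_snps, 1000)
    neutral_left = np.arange(5_000, 875_000, 3_000)
    neutral_right = np.arange(1_180_000, chrom_len - 5_000, 3_000)
    positions = pd.DataFrame(
        {"chrom": "chr1", "pos": np.concatenate([neutral_left, sweep_pos, neutral_right])}
    )
    seeds = np.random.SeedSequence(seed).generate_state(3)
    cohort = build_cohort(
        chrom_len=chrom_len,
        mean_depth=mean_depth,
        error_rate=error_rate,
        seed=int(seeds[0]),
        snp_positions=positions,
    )
    model = plant_sweep(cohort.model, region, differential=1.0)
    truth = simulate_genotypes(model, seed=int(seeds[1]))
    counts = simulate_counts(
        truth, ReadCountModel(mean_depth=mean_depth, error_rate=error_rate, seed=int(seeds[2]))
    )
    callset = call_population(counts, caller, error_rate=error_rate)
    snps = population_filter(callset, truth.populations)
    scan = sliding_window_scan(snps, {"chr1": chrom_len})
    flagged = set(zip(scan.outliers()["chrom"], scan.outliers()["start"]))
    w = scan.windows
    overlaps = (w["start"] <= region[2]) & (w["end"] >= region[1]) & (w["chrom"] == region[0])
    expected = set(zip(w.loc[overlaps, "chrom"], w.loc[overlaps, "start"]))
    return {
        "region": region,
        "n_snps_retained": len(snps),
        "scan": scan,
        "flagged_windows": flagged,
        "expected_windows": expected,
        "exact_recovery": flagged == expected,
    }


def allele_frequency_recovery(
    n_sites: int = 2_000,
    n_individuals: dict[str, int] | None = None,
    mean_depth: float = 40.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> dict:
    """Per-site allele-frequency estimation accuracy from called genotypes.

    Compares p estimated from likelihood-caller genotypes against the
    generator's per-population frequencies; a (site, population) estimate
    passes when it lies within 3 binomial standard errors
    sqrt(p(1-p) / 2n_called) of the truth.
    """
    if n_individuals is None:
        n_individuals = {"WA": 15, "SK": 16}
    seeds = np.random.SeedSequence(seed).generate_state(3)
    rng = np.random.default_rng(seeds[0])
    sites = _site_frame(n_sites)
    model = PopulationModel(
        sites=sites,
        n_individuals=dict(n_individuals),
        freqs={pop: rng.uniform(0.05, 0.95, n_sites) for pop in n_individuals},
    )
    truth = simulate_genotypes(model, seed=int(seeds[1]))
    counts = simulate_counts(
        truth, ReadCountModel(mean_depth=mean_depth, error_rate=error_rate, seed=int(seeds[2]))
    )
    callset = call_population(counts, "likelihood", error_rate=error_rate)
    labels = truth.populations.loc[callset.individuals].to_numpy()
    n_checked = 0
    n_within = 0
    for pop in model.n_individuals:
        idx = np.flatnonzero(labels == pop)
        gt = callset.gt[:, idx]
        called = (gt != MISSING).sum(axis=1)
        copies = (gt == HET).sum(axis=1) + 2 * (gt == HOMALT).sum(axis=1)
        ok = called > 0
        p_hat = copies[ok] / (2 * called[ok])
        p_true = model.freqs[pop][ok]
        se = np.sqrt(p_true * (1 - p_true) / (2 * called[ok]))
        n_checked += int(ok.sum())
        n_within += int((np.abs(p_hat - p_true) <= 3 * se).sum())
    return {
        "n_checked": n_checked,
        "n_within_3se": n_within,
        "fraction_within_3se": n_within / n_checked,
    }


def published_validation_counts() -> tuple[pd.DataFrame, tuple[int, int, int]]:
    """Sanger-validation outcomes of conflicting and concordant genotype
    calls between a hard-filter caller (caller A) and probabilistic callers
    (caller B) in the two-population orangutan RRL dataset this pipeline is
    modelled on.  Used as input to :func:`rrlpopgen.score_validation`.

    Discordant rows: (category, SNPs validated, genotypes validated, number
    where caller A's genotype proved correct, number where caller B's did).
    The concordant tuple is (SNPs, genotypes, correct genotypes).
    """
    discordant = pd.DataFrame(
        [
            ("singleton_by_B", 8, 8, 1, 7),
            ("singleton_by_A", 4, 4, 0, 4),
            ("hom_B_het_A", 23, 28, 3, 25),
            ("het_B_hom_A", 23, 23, 7, 16),
        ],
        columns=["category", "n_snps", "n_genotypes", "n_true_a", "n_true_b"],
    )
    concordant = (53, 114, 110)
    return discordant, concordant
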