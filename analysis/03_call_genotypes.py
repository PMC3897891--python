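#!/usr/bin/env python
"""Call genotypes on the simulated cohort with both callers and apply the
population-based filter.

Produces, per caller, a VCF of all calls and a filtered SNP table with
per-population allele frequencies, plus a summary in the style of a SNP-
discovery overview: SNP counts, singleton percentages, private SNPs and
median site heterozygosity per population.
"""

import json
from pathlib import Path

import numpy as np

from rrlpopgen import io
from rrlpopgen.calling import call_population
from rrlpopgen.filtering import population_filter
from rrlpopgen.popstats import singleton_and_private, site_heterozygosity

COHORT = Path("results/cohort")
OUT = Path("results/calls")
OUT.mkdir(parents=True, exist_ok=True)

if not (COHORT / "counts.tsv").exists():
    raise SystemExit("run analysis/02_simulate_cohort.py first")

counts = io.read_counts(COHORT / "counts.tsv")
pops = io.read_populations(COHORT / "populations.tsv")
genome = io.read_fasta(COHORT / "genome.fasta")
contigs = {name: len(seq) for name, seq in genome.items()}

summary = {}
for caller, kwargs in [
    ("hard_filter", {}),
    ("likelihood", {"error_rate": 0.001}),
]:
    callset = call_population(counts, caller, **kwargs)
    io.write_vcf(callset, OUT / f"{caller}.vcf", contigs=contigs)
    snps = population_filter(callset, pops, min_individuals=8)
    snps.table.to_csv(OUT / f"{caller}.snps.tsv", sep="\t", index=False)
    flags = singleton_and_private(snps, scope="overall")
    stats = flags.attrs["summary"]
    entry = {
        "n_variant_sites": int(callset.sites["variant"].sum()),
        "n_snps_after_population_filter": len(snps),
        "pct_singletons_overall": round(float(stats["pct_singletons"]), 2),
    }
    for pop in snps.populations:
        entry[f"n_private_{pop}"] = stats[f"n_private:{pop}"]
        het = site_heterozygosity(snps, pop)
        entry[f"median_site_het_{pop}"] = round(float(np.median(het)), 3)
    summary[caller] = entry
    print(f"{caller}: {entry}")

(OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
print(f"written: {OUT}/<caller>.vcf, <caller>.snps.tsv, summary.json")
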