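# Methods

`rrlpopgen` implements the computational arm of a reduced-representation
library (RRL) genotyping-by-sequencing study: library design by in-silico
restriction digestion, genotype calling from allelic read counts by two
conceptually different callers, the population-based filters that make
direct allele-frequency estimation valid, concordance analysis between call
sets, and an allele-frequency-differential scan for selective sweeps. All
stages are exercised on synthetic cohorts with known truth, so every
downstream claim is checkable against the generator.

## In-silico digestion and size selection

A genome is a mapping of sequence names to nucleotide strings; lowercase
bases are soft-masked repeats, `N` is an assembly gap. An enzyme is a 4–6 bp
unambiguous palindromic recognition site with a cut offset (HaeIII = GG^CC,
offset 2); non-palindromic or ambiguous sites are rejected because the
digest scans the forward strand only. Every occurrence of the site — 
including overlapping occurrences — contributes a cut at
`occurrence_start + offset`; duplicate cut positions collapse. Fragments are
the maximal runs between consecutive cuts, so they tile each sequence
exactly (asserted in tests as an invariant). A site never matches across an
`N` because the site alphabet is A/C/G/T; fragments may contain `N`, and a
per-fragment N-fraction and soft-masked fraction are reported so users can
exclude gap-adjacent or repetitive targets.

Size selection keeps fragments with `min_len <= L <= max_len`, both bounds
inclusive (a printed range like "104–123 bp" denotes 20 distinct lengths).
The genome fraction uses the total sequence length including `N` as
denominator. Coordinates are 0-based half-open internally and in BED;
1-based inclusive in human-readable reports.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the sequencing chemistry:

* **Genome / targets.** `build_cohort` places each SNP inside its own
  restriction fragment of in-window length by planting a flanking pair of
  recognition sites and erasing accidental occurrences elsewhere, so the
  digest + size selection provably recovers exactly the SNP-bearing
  fragments. SNPs exist only inside target regions because RRL sequencing
  yields no data elsewhere. A minimum SNP spacing of `2*max_len + 2` bp
  guarantees spacer fragments can never be co-selected.
* **Genotypes.** Individuals are unrelated; genotypes are two independent
  Bernoulli(p) allele copies (Hardy–Weinberg), with per-population,
  per-site alt-allele frequencies p. Defaults mirror the study conditions
  the pipeline is tested under: two populations of 15 (WA) and 16 (SK)
  individuals; where an experiment does not fix frequencies they are drawn
  Uniform(0.05, 0.95) per population — a flat, ascertainment-free spectrum
  chosen for testability rather than coalescent realism.
* **Read counts.** Depth is Poisson with mean 41 (the study-scale median
  coverage); each read reports the allele of a uniformly chosen chromosome
  copy, flipped with probability ε (default 1e-3, the error level of
  phred-Q30-filtered data). Counts are quality-passing by construction:
  base/mapping-quality filtering is modelled as already applied, because
  both callers consume post-filter pileups. Equivalently, alt reads are
  Binomial(depth, μ) with μ = ε, 1/2, 1−ε per genotype.
* **Sweeps.** `plant_sweep` forces |pSK − pWA| = d symmetrically around 1/2
  at every SNP in a region (d = 1 gives alternatively fixed alleles).

What the generator does **not** model: linkage disequilibrium, indels,
mapping artefacts, colorspace/read-level errors, allele-specific bias,
demography beyond independent per-population frequencies. Passing tests
therefore demonstrate the correctness of the pipeline's arithmetic and the
qualitative caller phenomena, not the field performance of any real caller.

## Genotype calling

Both callers see identical (ref, alt) read counts per site and individual
and apply the same depth band (10–1000 reads inclusive); outside it the
genotype is missing, as is a depth-0 entry.

**Hard-filter caller.** With f = alt/(ref+alt): f < 0.15 → homozygous
reference; 0.20 ≤ f ≤ 0.80 → heterozygous; f > 0.85 → homozygous
alternative; the borderline bands [0.15, 0.20) and (0.80, 0.85] are
conservatively missing ('N'). Band edges are resolved to the conservative
side; the het band is closed on both ends per its "20–80%" definition.
Threshold comparisons use exact rational arithmetic (integer
cross-multiplication of `Fraction` thresholds), so e.g. 3 alt reads of 20
(f = 0.15 exactly) is always borderline — float division would make such
edges platform-dependent. No genotype quality is produced and no GQ filter
applies, matching how hard-filter callers are used in practice.

**Likelihood caller.** Binomial genotype likelihoods
L(g) = B(alt; depth, p_g) with p = ε, 1/2, 1−ε, combined with one of two
priors:

* *single-sample mode* (default): {1−θ−θ², θ, θ²} with θ = 0.001 — an
  arbitrary genomic site is a priori almost certainly homozygous reference;
* *population-prior mode*: per-site Hardy–Weinberg priors {q², 2pq, p²}
  with p estimated from the pooled reads of all individuals, emulating
  multi-sample calling at an ascertained SNP site. Frequencies are clipped
  to [1e-4, 1−1e-4] so no observed allele receives a zero prior.

The call is the maximum-posterior genotype; GQ is the phred-scaled
probability the call is wrong, rounded and capped at 99; calls with
GQ < 10 are missing. The caller is deliberately minimal — no indel
realignment, no linkage or multi-site model — because the pipeline studies
caller *disagreement*, not fidelity to any specific production caller.

The low-coverage het-underestimation phenomenon deserves a note, because it
dictated a design choice. Working the band geometry and the posterior odds
through analytically shows that at ~12x coverage a likelihood caller with
the *rare-variant* prior is more conservative about heterozygotes than the
20–80% band (the θ = 0.001 prior demands roughly a 10^4 likelihood ratio,
which 3 alt reads of 12 cannot supply), so the textbook direction —
fixed-cut-off calling underestimates heterozygotes relative to
probabilistic multi-sample calling — emerges only in population-prior mode.
The het-bias experiment therefore runs the likelihood caller with the
Hardy–Weinberg population prior, which is exactly what multi-sample callers
do at a discovered SNP. Significance is assessed with an exact one-sided
sign test on the paired per-genotype disagreements (the two callers see the
same reads, so an unpaired rate comparison would waste most of the power).

**Multi-allelic handling.** Sites whose third-allele read total reaches 2
are flagged and removed by the population filter, enforcing the biallelic
restriction of the analysis.

## Population-based filtering and target efficiency

The population filter keeps variant, biallelic sites with non-missing
genotypes in at least 8 individuals *per population* (≥ 16 chromosomes
each), then estimates per-population alt-allele frequencies directly from
called genotypes — missing individuals leave the denominator, which the
filter guarantees is large enough for stable estimates. Re-filtering is
idempotent and raising the threshold can only shrink the site set (both
property-tested).

Target efficiency is the percentage of an individual's high-quality
sequenced positions (bp_hiqual: mapping and base quality ≥ 30, depth ≥ 10)
that fall inside the predicted target fragments, summarized per population
by the median. bp_hiqual is consumed as per-individual BED intervals; a
converter from samtools-depth-style tables is provided so the module stays
mapping-tool-agnostic.

## Concordance, intersection, validation

Site identity is chrom + position + allele pair, irrespective of genotype,
so "overlap" means the same variant was discovered. Concordance is
computed per individual over sites where both callers made a call; entries
missing in exactly one set count toward neither agreement nor disagreement.
Discordant pairs are classified as het-versus-hom (one caller heterozygous)
or homref-versus-homalt (opposite homozygotes); the het-direction bias is
the fraction of het-vs-hom pairs in which a given caller is the
heterozygous one. Intersection keeps a genotype only where both callers
agree (non-missing), and happens *before* the population filter, which is
then re-applied to the intersect set.

Validation scoring consumes a contingency table of Sanger-validated
genotype calls (category, SNPs, genotypes, correct-per-caller) and reports
exact percentage splits, rounded half-up to two decimals with `Decimal`
arithmetic so printed values are reproduced digit-for-digit.

## Population statistics and the sweep scan

Observed site heterozygosity is het-individuals / called-individuals per
population. The allele-frequency differential of a biallelic site is
D = (|pSK − pWA| + |qSK − qWA|)/2, which equals |pSK − pWA| — the identity
is asserted on a dense frequency grid. The scan tiles each chromosome with
100 kb windows advanced by 25 kb, anchored at position 1, including
trailing partial windows (dropping them is one configuration switch away);
an interior SNP is counted in exactly window/step = 4 windows. A window's
mean D weights SNPs equally; windows with mean D > 0.95 covered by at
least 2 SNPs are sweep-candidate outliers. Unplaced scaffolds (names
containing `_random`) are excluded by default. Singletons carry exactly one
alternative allele copy in the scope (overall or per population — both
senses are implemented and labelled); private SNPs are polymorphic in
exactly one population. MAF spectra fold p at 1/2; KDE plots use a
Gaussian kernel with Silverman's bandwidth.

## Experiment sizing

The packaged experiments are sized for a desk-scale machine: the
caller-disagreement classification runs 200,000 sites × 31 individuals
(6.2M genotype pairs per caller); the het-bias experiment 12,000 true-het
sites × 31 individuals at 12x; sweep recovery a 2 Mb chromosome with 50
swept and ~560 neutral SNPs at 40x; frequency recovery 2,000 sites at 40x.
In the sweep experiment the neutral SNPs are kept one full window-length
clear of the swept region so that "the windows overlapping the region" is
exactly the set that should fire; on real data, windows straddling a sweep
edge mix swept and neutral SNPs and dilution at the boundary is expected.

## Known limitations

* The likelihood caller is a two-allele binomial model; it cannot express
  strand bias, base-quality heterogeneity or indel uncertainty.
* The generator's per-read error is symmetric and independent; systematic
  errors (which hard-filter callers are notoriously sensitive to) are not
  modelled, so real-data discordance rates will exceed the synthetic ones.
* The digest assumes complete digestion of both strands at palindromic
  sites; partial digests, methylation sensitivity and sticky-end enzymes
  are out of scope.
* Checking the design numbers of a real genome (e.g. the orangutan
  reference) requires supplying that FASTA to the `digest` CLI; it is not
  bundled.
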