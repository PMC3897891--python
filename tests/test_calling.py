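"""Genotype callers: hard-filter bands, binomial likelihood model, filters."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrlpopgen.calling import (
    CallerThresholds,
    call_population,
    genotype_posteriors,
    hard_filter_call,
    hwe_priors,
    likelihood_call,
)
from rrlpopgen.core import HET, HOMALT, HOMREF, MISSING, SiteCounts, TruthSet
from rrlpopgen.simulate import ReadCountModel, simulate_counts


def rule_table_oracle(ref: int, alt: int, t: CallerThresholds = CallerThresholds()) -> int:
    """Independent exact-rational statement of the hard-filter rules."""
    depth = ref + alt
    if depth < t.min_depth or depth > t.max_depth:
        return MISSING
    f = Fraction(alt, depth)
    if f < Fraction("0.15"):
        return HOMREF
    if f < Fraction("0.20"):
        return MISSING
    if f <= Fraction("0.80"):
        return HET
    if f <= Fraction("0.85"):
        return MISSING
    return HOMALT


class TestHardFilter:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            (18, 2, HOMREF),    # f = 0.10
            (10, 10, HET),      # f = 0.50
            (33, 7, MISSING),   # f = 0.175, borderline band
            (5, 4, MISSING),    # depth 9 < 10
            (0, 0, MISSING),    # no data
            (900, 200, MISSING),  # depth 1100 > 1000
            (17, 3, MISSING),   # f = 0.15 exactly: borderline
            (16, 4, HET),       # f = 0.20 exactly: het band is closed
            (4, 16, HET),       # f = 0.80 exactly
            (3, 17, MISSING),   # f = 0.85 exactly: borderline
            (2, 18, HOMALT),    # f = 0.90
        ],
    )
    def test_band_examples(self, ref, alt, expected):
        assert int(hard_filter_call(ref, alt)) == expected

    def test_matches_rule_table_to_depth_30(self):
        for depth in range(31):
            for alt in range(depth + 1):
                assert int(hard_filter_call(depth - alt, alt)) == rule_table_oracle(
                    depth - alt, alt
                )

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(0, 60, size=200)
        alt = rng.integers(0, 60, size=200)
        vec = hard_filter_call(ref, alt)
        assert all(int(v) == int(hard_filter_call(r, a)) for v, r, a in zip(vec, ref, alt))

    def test_raising_min_depth_never_adds_calls(self):
        rng = np.random.default_rng(1)
        ref = rng.integers(0, 40, size=500)
        alt = rng.integers(0, 40, size=500)
        n_called = [
            int((hard_filter_call(ref, alt, CallerThresholds(min_depth=d)) != MISSING).sum())
            for d in range(0, 30, 3)
        ]
        assert all(b <= a for a, b in zip(n_called, n_called[1:]))

    def test_band_validation(self):
        with pytest.raises(ValueError, match="ordered"):
            CallerThresholds(homref_max=0.5, het_low=0.2)


class TestLikelihoodCaller:
    def test_clean_homref_is_certain(self):
        gt, gq = likelihood_call(40, 0, error_rate=0.001)
        assert int(gt) == HOMREF and int(gq) == 99

    def test_balanced_counts_are_het(self):
        gt, gq = likelihood_call(20, 20, error_rate=0.001)
        assert int(gt) == HET and int(gq) >= 10

    def test_clean_homalt(self):
        gt, _ = likelihood_call(0, 40, error_rate=0.001)
        assert int(gt) == HOMALT

    def test_no_data_is_missing(self):
        gt, _ = likelihood_call(0, 0)
        assert int(gt) == MISSING

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            genotype_posteriors(5, 5, error_rate=0.7)
        with pytest.raises(ValueError):
            genotype_posteriors(5, 5, het_prior=0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 400), st.integers(0, 400))
    def test_posteriors_sum_to_one(self, ref, alt):
        post = genotype_posteriors(ref, alt, error_rate=0.01, het_prior=0.01)
        assert abs(post.sum() - 1.0) < 1e-12

    def test_hwe_priors_shape_and_sum(self):
        pri = hwe_priors([0.0, 0.25, 1.0])
        assert pri.shape == (3, 3)
        assert np.allclose(pri.sum(axis=1), 1.0, atol=1e-6)

    def test_converges_to_truth_at_high_depth(self):
        """At 40x and eps = 1e-3 the caller recovers >= 99% of genotypes."""
        rng = np.random.default_rng(2)
        n = 3000
        gt_true = rng.integers(0, 3, size=n).astype(np.int8)
        depth = rng.poisson(40, size=n)
        p_alt = np.array([0.001, 0.5, 0.999])[gt_true]
        alt = rng.binomial(depth, p_alt)
        gt, _ = likelihood_call(depth - alt, alt, error_rate=0.001)
        called = gt != MISSING
        assert called.mean() > 0.95
        assert (gt[called] == gt_true[called]).mean() >= 0.99


def _counts(ref, alt, individuals=None, other=None):
    ref = np.asarray(ref)
    individuals = individuals or [f"I{j}" for j in range(ref.shape[1])]
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": 100 * np.arange(1, ref.shape[0] + 1),
            "ref": "A",
            "alt": "G",
        }
    )
    return SiteCounts(
        sites=sites, individuals=individuals, ref=ref, alt=np.asarray(alt),
        other=None if other is None else np.asarray(other),
    )


class TestCallPopulation:
    def test_all_homref_site_flagged_nonvariant(self):
        counts = _counts(ref=[[40, 38, 41]], alt=[[0, 1, 0]])
        cs = call_population(counts, "likelihood")
        assert not cs.sites["variant"].iloc[0]

    def test_single_het_makes_site_variant(self):
        counts = _counts(ref=[[40, 20, 41]], alt=[[0, 20, 0]])
        cs = call_population(counts, "hard_filter")
        assert cs.sites["variant"].iloc[0]
        assert (cs.gt[0] == [HOMREF, HET, HOMREF]).all()

    def test_depths_straddling_minimum(self):
        counts = _counts(ref=[[5, 6, 20]], alt=[[4, 4, 15]])  # depths 9, 10, 35
        cs = call_population(counts, "hard_filter")
        assert cs.gt[0, 0] == MISSING
        assert cs.gt[0, 1] == HET
        assert cs.gt[0, 2] == HET

    def test_third_allele_reads_flag_multiallelic(self):
        counts = _counts(
            ref=[[30, 30], [30, 30]],
            alt=[[10, 10], [10, 10]],
            other=[[1, 1], [1, 0]],
        )
        cs = call_population(counts, "hard_filter")
        assert cs.sites["multiallelic"].tolist() == [True, False]

    def test_unknown_caller_rejected(self):
        counts = _counts(ref=[[10]], alt=[[10]])
        with pytest.raises(ValueError, match="unknown caller"):
            call_population(counts, "gatk")

    def test_duplicate_individuals_rejected(self):
        with pytest.raises(ValueError, match="duplicate individual"):
            _counts(ref=[[10, 10]], alt=[[0, 0]], individuals=["A", "A"])

    def test_population_prior_mode_runs_deterministically(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(0, 30, size=(50, 8))
        alt = rng.integers(0, 30, size=(50, 8))
        a = call_population(_counts(ref, alt), "likelihood", population_prior=True)
        b = call_population(_counts(ref, alt), "likelihood", population_prior=True)
        assert (a.gt == b.gt).all()
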