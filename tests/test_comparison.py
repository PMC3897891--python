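"""Call-set overlap, concordance classification, intersection, validation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_callset
from rrlpopgen.comparison import (
    genotype_concordance,
    intersect_callsets,
    outlier_overlap,
    score_validation,
    site_overlap,
)
from rrlpopgen.core import HET, HOMALT, HOMREF, MISSING
from rrlpopgen.popstats import WindowScan


class TestSiteOverlap:
    def test_set_algebra(self):
        a = make_callset("A", np.full((2, 1), HET, np.int8), pos=[100, 200])
        b = make_callset("B", np.full((2, 1), HET, np.int8), pos=[200, 300])
        venn = site_overlap([a, b])
        assert venn["counts"][frozenset(["A"])] == 1
        assert venn["counts"][frozenset(["B"])] == 1
        assert venn["counts"][frozenset(["A", "B"])] == 1
        assert venn["n_union"] == 3
        assert venn["private_pct"]["A"] == 50.0

    def test_identical_sets_have_no_private_sites(self):
        a = make_callset("A", np.full((3, 1), HET, np.int8))
        b = make_callset("B", np.full((3, 1), HET, np.int8))
        venn = site_overlap([a, b])
        assert venn["n_all"] == 3
        assert venn["private_pct"] == {"A": 0.0, "B": 0.0}

    def test_disjoint_sets_fully_private(self):
        a = make_callset("A", np.full((2, 1), HET, np.int8), pos=[100, 200])
        b = make_callset("B", np.full((2, 1), HET, np.int8), pos=[500, 600])
        venn = site_overlap([a, b])
        assert venn["n_all"] == 0
        assert venn["private_pct"] == {"A": 100.0, "B": 100.0}

    def test_conflicting_alleles_at_same_locus_rejected(self):
        a = make_callset("A", np.full((1, 1), HET, np.int8), pos=[100])
        b = make_callset("B", np.full((1, 1), HET, np.int8), pos=[100])
        b.sites.loc[0, "alt"] = "T"
        with pytest.raises(ValueError, match="conflicting allele"):
            site_overlap([a, b])


class TestConcordance:
    def test_identical_callsets(self):
        gt = np.array([[HET, HOMREF], [HOMALT, HET]], dtype=np.int8)
        rep = genotype_concordance(make_callset("A", gt), make_callset("B", gt.copy()))
        assert rep.median_pct == 100.0
        assert rep.n_discordant == 0

    def test_single_discordance_classified_and_biased(self):
        # one individual, 10 shared sites, one disagreement (A het, B homref)
        gt_a = np.full((10, 1), HOMREF, dtype=np.int8)
        gt_b = gt_a.copy()
        gt_a[0, 0] = HET
        rep = genotype_concordance(make_callset("A", gt_a), make_callset("B", gt_b))
        row = rep.per_individual.iloc[0]
        assert row["n_compared"] == 10 and row["n_identical"] == 9
        assert row["pct_identical"] == pytest.approx(90.0)
        assert rep.classification["het_a_hom_b"] == 1
        assert rep.het_bias("a") == 1.0

    def test_missing_entries_excluded_from_comparison(self):
        gt_a = np.array([[HET], [MISSING], [HOMREF]], dtype=np.int8)
        gt_b = np.array([[HET], [HOMALT], [MISSING]], dtype=np.int8)
        rep = genotype_concordance(make_callset("A", gt_a), make_callset("B", gt_b))
        assert rep.per_individual["n_compared"].iloc[0] == 1

    def test_symmetry_up_to_direction_labels(self):
        rng = np.random.default_rng(0)
        gt_a = rng.integers(-1, 3, size=(40, 5)).astype(np.int8)
        gt_b = rng.integers(-1, 3, size=(40, 5)).astype(np.int8)
        ab = genotype_concordance(make_callset("A", gt_a), make_callset("B", gt_b))
        ba = genotype_concordance(make_callset("B", gt_b), make_callset("A", gt_a))
        assert ab.median_pct == ba.median_pct
        assert ab.classification["het_a_hom_b"] == ba.classification["hom_a_het_b"]
        assert ab.classification["homref_homalt"] == ba.classification["homref_homalt"]

    def test_no_shared_individuals_rejected(self):
        a = make_callset("A", np.full((1, 1), HET, np.int8), individuals=["X"])
        b = make_callset("B", np.full((1, 1), HET, np.int8), individuals=["Y"])
        with pytest.raises(ValueError, match="shared individuals"):
            genotype_concordance(a, b)


class TestIntersect:
    def test_self_intersection_is_identity(self):
        rng = np.random.default_rng(1)
        gt = rng.integers(-1, 3, size=(20, 4)).astype(np.int8)
        a = make_callset("A", gt)
        both = intersect_callsets(a, make_callset("B", gt.copy()))
        assert (both.gt == gt).all()

    def test_total_conflict_leaves_nothing(self):
        gt_a = np.full((5, 2), HET, dtype=np.int8)
        gt_b = np.full((5, 2), HOMREF, dtype=np.int8)
        both = intersect_callsets(make_callset("A", gt_a), make_callset("B", gt_b))
        assert (both.gt == MISSING).all()
        assert not both.sites["variant"].any()

    def test_intersect_fully_concordant_with_parents(self):
        rng = np.random.default_rng(2)
        gt_a = rng.integers(-1, 3, size=(30, 6)).astype(np.int8)
        gt_b = rng.integers(-1, 3, size=(30, 6)).astype(np.int8)
        a, b = make_callset("A", gt_a), make_callset("B", gt_b)
        both = intersect_callsets(a, b)
        for parent in (a, b):
            rep = genotype_concordance(both, parent)
            compared = rep.per_individual["n_compared"].sum()
            identical = rep.per_individual["n_identical"].sum()
            assert compared == identical


class TestScoreValidation:
    def test_percentage_splits(self):
        table = pd.DataFrame(
            [("x", 5, 10, 10, 0), ("y", 3, 8, 2, 6)],
            columns=["category", "n_snps", "n_genotypes", "n_true_a", "n_true_b"],
        )
        result = score_validation(table)
        assert result["table"]["pct_true_a"].tolist() == [100.0, 25.0]
        assert result["table"]["pct_true_b"].tolist() == [0.0, 75.0]
        assert result["totals"]["pct_true_a"] == pytest.approx(66.67)

    def test_inconsistent_counts_rejected(self):
        table = pd.DataFrame(
            [("x", 1, 10, 3, 3)],
            columns=["category", "n_snps", "n_genotypes", "n_true_a", "n_true_b"],
        )
        with pytest.raises(ValueError, match="n_true"):
            score_validation(table)

    def test_concordant_accuracy(self):
        table = pd.DataFrame(
            [("x", 1, 2, 1, 1)],
            columns=["category", "n_snps", "n_genotypes", "n_true_a", "n_true_b"],
        )
        result = score_validation(table, concordant=(10, 50, 49))
        assert result["concordant"]["accuracy_pct"] == 98.0


def _scan(label, outlier_starts, window=100_000, step=25_000):
    starts = np.arange(1, 500_000, step)
    windows = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": np.minimum(starts + window - 1, 500_000),
            "n_snps": 2,
            "mean_d": 0.0,
        }
    )
    windows["outlier"] = windows["start"].isin(outlier_starts)
    return WindowScan(label, windows, window, step, 0.95, 2)


class TestOutlierOverlap:
    def test_three_way_set_arithmetic(self):
        scans = [
            _scan("A", [1, 25_001]),
            _scan("B", [25_001]),
            _scan("C", [25_001, 50_001]),
        ]
        venn = outlier_overlap(scans)
        assert venn["n_all"] == 1
        assert venn["n_union"] == 3
        assert venn["pct_identical"] == pytest.approx(100 / 3)
        assert venn["counts"][frozenset(["A", "B", "C"])] == 1
        assert venn["counts"][frozenset(["A"])] == 1
        assert venn["counts"][frozenset(["C"])] == 1

    def test_identical_scans_fully_shared(self):
        venn = outlier_overlap([_scan("A", [1]), _scan("B", [1])])
        assert venn["pct_identical"] == 100.0

    def test_disjoint_scans_share_nothing(self):
        venn = outlier_overlap([_scan("A", [1]), _scan("B", [25_001])])
        assert venn["pct_identical"] == 0.0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            outlier_overlap([_scan("A", [1]), _scan("B", [1], step=50_000)])
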