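"""Per-site statistics and the sliding-window differentiation scan."""

import numpy as np
import pandas as pd
import pytest

from rrlpopgen.core import HET, HOMALT
from rrlpopgen.filtering import SNPTable
from rrlpopgen.popstats import (
    allele_freq_differential,
    maf_spectrum,
    singleton_and_private,
    site_heterozygosity,
    sliding_window_scan,
)
from rrlpopgen.simulate import PopulationModel, simulate_genotypes


def snp_table(pos, stats, pops=("SK", "WA"), chrom="chr1"):
    """SNPTable from {pop: (called, het, homalt)} per-site arrays."""
    table = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"})
    for pop in pops:
        called, het, homalt = stats[pop]
        table[f"{pop}:called"] = called
        table[f"{pop}:het"] = het
        table[f"{pop}:homalt"] = homalt
        table[f"{pop}:p"] = (table[f"{pop}:het"] + 2 * table[f"{pop}:homalt"]) / (
            2 * table[f"{pop}:called"]
        )
    return SNPTable(table=table, populations=list(pops), min_individuals=8)


class TestDifferential:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [(1.0, 0.0, 1.0), (0.3, 0.3, 0.0), (0.6, 0.1, 0.5), (0.0, 0.25, 0.25)],
    )
    def test_examples(self, p1, p2, expected):
        assert allele_freq_differential(p1, p2) == pytest.approx(expected)

    def test_identity_with_abs_difference_on_grid(self):
        """For biallelic sites D reduces to |p1 - p2|; check a dense grid."""
        grid = np.linspace(0, 1, 101)
        p1, p2 = np.meshgrid(grid, grid)
        d = allele_freq_differential(p1.ravel(), p2.ravel())
        assert np.allclose(d, np.abs(p1.ravel() - p2.ravel()), atol=1e-12)
        assert ((d >= 0) & (d <= 1)).all()

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        p1, p2 = rng.random(100), rng.random(100)
        assert np.array_equal(
            allele_freq_differential(p1, p2), allele_freq_differential(p2, p1)
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            allele_freq_differential(1.2, 0.5)


class TestHeterozygosity:
    def test_counting(self):
        snps = snp_table(
            [100, 200, 300],
            {
                "SK": ([10, 10, 10], [4, 0, 10], [1, 5, 0]),
                "WA": ([8, 8, 8], [0, 0, 8], [0, 0, 0]),
            },
        )
        het = site_heterozygosity(snps, "SK")
        assert het.tolist() == [0.4, 0.0, 1.0]


class TestWindowScan:
    def _table(self, pos, p_sk, p_wa, n=16):
        k = len(pos)
        full = np.full(k, n)
        return snp_table(
            pos,
            {
                "SK": (full, np.zeros(k, int), (np.asarray(p_sk) * n).astype(int)),
                "WA": (full, np.zeros(k, int), (np.asarray(p_wa) * n).astype(int)),
            },
        )

    def test_two_fixed_snps_flag_exactly_their_shared_windows(self):
        snps = self._table([120_000, 130_000], [1, 1], [0, 0])
        scan = sliding_window_scan(snps, {"chr1": 300_000})
        flagged = set(scan.outliers()["start"])
        # outliers need both SNPs: windows [s, s+1e5-1] with s <= 120000 and
        # s + 99999 >= 130000, on the 25 kb grid anchored at 1
        assert flagged == {50_001, 75_001, 100_001}

    def test_single_snp_window_not_outlier(self):
        snps = self._table([120_000], [1], [0])
        scan = sliding_window_scan(snps, {"chr1": 300_000})
        assert not scan.windows["outlier"].any()
        covering = scan.windows[
            (scan.windows["start"] <= 120_000) & (scan.windows["end"] >= 120_000)
        ]
        assert (covering["mean_d"] == 1.0).all()

    def test_undifferentiated_snps_give_no_outliers(self):
        pos = np.arange(10_000, 290_000, 5_000)
        p = np.full(len(pos), 0.5)
        scan = sliding_window_scan(self._table(pos, p, p), {"chr1": 300_000})
        assert not scan.windows["outlier"].any()
        covered = scan.windows["n_snps"] > 0
        assert (scan.windows.loc[covered, "mean_d"] == 0.0).all()

    def test_interior_snp_counted_in_four_windows(self):
        snps = self._table([150_000], [1], [0])
        scan = sliding_window_scan(snps, {"chr1": 300_000})
        assert int((scan.windows["n_snps"] > 0).sum()) == 4  # window/step = 4

    def test_trailing_partial_windows_present(self):
        scan = sliding_window_scan(self._table([50], [1], [0]), {"chr1": 130_000})
        assert scan.windows["start"].tolist() == [1, 25_001, 50_001, 75_001, 100_001, 125_001]
        assert scan.windows["end"].tolist() == [100_000, 125_000, 130_000, 130_000, 130_000, 130_000]

    def test_unplaced_scaffolds_excluded(self):
        snps = self._table([120_000, 130_000], [1, 1], [0, 0])
        scan = sliding_window_scan(
            snps, {"chr1": 300_000, "chrXY_random": 300_000}
        )
        assert "chrXY_random" not in set(scan.windows["chrom"])

    def test_zero_snp_windows_have_missing_mean(self):
        scan = sliding_window_scan(self._table([50], [1], [0]), {"chr1": 300_000})
        empty = scan.windows["n_snps"] == 0
        assert scan.windows.loc[empty, "mean_d"].isna().all()


class TestSingletonsAndPrivate:
    def _table(self):
        # site 1: single het in SK only (overall singleton, private to SK)
        # site 2: polymorphic in both populations
        # site 3: fixed alt in SK, fixed ref in WA (not polymorphic in either)
        return snp_table(
            [100, 200, 300],
            {
                "SK": ([16, 16, 16], [1, 4, 0], [0, 2, 16]),
                "WA": ([15, 15, 15], [0, 3, 0], [0, 1, 0]),
            },
        )

    def test_overall_singleton(self):
        flags = singleton_and_private(self._table(), scope="overall")
        assert flags["singleton"].tolist() == [True, False, False]
        assert flags.attrs["summary"]["pct_singletons"] == pytest.approx(100 / 3)

    def test_private_requires_polymorphism_in_exactly_one_population(self):
        flags = singleton_and_private(self._table(), scope="overall")
        assert flags["private:SK"].tolist() == [True, False, False]
        assert flags["private:WA"].tolist() == [False, False, False]

    def test_population_scope(self):
        flags = singleton_and_private(self._table(), scope="population")
        assert flags["singleton:SK"].tolist() == [True, False, False]
        summary = flags.attrs["summary"]
        assert summary["pct_singletons:SK"] == pytest.approx(50.0)  # 1 of 2 poly SK sites

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            singleton_and_private(self._table(), scope="chromosome")


class TestMafSpectrum:
    def test_folding(self):
        snps = snp_table(
            [100, 200],
            {
                "SK": ([10, 10], [0, 10], [9, 0]),  # p = 0.9, 0.5
                "WA": ([10, 10], [0, 0], [0, 0]),
            },
        )
        maf, density = maf_spectrum(snps, "SK", grid=np.linspace(0, 0.5, 11))
        assert maf.tolist() == [pytest.approx(0.1), pytest.approx(0.5)]
        assert density is not None and (density["density"] >= 0).all()

    def test_spectrum_tracks_generator_frequencies(self):
        """Median truth heterozygosity approaches the Hardy-Weinberg 2pq."""
        p = 0.3
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": 100 * np.arange(1, 401), "ref": "A", "alt": "G"}
        )
        model = PopulationModel(
            sites=sites, n_individuals={"P": 31}, freqs={"P": np.full(400, p)}
        )
        truth = simulate_genotypes(model, seed=3)
        het = (truth.gt == HET).mean(axis=1)
        assert abs(np.median(het) - 2 * p * (1 - p)) < 0.05
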