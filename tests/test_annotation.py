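import numpy as np
import pandas as pd
import pytest

from cpgdm.annotation import (
    assign_features,
    coverage_matched_background,
    enhancer_proximity,
    feature_enrichment,
    tss_distance_bins,
)
from cpgdm.bundle import AnnotationBundle, empty_track
from oracles import fisher_oracle


def track(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


@pytest.fixture
def toy_bundle():
    """One 100 kb chromosome; gene G1 (+) at [10000, 20000) with exon1
    [10000,11000) + exon2 [15000,16000); enhancer inside the intron; island
    far away; gene G2 (-) TSS at 49999."""
    genes = pd.DataFrame(
        {
            "gene_id": ["G1", "G2"],
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 40_000],
            "end": [20_000, 50_000],
            "strand": ["+", "-"],
            "gene_type": ["protein_coding"] * 2,
        }
    )
    exons = pd.DataFrame(
        {
            "gene_id": ["G1", "G1", "G2"],
            "transcript_id": ["G1.1", "G1.1", "G2.1"],
            "chrom": ["chr1"] * 3,
            "start": [10_000, 15_000, 40_000],
            "end": [11_000, 16_000, 50_000],
            "strand": ["+", "+", "-"],
            "exon_number": [1, 2, 1],
        }
    )
    return AnnotationBundle(
        chrom_sizes={"chr1": 100_000},
        genes=genes,
        exons=exons,
        enhancers=track([("chr1", 12_000, 13_000, "E1", 0.0, ".")]),
        cpg_islands=track([("chr1", 70_000, 71_000, "I1", 0.0, ".")]),
    )


def sites_at(positions):
    return pd.DataFrame({"chrom": "chr1", "pos": positions})


class TestAssignFeatures:
    def test_promoter_beats_exon(self, toy_bundle):
        out = assign_features(sites_at([10_100]), toy_bundle)
        assert out.loc[0, "primary_label"] == "promoter"

    def test_intronic_enhancer_keeps_intron_label(self, toy_bundle):
        out = assign_features(sites_at([12_500]), toy_bundle)
        assert out.loc[0, "primary_label"] == "intron"
        assert bool(out.loc[0, "enhancer_overlap"])

    def test_plain_exon(self, toy_bundle):
        out = assign_features(sites_at([15_500]), toy_bundle)
        assert out.loc[0, "primary_label"] == "exon"
        assert not bool(out.loc[0, "enhancer_overlap"])

    def test_island_and_intergenic(self, toy_bundle):
        out = assign_features(sites_at([70_500, 99_000]), toy_bundle)
        assert list(out["primary_label"]) == ["cpg_island", "intergenic"]

    def test_minus_strand_promoter_window(self, toy_bundle):
        # G2 TSS at 49,999 ('-'): promoter = signed distance in [-1500, 500)
        inside = assign_features(sites_at([50_500]), toy_bundle)  # d = -501
        assert inside.loc[0, "primary_label"] == "promoter"
        out = assign_features(sites_at([51_600]), toy_bundle)  # d = -1601
        assert out.loc[0, "primary_label"] == "intergenic"

    def test_unknown_chromosome_counted(self, toy_bundle):
        out = assign_features(
            pd.DataFrame({"chrom": ["chrX"], "pos": [5]}), toy_bundle
        )
        assert out.loc[0, "primary_label"] == "intergenic"
        assert out.attrs["n_unknown_chrom"] == 1

    def test_every_site_exactly_one_label(self, toy_bundle):
        rng = np.random.default_rng(0)
        out = assign_features(sites_at(sorted(rng.integers(0, 99_999, 500))), toy_bundle)
        assert out["primary_label"].notna().all()
        assert len(out) == 500


class TestTSSDistance:
    def test_upstream_of_plus_gene(self, toy_bundle):
        out = assign_features(sites_at([9_400]), toy_bundle)
        assert out.loc[0, "tss_distance"] == -600
        assert out.loc[0, "orientation"] == "upstream"
        assert out.loc[0, "nearest_gene"] == "G1"

    def test_minus_strand_flips_sign(self, toy_bundle):
        # site 600 bp left of G2's TSS (49,999) => downstream for a '-' gene
        out = assign_features(sites_at([49_399]), toy_bundle)
        assert out.loc[0, "tss_distance"] == 600
        assert out.loc[0, "orientation"] == "downstream"

    def test_equidistant_tie_goes_to_lower_gene_id(self, toy_bundle):
        # TSSs at 10,000 (G1) and 49,999 (G2): midpoint 29,999.5 -> use 30,000
        out = assign_features(sites_at([29_999, 30_000]), toy_bundle)
        assert out.loc[0, "nearest_gene"] == "G1"
        d1 = abs(30_000 - 10_000)
        d2 = abs(30_000 - 49_999)
        assert d1 != d2 or out.loc[1, "nearest_gene"] == "G1"

    def test_bins_sum_to_sites(self, toy_bundle):
        rng = np.random.default_rng(1)
        out = assign_features(sites_at(sorted(rng.integers(0, 99_999, 200))), toy_bundle)
        bins = tss_distance_bins(out)
        assert bins["count"].sum() == 200

    def test_small_distance_bin(self, toy_bundle):
        out = assign_features(sites_at([9_400]), toy_bundle)
        bins = tss_distance_bins(out)
        hit = bins[(bins["bin"] == "[0,1000)") & (bins["orientation"] == "upstream")]
        assert hit["count"].iloc[0] == 1

    def test_empty_gene_set_errors(self, toy_bundle):
        bundle = AnnotationBundle(
            chrom_sizes={"chr1": 100}, genes=toy_bundle.genes.iloc[:0],
            exons=toy_bundle.exons.iloc[:0],
        )
        out = assign_features(sites_at([50]), bundle)
        with pytest.raises(ValueError):
            tss_distance_bins(out)


class TestCoverageBackground:
    @staticmethod
    def _tested(n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(n) * 10,
             "coverage": rng.gamma(5, 4, size=n)}
        )

    def test_top_decile_query_gets_top_decile_background(self):
        tested = self._tested()
        top = np.argsort(tested["coverage"].to_numpy())[-20:]
        bg = coverage_matched_background(top, tested, seed=1)
        threshold = np.quantile(tested["coverage"], 0.9)
        assert (tested["coverage"].to_numpy()[bg] >= threshold - 1e-9).all()

    def test_degenerate_single_stratum(self):
        tested = self._tested()
        bg = coverage_matched_background([1, 2, 3], tested, n_strata=1, multiplier=1, seed=0)
        assert bg.size == 3

    def test_same_seed_identical(self):
        tested = self._tested()
        a = coverage_matched_background([5, 6, 7], tested, seed=9)
        b = coverage_matched_background([5, 6, 7], tested, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_stratum_proportions_preserved(self):
        tested = self._tested(5000)
        rng = np.random.default_rng(3)
        dm = rng.choice(5000, 200, replace=False)
        bg = coverage_matched_background(dm, tested, seed=2)
        qs = np.quantile(tested["coverage"], np.linspace(0, 1, 11))
        qs[0], qs[-1] = -np.inf, np.inf
        strata = np.searchsorted(qs, tested["coverage"], side="right") - 1
        for s in range(10):
            p_dm = (strata[dm] == s).mean()
            p_bg = (strata[bg] == s).mean()
            assert abs(p_dm - p_bg) <= 0.02

    def test_background_excludes_query(self):
        tested = self._tested()
        bg = coverage_matched_background([0, 1], tested, seed=0)
        assert not set(bg) & {0, 1}


class TestFeatureEnrichment:
    @staticmethod
    def _assignments(labels, enh=None):
        n = len(labels)
        return pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(n), "primary_label": labels,
             "enhancer_overlap": enh if enh is not None else [False] * n,
             "tss_distance": 0.0, "nearest_gene": "G1",
             "orientation": "downstream"}
        )

    def test_balanced_table_or_and_ci(self):
        labels = ["intron"] * 10 + ["exon"] * 10 + ["intron"] * 10 + ["exon"] * 10
        res = feature_enrichment(range(20), range(20, 40), self._assignments(labels))
        intron = next(r for r in res if r.label == "intron")
        assert intron.odds_ratio == pytest.approx(1.0)
        assert intron.ci_low == pytest.approx(0.290, abs=5e-4)
        assert intron.ci_high == pytest.approx(3.454, abs=5e-4)

    def test_small_table_matches_oracle(self):
        labels = ["intron"] * 3 + ["exon"] + ["intron"] + ["exon"] * 3
        res = feature_enrichment(range(4), range(4, 8), self._assignments(labels))
        intron = next(r for r in res if r.label == "intron")
        assert intron.odds_ratio == pytest.approx(9.0)
        assert intron.p == pytest.approx(fisher_oracle(3, 1, 1, 3), abs=1e-12)

    def test_zero_cell_finite_or(self):
        labels = ["exon"] * 4 + ["intron"] * 4
        res = feature_enrichment(range(4), range(4, 8), self._assignments(labels))
        intron = next(r for r in res if r.label == "intron")
        assert np.isfinite(intron.odds_ratio)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            feature_enrichment([], [1], self._assignments(["exon", "exon"]))


class TestEnhancerProximity:
    @staticmethod
    def _enhancers():
        return track([("chr1", 4_900, 5_100, "E1", 0.0, ".")])

    def test_overlap(self):
        out = enhancer_proximity(sites_at([5_000]), self._enhancers())
        assert out.loc[0, "relation"] == "overlap"
        assert out.loc[0, "enhancer_distance"] == 0

    def test_proximal_distance_respects_half_open_end(self):
        out = enhancer_proximity(sites_at([6_050]), self._enhancers())
        assert out.loc[0, "relation"] == "proximal"
        assert out.loc[0, "enhancer_distance"] == 951

    def test_no_enhancer_on_chromosome_is_distal_inf(self):
        out = enhancer_proximity(
            pd.DataFrame({"chrom": ["chr2"], "pos": [100]}), self._enhancers()
        )
        assert out.loc[0, "relation"] == "distal"
        assert np.isinf(out.loc[0, "enhancer_distance"])

    def test_associated_gene_is_nearest_to_enhancer(self, toy_bundle):
        out = enhancer_proximity(
            sites_at([12_500]), toy_bundle.enhancers, gene_models=toy_bundle.genes
        )
        assert out.loc[0, "associated_gene"] == "G1"
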