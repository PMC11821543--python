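import numpy as np
import pytest

from oracles import exhaustive_permutation_p, hypergeometric_fisher_p
from sdpanpop.io_formats import GenomeLayout, SDPair, ValidationError
from sdpanpop import sd_properties as sdp


def _pair(sa, ea, sb, eb, chrom_b="chr1", orientation="direct"):
    return SDPair("h1", "chr1", sa, ea, chrom_b, sb, eb, orientation,
                  0.95, ea - sa)


class TestClassifyPair:
    @pytest.mark.parametrize("gap,expected", [
        (500_000, "clustered"),
        (1_000_000, "clustered"),        # boundary: >1 Mb begins interspersed
        (1_000_001, "interspersed"),
        (10_000_000, "interspersed"),
        (50_000_000, "interspersed"),    # boundary: >50 Mb begins distant
        (50_000_001, "distant"),
        (60_000_000, "distant"),
    ])
    def test_dispersion_bands(self, gap, expected):
        cls = sdp.classify_pair(_pair(0, 2000, 2000 + gap, 4000 + gap))
        assert cls.dispersion == expected
        assert cls.gap_bp == gap

    def test_overlapping_mates_gap_zero(self):
        cls = sdp.classify_pair(_pair(0, 3000, 1500, 4500))
        assert cls.gap_bp == 0 and cls.dispersion == "clustered"

    def test_interchromosomal_has_no_gap(self):
        cls = sdp.classify_pair(_pair(0, 2000, 0, 2000, chrom_b="chr2",
                                      orientation="inverted"))
        assert cls.dispersion == "interchromosomal"
        assert cls.gap_bp is None
        assert cls.orientation == "inverted"


class TestRarityBand:
    @pytest.mark.parametrize("count,band", [
        (1, "rare"), (5, "rare"), (6, "common"), (20, "common"), (21, "other"),
    ])
    def test_bands(self, count, band):
        got, af = sdp.rarity_band(count, 170)
        assert got == band
        assert af == count / 170

    def test_five_of_170_is_below_three_percent(self):
        band, af = sdp.rarity_band(5, 170)
        assert band == "rare" and af < 0.03

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sdp.rarity_band(0, 170)
        with pytest.raises(ValidationError):
            sdp.rarity_band(171, 170)


class TestPermutationCompare:
    def test_identical_groups_near_half(self):
        a = np.arange(20.0)
        res = sdp.permutation_compare(a, a, n_perm=10_000, seed=5)
        assert 0.4 < res.p_value < 0.62

    def test_deterministic_under_seed(self):
        a, b = np.arange(15.0), np.arange(15.0) + 0.3
        r1 = sdp.permutation_compare(a, b, n_perm=500, seed=42)
        r2 = sdp.permutation_compare(a, b, n_perm=500, seed=42)
        assert r1.p_value == r2.p_value

    def test_exact_matches_enumeration(self):
        a, b = [10, 11, 12], [1, 2, 3]
        res = sdp.permutation_compare(a, b, n_perm=100, seed=0)
        oracle = exhaustive_permutation_p(
            a, b, lambda x, y: x.mean() - y.mean(), "auto")
        assert res.p_value == oracle == 1 / 20  # C(6,3) = 20 assignments

    @pytest.mark.parametrize("alternative", ["auto", "greater", "less", "two_sided"])
    def test_exact_matches_enumeration_random(self, rng, alternative):
        for _ in range(10):
            a = rng.normal(size=rng.integers(2, 5))
            b = rng.normal(size=rng.integers(2, 5))
            res = sdp.permutation_compare(a, b, n_perm=100, seed=1,
                                          alternative=alternative)
            oracle = exhaustive_permutation_p(
                a, b, lambda x, y: x.mean() - y.mean(), alternative)
            assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            sdp.permutation_compare([], [1.0], n_perm=100)


class TestProximityPermutation:
    LAYOUT = GenomeLayout({"c1": 5_000_000})

    def test_coincident_regions_give_minimal_p(self):
        known = [("c1", 1_000_000, 1_050_000), ("c1", 3_000_000, 3_040_000)]
        novel = [("c1", 1_010_000, 1_020_000), ("c1", 3_005_000, 3_015_000)]
        res = sdp.proximity_permutation(novel, known, self.LAYOUT,
                                        n_perm=199, seed=3)
        assert res.observed == 0
        assert res.p_value == 1 / 200

    def test_reproducible_under_seed(self):
        known = [("c1", 1_000_000, 1_050_000)]
        novel = [("c1", 4_000_000, 4_010_000)]
        r1 = sdp.proximity_permutation(novel, known, self.LAYOUT, n_perm=199, seed=9)
        r2 = sdp.proximity_permutation(novel, known, self.LAYOUT, n_perm=199, seed=9)
        assert r1.p_value == r2.p_value

    def test_region_longer_than_chromosome_rejected(self):
        layout = GenomeLayout({"c1": 10_000})
        with pytest.raises(ValidationError, match="does not fit"):
            sdp.proximity_permutation([("c1", 0, 10_500)],
                                      [("c1", 0, 100)], layout, n_perm=100, seed=0)
        # excluded intervals shrink the placement space
        layout2 = GenomeLayout({"c1": 10_000}, excluded=[("c1", 2_000, 9_500)])
        with pytest.raises(ValidationError, match="does not fit"):
            sdp.proximity_permutation([("c1", 0, 3_000)],
                                      [("c1", 0, 100)], layout2, n_perm=100, seed=0)


class TestEnrichment2x2:
    def test_example_table_matches_hypergeometric_enumeration(self):
        res = sdp.enrichment_2x2([[10, 5], [5, 10]])
        assert res.odds_ratio == 4.0
        assert res.p_value == pytest.approx(0.1431, abs=2e-4)
        assert res.p_value == pytest.approx(
            hypergeometric_fisher_p([[10, 5], [5, 10]]), abs=1e-9)

    def test_symmetric_table(self):
        res = sdp.enrichment_2x2([[5, 5], [5, 5]])
        assert res.odds_ratio == 1.0 and res.p_value == 1.0

    def test_zero_cell_continuity_corrected(self):
        res = sdp.enrichment_2x2([[1, 0], [0, 1]])
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            sdp.enrichment_2x2([[0, 0], [5, 5]])

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(25):
            t = rng.integers(1, 15, size=(2, 2))
            res = sdp.enrichment_2x2(t)
            assert res.p_value == pytest.approx(
                hypergeometric_fisher_p(t.tolist()), abs=1e-9)


def test_classification_partitions_pairs(small_cohort):
    """Every call-set pair lands in exactly one orientation × dispersion cell."""
    pairs = [p for v in small_cohort.pairs_by_hap.values() for p in v]
    cells = {}
    for p in pairs:
        cls = sdp.classify_pair(p)
        cells[(cls.orientation, cls.dispersion)] = (
            cells.get((cls.orientation, cls.dispersion), 0) + 1)
    assert sum(cells.values()) == len(pairs)
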