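import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bitvector_intersection_bp, bitvector_union, project_base_by_base
from sdpanpop.io_formats import AlignmentBlock, ValidationError
from sdpanpop import sd_catalog as sdc


FWD = AlignmentBlock("h1", "h1#chr1", 5000, 6000, "+", "chr1", 1000, 2000, "b0")
REV = AlignmentBlock("h1", "h1#chr1", 5000, 6000, "-", "chr1", 1000, 2000, "b0")


class TestProjectInterval:
    @pytest.mark.parametrize("block,interval,expected", [
        (FWD, (5100, 5200), ("chr1", 1100, 1200)),
        (REV, (5100, 5200), ("chr1", 1800, 1900)),
    ])
    def test_single_block_matches_per_base_oracle(self, block, interval, expected):
        projected, unplaced = sdc.project_interval("h1#chr1", *interval, [block])
        assert projected == [expected]
        assert unplaced == []
        assert project_base_by_base(*interval, block) == expected

    def test_partial_overlap_reports_unplaced(self):
        projected, unplaced = sdc.project_interval("h1#chr1", 4900, 5050, [FWD])
        assert projected == [("chr1", 1000, 1050)]
        assert unplaced == [100]

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValidationError, match="no alignment blocks"):
            sdc.project_interval("h9#chrX", 0, 10, [FWD])

    def test_round_trip_on_forward_blocks(self):
        projected, _ = sdc.project_interval("h1#chr1", 5100, 5400, [FWD])
        back = sdc.back_project_interval(*projected[0], [FWD])
        assert back == [("h1#chr1", 5100, 5400)]

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_projection_matches_per_base_oracle(self, data):
        """Random blocks, random intervals: pieces equal the base-by-base
        projection and lengths are conserved (projected + unplaced)."""
        n_blocks = data.draw(st.integers(1, 4))
        blocks, cursor, ref_cursor = [], 0, 0
        for k in range(n_blocks):
            cursor += data.draw(st.integers(0, 50))
            ref_cursor += data.draw(st.integers(0, 50))
            length = data.draw(st.integers(10, 200))
            strand = data.draw(st.sampled_from("+-"))
            blocks.append(AlignmentBlock(
                "h", "hc", cursor, cursor + length, strand,
                "rc", ref_cursor, ref_cursor + length, f"b{k}"))
            cursor += length
            ref_cursor += length
        start = data.draw(st.integers(0, cursor - 1))
        end = data.draw(st.integers(start + 1, cursor))
        projected, unplaced = sdc.project_interval("hc", start, end, blocks)
        oracle = [project_base_by_base(start, end, b) for b in blocks]
        oracle = [o for o in oracle if o is not None]
        assert sorted(projected) == sorted(oracle)
        assert sum(e - s for _, s, e in projected) + sum(unplaced) == end - start


class TestFlattenUnion:
    def test_overlapping_merge(self):
        merged, total = sdc.flatten_union(
            [("c", 100, 200), ("c", 150, 300), ("c", 500, 600)])
        assert merged == [("c", 100, 300), ("c", 500, 600)]
        assert total == 300

    def test_disjoint_unchanged(self):
        ivals = [("c", 0, 10), ("c", 20, 30), ("d", 5, 15)]
        merged, total = sdc.flatten_union(ivals)
        assert total == 30
        assert len(merged) == 3

    def test_empty(self):
        assert sdc.flatten_union([]) == ([], 0)

    @given(st.lists(
        st.tuples(st.sampled_from(["c1", "c2"]), st.integers(0, 3000),
                  st.integers(1, 400)),
        min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_matches_bitvector_oracle(self, raw):
        ivals = [(c, s, s + L) for c, s, L in raw]
        merged, total = sdc.flatten_union(ivals)
        o_merged, o_total = bitvector_union(ivals)
        assert total == o_total
        assert sorted(merged) == sorted(o_merged)
        # pairwise disjoint and sorted within chromosome
        for (c1, s1, e1), (c2, s2, e2) in zip(merged, merged[1:]):
            if c1 == c2:
                assert e1 < s2

    def test_inclusion_exclusion(self, rng):
        a = [("c", int(s), int(s) + int(L))
             for s, L in zip(rng.integers(0, 5000, 25), rng.integers(1, 300, 25))]
        b = [("c", int(s), int(s) + int(L))
             for s, L in zip(rng.integers(0, 5000, 25), rng.integers(1, 300, 25))]
        _, ua = sdc.flatten_union(a)
        _, ub = sdc.flatten_union(b)
        _, uab = sdc.flatten_union(a + b)
        inter = sdc.intersect_bp(a, b)
        assert uab == ua + ub - inter
        assert inter == bitvector_intersection_bp(a, b)


class TestPresenceAndClassification:
    def _regions(self):
        return pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1000]})

    @pytest.mark.parametrize("covered_to,expected", [
        (600, 1),   # coverage 0.6 >= 0.5
        (400, 0),   # coverage 0.4 < 0.5
        (500, 1),   # exactly at threshold: inclusive
    ])
    def test_coverage_threshold(self, toy_labels, covered_to, expected):
        pres = sdc.build_presence(
            self._regions(), {"S0_h1": [("c", 0, covered_to)]},
            toy_labels.haplotypes)
        assert pres[0, 0] == expected

    def test_unknown_haplotype_errors(self, toy_labels):
        with pytest.raises(ValidationError, match="not in cohort"):
            sdc.build_presence(self._regions(), {"nope": [("c", 0, 600)]},
                               toy_labels.haplotypes)

    def test_classification_rules(self, toy_labels):
        haps = toy_labels.haplotypes  # 6 haplotypes, 3 samples
        full = np.ones(6, dtype=np.int8)
        assert sdc.classify_frequency(full, True, haps, toy_labels) == "fixed"
        one_sample = np.array([1, 1, 0, 0, 0, 0], dtype=np.int8)
        assert sdc.classify_frequency(one_sample, False, haps, toy_labels) == "private"
        assert (sdc.classify_frequency(one_sample, True, haps, toy_labels)
                == "polymorphic_known")
        three_samples = np.array([1, 0, 1, 0, 1, 0], dtype=np.int8)
        assert (sdc.classify_frequency(three_samples, False, haps, toy_labels)
                == "polymorphic_novel")
        with pytest.raises(ValidationError):
            sdc.classify_frequency(np.zeros(6, dtype=np.int8), False, haps, toy_labels)

    def test_classes_partition_catalog(self, small_cohort):
        from sdpanpop.pipeline import project_pairs
        ivals, kinds, _, _ = project_pairs(small_cohort.pairs_by_hap,
                                           small_cohort.blocks_by_hap)
        cat = sdc.build_catalog(ivals, small_cohort.labels,
                                reference_sd=small_cohort.reference_sd,
                                per_hap_kinds=kinds)
        assert cat.class_counts().sum() == len(cat.regions)
        assert set(cat.regions["freq_class"]) <= {
            "fixed", "polymorphic_known", "polymorphic_novel", "private"}


class TestAccumulation:
    def _catalog(self, toy_labels):
        regions = pd.DataFrame({
            "chrom": ["c", "c"], "start": [0, 2000], "end": [1000, 2500],
            "freq_class": ["fixed", "private"],
            "kind": ["intrachromosomal", "intrachromosomal"],
        })
        presence = np.array([[1] * 6, [1, 0, 0, 0, 0, 0]], dtype=np.int8)
        return sdc.RegionCatalog(regions=regions, presence=presence,
                                 haplotypes=toy_labels.haplotypes)

    def test_identical_haplotypes_add_nothing(self, toy_labels):
        cat = self._catalog(toy_labels)
        table, summary = sdc.accumulation_curve(cat, labels=toy_labels)
        assert table["cumulative_bp"].is_monotonic_increasing
        assert summary["final_total_bp"] == 1500
        # region 1 is carried only by the first sample's first haplotype
        assert table["added_bp"].iloc[0] > 0

    def test_final_total_is_ordering_invariant(self, small_cohort):
        from sdpanpop.pipeline import project_pairs
        ivals, kinds, _, _ = project_pairs(small_cohort.pairs_by_hap,
                                           small_cohort.blocks_by_hap)
        cat = sdc.build_catalog(ivals, small_cohort.labels,
                                reference_sd=small_cohort.reference_sd,
                                per_hap_kinds=kinds)
        _, s1 = sdc.accumulation_curve(cat, labels=small_cohort.labels)
        reversed_order = list(reversed(cat.haplotypes))
        _, s2 = sdc.accumulation_curve(cat, ordering=reversed_order)
        assert s1["final_total_bp"] == s2["final_total_bp"] == cat.union_bp

    def test_bad_ordering_rejected(self, toy_labels):
        cat = self._catalog(toy_labels)
        with pytest.raises(ValidationError, match="permutation"):
            sdc.accumulation_curve(cat, ordering=["S0_h1"])
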