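import numpy as np
import pandas as pd
import pytest

from sdpanpop import io_formats as iof
from sdpanpop.synthetic_data import (
    SimConfig,
    simulate_cohort,
    simulate_depth,
    simulate_isoseq,
    simulate_pair_table,
    write_cohort,
)


class TestDeterminism:
    def test_same_seed_byte_identical(self, small_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(small_config, seed=3, out_dir=d1)
        simulate_cohort(small_config, seed=3, out_dir=d2)
        for name in ("sd_pairs.tsv", "alignment_blocks.tsv", "labels.tsv",
                     "reference_sd.bed", "hits.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seed_differs(self, small_config):
        c1 = simulate_cohort(small_config, seed=3)
        c2 = simulate_cohort(small_config, seed=4)
        assert not c1.truth.regions.equals(c2.truth.regions)


class TestCohortStructure:
    def test_haplotype_and_sample_counts(self):
        config = SimConfig.small()  # 5 samples -> 10 haplotypes
        cohort = simulate_cohort(config, seed=1)
        assert len(cohort.labels.haplotypes) == 10
        assert len(cohort.labels.samples) == 5
        assert len(cohort.labels.afr_samples()) == 2

    def test_emitted_files_validate(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        pairs, dropped = iof.read_sd_pairs(tmp_path / "sd_pairs.tsv",
                                           frame="assembly")
        assert dropped == 0 and len(pairs) > 0
        blocks = iof.read_alignment_blocks(tmp_path / "alignment_blocks.tsv")
        assert set(blocks) == set(small_cohort.labels.haplotypes)
        iof.read_labels(tmp_path / "labels.tsv")
        iof.validate_bed_output(tmp_path / "reference_sd.bed")

    def test_truth_consistency(self, small_cohort):
        truth = small_cohort.truth
        # family CN equals the sum of member gene CNs
        fam = truth.cn_gene.groupby(
            [small_cohort.families[g] for g in truth.cn_gene.index]).sum()
        pd.testing.assert_frame_equal(fam, truth.cn_family, check_names=False)
        # truth regions are pairwise disjoint
        regions = truth.regions.sort_values(["chrom", "start"])
        for (_, r1), (_, r2) in zip(regions.iterrows(), regions.iloc[1:].iterrows()):
            if r1["chrom"] == r2["chrom"]:
                assert r1["end"] <= r2["start"]

    def test_rare_regions_longer_and_more_identical(self):
        """The configured rare-vs-common length/identity shift is visible in
        the drawn pair table."""
        pt = simulate_pair_table(SimConfig(), seed=2)
        poly = pt[pt["carrier_count"] < SimConfig().n_haplotypes]
        rare = poly[poly["carrier_count"] <= 5]
        common = poly[(poly["carrier_count"] >= 6) & (poly["carrier_count"] <= 20)]
        assert rare["length"].median() > common["length"].median()
        assert rare["identity"].median() > common["identity"].median()

    def test_afr_intrachromosomal_excess_matches_configured_effect(self):
        """Mean AFR − non-AFR intrachromosomal bp per haplotype is within
        20% of the configured effect (averaged over seeds)."""
        config = SimConfig(n_sd_pairs=120)  # lighter spectrum, same AFR effect
        diffs = []
        for seed in range(8):
            cohort = simulate_cohort(config, seed=seed)
            per_hap = {}
            for hap, pairs in cohort.pairs_by_hap.items():
                per_hap[hap] = sum(
                    (p.end_a - p.start_a) + (p.end_b - p.start_b)
                    for p in pairs if p.intrachromosomal)
            afr = [per_hap[h] for h in per_hap
                   if cohort.labels.is_afr_hap(h)]
            non = [per_hap[h] for h in per_hap
                   if not cohort.labels.is_afr_hap(h)]
            diffs.append(np.mean(afr) - np.mean(non))
        effect = config.afr_intra_effect_bp
        assert abs(np.mean(diffs) - effect) < 0.2 * effect

    def test_layout_too_small_errors(self):
        config = SimConfig(chrom_lengths={"c1": 100_000, "c2": 100_000},
                           n_sd_pairs=500)
        with pytest.raises(iof.ValidationError):
            simulate_cohort(config, seed=0)


class TestDepth:
    def test_flat_depth_without_bias_or_noise(self, small_config):
        config = SimConfig.small()
        config.gc_bias_strength = 0.0
        cohort = simulate_cohort(config, seed=6)
        depth = simulate_depth(cohort, seed=7)
        # self sample is noiseless: outside genes/repeats it sits at coverage
        from sdpanpop.sd_catalog import coverage_within
        in_unique = coverage_within(depth.self_depth, depth.unique_regions) >= 1.0
        vals = depth.self_depth.loc[in_unique, "depth"]
        assert np.allclose(vals, config.coverage)

    def test_cn4_windows_double_depth(self, small_cohort):
        depth = simulate_depth(small_cohort, seed=8)
        truth = small_cohort.truth
        sample = next(iter(depth.sample_depth))
        tab = depth.sample_depth[sample]
        cn4_genes = truth.cn_gene.index[truth.cn_gene[sample] == 4]
        genes = small_cohort.genes.set_index("gene_id")
        sel = []
        for g in cn4_genes:
            row = genes.loc[g]
            mask = ((tab["chrom"] == row["chrom"]) & (tab["start"] >= row["start"])
                    & (tab["end"] <= row["end"]))
            if row["attenuation"] == 1.0:
                sel.append(tab.loc[mask, "depth"])
        assert sel, "no unattenuated CN=4 gene in this draw"
        mean_cn4 = pd.concat(sel).mean()
        assert mean_cn4 == pytest.approx(2 * small_cohort.config.coverage, rel=0.15)

    def test_deterministic(self, small_cohort):
        d1 = simulate_depth(small_cohort, seed=9)
        d2 = simulate_depth(small_cohort, seed=9)
        for s in d1.sample_depth:
            pd.testing.assert_frame_equal(d1.sample_depth[s], d2.sample_depth[s])


class TestIsoSeq:
    def test_zero_planted_zero_passing(self):
        config = SimConfig.small()
        config.n_planted_families = 0
        cohort = simulate_cohort(config, seed=10)
        alignments, predictions = simulate_isoseq(cohort, seed=11)
        from sdpanpop.isoseq_novel import filter_alignments
        per_read = filter_alignments(alignments)
        assert per_read["divergent"].sum() == 0
        assert len(predictions) == 0

    def test_deterministic(self, small_cohort):
        a1, _ = simulate_isoseq(small_cohort, seed=12)
        a2, _ = simulate_isoseq(small_cohort, seed=12)
        pd.testing.assert_frame_equal(a1, a2)
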