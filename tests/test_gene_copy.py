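import numpy as np
import pandas as pd
import pytest

from sdpanpop import gene_copy as gc
from sdpanpop.io_formats import ValidationError


def _hits(rows):
    base = dict(target_chrom="c", target_start=0, target_end=1000,
                coverage=0.9, identity=0.98, repeat_overlap=0.1,
                cds_bp=1000, distance_to_break=100_000)
    return pd.DataFrame([{**base, **r} for r in rows], columns=gc.HIT_COLUMNS)


class TestFilterHits:
    @pytest.mark.parametrize("field,value,kept", [
        ("coverage", 0.55, False), ("coverage", 0.60, False), ("coverage", 0.601, True),
        ("identity", 0.89, False), ("identity", 0.90, False), ("identity", 0.901, True),
        ("cds_bp", 150, False), ("cds_bp", 199, False), ("cds_bp", 200, True),
        ("repeat_overlap", 1.0, False), ("repeat_overlap", 0.99, True),
    ])
    def test_threshold_boundaries(self, field, value, kept):
        hits = _hits([{"gene_id": "g", "haplotype_id": "h", field: value}])
        retained, tally = gc.filter_hits(hits)
        assert (len(retained) == 1) is kept
        if not kept:
            assert sum(tally.values()) == 1

    @pytest.mark.parametrize("dist,kept", [(29_999, False), (30_000, True)])
    def test_break_flank_only_when_enabled(self, dist, kept):
        hits = _hits([{"gene_id": "g", "haplotype_id": "h",
                       "distance_to_break": dist}])
        retained, _ = gc.filter_hits(hits, flank_filter=True)
        assert (len(retained) == 1) is kept
        retained_off, _ = gc.filter_hits(hits, flank_filter=False)
        assert len(retained_off) == 1

    def test_idempotent_and_monotone(self, rng):
        hits = _hits([
            {"gene_id": f"g{i}", "haplotype_id": "h",
             "coverage": float(c), "identity": float(idn), "cds_bp": int(cds)}
            for i, (c, idn, cds) in enumerate(zip(
                rng.uniform(0.4, 1.0, 40), rng.uniform(0.85, 1.0, 40),
                rng.integers(100, 2000, 40)))
        ])
        once, _ = gc.filter_hits(hits)
        twice, _ = gc.filter_hits(once)
        pd.testing.assert_frame_equal(once, twice)
        relaxed, _ = gc.filter_hits(hits, min_coverage=0.3, min_identity=0.8,
                                    min_cds_bp=50)
        assert len(relaxed) >= len(once)
        assert set(once["gene_id"]) <= set(relaxed["gene_id"])


class TestAssemblyCopyNumber:
    def test_diploid_counts_match_hand_computation(self, toy_labels):
        # S0: 2 hits on each haplotype of gA -> CN 4; S1: one hit on h1 -> 1
        rows = []
        for hap in ("S0_h1", "S0_h2"):
            rows += [{"gene_id": "gA", "haplotype_id": hap}] * 2
        rows.append({"gene_id": "gA", "haplotype_id": "S1_h1"})
        rows.append({"gene_id": "gB", "haplotype_id": "S2_h2"})
        mat = gc.assembly_copy_number(_hits(rows), toy_labels)
        assert mat.values.loc["gA", "S0"] == 4
        assert mat.values.loc["gA", "S1"] == 1
        assert mat.values.loc["gA", "S2"] == 0
        assert mat.values.loc["gB", "S2"] == 1

    def test_single_haplotype_duplication_flagged(self, toy_labels):
        rows = [{"gene_id": "gA", "haplotype_id": "S0_h1"}] * 3
        rows += [{"gene_id": "gA", "haplotype_id": h} for h in
                 ("S0_h2", "S1_h1", "S1_h2", "S2_h1", "S2_h2")]
        mat = gc.assembly_copy_number(_hits(rows), toy_labels)
        assert list(mat.excluded_units["unit_id"]) == ["gA"]
        kept = gc.assembly_copy_number(_hits(rows), toy_labels,
                                       exclude_single_haplotype=False)
        assert len(kept.excluded_units) == 0

    def test_family_conservation(self, toy_labels, rng):
        genes = [f"g{i}" for i in range(6)]
        families = {g: f"F{i % 2}" for i, g in enumerate(genes)}
        rows = []
        for g in genes:
            for hap in toy_labels.haplotypes:
                rows += [{"gene_id": g, "haplotype_id": hap}] * int(rng.integers(0, 3))
        mat = gc.assembly_copy_number(_hits(rows), toy_labels,
                                      exclude_single_haplotype=False)
        fam = gc.family_copy_number(mat, families)
        for f in fam.values.index:
            members = [g for g in genes if families[g] == f and g in mat.values.index]
            expected = mat.values.loc[members].sum(axis=0)
            assert (fam.values.loc[f] == expected).all()


class TestDispersionIndex:
    def test_constant_is_zero(self):
        assert gc.dispersion_index([4, 4, 4, 4]) == 0.0

    def test_hand_example(self):
        assert gc.dispersion_index([2, 4, 6]) == 1.0  # var 4 (n-1), mean 4

    def test_scaling_property(self, rng):
        v = rng.integers(1, 10, size=30).astype(float)
        c = 3.7
        assert gc.dispersion_index(c * v) == pytest.approx(
            c * gc.dispersion_index(v), rel=1e-12)

    def test_agrees_with_two_pass(self, rng):
        v = rng.uniform(1, 20, size=50)
        mean = sum(v) / len(v)
        var = sum((x - mean) ** 2 for x in v) / (len(v) - 1)
        assert gc.dispersion_index(v) == pytest.approx(var / mean, rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            gc.dispersion_index([0, 0, 0])


class TestRankFamilies:
    def _matrix(self, values):
        df = pd.DataFrame(values).T
        df.columns = [f"S{i}" for i in range(df.shape[1])]
        return gc.CopyNumberMatrix(values=df.astype(float), unit="family",
                                   method="assembly")

    def test_ordering_and_mean_cn_filter(self):
        mat = self._matrix({
            "FA": [4, 6, 8, 2],      # variable, mean 5
            "FB": [4, 4, 4, 4],      # constant, mean 4
            "FC": [2, 3, 3, 3.6],    # mean 2.9 -> excluded
        })
        with pytest.warns(UserWarning):
            most, least = gc.rank_families(mat, top_k=25)
        assert list(most["family_id"]) == ["FA", "FB"]
        assert list(least["family_id"]) == ["FB", "FA"]
        assert "FC" not in set(most["family_id"])

    def test_ranking_matches_independent_sort(self, rng):
        values = {f"F{i:02d}": rng.integers(1, 12, size=20).astype(float) + 3
                  for i in range(30)}
        mat = self._matrix(values)
        most, least = gc.rank_families(mat, top_k=30)
        oracle = sorted(
            ((np.var(v, ddof=1) / np.mean(v), f) for f, v in values.items()
             if np.mean(v) > 3.0),
            key=lambda t: (-t[0], t[1]))
        assert list(most["family_id"]) == [f for _, f in oracle]
        assert list(least["family_id"]) == [f for _, f in oracle[::-1]]
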