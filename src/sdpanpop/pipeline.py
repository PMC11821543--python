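"""End-to-end orchestration: simulate → catalog → properties → genecn →
depthcn → popdiff → isofilter, with a consolidated run report.

Every number in the report is recomputed from the stage outputs it cites;
re-running with the same seed and configuration reproduces the report
bit-exactly.  Stage failures abort with the stage name; completed stages
are recorded in a MANIFEST file so partial outputs remain interpretable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gene_copy, io_formats, isoseq_novel, pop_stats, read_depth_cn
from . import sd_catalog, sd_properties
from .synthetic_data import SimConfig, SimulatedCohort, simulate_cohort, simulate_depth, simulate_isoseq

log = logging.getLogger("sdpanpop")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    seed: int
    config_digest: str
    headline: dict = field(default_factory=dict)
    stage_outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "config_digest": self.config_digest,
                       "headline": self.headline,
                       "stage_outputs": self.stage_outputs}, fh, indent=2,
                      default=float)


def _digest(config: SimConfig) -> str:
    payload = json.dumps(config.__dict__, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def project_pairs(
    pairs_by_hap: dict[str, list[io_formats.SDPair]],
    blocks_by_hap: dict[str, list[io_formats.AlignmentBlock]],
):
    """Project every call-set pair to the reference frame.

    Returns (per_hap_intervals, per_hap_kinds, per_hap_pair_loci,
    unplaced_df): reference-frame intervals per haplotype with their
    intra/interchromosomal kind tags, the projected (mate A, mate B) locus
    pair per record (None for an unplaceable mate), and the side table of
    unplaced fragment lengths.
    """
    per_hap_intervals: dict[str, list] = {}
    per_hap_kinds: dict[str, list] = {}
    per_hap_loci: dict[str, list] = {}
    unplaced_rows = []
    for hap, pairs in pairs_by_hap.items():
        blocks = blocks_by_hap.get(hap, [])
        ivals, kinds, loci = [], [], []
        for pair in pairs:
            kind = ("intrachromosomal" if pair.intrachromosomal
                    else "interchromosomal")
            mates = []
            for chrom, s, e in ((pair.chrom_a, pair.start_a, pair.end_a),
                                (pair.chrom_b, pair.start_b, pair.end_b)):
                pieces, unplaced = sd_catalog.project_interval(chrom, s, e, blocks)
                for piece in pieces:
                    ivals.append(piece)
                    kinds.append(kind)
                for length in unplaced:
                    unplaced_rows.append({"haplotype_id": hap, "length": length})
                mates.append(max(pieces, key=lambda p: p[2] - p[1]) if pieces else None)
            loci.append((pair, mates[0], mates[1]))
        per_hap_intervals[hap] = ivals
        per_hap_kinds[hap] = kinds
        per_hap_loci[hap] = loci
    unplaced_df = pd.DataFrame(unplaced_rows, columns=["haplotype_id", "length"])
    return per_hap_intervals, per_hap_kinds, per_hap_loci, unplaced_df


def dedupe_pair_loci(per_hap_loci, catalog: sd_catalog.RegionCatalog) -> pd.DataFrame:
    """Collapse per-haplotype pair records onto distinct pair loci.

    Orientation is a property of the duplication event shared by all its
    carriers, so enrichment statistics must not count one event once per
    carrier.  Records are keyed by the catalog regions their projected
    mates fall in (maximum-overlap assignment); one representative record
    per key is kept, along with the carrier count.
    """
    regions = catalog.regions
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, (c, s, e) in enumerate(zip(regions["chrom"], regions["start"], regions["end"])):
        by_chrom.setdefault(c, []).append((s, e, i))
    for c in by_chrom:
        by_chrom[c].sort()

    def region_of(locus) -> int | None:
        if locus is None:
            return None
        chrom, s, e = locus
        best, best_ov = None, 0
        for rs, re, idx in by_chrom.get(chrom, []):
            if rs >= e:
                break
            ov = min(re, e) - max(rs, s)
            if ov > best_ov:
                best, best_ov = idx, ov
        return best

    groups: dict[tuple, dict] = {}
    for hap, loci in per_hap_loci.items():
        for pair, locus_a, locus_b in loci:
            key = tuple(sorted((str(region_of(locus_a)), str(region_of(locus_b)))))
            g = groups.setdefault(key, {"pair": pair, "carriers": 0})
            g["carriers"] += 1
    rows = []
    for key, g in groups.items():
        cls = sd_properties.classify_pair(g["pair"])
        rows.append({
            "locus_key": "|".join(key),
            "orientation": cls.orientation,
            "dispersion": cls.dispersion,
            "gap_bp": cls.gap_bp,
            "identity": g["pair"].identity,
            "length": g["pair"].length,
            "carrier_count": g["carriers"],
        })
    return pd.DataFrame(rows)


def inversion_enrichment(pair_table: pd.DataFrame) -> sd_properties.EnrichmentResult:
    """2×2 inversion × (interspersed vs clustered) enrichment over distinct
    pair loci."""
    inter = pair_table[pair_table["dispersion"] == "interspersed"]
    clust = pair_table[pair_table["dispersion"] == "clustered"]
    table = [
        [int((inter["orientation"] == "inverted").sum()),
         int((inter["orientation"] == "direct").sum())],
        [int((clust["orientation"] == "inverted").sum()),
         int((clust["orientation"] == "direct").sum())],
    ]
    return sd_properties.enrichment_2x2(table)


def run_pipeline(
    config: SimConfig,
    seed: int,
    out_dir: str | os.PathLike,
    n_perm: int = 2_000,
) -> RunReport:
    """Run every stage in dependency order and write the consolidated
    report (JSON + human-readable summary) plus a MANIFEST of completed
    stages."""
    os.makedirs(out_dir, exist_ok=True)
    report = RunReport(seed=seed, config_digest=_digest(config))
    manifest_path = os.path.join(out_dir, "MANIFEST")
    completed: list[str] = []

    def stage(name: str):
        def decorator(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                with open(manifest_path, "w") as fh:
                    fh.write("\n".join(completed) + f"\nFAILED:{name}\n")
                raise StageError(name, exc) from exc
            elapsed = time.perf_counter() - t0
            log.info("stage=%s seed=%d elapsed=%.2fs", name, seed, elapsed)
            completed.append(name)
            return result
        return decorator

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=8)

    @stage("simulate")
    def cohort() -> SimulatedCohort:
        return simulate_cohort(config, int(sub_seeds[0]),
                               os.path.join(out_dir, "cohort"))

    @stage("catalog")
    def catalog_result():
        ivals, kinds, loci, unplaced = project_pairs(
            cohort.pairs_by_hap, cohort.blocks_by_hap
        )
        catalog = sd_catalog.build_catalog(
            ivals, cohort.labels, reference_sd=cohort.reference_sd,
            per_hap_kinds=kinds, unplaced=unplaced,
        )
        io_formats.write_region_catalog(
            catalog,
            os.path.join(out_dir, "catalog.bed"),
            os.path.join(out_dir, "catalog_presence.tsv"),
        )
        curve, curve_summary = sd_catalog.accumulation_curve(catalog, labels=cohort.labels)
        io_formats.write_tsv(curve, os.path.join(out_dir, "accumulation.tsv"))
        return catalog, loci, curve_summary

    catalog, loci, curve_summary = catalog_result

    @stage("properties")
    def properties():
        pair_table = dedupe_pair_loci(loci, catalog)
        io_formats.write_tsv(pair_table, os.path.join(out_dir, "pair_classes.tsv"))
        enr = inversion_enrichment(pair_table)
        # rare vs common contrasts on distinct polymorphic pair loci
        bands = [
            sd_properties.rarity_band(c, len(catalog.haplotypes))[0]
            for c in pair_table["carrier_count"]
        ]
        pair_table = pair_table.assign(band=bands)
        rare = pair_table[pair_table["band"] == "rare"]
        common = pair_table[pair_table["band"] == "common"]
        stats = {}
        if len(rare) and len(common):
            for col in ("length", "identity"):
                res = sd_properties.permutation_compare(
                    rare[col].to_numpy(), common[col].to_numpy(),
                    n_perm=n_perm, seed=int(sub_seeds[1]),
                    alternative="greater",
                )
                stats[f"rare_vs_common_{col}_p"] = res.p_value
        novel = catalog.regions[
            catalog.regions["freq_class"] == "polymorphic_novel"
        ][["chrom", "start", "end"]].itertuples(index=False)
        prox = sd_properties.proximity_permutation(
            list(novel), cohort.reference_sd, cohort.layout,
            n_perm=n_perm, seed=int(sub_seeds[2]),
        )
        return {
            "inversion_or": enr.odds_ratio,
            "inversion_p": enr.p_value,
            "proximity_p": prox.p_value,
            **stats,
        }

    @stage("genecn")
    def genecn():
        retained, tally = gene_copy.filter_hits(cohort.hits)
        gene_cn = gene_copy.assembly_copy_number(retained, cohort.labels,
                                                 exclude_single_haplotype=False)
        family_cn = gene_copy.family_copy_number(gene_cn, cohort.families)
        io_formats.write_tsv(gene_cn.values, os.path.join(out_dir, "gene_cn.tsv"),
                             index=True)
        io_formats.write_tsv(family_cn.values, os.path.join(out_dir, "family_cn.tsv"),
                             index=True)
        most, least = gene_copy.rank_families(family_cn, top_k=10)
        io_formats.write_tsv(most, os.path.join(out_dir, "families_most_variable.tsv"))
        io_formats.write_tsv(least, os.path.join(out_dir, "families_least_variable.tsv"))
        return gene_cn, family_cn, tally, most

    gene_cn, family_cn, hit_tally, most_variable = genecn

    @stage("depthcn")
    def depthcn():
        depth = simulate_depth(cohort, int(sub_seeds[3]),
                               os.path.join(out_dir, "depth"))
        self_flagged = read_depth_cn.exclude_windows(depth.self_depth, depth.repeats)
        model = read_depth_cn.gc_recalibrate(self_flagged)
        baseline_self = read_depth_cn.baseline_from_regions(
            self_flagged, model, depth.unique_regions
        )
        self_cn = read_depth_cn.window_cn(self_flagged, model, baseline_self)
        genes = cohort.genes[["gene_id", "chrom", "start", "end"]]
        self_gene_cn = read_depth_cn.gene_cn_from_windows(genes, self_cn)
        # calibration: the self sample is reference-matched with known CN 2
        assembly_truth = pd.Series(2.0, index=self_gene_cn.index)
        adjust = read_depth_cn.calibrate_adjustment(self_gene_cn, assembly_truth)
        excl = depth.sample_depth and read_depth_cn.exclude_windows(
            next(iter(depth.sample_depth.values())), depth.repeats
        )["excluded"]
        rd_cols = {}
        for sample, tab in depth.sample_depth.items():
            flagged = tab.copy()
            flagged["excluded"] = excl.to_numpy()
            cn_tab = read_depth_cn.window_cn(flagged, model, baseline_self)
            rd_cols[sample] = read_depth_cn.gene_cn_from_windows(genes, cn_tab)
        rd_matrix = pd.DataFrame(rd_cols)
        rd_matrix = read_depth_cn.apply_adjustment(rd_matrix, adjust)
        io_formats.write_tsv(rd_matrix, os.path.join(out_dir, "read_depth_gene_cn.tsv"),
                             index=True)
        r2 = read_depth_cn.concordance_r2(gene_cn.values, rd_matrix)
        return rd_matrix, adjust, r2

    rd_matrix, adjust_table, r2 = depthcn

    @stage("popdiff")
    def popdiff():
        primary = pop_stats.cn_differentiation(family_cn, cohort.labels)
        rd_family = rd_matrix.groupby(
            [cohort.families[g] for g in rd_matrix.index]
        ).sum()
        rd_cnm = gene_copy.CopyNumberMatrix(values=rd_family, unit="family",
                                            method="read_depth")
        secondary = pop_stats.cn_differentiation(rd_cnm, cohort.labels)
        replicated = pop_stats.replication(primary, secondary)
        io_formats.write_tsv(primary.results, os.path.join(out_dir, "popdiff.tsv"))
        io_formats.write_tsv(replicated, os.path.join(out_dir, "popdiff_replication.tsv"))
        return primary, replicated

    primary_diff, replicated = popdiff

    @stage("isofilter")
    def isofilter():
        alignments, predictions = simulate_isoseq(cohort, int(sub_seeds[4]),
                                                  os.path.join(out_dir, "isoseq"))
        per_read = isoseq_novel.filter_alignments(alignments)
        io_formats.write_tsv(per_read, os.path.join(out_dir, "isoseq_filter.tsv"))
        passing = predictions[predictions["read_id"].isin(
            per_read[per_read["divergent"]]["read_id"]
        )]
        counts, total = isoseq_novel.count_novel_families(passing)
        return {"novel_family_counts": counts.to_dict(), "novel_gene_total": total,
                "n_divergent_reads": int(per_read["divergent"].sum())}

    class_counts = catalog.class_counts().to_dict()
    report.headline = {
        "union_bp": catalog.union_bp,
        "n_regions": len(catalog.regions),
        "class_counts": class_counts,
        "mean_increment_bp": curve_summary["mean_increment_bp"],
        "regression_slope_bp_per_genome": curve_summary["regression_slope_bp_per_genome"],
        **properties,
        "hit_rejections": hit_tally,
        "top_variable_families": most_variable["family_id"].tolist()[:5],
        "concordance_r2": r2,
        "n_adjustment_excluded": int(adjust_table["excluded"].sum()),
        "n_eligible_families": primary_diff.n_eligible,
        "n_significant_families": primary_diff.n_significant,
        "n_afr_higher": primary_diff.n_afr_higher,
        "direction_binomial_p": primary_diff.direction_binomial_p,
        "n_replicated": int(replicated["replicated"].sum()) if len(replicated) else 0,
        **isofilter,
    }
    report.stage_outputs = {
        "catalog_bed": os.path.join(out_dir, "catalog.bed"),
        "pair_classes": os.path.join(out_dir, "pair_classes.tsv"),
        "gene_cn": os.path.join(out_dir, "gene_cn.tsv"),
        "read_depth_gene_cn": os.path.join(out_dir, "read_depth_gene_cn.tsv"),
        "popdiff": os.path.join(out_dir, "popdiff.tsv"),
    }
    report.to_json(os.path.join(out_dir, "report.json"))
    _write_summary(report, os.path.join(out_dir, "report.txt"))
    with open(manifest_path, "w") as fh:
        fh.write("\n".join(completed) + "\n")
    return report


def _write_summary(report: RunReport, path) -> None:
    h = report.headline
    lines = [
        f"seed {report.seed}  config {report.config_digest}",
        f"SD regions: {h['n_regions']} covering {h['union_bp']:,} bp",
        "class counts: " + ", ".join(f"{k}={v}" for k, v in h["class_counts"].items()),
        f"mean per-genome increment: {h['mean_increment_bp']:.1f} bp "
        f"(regression slope {h['regression_slope_bp_per_genome']:.1f})",
        f"interspersed inversion OR: {h['inversion_or']:.2f} (P={h['inversion_p']:.3g})",
        f"novel-SD proximity P: {h['proximity_p']:.4g}",
        f"assembly vs read-depth CN R^2: {h['concordance_r2']:.3f}",
        f"differentiated families: {h['n_significant_families']} of "
        f"{h['n_eligible_families']} eligible; AFR higher in {h['n_afr_higher']} "
        f"(binomial P={h['direction_binomial_p']})",
        f"replicated in read-depth cohort: {h['n_replicated']}",
        f"novel genes (Iso-Seq): {h['novel_gene_total']} from "
        f"{len(h['novel_family_counts'])} families",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
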