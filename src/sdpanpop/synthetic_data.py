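"""Synthetic cohort generator.

Emulates the statistical structure of a pangenome SD survey over a toy
genome (three chromosomes, ~30 Mb by default, holding 1–100 kb SDs):

* a configurable SD frequency spectrum (fixed / polymorphic / private)
  over a cohort of H haplotypes (default 170: 76 African + 94 non-African
  haplotypes, i.e. 38 + 47 samples);
* rare SDs (≤ 5 carriers) drawn longer and with higher pair identity than
  common ones;
* an African excess of intrachromosomal SD content, realised as extra
  AFR-biased intrachromosomal duplications with a configured expected
  per-haplotype bp effect;
* an inversion bias among interspersed pairs (default odds ratio 2.0
  relative to clustered pairs);
* gene families with per-sample diploid copy-number truth, a subset
  shifted upward in African samples;
* GC-biased, overdispersed windowed read depth conditioned on true copy
  number, plus a noiseless "self sample" for GC recalibration and
  adjustment-factor calibration;
* Iso-Seq alignment summaries with a planted reference-divergent read set.

Call sets are emitted in assembly coordinates together with 1-to-1
alignment blocks (with indel offsets and one reverse-strand block per
chromosome), so interval projection is exercised on every run.  The
ground truth against which recovery is tested is returned as a
:class:`TruthSet`.
"""

from __future__ import annotations

import bisect
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    AlignmentBlock,
    GenomeLayout,
    PopulationLabels,
    SDPair,
    ValidationError,
    write_alignment_blocks,
    write_bed,
    write_labels,
    write_layout,
    write_sd_pairs,
    write_tsv,
)
from .sd_catalog import back_project_interval, flatten_union


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the 170-haplotype cohort structure (38 African and 47
    non-African samples) on a 30 Mb three-chromosome toy genome.
    """

    # cohort
    n_afr_samples: int = 38
    n_nonafr_samples: int = 47

    # genome layout
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12_000_000, "chr2": 10_000_000, "chr3": 8_000_000}
    )
    excluded: list[tuple[str, int, int]] = field(default_factory=list)

    # SD pairs and frequency spectrum
    n_sd_pairs: int = 240
    frac_fixed: float = 0.25
    frac_polymorphic: float = 0.55
    frac_private: float = 0.20
    frac_known_among_polymorphic: float = 0.5
    carrier_mix: tuple[float, float, float] = (0.40, 0.35, 0.25)  # rare / common / higher

    # dispersion classes and orientation
    frac_clustered: float = 0.55
    frac_interspersed: float = 0.30
    frac_distant: float = 0.0        # a 30 Mb toy genome cannot host >50 Mb gaps
    frac_interchromosomal: float = 0.15
    clustered_inverted_prob: float = 0.20
    interspersed_inversion_odds: float = 2.0
    interchromosomal_inverted_prob: float = 0.25

    # length / identity distributions (log-normal lengths, bp)
    rare_log_length_mean: float = 9.0
    rare_log_length_sd: float = 0.5
    base_log_length_mean: float = 8.3
    base_log_length_sd: float = 0.4
    min_length: int = 1_300
    max_length: int = 100_000
    rare_divergence_mean: float = 0.012
    rare_divergence_sd: float = 0.004
    base_divergence_mean: float = 0.035
    base_divergence_sd: float = 0.010
    boundary_jitter_bp: int = 100

    # African intrachromosomal excess
    n_afr_regions: int = 30
    afr_region_length: int = 10_000
    afr_carrier_prob: float = 0.5

    # gene families and copy number
    n_families: int = 50
    max_genes_per_family: int = 3
    n_shifted_families: int = 10
    afr_shift: float = 0.6           # AFR haplotype rate multiplier 1 + shift
    gene_length_range: tuple[int, int] = (8_000, 16_000)
    hap_rate_range: tuple[float, float] = (0.6, 2.0)
    shifted_hap_rate_range: tuple[float, float] = (1.2, 2.0)
    max_hap_copies: int = 6

    # read depth
    coverage: float = 30.0
    nb_size: float = 200.0           # NB size parameter; larger = closer to Poisson
    gc_bias_strength: float = 2.0
    n_depth_samples: int = 20
    window_size: int = 1_000
    repeat_fraction: float = 0.05
    repeat_junk_factor: float = 3.0
    frac_attenuated_genes: float = 0.30
    attenuation_range: tuple[float, float] = (0.72, 1.0)
    frac_strongly_attenuated: float = 0.05
    strong_attenuation_range: tuple[float, float] = (0.50, 0.60)

    # Iso-Seq
    n_planted_families: int = 5
    reads_per_planted_gene: int = 3
    n_background_reads: int = 50

    def __post_init__(self) -> None:
        total = self.frac_fixed + self.frac_polymorphic + self.frac_private
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("frequency spectrum fractions must sum to 1")
        dtotal = (self.frac_clustered + self.frac_interspersed
                  + self.frac_distant + self.frac_interchromosomal)
        if abs(dtotal - 1.0) > 1e-9:
            raise ValidationError("dispersion fractions must sum to 1")
        if min(self.n_afr_samples, self.n_nonafr_samples) < 1:
            raise ValidationError("need at least one sample per superpopulation")

    @property
    def n_haplotypes(self) -> int:
        return 2 * (self.n_afr_samples + self.n_nonafr_samples)

    @property
    def afr_intra_effect_bp(self) -> float:
        """Expected per-haplotype African excess of intrachromosomal SD bp
        (both mates of each AFR-biased pair carry SD bases)."""
        return self.n_afr_regions * 2 * self.afr_region_length * self.afr_carrier_prob

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(dict(self.chrom_lengths), list(self.excluded))

    @classmethod
    def small(cls) -> "SimConfig":
        """A desk-test configuration: 5 samples, 6 Mb, a minute's worth of
        everything."""
        return cls(
            n_afr_samples=2, n_nonafr_samples=3,
            chrom_lengths={"chr1": 3_000_000, "chr2": 3_000_000},
            n_sd_pairs=50, n_afr_regions=6, afr_region_length=8_000,
            n_families=12, n_shifted_families=3, n_depth_samples=4,
            max_length=30_000, n_planted_families=2, n_background_reads=15,
        )

    @classmethod
    def pair_survey(cls) -> "SimConfig":
        """Configuration for orientation × dispersion surveys: a large
        layout dense with short pairs (≥ 2,000 distinct interspersed pair
        loci), few haplotypes, no gene/depth content."""
        return cls(
            n_afr_samples=2, n_nonafr_samples=2,
            chrom_lengths={"chr1": 60_000_000, "chr2": 60_000_000},
            n_sd_pairs=4500,
            frac_clustered=0.48, frac_interspersed=0.48,
            frac_distant=0.0, frac_interchromosomal=0.04,
            frac_fixed=0.05, frac_polymorphic=0.75, frac_private=0.20,
            rare_log_length_mean=7.4, base_log_length_mean=7.3,
            rare_log_length_sd=0.15, base_log_length_sd=0.15,
            min_length=1_300, max_length=4_000,
            n_afr_regions=0, n_families=4, n_shifted_families=0,
            n_depth_samples=0, n_planted_families=0, n_background_reads=0,
        )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "chrom_lengths" in raw:
            raw["chrom_lengths"] = {str(k): int(v) for k, v in raw["chrom_lengths"].items()}
        for key in ("carrier_mix", "gene_length_range", "hap_rate_range",
                    "shifted_hap_rate_range", "attenuation_range",
                    "strong_attenuation_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "excluded" in raw:
            raw["excluded"] = [tuple(x) for x in raw["excluded"]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic cohort."""

    regions: pd.DataFrame            # reference-frame truth regions + classes
    pairs: pd.DataFrame              # distinct pair loci with orientation/dispersion
    gene_table: pd.DataFrame         # gene_id, family_id, locus, rate, attenuation
    cn_gene: pd.DataFrame            # gene × sample diploid CN
    cn_family: pd.DataFrame          # family × sample diploid CN
    shifted_families: dict[str, str]  # family_id -> expected direction
    afr_intra_effect_bp: float
    gc_bias_strength: float
    planted_reads: list[str]

    def to_json(self, path) -> None:
        payload = {
            "regions": self.regions.to_dict(orient="list"),
            "pairs": self.pairs.to_dict(orient="list"),
            "gene_table": self.gene_table.to_dict(orient="list"),
            "cn_gene": {"index": list(self.cn_gene.index),
                        "columns": list(self.cn_gene.columns),
                        "data": self.cn_gene.to_numpy().tolist()},
            "cn_family": {"index": list(self.cn_family.index),
                          "columns": list(self.cn_family.columns),
                          "data": self.cn_family.to_numpy().tolist()},
            "shifted_families": self.shifted_families,
            "afr_intra_effect_bp": self.afr_intra_effect_bp,
            "gc_bias_strength": self.gc_bias_strength,
            "planted_reads": self.planted_reads,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            regions=pd.DataFrame(raw["regions"]),
            pairs=pd.DataFrame(raw["pairs"]),
            gene_table=pd.DataFrame(raw["gene_table"]),
            cn_gene=pd.DataFrame(raw["cn_gene"]["data"],
                                 index=raw["cn_gene"]["index"],
                                 columns=raw["cn_gene"]["columns"]),
            cn_family=pd.DataFrame(raw["cn_family"]["data"],
                                   index=raw["cn_family"]["index"],
                                   columns=raw["cn_family"]["columns"]),
            shifted_families=raw["shifted_families"],
            afr_intra_effect_bp=raw["afr_intra_effect_bp"],
            gc_bias_strength=raw["gc_bias_strength"],
            planted_reads=raw["planted_reads"],
        )


@dataclass
class SimulatedCohort:
    config: SimConfig
    labels: PopulationLabels
    layout: GenomeLayout
    pairs_by_hap: dict[str, list[SDPair]]
    blocks_by_hap: dict[str, list[AlignmentBlock]]
    reference_sd: list[tuple[str, int, int]]
    genes: pd.DataFrame              # gene_id, family_id, chrom, start, end, cds_bp
    families: dict[str, str]         # gene_id -> family_id
    hits: pd.DataFrame               # paralog hit table
    truth: TruthSet


# ---------------------------------------------------------------------------
# interval placement with spacing
# ---------------------------------------------------------------------------

class _Placer:
    """Tracks occupied intervals per chromosome with a spacing pad and
    answers placement queries by rejection sampling."""

    PAD = 1_000

    def __init__(self, layout: GenomeLayout, rng: np.random.Generator) -> None:
        self.layout = layout
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chroms}
        for c, s, e in layout.excluded:
            self._insert(c, s, e)

    def _conflicts(self, chrom: str, start: int, end: int) -> bool:
        ivals = self.occupied[chrom]
        i = bisect.bisect_left(ivals, (start, start))
        for j in (i - 1, i):
            if 0 <= j < len(ivals):
                s, e = ivals[j]
                if s < end + self.PAD and e + self.PAD > start:
                    return True
        return False

    def _insert(self, chrom: str, start: int, end: int) -> None:
        bisect.insort(self.occupied[chrom], (start, end))

    def reserve(self, chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > self.layout.chrom_lengths[chrom]:
            return False
        if self._conflicts(chrom, start, end):
            return False
        self._insert(chrom, start, end)
        return True

    def random_chrom(self, min_len: int = 0) -> str:
        chroms = [c for c, L in self.layout.chrom_lengths.items() if L >= min_len]
        if not chroms:
            raise ValidationError("layout too small for requested placement")
        weights = np.array([self.layout.chrom_lengths[c] for c in chroms], dtype=float)
        return chroms[self.rng.choice(len(chroms), p=weights / weights.sum())]

    def place_single(self, length: int, chrom: str | None = None, tries: int = 300):
        for _ in range(tries):
            c = chrom or self.random_chrom(length + 2 * self.PAD)
            start = int(self.rng.integers(0, self.layout.chrom_lengths[c] - length))
            if self.reserve(c, start, start + length):
                return c, start, start + length
        raise ValidationError("layout too small for requested SD content")

    def place_pair(self, length: int, dispersion: str, tries: int = 300):
        """Place two same-length mate slots with the gap required by the
        dispersion class."""
        rng = self.rng
        for _ in range(tries):
            if dispersion == "interchromosomal":
                chroms = self.layout.chroms
                if len(chroms) < 2:
                    raise ValidationError("interchromosomal pairs need ≥2 chromosomes")
                ca, cb = rng.choice(len(chroms), size=2, replace=False)
                ca, cb = chroms[ca], chroms[cb]
                sa = int(rng.integers(0, self.layout.chrom_lengths[ca] - length))
                sb = int(rng.integers(0, self.layout.chrom_lengths[cb] - length))
                if self.reserve(ca, sa, sa + length):
                    if self.reserve(cb, sb, sb + length):
                        return (ca, sa, sa + length), (cb, sb, sb + length)
                    self.occupied[ca].remove((sa, sa + length))
                continue
            max_chrom = max(self.layout.chrom_lengths.values())
            if dispersion == "clustered":
                gap_lo, gap_hi = 2_000, min(900_000, max_chrom - 2 * length - 2 * self.PAD)
            elif dispersion == "interspersed":
                gap_lo = 1_200_000
                gap_hi = min(8_000_000, max_chrom - 2 * length - 2 * self.PAD)
            else:  # distant
                gap_lo = 50_200_000
                gap_hi = min(58_000_000, max_chrom - 2 * length - 2 * self.PAD)
            if gap_hi <= gap_lo:
                raise ValidationError(
                    f"layout too small for a {dispersion} pair of length {length}"
                )
            gap = int(rng.integers(gap_lo, gap_hi))
            span = 2 * length + gap
            c = self.random_chrom(span + 2 * self.PAD)
            if self.layout.chrom_lengths[c] <= span:
                continue
            sa = int(rng.integers(0, self.layout.chrom_lengths[c] - span))
            sb = sa + length + gap
            if self.reserve(c, sa, sa + length):
                if self.reserve(c, sb, sb + length):
                    return (c, sa, sa + length), (c, sb, sb + length)
                self.occupied[c].remove((sa, sa + length))
        raise ValidationError(
            f"layout too small to place a {dispersion} pair of length {length}"
        )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _make_labels(config: SimConfig) -> PopulationLabels:
    sample_of, superpop, popname = {}, {}, {}
    idx = 0
    for group, n, pop in (("AFR", config.n_afr_samples, "YRI-like"),
                          ("non-AFR", config.n_nonafr_samples, "CEU-like")):
        for _ in range(n):
            sample = f"S{idx:03d}"
            for h in (1, 2):
                sample_of[f"{sample}_h{h}"] = sample
            superpop[sample] = group
            popname[sample] = pop
            idx += 1
    return PopulationLabels(sample_of, superpop, popname)


def _draw_carriers(config, rng, labels, freq_class: str) -> list[str]:
    haps = labels.haplotypes
    H = len(haps)
    if freq_class == "fixed":
        return list(haps)
    if freq_class == "private":
        sample = labels.samples[int(rng.integers(len(labels.samples)))]
        hs = labels.haplotypes_of(sample)
        return hs if rng.random() < 0.5 else [hs[int(rng.integers(2))]]
    # polymorphic: carrier count from the rare/common/higher mix
    band = rng.choice(3, p=np.array(config.carrier_mix) / sum(config.carrier_mix))
    if band == 0:
        lo, hi = 2, min(5, H - 1)
    elif band == 1:
        lo, hi = min(6, H - 1), min(20, H - 1)
    else:
        lo, hi = min(21, H - 1), H - 1
    count = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    picked = rng.choice(H, size=count, replace=False)
    return [haps[i] for i in sorted(picked)]


def _draw_length_identity(config, rng, rare: bool) -> tuple[int, float]:
    if rare:
        length = int(np.exp(rng.normal(config.rare_log_length_mean,
                                       config.rare_log_length_sd)))
        div = abs(rng.normal(config.rare_divergence_mean, config.rare_divergence_sd))
    else:
        length = int(np.exp(rng.normal(config.base_log_length_mean,
                                       config.base_log_length_sd)))
        div = abs(rng.normal(config.base_divergence_mean, config.base_divergence_sd))
    length = int(np.clip(length, config.min_length, config.max_length))
    identity = float(np.clip(1.0 - div, 0.905, 0.9999))
    return length, identity


def _build_blocks(config, rng, labels, placer) -> dict[str, list[AlignmentBlock]]:
    """Cut each chromosome at SD-free positions into contiguous blocks,
    assign per-haplotype indel offsets, and reverse one interior block."""
    layout = config.layout
    cuts_by_chrom: dict[str, list[int]] = {}
    for chrom, clen in layout.chrom_lengths.items():
        cuts = []
        for frac in (0.3, 0.55, 0.8):
            target = int(clen * frac)
            cut = _free_position_near(placer, chrom, target, clen)
            if cut is not None:
                cuts.append(cut)
        cuts_by_chrom[chrom] = sorted(set(cuts))

    blocks: dict[str, list[AlignmentBlock]] = {}
    for hap in labels.haplotypes:
        hap_blocks = []
        for chrom, clen in layout.chrom_lengths.items():
            bounds = [0] + cuts_by_chrom[chrom] + [clen]
            offsets = np.cumsum(rng.integers(0, 2_000, size=len(bounds) - 1))
            reverse_idx = (len(bounds) - 2) // 2  # one interior block mirrored
            for k in range(len(bounds) - 1):
                rs, re = bounds[k], bounds[k + 1]
                off = int(offsets[k])
                hap_blocks.append(AlignmentBlock(
                    haplotype_id=hap,
                    hap_chrom=f"{hap}#{chrom}",
                    hap_start=rs + off, hap_end=re + off,
                    strand="-" if k == reverse_idx and len(bounds) > 2 else "+",
                    ref_chrom=chrom, ref_start=rs, ref_end=re,
                    block_id=f"{hap}.{chrom}.{k}",
                ))
        blocks[hap] = hap_blocks
    return blocks


def _free_position_near(placer, chrom, target, clen, margin=500):
    """A position ≥ margin away from every occupied interval, near target."""
    occupied = placer.occupied[chrom]
    for delta in range(0, clen, 10_000):
        for pos in (target + delta, target - delta):
            if not 10_000 < pos < clen - 10_000:
                continue
            i = bisect.bisect_left(occupied, (pos, pos))
            clear = True
            for j in (i - 1, i):
                if 0 <= j < len(occupied):
                    s, e = occupied[j]
                    if s - margin < pos < e + margin:
                        clear = False
            if clear:
                return pos
    return None


def _draw_pair_table(config: SimConfig, rng, labels, placer):
    """Draw the distinct pair loci: spectrum class, dispersion class,
    orientation, carriers, length/identity, and placed mate slots.

    Returns (pairs_df, regions_df, carriers_of_region) where regions holds
    two rows (mate A, mate B) per pair, aligned with carriers_of_region.
    """
    haps = labels.haplotypes
    disp_names = ["clustered", "interspersed", "distant", "interchromosomal"]
    disp_probs = np.array([config.frac_clustered, config.frac_interspersed,
                           config.frac_distant, config.frac_interchromosomal])
    class_names = ["fixed", "polymorphic", "private"]
    class_probs = np.array([config.frac_fixed, config.frac_polymorphic,
                            config.frac_private])
    p_clustered_inv = config.clustered_inverted_prob
    odds_clustered = p_clustered_inv / (1 - p_clustered_inv)
    odds_inter = odds_clustered * config.interspersed_inversion_odds
    p_inter_inv = odds_inter / (1 + odds_inter)

    pair_rows = []
    region_rows = []
    carriers_of_region: list[list[str]] = []

    def add_pair(pair_id, spectrum_class, dispersion, carriers, in_reference,
                 length, identity, orientation):
        slot_a, slot_b = placer.place_pair(length, dispersion)
        kind = ("interchromosomal" if dispersion == "interchromosomal"
                else "intrachromosomal")
        pair_rows.append({
            "pair_id": pair_id,
            "chrom_a": slot_a[0], "start_a": slot_a[1], "end_a": slot_a[2],
            "chrom_b": slot_b[0], "start_b": slot_b[1], "end_b": slot_b[2],
            "orientation": orientation, "dispersion": dispersion,
            "identity": identity, "length": length,
            "carrier_count": len(carriers),
        })
        for slot in (slot_a, slot_b):
            region_rows.append({
                "chrom": slot[0], "start": slot[1], "end": slot[2],
                "kind": kind, "in_reference": in_reference,
                "carrier_count": len(carriers),
                "spectrum_class": spectrum_class,
            })
            carriers_of_region.append(carriers)

    for i in range(config.n_sd_pairs):
        spectrum = class_names[rng.choice(3, p=class_probs / class_probs.sum())]
        dispersion = disp_names[rng.choice(4, p=disp_probs / disp_probs.sum())]
        carriers = _draw_carriers(config, rng, labels, spectrum)
        rare = len(carriers) <= 5 and spectrum != "fixed"
        length, identity = _draw_length_identity(config, rng, rare)
        if dispersion == "clustered":
            inverted = rng.random() < p_clustered_inv
        elif dispersion in ("interspersed", "distant"):
            inverted = rng.random() < p_inter_inv
        else:
            inverted = rng.random() < config.interchromosomal_inverted_prob
        if spectrum == "fixed":
            in_ref = True
        elif spectrum == "private":
            in_ref = False
        else:
            in_ref = bool(rng.random() < config.frac_known_among_polymorphic)
        add_pair(f"P{i:05d}", spectrum, dispersion, carriers, in_ref,
                 length, identity, "inverted" if inverted else "direct")

    # AFR-biased intrachromosomal pairs (the configured African excess)
    afr_haps = [h for h in haps if labels.is_afr_hap(h)]
    for i in range(config.n_afr_regions):
        mask = rng.random(len(afr_haps)) < config.afr_carrier_prob
        carriers = [h for h, m in zip(afr_haps, mask) if m]
        if not carriers:
            continue
        length = config.afr_region_length
        identity = float(np.clip(1 - abs(rng.normal(0.02, 0.008)), 0.905, 0.9999))
        inverted = rng.random() < p_clustered_inv
        add_pair(f"A{i:05d}", "afr_extra", "clustered", carriers, False,
                 length, identity, "inverted" if inverted else "direct")

    return pd.DataFrame(pair_rows), pd.DataFrame(region_rows), carriers_of_region


def simulate_pair_table(config: SimConfig, seed: int) -> pd.DataFrame:
    """Distinct pair loci only (no call-set emission): the fast path for
    orientation × dispersion surveys."""
    rng = np.random.default_rng(seed)
    labels = _make_labels(config)
    placer = _Placer(config.layout, rng)
    pairs_df, _, _ = _draw_pair_table(config, rng, labels, placer)
    return pairs_df


def simulate_cohort(
    config: SimConfig, seed: int, out_dir: str | os.PathLike | None = None
) -> SimulatedCohort:
    """Generate a full synthetic cohort; deterministic under ``seed``.

    When ``out_dir`` is given, all cohort files (pair call sets, alignment
    blocks, labels, layout, reference SD BED, gene/family/hit tables and
    truth.json) are written there.
    """
    rng = np.random.default_rng(seed)
    labels = _make_labels(config)
    layout = config.layout
    placer = _Placer(layout, rng)
    haps = labels.haplotypes

    pairs_df, regions_df, carriers_of_region = _draw_pair_table(
        config, rng, labels, placer
    )

    # --- truth frequency classes ------------------------------------------
    H = len(haps)
    freq_class = []
    for (_, row), carriers in zip(regions_df.iterrows(), carriers_of_region):
        n_samples = len({labels.sample_of[h] for h in carriers})
        if len(carriers) == H:
            freq_class.append("fixed")
        elif row["in_reference"]:
            freq_class.append("polymorphic_known")
        elif n_samples == 1:
            freq_class.append("private")
        else:
            freq_class.append("polymorphic_novel")
    regions_df["freq_class"] = freq_class
    regions_df["region_id"] = [f"R{i:05d}" for i in range(len(regions_df))]

    # --- alignment blocks and per-haplotype call sets ---------------------
    blocks_by_hap = _build_blocks(config, rng, labels, placer)
    pairs_by_hap: dict[str, list[SDPair]] = {h: [] for h in haps}
    jit = config.boundary_jitter_bp

    for (_, prow), carriers in zip(
        pairs_df.iterrows(), carriers_of_region[::2]
    ):
        for hap in carriers:
            blocks = blocks_by_hap[hap]

            def hap_interval(chrom, start, end):
                pieces = back_project_interval(chrom, start, end, blocks)
                if len(pieces) != 1:
                    raise AssertionError("slot straddles a block boundary")
                c, s, e = pieces[0]
                ds, de = int(rng.integers(-jit, jit + 1)), int(rng.integers(-jit, jit + 1))
                return c, max(0, s + ds), e + de

            ca, sa, ea = hap_interval(prow["chrom_a"], prow["start_a"], prow["end_a"])
            cb, sb, eb = hap_interval(prow["chrom_b"], prow["start_b"], prow["end_b"])
            identity = float(np.clip(prow["identity"] + rng.normal(0, 0.001),
                                     0.902, 0.9999))
            pairs_by_hap[hap].append(SDPair(
                haplotype_id=hap,
                chrom_a=ca, start_a=sa, end_a=ea,
                chrom_b=cb, start_b=sb, end_b=eb,
                orientation=prow["orientation"],
                identity=identity, length=ea - sa,
            ))

    reference_sd = [
        (r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in regions_df.iterrows() if r["in_reference"]
    ]

    # --- gene families, truth CN, paralog hits ----------------------------
    genes_df, families, cn_gene, cn_family, shifted, hits = _simulate_genes(
        config, rng, labels, placer
    )

    truth = TruthSet(
        regions=regions_df[["region_id", "chrom", "start", "end", "kind",
                            "in_reference", "carrier_count", "freq_class",
                            "spectrum_class"]],
        pairs=pairs_df,
        gene_table=genes_df,
        cn_gene=cn_gene,
        cn_family=cn_family,
        shifted_families=shifted,
        afr_intra_effect_bp=config.afr_intra_effect_bp,
        gc_bias_strength=config.gc_bias_strength,
        planted_reads=[],
    )
    cohort = SimulatedCohort(
        config=config, labels=labels, layout=layout,
        pairs_by_hap=pairs_by_hap, blocks_by_hap=blocks_by_hap,
        reference_sd=reference_sd, genes=genes_df, families=families,
        hits=hits, truth=truth,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def _simulate_genes(config, rng, labels, placer):
    genes = []
    families: dict[str, str] = {}
    g_idx = 0
    shifted_ids = [f"F{i:03d}" for i in range(config.n_shifted_families)]
    for f in range(config.n_families):
        fam = f"F{f:03d}"
        n_genes = int(rng.integers(1, config.max_genes_per_family + 1))
        shifted = fam in shifted_ids
        for _ in range(n_genes):
            length = int(rng.integers(*config.gene_length_range))
            chrom, start, end = placer.place_single(length)
            lo, hi = (config.shifted_hap_rate_range if shifted
                      else config.hap_rate_range)
            rate = float(rng.uniform(lo, hi))
            if rng.random() < config.frac_strongly_attenuated:
                atten = float(rng.uniform(*config.strong_attenuation_range))
            elif rng.random() < config.frac_attenuated_genes:
                atten = float(rng.uniform(*config.attenuation_range))
            else:
                atten = 1.0
            genes.append({
                "gene_id": f"G{g_idx:04d}", "family_id": fam,
                "chrom": chrom, "start": start, "end": end,
                "cds_bp": int(rng.integers(300, 3_000)),
                "hap_rate": rate, "attenuation": atten, "shifted": shifted,
            })
            families[f"G{g_idx:04d}"] = fam
            g_idx += 1
    genes_df = pd.DataFrame(genes)

    # haplotype-level true copy counts (rate matrix → truncated Poisson)
    base_rates = genes_df["hap_rate"].to_numpy()[:, None]
    afr_mask = np.array([labels.is_afr_hap(h) for h in labels.haplotypes])[None, :]
    shifted_mask = genes_df["shifted"].to_numpy()[:, None]
    rates = base_rates * np.where(shifted_mask & afr_mask, 1 + config.afr_shift, 1.0)
    counts = np.minimum(rng.poisson(rates), config.max_hap_copies)
    hap_counts = pd.DataFrame(counts, index=genes_df["gene_id"],
                              columns=labels.haplotypes)
    cn_gene = pd.DataFrame(0, index=genes_df["gene_id"],
                           columns=labels.samples, dtype=int)
    for sample in labels.samples:
        h1, h2 = labels.haplotypes_of(sample)
        cn_gene[sample] = hap_counts[h1] + hap_counts[h2]
    cn_family = cn_gene.groupby([families[g] for g in cn_gene.index]).sum()
    cn_family.index.name = "family_id"
    shifted = {fam: "AFR_higher" for fam in shifted_ids}

    # paralog hits: one row per true copy, all passing the filters
    hit_rows = []
    for _, g in genes_df.iterrows():
        glen = g["end"] - g["start"]
        for hap in labels.haplotypes:
            for copy in range(hap_counts.loc[g["gene_id"], hap]):
                hit_rows.append({
                    "gene_id": g["gene_id"], "haplotype_id": hap,
                    "target_chrom": f"{hap}#{g['chrom']}",
                    "target_start": int(g["start"] + copy * glen),
                    "target_end": int(g["end"] + copy * glen),
                    "coverage": float(rng.uniform(0.85, 1.0)),
                    "identity": float(rng.uniform(0.95, 1.0)),
                    "repeat_overlap": float(rng.uniform(0.0, 0.5)),
                    "cds_bp": int(g["cds_bp"]),
                    "distance_to_break": int(rng.integers(50_000, 1_000_000)),
                })
    hits = pd.DataFrame(hit_rows, columns=[
        "gene_id", "haplotype_id", "target_chrom", "target_start", "target_end",
        "coverage", "identity", "repeat_overlap", "cds_bp", "distance_to_break",
    ])
    return genes_df, families, cn_gene, cn_family, shifted, hits


# ---------------------------------------------------------------------------
# read depth
# ---------------------------------------------------------------------------

def gc_bias_curve(gc: np.ndarray, strength: float) -> np.ndarray:
    """Smooth unimodal GC response: depressed coverage at extreme GC."""
    return np.clip(1.0 - strength * (gc - 0.45) ** 2, 0.5, None)


@dataclass
class DepthData:
    windows: pd.DataFrame                 # chrom, start, end, gc (shared)
    self_depth: pd.DataFrame              # windows + noiseless self depth
    sample_depth: dict[str, pd.DataFrame]
    repeats: list[tuple[str, int, int]]
    unique_regions: list[tuple[str, int, int]]


def simulate_depth(cohort: SimulatedCohort, seed: int,
                   out_dir: str | os.PathLike | None = None) -> DepthData:
    """Windowed depth tables for the first ``n_depth_samples`` samples plus
    the noiseless self sample.

    Window depth follows an overdispersed (negative-binomial) count model
    with mean coverage × (CN/2) × gc_bias(gc) × attenuation, where CN is
    the sample's diploid copy number of the gene containing the window (2
    outside genes).  Repeat-overlapping windows carry inflated junk depth;
    the emitted repeat BED marks them for exclusion.
    """
    config = cohort.config
    rng = np.random.default_rng(seed)
    layout = cohort.layout
    ws = config.window_size

    rows = []
    for chrom, clen in layout.chrom_lengths.items():
        starts = np.arange(0, clen - ws + 1, ws)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + ws,
        }))
    windows = pd.concat(rows, ignore_index=True)
    windows["gc"] = rng.beta(6, 6, size=len(windows))

    # repeats: random intervals covering ~repeat_fraction of the genome
    repeats: list[tuple[str, int, int]] = []
    target_bp = config.repeat_fraction * layout.total_bp
    acc = 0
    while acc < target_bp:
        chrom = layout.chroms[int(rng.integers(len(layout.chroms)))]
        length = int(rng.integers(500, 5_000))
        start = int(rng.integers(0, layout.chrom_lengths[chrom] - length))
        repeats.append((chrom, start, start + length))
        acc += length
    repeats, _ = flatten_union(repeats)

    bias = gc_bias_curve(windows["gc"].to_numpy(), config.gc_bias_strength)

    # per-window gene assignment (windows fully inside a gene span)
    gene_idx = np.full(len(windows), -1)
    gene_list = cohort.genes.reset_index(drop=True)
    wstart = windows["start"].to_numpy()
    wend = windows["end"].to_numpy()
    wchrom = windows["chrom"].to_numpy()
    for gi, g in gene_list.iterrows():
        mask = (wchrom == g["chrom"]) & (wstart >= g["start"]) & (wend <= g["end"])
        gene_idx[mask] = gi
    atten = np.ones(len(windows))
    for gi, g in gene_list.iterrows():
        atten[gene_idx == gi] = g["attenuation"]

    from .sd_catalog import coverage_within
    rep_frac = coverage_within(windows, repeats)
    junk = np.where(rep_frac > 0.10, config.repeat_junk_factor, 1.0)

    # noiseless self sample: CN = 2 everywhere
    self_depth = windows.copy()
    self_depth["depth"] = config.coverage * bias * atten * junk

    sample_depth: dict[str, pd.DataFrame] = {}
    # balance the depth cohort across superpopulations
    afr = cohort.labels.afr_samples()
    nonafr = cohort.labels.nonafr_samples()
    n = config.n_depth_samples
    depth_samples = afr[: n - n // 2] + nonafr[: n // 2]
    depth_samples = depth_samples[:n]
    r = config.nb_size
    for sample in depth_samples:
        cn = np.full(len(windows), 2.0)
        for gi, g in gene_list.iterrows():
            cn[gene_idx == gi] = cohort.truth.cn_gene.loc[g["gene_id"], sample]
        mu = config.coverage * (cn / 2.0) * bias * atten * junk
        depth = np.where(
            mu > 0,
            rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-9))),
            0,
        ).astype(float)
        tab = windows.copy()
        tab["depth"] = depth
        sample_depth[sample] = tab

    # unique (known CN=2) regions: complement of genes, SDs and repeats
    busy = repeats + [
        (g["chrom"], int(g["start"]), int(g["end"])) for _, g in gene_list.iterrows()
    ] + [(r_["chrom"], int(r_["start"]), int(r_["end"]))
         for _, r_ in cohort.truth.regions.iterrows()]
    busy_flat, _ = flatten_union(busy)
    unique_regions: list[tuple[str, int, int]] = []
    for chrom, clen in layout.chrom_lengths.items():
        cursor = 0
        for c, s, e in busy_flat:
            if c != chrom:
                continue
            if s - cursor > 2 * ws:
                unique_regions.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if clen - cursor > 2 * ws:
            unique_regions.append((chrom, cursor, clen))

    data = DepthData(windows=windows, self_depth=self_depth,
                     sample_depth=sample_depth, repeats=repeats,
                     unique_regions=unique_regions)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_tsv(self_depth, os.path.join(out_dir, "depth_self.tsv"))
        for sample, tab in sample_depth.items():
            write_tsv(tab, os.path.join(out_dir, f"depth_{sample}.tsv"))
        write_bed(repeats, os.path.join(out_dir, "repeats.bed"))
        write_bed(unique_regions, os.path.join(out_dir, "unique_regions.bed"))
    return data


# ---------------------------------------------------------------------------
# Iso-Seq
# ---------------------------------------------------------------------------

def simulate_isoseq(cohort: SimulatedCohort, seed: int,
                    out_dir: str | os.PathLike | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iso-Seq alignment summaries with a planted reference-divergent set.

    Returns ``(alignments, predictions)``; planted read ids are recorded in
    the cohort's TruthSet.  Planted reads exceed 99.9% haplotype identity
    and stay below 99.7% reference gap-compressed identity; background
    reads violate at least one threshold.
    """
    config = cohort.config
    rng = np.random.default_rng(seed)
    haps = cohort.labels.haplotypes

    def alignment_row(read_id, target, identity_target, gc_target):
        n_ops = 20_000
        go = int(rng.integers(1, 4))
        matches = int(round(gc_target * n_ops))
        mismatches = max(0, n_ops - matches - go)
        gap_bases = go * int(rng.integers(1, 6))
        return {
            "read_id": read_id, "target": target,
            "matches": matches, "mismatches": mismatches,
            "gap_openings": go, "gap_bases": gap_bases,
            "identity": round(identity_target, 6),
            "gap_compressed_identity": round(
                matches / (matches + mismatches + go), 6),
        }

    align_rows, pred_rows, planted = [], [], []
    fam_pool = sorted(set(cohort.families.values()))
    chosen = fam_pool[: config.n_planted_families]
    ridx = 0
    for fam in chosen:
        hap = haps[int(rng.integers(len(haps)))]
        genes = [g for g, f in cohort.families.items() if f == fam][:2]
        for gene in genes:
            for _ in range(config.reads_per_planted_gene):
                read_id = f"iso{ridx:05d}"
                ridx += 1
                hap_id = float(rng.uniform(0.9992, 0.9999))
                ref_id = float(rng.uniform(0.990, 0.9965))
                align_rows.append(alignment_row(read_id, hap, hap_id, hap_id))
                align_rows.append(alignment_row(read_id, "reference", ref_id, ref_id))
                pred_rows.append({"read_id": read_id, "family_id": fam,
                                  "haplotype_id": hap, "gene_id": gene})
                planted.append(read_id)
    for _ in range(config.n_background_reads):
        read_id = f"iso{ridx:05d}"
        ridx += 1
        hap = haps[int(rng.integers(len(haps)))]
        if rng.random() < 0.5:   # fails the haplotype side
            hap_id = float(rng.uniform(0.990, 0.9988))
            ref_id = float(rng.uniform(0.985, 0.9965))
        else:                    # fails the reference side
            hap_id = float(rng.uniform(0.9992, 0.9999))
            ref_id = float(rng.uniform(0.9972, 0.9995))
        align_rows.append(alignment_row(read_id, hap, hap_id, hap_id))
        align_rows.append(alignment_row(read_id, "reference", ref_id, ref_id))

    alignments = pd.DataFrame(align_rows)
    predictions = pd.DataFrame(
        pred_rows, columns=["read_id", "family_id", "haplotype_id", "gene_id"]
    )
    cohort.truth.planted_reads = planted
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_tsv(alignments, os.path.join(out_dir, "isoseq_alignments.tsv"))
        write_tsv(predictions, os.path.join(out_dir, "isoseq_predictions.tsv"))
    return alignments, predictions


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    join = lambda name: os.path.join(out_dir, name)  # noqa: E731
    all_pairs = [p for hap in cohort.labels.haplotypes
                 for p in cohort.pairs_by_hap.get(hap, [])]
    write_sd_pairs(all_pairs, join("sd_pairs.tsv"))
    write_alignment_blocks(cohort.blocks_by_hap, join("alignment_blocks.tsv"))
    write_labels(cohort.labels, join("labels.tsv"))
    write_layout(cohort.layout, join("layout.tsv"), join("excluded.bed"))
    write_bed(cohort.reference_sd, join("reference_sd.bed"))
    write_bed(
        [(g["chrom"], int(g["start"]), int(g["end"]), g["gene_id"])
         for _, g in cohort.genes.iterrows()],
        join("genes.bed"),
    )
    write_tsv(pd.DataFrame(
        {"gene_id": list(cohort.families), "family_id": list(cohort.families.values())}
    ), join("families.tsv"))
    write_tsv(cohort.hits, join("hits.tsv"))
    cohort.truth.to_json(join("truth.json"))
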