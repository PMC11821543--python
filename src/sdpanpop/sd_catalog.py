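"""Reference-frame SD region catalog.

Per-haplotype SD intervals (assembly frame) are projected to the reference
through 1-to-1 alignment blocks, flattened into nonoverlapping regions,
scored for presence across the cohort, and classified into the four
frequency classes of the pangenome SD spectrum:

fixed
    present in every haplotype of the cohort,
polymorphic (known)
    in the reference SD annotation but not fixed,
polymorphic (novel)
    absent from the reference, seen in two or more samples,
private
    absent from the reference, seen in exactly one sample.

Presence of a haplotype in a region requires its projected SD bases to
cover at least half of the region (reciprocal-overlap style; guards against
trivial edge overlaps while tolerating boundary jitter between assemblies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentBlock, PopulationLabels, SDPair, ValidationError

DEFAULT_COVERAGE_THRESHOLD = 0.5

Interval = tuple[str, int, int]


# ---------------------------------------------------------------------------
# interval projection through alignment blocks
# ---------------------------------------------------------------------------

def project_interval(
    chrom: str,
    start: int,
    end: int,
    blocks: Sequence[AlignmentBlock],
) -> tuple[list[Interval], list[int]]:
    """Project an assembly-frame interval to the reference frame.

    Each alignment block overlapping the interval contributes one projected
    reference interval: forward blocks preserve offsets within the block,
    reverse blocks mirror them.  Portions of the interval covered by no
    block are returned separately as unplaced lengths.

    Returns ``(projected, unplaced_lengths)``.
    """
    if start >= end:
        raise ValidationError(f"empty interval [{start},{end})")
    relevant = sorted(
        (b for b in blocks if b.hap_chrom == chrom and b.hap_start < end and b.hap_end > start),
        key=lambda b: b.hap_start,
    )
    if not any(b.hap_chrom == chrom for b in blocks):
        raise ValidationError(f"no alignment blocks on haplotype chromosome {chrom}")
    projected: list[Interval] = []
    unplaced: list[int] = []
    cursor = start
    for b in relevant:
        if b.hap_start > cursor:
            unplaced.append(b.hap_start - cursor)
            cursor = b.hap_start
        seg_start = max(start, b.hap_start)
        seg_end = min(end, b.hap_end)
        if b.strand == "+":
            ref_s = b.ref_start + (seg_start - b.hap_start)
            ref_e = b.ref_start + (seg_end - b.hap_start)
        else:
            # mirror: haplotype base x maps to ref_end - 1 - (x - hap_start)
            ref_s = b.ref_end - (seg_end - b.hap_start)
            ref_e = b.ref_end - (seg_start - b.hap_start)
        projected.append((b.ref_chrom, ref_s, ref_e))
        cursor = seg_end
    if cursor < end:
        unplaced.append(end - cursor)
    return projected, unplaced


def back_project_interval(
    ref_chrom: str, ref_start: int, ref_end: int, blocks: Sequence[AlignmentBlock]
) -> list[tuple[str, int, int]]:
    """Inverse projection (reference → assembly frame); used by the
    synthetic generator and for the round-trip invariant."""
    out = []
    for b in blocks:
        if b.ref_chrom != ref_chrom or b.ref_start >= ref_end or b.ref_end <= ref_start:
            continue
        seg_s = max(ref_start, b.ref_start)
        seg_e = min(ref_end, b.ref_end)
        if b.strand == "+":
            out.append((b.hap_chrom, b.hap_start + (seg_s - b.ref_start),
                        b.hap_start + (seg_e - b.ref_start)))
        else:
            out.append((b.hap_chrom, b.hap_start + (b.ref_end - seg_e),
                        b.hap_start + (b.ref_end - seg_s)))
    return out


# ---------------------------------------------------------------------------
# union flattening
# ---------------------------------------------------------------------------

def flatten_union(intervals: Iterable[Interval]) -> tuple[list[Interval], int]:
    """Flatten intervals into their nonoverlapping, sorted union.

    Touching intervals ([a,b) and [b,c)) are merged.  Returns the merged
    regions and the total union size in bp (the size of the set-theoretic
    union of bases).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        if s >= e:
            raise ValidationError(f"empty interval [{s},{e}) on {chrom}")
        by_chrom.setdefault(chrom, []).append((s, e))
    merged: list[Interval] = []
    total = 0
    for chrom in sorted(by_chrom):
        ivals = np.array(sorted(by_chrom[chrom]), dtype=np.int64)
        starts, ends = ivals[:, 0], ivals[:, 1]
        run_end = np.maximum.accumulate(ends)
        # a new run begins where the start exceeds the furthest end seen so far
        new_run = np.ones(len(starts), dtype=bool)
        new_run[1:] = starts[1:] > run_end[:-1]
        run_starts = starts[new_run]
        idx = np.flatnonzero(new_run)
        run_ends = np.append(run_end[idx[1:] - 1], run_end[-1])
        for s, e in zip(run_starts, run_ends):
            merged.append((chrom, int(s), int(e)))
            total += int(e - s)
    return merged, total


def intersect_bp(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    """Total bp in the intersection of two interval sets (each flattened
    first)."""
    fa, _ = flatten_union(a)
    fb, _ = flatten_union(b)
    by_chrom_b: dict[str, np.ndarray] = {}
    for chrom, s, e in fb:
        by_chrom_b.setdefault(chrom, []).append((s, e))
    by_chrom_b = {c: np.array(v, dtype=np.int64) for c, v in by_chrom_b.items()}
    total = 0
    for chrom, s, e in fa:
        arr = by_chrom_b.get(chrom)
        if arr is None:
            continue
        overlap = np.minimum(arr[:, 1], e) - np.maximum(arr[:, 0], s)
        total += int(overlap[overlap > 0].sum())
    return total


def coverage_within(
    regions: pd.DataFrame, intervals: Iterable[Interval]
) -> np.ndarray:
    """Fraction of each region's bases covered by an interval set.

    ``regions`` needs chrom/start/end columns; the interval set is flattened
    internally so overlaps are not double-counted.
    """
    flat, _ = flatten_union(intervals) if intervals else ([], 0)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, s, e in flat:
        by_chrom.setdefault(chrom, []).append((s, e))
    by_chrom = {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}
    out = np.zeros(len(regions), dtype=float)
    for i, (chrom, s, e) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        arr = by_chrom.get(chrom)
        if arr is None:
            continue
        ov = np.minimum(arr[:, 1], e) - np.maximum(arr[:, 0], s)
        covered = int(ov[ov > 0].sum())
        out[i] = covered / (e - s)
    return out


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

@dataclass
class RegionCatalog:
    """Flattened SD regions with per-haplotype presence and frequency class.

    ``regions`` columns: chrom, start, end, freq_class, haplotype_count and
    (when built by :func:`build_catalog`) sample_count, in_reference, kind.
    ``presence`` is a regions × haplotypes 0/1 matrix aligned with
    ``haplotypes``.
    """

    regions: pd.DataFrame
    presence: np.ndarray
    haplotypes: list[str]
    unplaced: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["haplotype_id", "length"])
    )

    def __post_init__(self) -> None:
        if self.presence.shape != (len(self.regions), len(self.haplotypes)):
            raise ValidationError("presence matrix shape does not match catalog")

    @property
    def union_bp(self) -> int:
        return int((self.regions["end"] - self.regions["start"]).sum())

    def class_counts(self) -> pd.Series:
        return self.regions["freq_class"].value_counts()


def build_presence(
    regions: pd.DataFrame,
    per_hap_intervals: Mapping[str, list[Interval]],
    haplotypes: Sequence[str],
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> np.ndarray:
    """presence[r, h] = 1 iff haplotype h's SD bases cover at least
    ``coverage_threshold`` of region r (inclusive at the threshold)."""
    for hap in per_hap_intervals:
        if hap not in set(haplotypes):
            raise ValidationError(f"haplotype {hap} not in cohort")
    presence = np.zeros((len(regions), len(haplotypes)), dtype=np.int8)
    for j, hap in enumerate(haplotypes):
        ivals = per_hap_intervals.get(hap, [])
        if not ivals:
            continue
        cov = coverage_within(regions, ivals)
        presence[:, j] = cov >= coverage_threshold
    return presence


def classify_frequency(
    presence_row: np.ndarray,
    in_reference: bool,
    haplotypes: Sequence[str],
    labels: PopulationLabels,
) -> str:
    """Assign the frequency class of one region.

    fixed: present in all haplotypes.  private: exactly one carrier sample
    (one or both haplotypes) and absent from the reference.  A region in the
    reference annotation that is not fixed is polymorphic (known) — the
    reference counts as evidence of recurrence even for single-sample
    carriers.  Non-reference regions in ≥2 samples are polymorphic (novel).
    """
    count = int(np.sum(presence_row))
    h_total = len(haplotypes)
    if count == h_total:
        return "fixed"
    carrier_samples = {
        labels.sample_of[haplotypes[j]] for j in np.flatnonzero(presence_row)
    }
    if in_reference:
        return "polymorphic_known"
    if len(carrier_samples) == 0:
        raise ValidationError("region absent from cohort and reference: should not exist")
    if len(carrier_samples) == 1:
        return "private"
    return "polymorphic_novel"


def build_catalog(
    per_hap_intervals: Mapping[str, list[Interval]],
    labels: PopulationLabels,
    reference_sd: Iterable[Interval] = (),
    per_hap_kinds: Mapping[str, list[str]] | None = None,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    unplaced: pd.DataFrame | None = None,
) -> RegionCatalog:
    """Flatten per-haplotype reference-frame SD intervals into a classified
    region catalog.

    ``per_hap_kinds``, when given, parallels ``per_hap_intervals`` with
    "intrachromosomal"/"interchromosomal" tags per interval (from the SD
    pair that generated it); regions receiving both tags are marked "both"
    and counted once in union totals.
    """
    haplotypes = labels.haplotypes
    all_intervals = [iv for hap in haplotypes for iv in per_hap_intervals.get(hap, [])]
    flat, _ = flatten_union(all_intervals) if all_intervals else ([], 0)
    regions = pd.DataFrame(flat, columns=["chrom", "start", "end"])
    presence = build_presence(regions, per_hap_intervals, haplotypes, coverage_threshold)

    ref_list = list(reference_sd)
    ref_cov = coverage_within(regions, ref_list) if ref_list else np.zeros(len(regions))
    in_reference = ref_cov >= 0.5  # same reciprocal-style rule as presence

    kinds = _assign_kinds(regions, per_hap_intervals, per_hap_kinds, haplotypes)

    classes = []
    for i in range(len(regions)):
        classes.append(
            classify_frequency(presence[i], bool(in_reference[i]), haplotypes, labels)
        )
    regions["haplotype_count"] = presence.sum(axis=1).astype(int)
    regions["sample_count"] = [
        len({labels.sample_of[haplotypes[j]] for j in np.flatnonzero(presence[i])})
        for i in range(len(regions))
    ]
    regions["in_reference"] = in_reference
    regions["freq_class"] = classes
    regions["kind"] = kinds
    return RegionCatalog(
        regions=regions,
        presence=presence,
        haplotypes=list(haplotypes),
        unplaced=unplaced if unplaced is not None
        else pd.DataFrame(columns=["haplotype_id", "length"]),
    )


def _assign_kinds(regions, per_hap_intervals, per_hap_kinds, haplotypes):
    if per_hap_kinds is None:
        return ["intrachromosomal"] * len(regions)
    intra: list[Interval] = []
    inter: list[Interval] = []
    for hap in haplotypes:
        for iv, kind in zip(per_hap_intervals.get(hap, []), per_hap_kinds.get(hap, [])):
            (intra if kind == "intrachromosomal" else inter).append(iv)
    cov_intra = coverage_within(regions, intra) if intra else np.zeros(len(regions))
    cov_inter = coverage_within(regions, inter) if inter else np.zeros(len(regions))
    out = []
    for ci, cj in zip(cov_intra, cov_inter):
        if ci > 0 and cj > 0:
            out.append("both")
        elif cj > 0:
            out.append("interchromosomal")
        else:
            out.append("intrachromosomal")
    return out


# ---------------------------------------------------------------------------
# accumulation curve
# ---------------------------------------------------------------------------

def accumulation_curve(
    catalog: RegionCatalog,
    ordering: Sequence[str] | None = None,
    labels: PopulationLabels | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cumulative SD bp added per genome in a haplotype ordering.

    The default ordering is the non-African block followed by the African
    block (requires ``labels``).  A region's bp is attributed to the first
    carrier haplotype in the ordering; cumulative totals are therefore
    monotone nondecreasing and end at the catalog union bp of carried
    regions.  Returns the per-step table (total and per freq_class / kind
    breakdowns) and a summary with the mean per-genome novel-bp increment
    and the least-squares slope over the curve.
    """
    if ordering is None:
        if labels is None:
            raise ValidationError("default ordering requires population labels")
        ordering = [h for h in catalog.haplotypes if not labels.is_afr_hap(h)] + [
            h for h in catalog.haplotypes if labels.is_afr_hap(h)
        ]
    if sorted(ordering) != sorted(catalog.haplotypes):
        raise ValidationError("ordering is not a permutation of the cohort haplotypes")

    col = {h: j for j, h in enumerate(catalog.haplotypes)}
    perm = np.array([col[h] for h in ordering])
    pres = catalog.presence[:, perm]  # regions × ordered haplotypes
    lengths = (catalog.regions["end"] - catalog.regions["start"]).to_numpy()
    carried = pres.any(axis=1)
    # step (1-based position in the ordering) at which each region first appears
    first = np.argmax(pres, axis=1)
    H = len(ordering)

    rows = []
    cum = {}
    keys = [
        (fc, kd)
        for fc in catalog.regions["freq_class"].unique()
        for kd in catalog.regions["kind"].unique()
    ]
    fc_arr = catalog.regions["freq_class"].to_numpy()
    kd_arr = catalog.regions["kind"].to_numpy()
    added = np.zeros(H, dtype=np.int64)
    for i in np.flatnonzero(carried):
        added[first[i]] += lengths[i]
    cum_total = np.cumsum(added)
    for fc, kd in keys:
        mask = carried & (fc_arr == fc) & (kd_arr == kd)
        a = np.zeros(H, dtype=np.int64)
        for i in np.flatnonzero(mask):
            a[first[i]] += lengths[i]
        cum[(fc, kd)] = np.cumsum(a)
    for step in range(H):
        row = {
            "step": step + 1,
            "haplotype_id": ordering[step],
            "added_bp": int(added[step]),
            "cumulative_bp": int(cum_total[step]),
        }
        for (fc, kd), series in cum.items():
            row[f"{fc}:{kd}"] = int(series[step])
        rows.append(row)
    table = pd.DataFrame(rows)

    increments = added[1:]  # novel bp added by each genome after the first
    slope = float(np.polyfit(np.arange(1, H + 1), cum_total, 1)[0]) if H > 1 else 0.0
    summary = {
        "final_total_bp": int(cum_total[-1]) if H else 0,
        "mean_increment_bp": float(increments.mean()) if H > 1 else 0.0,
        "regression_slope_bp_per_genome": slope,
    }
    return table, summary
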