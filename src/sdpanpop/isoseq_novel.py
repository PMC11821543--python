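"""Reference-divergent transcript filtering and novel-gene counting for
full-length cDNA (Iso-Seq) alignments.

A read supports a reference-divergent novel paralog when it aligns to a
haplotype assembly at more than 99.9% identity while its best reference
alignment stays below 99.7% gap-compressed identity — below the allelic
divergence expected for most protein-coding loci, so the haplotype copy
cannot be the reference allele.  Family-level novel-gene counts take, for
each family, the haplotype with the most novel paralog predictions, so a
paralog shared by many carriers is not counted once per carrier.

Iso-Seq alignment table columns (TSV): read_id, target (haplotype_id or
"reference"), matches, mismatches, gap_openings, gap_bases, identity,
gap_compressed_identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import ValidationError

HAP_IDENTITY_MIN = 0.999     # strict: identity must exceed this
REF_IDENTITY_MAX = 0.997     # strict: gap-compressed identity must stay below
MAX_CARRIER_HAPLOTYPES = 10  # rare-duplication eligibility pre-filter


@dataclass(frozen=True)
class IsoAlignment:
    read_id: str
    target: str              # haplotype_id or "reference"
    matches: int
    mismatches: int
    gap_openings: int
    gap_bases: int
    identity: float
    gap_compressed_identity: float


def gap_compressed_identity(matches: int, mismatches: int, gap_openings: int) -> float:
    """matches / (matches + mismatches + gap_openings).

    Each gap counts once regardless of its length (a 5-bp deletion is one
    gap opening, one difference).
    """
    if min(matches, mismatches, gap_openings) < 0:
        raise ValidationError("negative alignment counts")
    if matches + mismatches == 0:
        raise ValidationError("alignment with no aligned bases")
    return matches / (matches + mismatches + gap_openings)


def reference_divergent(
    hap_identity: float,
    ref_gap_compressed_identity: float | None,
    hap_threshold: float = HAP_IDENTITY_MIN,
    ref_threshold: float = REF_IDENTITY_MAX,
) -> bool:
    """True iff the read passes the reference-divergence filter.

    Both comparisons are strict: haplotype identity > 99.9% and reference
    gap-compressed identity < 99.7%.  A missing reference alignment is
    treated as identity 0 (maximally divergent).
    """
    if ref_gap_compressed_identity is None:
        ref_gap_compressed_identity = 0.0
    return hap_identity > hap_threshold and ref_gap_compressed_identity < ref_threshold


def filter_alignments(
    alignments: pd.DataFrame,
    hap_threshold: float = HAP_IDENTITY_MIN,
    ref_threshold: float = REF_IDENTITY_MAX,
) -> pd.DataFrame:
    """Pair each read's best haplotype hit with its best reference hit and
    apply :func:`reference_divergent`.

    Best = highest (gap-compressed) identity per read per side.  Returns a
    per-read table with hap/ref identities and a ``divergent`` flag.
    """
    hap = alignments[alignments["target"] != "reference"]
    ref = alignments[alignments["target"] == "reference"]
    best_hap = hap.loc[hap.groupby("read_id")["identity"].idxmax()]
    best_ref = ref.loc[ref.groupby("read_id")["gap_compressed_identity"].idxmax()]
    merged = best_hap[["read_id", "target", "identity"]].merge(
        best_ref[["read_id", "gap_compressed_identity"]], on="read_id", how="left"
    )
    merged = merged.rename(columns={
        "target": "haplotype_id",
        "identity": "hap_identity",
        "gap_compressed_identity": "ref_identity",
    })
    merged["divergent"] = [
        reference_divergent(
            h, None if pd.isna(r) else float(r), hap_threshold, ref_threshold
        )
        for h, r in zip(merged["hap_identity"], merged["ref_identity"])
    ]
    return merged


def rare_duplication_filter(
    regions: pd.DataFrame, max_carriers: int = MAX_CARRIER_HAPLOTYPES
) -> pd.DataFrame:
    """Restrict candidate regions to those carried by at most
    ``max_carriers`` haplotypes (the low-frequency duplication focus)."""
    return regions[regions["haplotype_count"] <= max_carriers]


def count_novel_families(predictions: pd.DataFrame) -> tuple[pd.Series, int]:
    """Per-family novel-gene counts and their total.

    ``predictions`` rows carry family_id, haplotype_id, gene_id.  For each
    family the count is the number of predictions on the haplotype with
    the greatest number of that family's novel paralogs (ties broken by
    lexicographic haplotype_id, which cannot change the count).  The total
    sums over families.
    """
    if len(predictions) == 0:
        return pd.Series(dtype=int), 0
    per_hap = predictions.groupby(["family_id", "haplotype_id"]).size()
    counts = per_hap.groupby("family_id").max().astype(int)
    return counts, int(counts.sum())


def classify_prediction_region(
    locus: tuple[str, int, int],
    reference_sd,
    per_hap_sd: dict[str, list[tuple[str, int, int]]],
) -> str:
    """Three-way location class of a novel-gene locus (reference frame).

    reference_sd if it overlaps the reference SD annotation by ≥ 1 bp;
    else haplotype_sd_only if it lies inside any haplotype's SD intervals;
    else unique.  A locus that could not be projected (None) is
    "unplaced".
    """
    if locus is None:
        return "unplaced"
    chrom, start, end = locus
    if start >= end:
        raise ValidationError(f"empty locus [{start},{end})")

    def overlaps(intervals) -> bool:
        return any(c == chrom and s < end and e > start for c, s, e, *_ in intervals)

    if overlaps(reference_sd):
        return "reference_sd"
    for intervals in per_hap_sd.values():
        if overlaps(intervals):
            return "haplotype_sd_only"
    return "unique"
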