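"""Readers and writers for the on-disk formats of the SD analysis pipeline.

All coordinates are 0-based half-open (BED convention), both in memory and
on disk.  Chromosome names are taken verbatim from input files; no "chr"
normalisation is performed, so mixed naming dialects fail loudly at
validation time.

File contracts
--------------
SD pair table (TSV, 10 columns)
    haplotype_id, chrom_a, start_a, end_a, chrom_b, start_b, end_b,
    orientation (+/-), identity (float), length (int)

Alignment blocks (TSV, 9 columns)
    haplotype_id, hap_chrom, hap_start, hap_end, strand (+/-),
    ref_chrom, ref_start, ref_end, block_id

Population labels (TSV, 4 columns)
    sample_id, haplotype_id, superpopulation (AFR / non-AFR), population

Region catalog
    BED5 (chrom, start, end, freq_class, haplotype_count) plus a TSV
    presence matrix (region rows, haplotype columns, 0/1 entries).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Operational SD definition: >90% identity and >1 kb length.
MIN_SD_IDENTITY = 0.90
MIN_SD_LENGTH = 1000

ORIENTATIONS = ("direct", "inverted")
FREQ_CLASSES = ("fixed", "polymorphic_known", "polymorphic_novel", "private")


class FormatError(ValueError):
    """Malformed record in an input file (carries the offending line number)."""


class ValidationError(ValueError):
    """Record parsed but violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SDPair:
    """One aligned duplication pair from a haplotype call set.

    ``length`` is the span of mate A (``end_a - start_a``); identity is the
    alignment identity between the two mates, bounded below by the 90%
    operational threshold.
    """

    haplotype_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str  # "direct" | "inverted"
    identity: float
    length: int

    def validate(self) -> None:
        if self.start_a >= self.end_a:
            raise ValidationError(
                f"empty/negative mate A interval [{self.start_a},{self.end_a})"
            )
        if self.start_b >= self.end_b:
            raise ValidationError(
                f"empty/negative mate B interval [{self.start_b},{self.end_b})"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValidationError(f"identity {self.identity} outside [0,1]")
        if self.length != self.end_a - self.start_a:
            raise ValidationError("length does not equal end_a - start_a")

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom_a == self.chrom_b

    def passes_sd_definition(self) -> bool:
        """The operational SD definition: >90% identity and >1 kb."""
        return self.identity > MIN_SD_IDENTITY and self.length > MIN_SD_LENGTH


@dataclass(frozen=True)
class AlignmentBlock:
    """A gap-free 1-to-1 alignment block between a haplotype assembly and
    the reference.  Both sides have equal length; indels are represented by
    block boundaries, not within blocks."""

    haplotype_id: str
    hap_chrom: str
    hap_start: int
    hap_end: int
    strand: str  # "+" | "-"
    ref_chrom: str
    ref_start: int
    ref_end: int
    block_id: str = ""

    def validate(self) -> None:
        if self.hap_start >= self.hap_end or self.ref_start >= self.ref_end:
            raise ValidationError("empty alignment block interval")
        if (self.hap_end - self.hap_start) != (self.ref_end - self.ref_start):
            raise ValidationError(
                f"block {self.block_id or '?'}: unequal lengths "
                f"hap {self.hap_end - self.hap_start} vs ref {self.ref_end - self.ref_start}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")


@dataclass
class GenomeLayout:
    """Ordered chromosome names with lengths, plus excluded intervals
    (acrocentric-arm proxies, assembly gaps)."""

    chrom_lengths: dict[str, int]
    excluded: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has length {length}")
        for chrom, start, end in self.excluded:
            if chrom not in self.chrom_lengths:
                raise ValidationError(f"excluded interval on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValidationError(
                    f"excluded interval [{start},{end}) outside {chrom} bounds"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def excluded_on(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.excluded if c == chrom]


@dataclass
class PopulationLabels:
    """Sample/haplotype bookkeeping: each sample has exactly two haplotypes
    and one superpopulation label (AFR or non-AFR)."""

    sample_of: dict[str, str]          # haplotype_id -> sample_id
    superpop_of: dict[str, str]        # sample_id -> "AFR" | "non-AFR"
    population_of: dict[str, str]      # sample_id -> finer label

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for hap, sample in self.sample_of.items():
            if sample not in self.superpop_of:
                raise ValidationError(f"haplotype {hap} maps to unlabelled sample {sample}")
            counts[sample] = counts.get(sample, 0) + 1
        for sample, n in counts.items():
            if n != 2:
                raise ValidationError(f"sample {sample} has {n} haplotypes, expected 2")

    @property
    def haplotypes(self) -> list[str]:
        return list(self.sample_of)

    @property
    def samples(self) -> list[str]:
        return list(self.superpop_of)

    def haplotypes_of(self, sample: str) -> list[str]:
        return [h for h, s in self.sample_of.items() if s == sample]

    def afr_samples(self) -> list[str]:
        return [s for s, p in self.superpop_of.items() if p == "AFR"]

    def nonafr_samples(self) -> list[str]:
        return [s for s, p in self.superpop_of.items() if p != "AFR"]

    def is_afr_hap(self, hap: str) -> bool:
        return self.superpop_of[self.sample_of[hap]] == "AFR"


# ---------------------------------------------------------------------------
# SD pairs
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "haplotype_id", "chrom_a", "start_a", "end_a",
    "chrom_b", "start_b", "end_b", "orientation", "identity", "length",
]


def read_sd_pairs(
    path: str | os.PathLike,
    frame: str = "reference",
    layout: GenomeLayout | None = None,
) -> tuple[list[SDPair], int]:
    """Read an SD pair table.

    Records failing the operational SD definition (identity > 0.90 and
    length > 1000) are dropped, not erred; the second return value is the
    drop count.  ``frame`` is advisory metadata ("reference" or "assembly");
    when a ``layout`` is given (reference frame), chromosome names are
    validated against it.

    Raises :class:`FormatError` naming the line for malformed rows and
    :class:`ValidationError` for invariant violations.
    """
    if frame not in ("reference", "assembly"):
        raise ValueError(f"unknown frame {frame!r}")
    pairs: list[SDPair] = []
    dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(f"{path}:{lineno}: expected 10 columns, got {len(fields)}")
            try:
                pair = SDPair(
                    haplotype_id=fields[0],
                    chrom_a=fields[1], start_a=int(fields[2]), end_a=int(fields[3]),
                    chrom_b=fields[4], start_b=int(fields[5]), end_b=int(fields[6]),
                    orientation={"+": "direct", "-": "inverted"}[fields[7]],
                    identity=float(fields[8]),
                    length=int(fields[9]),
                )
            except KeyError:
                raise FormatError(f"{path}:{lineno}: bad orientation {fields[7]!r}") from None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            pair.validate()
            if layout is not None and frame == "reference":
                for chrom in (pair.chrom_a, pair.chrom_b):
                    if chrom not in layout.chrom_lengths:
                        raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if not pair.passes_sd_definition():
                dropped += 1
                continue
            pairs.append(pair)
    return pairs, dropped


def write_sd_pairs(pairs: Iterable[SDPair], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            strand = "+" if p.orientation == "direct" else "-"
            fh.write(
                f"{p.haplotype_id}\t{p.chrom_a}\t{p.start_a}\t{p.end_a}\t"
                f"{p.chrom_b}\t{p.start_b}\t{p.end_b}\t{strand}\t"
                f"{p.identity:.6g}\t{p.length}\n"
            )


# ---------------------------------------------------------------------------
# alignment blocks
# ---------------------------------------------------------------------------

def read_alignment_blocks(path: str | os.PathLike) -> dict[str, list[AlignmentBlock]]:
    """Read 1-to-1 alignment blocks, grouped by haplotype.

    Validates that each block has equal lengths on both sides and that one
    haplotype's blocks do not overlap on the haplotype side.
    """
    by_hap: dict[str, list[AlignmentBlock]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            try:
                block = AlignmentBlock(
                    haplotype_id=fields[0],
                    hap_chrom=fields[1], hap_start=int(fields[2]), hap_end=int(fields[3]),
                    strand=fields[4],
                    ref_chrom=fields[5], ref_start=int(fields[6]), ref_end=int(fields[7]),
                    block_id=fields[8],
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            block.validate()
            by_hap.setdefault(block.haplotype_id, []).append(block)
    for hap, blocks in by_hap.items():
        _check_hap_side_disjoint(hap, blocks)
    return by_hap


def _check_hap_side_disjoint(hap: str, blocks: Sequence[AlignmentBlock]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_chrom.setdefault(b.hap_chrom, []).append((b.hap_start, b.hap_end))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"haplotype {hap}: overlapping blocks on {chrom}: "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )


def write_alignment_blocks(
    blocks: dict[str, list[AlignmentBlock]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for hap in blocks:
            for b in blocks[hap]:
                fh.write(
                    f"{b.haplotype_id}\t{b.hap_chrom}\t{b.hap_start}\t{b.hap_end}\t"
                    f"{b.strand}\t{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t{b.block_id}\n"
                )


# ---------------------------------------------------------------------------
# labels, layout, BED helpers
# ---------------------------------------------------------------------------

def read_labels(path: str | os.PathLike) -> PopulationLabels:
    df = pd.read_csv(
        path, sep="\t",
        names=["sample_id", "haplotype_id", "superpopulation", "population"],
        dtype=str, comment="#",
    )
    sample_of = dict(zip(df["haplotype_id"], df["sample_id"]))
    if len(sample_of) != len(df):
        raise ValidationError("duplicate haplotype_id in labels file")
    superpop = {}
    popname = {}
    for _, row in df.iterrows():
        prev = superpop.get(row["sample_id"])
        if prev is not None and prev != row["superpopulation"]:
            raise ValidationError(f"sample {row['sample_id']} has conflicting superpopulations")
        superpop[row["sample_id"]] = row["superpopulation"]
        popname[row["sample_id"]] = row["population"]
    return PopulationLabels(sample_of, superpop, popname)


def write_labels(labels: PopulationLabels, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for hap, sample in labels.sample_of.items():
            fh.write(
                f"{sample}\t{hap}\t{labels.superpop_of[sample]}\t"
                f"{labels.population_of.get(sample, 'NA')}\n"
            )


def read_layout(path: str | os.PathLike, excluded_bed: str | os.PathLike | None = None) -> GenomeLayout:
    """Layout TSV: chrom, length.  Optional excluded-region BED."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            lengths[fields[0]] = int(fields[1])
    excluded = read_bed(excluded_bed) if excluded_bed else []
    return GenomeLayout(lengths, [(c, s, e) for c, s, e, *_ in excluded])


def write_layout(layout: GenomeLayout, path: str | os.PathLike,
                 excluded_bed: str | os.PathLike | None = None) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    if excluded_bed is not None:
        write_bed([(c, s, e) for c, s, e in layout.excluded], excluded_bed)


def read_bed(path: str | os.PathLike) -> list[tuple]:
    """Minimal BED reader: returns (chrom, start, end, *extra) tuples,
    validating start < end."""
    out: list[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected ≥3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            out.append((fields[0], start, end, *fields[3:]))
    return out


def write_bed(intervals: Iterable[tuple], path: str | os.PathLike) -> None:
    rows = sorted(intervals, key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# region catalog
# ---------------------------------------------------------------------------

def write_region_catalog(catalog, bed_path, matrix_path) -> None:
    """Write an SD region catalog as BED5 + a 0/1 presence matrix TSV.

    ``catalog`` is an :class:`sdpanpop.sd_catalog.RegionCatalog`.  Output is
    sorted by (chrom, start); re-reading reproduces identical content.
    """
    order = np.lexsort((catalog.regions["start"].to_numpy(),
                        catalog.regions["chrom"].to_numpy()))
    regions = catalog.regions.iloc[order].reset_index(drop=True)
    presence = catalog.presence[order]
    with open(bed_path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                     f"{r['freq_class']}\t{r['haplotype_count']}\n")
    mat = pd.DataFrame(presence, columns=catalog.haplotypes)
    mat.insert(0, "chrom", regions["chrom"])
    mat.insert(1, "start", regions["start"])
    mat.insert(2, "end", regions["end"])
    mat.to_csv(matrix_path, sep="\t", index=False)


def read_region_catalog(bed_path, matrix_path):
    """Inverse of :func:`write_region_catalog` (freq classes and presence
    only; kind and sample counts are not stored in BED5)."""
    from .sd_catalog import RegionCatalog  # local import to avoid a cycle

    bed = read_bed(bed_path)
    mat = pd.read_csv(matrix_path, sep="\t")
    haplotypes = [c for c in mat.columns if c not in ("chrom", "start", "end")]
    presence = mat[haplotypes].to_numpy(dtype=np.int8)
    regions = pd.DataFrame(
        {
            "chrom": [b[0] for b in bed],
            "start": [b[1] for b in bed],
            "end": [b[2] for b in bed],
            "freq_class": [b[3] for b in bed],
            "haplotype_count": [int(b[4]) for b in bed],
        }
    )
    if len(regions) != len(presence):
        raise ValidationError("catalog BED and presence matrix row counts differ")
    return RegionCatalog(regions=regions, presence=presence, haplotypes=haplotypes)


# ---------------------------------------------------------------------------
# tabular odds and ends
# ---------------------------------------------------------------------------

def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def validate_bed_output(path: str | os.PathLike) -> None:
    """Validator pass over an emitted BED file: 0-based half-open, sorted.

    Raises on any violation; used as a post-write sanity check.
    """
    prev: tuple[str, int] | None = None
    for chrom, start, end, *_ in read_bed(path):
        if prev is not None and (chrom, start) < prev:
            raise ValidationError(f"{path}: not sorted at {chrom}:{start}")
        prev = (chrom, start)
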