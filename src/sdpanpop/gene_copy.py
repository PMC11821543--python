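"""Assembly-based gene copy number.

Paralog alignment hits (one row per gene placement in a haplotype
assembly) are filtered on coverage, identity, repeat containment, CDS
length and optionally distance to the nearest assembly break; retained
hits are counted per haplotype and summed into diploid copy numbers per
sample.  Families aggregate member genes by summation, and copy-number
variability is ranked by the index of dispersion (sample variance divided
by mean).

Hit table columns (TSV): gene_id, haplotype_id, target_chrom,
target_start, target_end, coverage, identity, repeat_overlap, cds_bp,
distance_to_break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PopulationLabels, ValidationError

MIN_COVERAGE = 0.60
MIN_IDENTITY = 0.90
MIN_CDS_BP = 200
BREAK_FLANK_BP = 30_000

HIT_COLUMNS = [
    "gene_id", "haplotype_id", "target_chrom", "target_start", "target_end",
    "coverage", "identity", "repeat_overlap", "cds_bp", "distance_to_break",
]


@dataclass
class CopyNumberMatrix:
    """Unit (gene or family) × sample diploid copy numbers."""

    values: pd.DataFrame            # rows: unit ids, columns: sample ids
    unit: str                       # "gene" | "family"
    method: str                     # "assembly" | "read_depth"
    excluded_units: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["unit_id", "reason"])
    )

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative copy number")

    def dispersion(self) -> pd.Series:
        """Per-unit index of dispersion across samples."""
        return self.values.apply(lambda row: dispersion_index(row.to_numpy()), axis=1)


def filter_hits(
    hits: pd.DataFrame,
    min_coverage: float = MIN_COVERAGE,
    min_identity: float = MIN_IDENTITY,
    min_cds_bp: int = MIN_CDS_BP,
    break_flank_bp: int = BREAK_FLANK_BP,
    flank_filter: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the paralog hit filters; returns retained hits and a tally of
    rejections by (first-failing) reason.

    Retention requires coverage > ``min_coverage`` and identity >
    ``min_identity`` (both strict), a hit not fully contained in repeat
    annotation (repeat_overlap < 1 to machine precision), gene CDS ≥
    ``min_cds_bp``, and — when ``flank_filter`` is on, as in
    paralog-resolved reporting — no assembly break within
    ``break_flank_bp``.
    """
    for col in ("coverage", "identity", "repeat_overlap"):
        vals = hits[col]
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError(f"{col} outside [0,1]")
    tally = {"coverage": 0, "identity": 0, "repeat_contained": 0, "short_cds": 0, "break_flank": 0}
    keep = np.ones(len(hits), dtype=bool)

    def reject(mask: np.ndarray, reason: str) -> None:
        newly = mask & keep
        tally[reason] += int(newly.sum())
        keep[newly] = False

    reject((hits["coverage"] <= min_coverage).to_numpy(), "coverage")
    reject((hits["identity"] <= min_identity).to_numpy(), "identity")
    reject(np.isclose(hits["repeat_overlap"].to_numpy(), 1.0) |
           (hits["repeat_overlap"].to_numpy() >= 1.0), "repeat_contained")
    reject((hits["cds_bp"] < min_cds_bp).to_numpy(), "short_cds")
    if flank_filter:
        reject((hits["distance_to_break"] < break_flank_bp).to_numpy(), "break_flank")
    return hits[keep].reset_index(drop=True), tally


def assembly_copy_number(
    hits: pd.DataFrame,
    labels: PopulationLabels,
    exclude_single_haplotype: bool = True,
) -> CopyNumberMatrix:
    """Diploid gene copy number per sample from retained paralog hits.

    CN(gene, sample) = hit count in haplotype 1 + hit count in haplotype 2.
    Genes whose extra copies (per-haplotype count > 1) occur in exactly one
    haplotype across the whole cohort are flagged as potential assembly
    artefacts; with ``exclude_single_haplotype`` they are dropped from
    downstream family statistics (kept in the matrix for inspection via
    ``excluded_units``).
    """
    for sample in labels.samples:
        if len(labels.haplotypes_of(sample)) != 2:
            raise ValidationError(f"sample {sample} missing a haplotype")
    counts = (
        hits.groupby(["gene_id", "haplotype_id"]).size().unstack(fill_value=0)
    )
    genes = counts.index.tolist()
    mat = pd.DataFrame(0, index=genes, columns=labels.samples, dtype=int)
    for sample in labels.samples:
        h1, h2 = labels.haplotypes_of(sample)
        c1 = counts[h1] if h1 in counts.columns else 0
        c2 = counts[h2] if h2 in counts.columns else 0
        mat[sample] = c1 + c2
    flagged = []
    extra = counts > 1
    n_haps_with_extra = extra.sum(axis=1)
    for gene in genes:
        if n_haps_with_extra[gene] == 1:
            flagged.append(gene)
    excluded = pd.DataFrame(
        {"unit_id": flagged, "reason": ["single_haplotype_duplication"] * len(flagged)}
    )
    if not exclude_single_haplotype:
        excluded = excluded.iloc[0:0]
    return CopyNumberMatrix(values=mat, unit="gene", method="assembly",
                            excluded_units=excluded)


def family_copy_number(
    gene_matrix: CopyNumberMatrix, families: dict[str, str]
) -> CopyNumberMatrix:
    """Aggregate a gene-level matrix to families (sum of member genes),
    dropping genes flagged in ``excluded_units``.

    ``families`` maps gene_id → family_id and must cover every gene.
    """
    if gene_matrix.unit != "gene":
        raise ValidationError("family aggregation requires a gene-level matrix")
    dropped = set(gene_matrix.excluded_units["unit_id"])
    rows = gene_matrix.values.drop(index=[g for g in dropped if g in gene_matrix.values.index])
    missing = [g for g in rows.index if g not in families]
    if missing:
        raise ValidationError(f"genes without family assignment: {missing[:5]}")
    fam = rows.groupby([families[g] for g in rows.index]).sum()
    fam.index.name = "family_id"
    return CopyNumberMatrix(values=fam, unit="family", method=gene_matrix.method)


def dispersion_index(values) -> float:
    """Index of dispersion: sample variance (n−1 denominator) over mean."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean <= 0:
        raise ValidationError("dispersion index undefined for mean ≤ 0")
    if v.size < 2:
        return 0.0
    return float(v.var(ddof=1) / mean)


def rank_families(
    matrix: CopyNumberMatrix,
    min_mean_cn: float = 3.0,
    top_k: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Most- and least-variable family rankings by dispersion index.

    Only families with mean diploid CN strictly greater than
    ``min_mean_cn`` are eligible.  Ties break lexicographically by
    family_id.  Returns (most_variable, least_variable) tables with columns
    family_id, mean_cn, dispersion.
    """
    if matrix.unit != "family":
        raise ValidationError("ranking requires a family-level matrix")
    means = matrix.values.mean(axis=1)
    eligible = matrix.values[means > min_mean_cn]
    table = pd.DataFrame({
        "family_id": eligible.index,
        "mean_cn": means[eligible.index].to_numpy(),
        "dispersion": [dispersion_index(eligible.loc[f].to_numpy()) for f in eligible.index],
    })
    if len(table) < top_k:
        warnings.warn(
            f"only {len(table)} families eligible (requested top {top_k})",
            stacklevel=2,
        )
    most = table.sort_values(["dispersion", "family_id"],
                             ascending=[False, True]).head(top_k).reset_index(drop=True)
    least = table.sort_values(["dispersion", "family_id"],
                              ascending=[True, True]).head(top_k).reset_index(drop=True)
    return most, least
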