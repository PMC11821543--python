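"""Windowed read-depth copy number with GC recalibration.

The estimator follows the standard windowed read-depth scheme: fixed-size
non-overlapping windows tile the genome; windows overlapping tandem-repeat
or low-complexity annotation by more than 10% are excluded; a GC correction
model is fitted on a noiseless "self sample" (the reference decomposed
against itself at uniform expected depth, so any depth structure it shows
is pure GC bias); corrected depth is scaled to diploid copy number against
a baseline of known CN=2 regions.  Gene copy number is the median of
windows fully contained in the gene span, optionally multiplied by a
per-gene adjustment factor calibrated so the self sample's read-depth CN
matches assembly CN (genes needing more than a 50% adjustment are
excluded).

Window table columns (TSV): chrom, start, end, gc, depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

DEFAULT_WINDOW_SIZE = 1000
MAX_REPEAT_OVERLAP = 0.10
GC_BIN_WIDTH = 0.01
MIN_BIN_OCCUPANCY = 100
MAX_ADJUSTMENT = 0.5


# ---------------------------------------------------------------------------
# window exclusion
# ---------------------------------------------------------------------------

def exclude_windows(
    windows: pd.DataFrame,
    repeats,
    max_overlap: float = MAX_REPEAT_OVERLAP,
) -> pd.DataFrame:
    """Flag windows overlapping repeat annotation by strictly more than
    ``max_overlap`` of their length.

    Returns a copy of ``windows`` with an ``excluded`` boolean column.
    ``repeats`` is an iterable of (chrom, start, end[, ...]) intervals.
    """
    from .sd_catalog import coverage_within

    out = windows.copy()
    reps = [(c, int(s), int(e)) for c, s, e, *_ in repeats]
    if reps:
        frac = coverage_within(out, reps)
    else:
        frac = np.zeros(len(out))
    out["repeat_fraction"] = frac
    out["excluded"] = frac > max_overlap
    return out


# ---------------------------------------------------------------------------
# GC recalibration
# ---------------------------------------------------------------------------

@dataclass
class GCModel:
    """Per-GC-bin depth correction factors.

    ``edges`` are bin boundaries on [0,1] after pooling sparse bins to a
    minimum occupancy; ``factors[i]`` is the mean depth of bin i divided by
    the global mean, so dividing a window's depth by its bin factor
    flattens pure GC structure.
    """

    edges: np.ndarray       # length n_bins + 1
    factors: np.ndarray     # length n_bins
    occupancy: np.ndarray   # length n_bins

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("nonpositive GC correction factor")

    def factor_for(self, gc) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.edges, gc, side="right") - 1,
                      0, len(self.factors) - 1)
        return self.factors[idx]

    def apply(self, windows: pd.DataFrame, depth_col: str = "depth") -> np.ndarray:
        """Corrected depth = depth / bin factor."""
        return windows[depth_col].to_numpy() / self.factor_for(windows["gc"].to_numpy())


def gc_recalibrate(
    self_windows: pd.DataFrame,
    bin_width: float = GC_BIN_WIDTH,
    min_occupancy: int = MIN_BIN_OCCUPANCY,
) -> GCModel:
    """Fit a GC correction model from the uniform self sample.

    The self sample emulates sequencing the reference against itself at
    uniform expected depth; departures of bin mean depth from the global
    mean are attributed to GC bias.  Bins of width ``bin_width`` are pooled
    left-to-right until each pooled bin holds at least ``min_occupancy``
    windows.  Excluded windows (if flagged) are ignored.
    """
    win = self_windows
    if "excluded" in win.columns:
        win = win[~win["excluded"]]
    if len(win) == 0:
        raise ValidationError("no usable windows for GC recalibration")
    gc = win["gc"].to_numpy()
    depth = win["depth"].to_numpy(dtype=float)
    n_fine = int(round(1.0 / bin_width))
    fine_edges = np.linspace(0.0, 1.0, n_fine + 1)
    fine_idx = np.clip(np.digitize(gc, fine_edges) - 1, 0, n_fine - 1)
    counts = np.bincount(fine_idx, minlength=n_fine)
    sums = np.bincount(fine_idx, weights=depth, minlength=n_fine)

    # pool fine bins left-to-right until each pooled bin reaches occupancy
    edges = [0.0]
    pooled_counts, pooled_sums = [], []
    acc_c, acc_s = 0, 0.0
    for i in range(n_fine):
        acc_c += counts[i]
        acc_s += sums[i]
        if acc_c >= min_occupancy:
            edges.append(fine_edges[i + 1])
            pooled_counts.append(acc_c)
            pooled_sums.append(acc_s)
            acc_c, acc_s = 0, 0.0
    if acc_c > 0:
        if pooled_counts:
            # fold the underfull tail into the last pooled bin
            pooled_counts[-1] += acc_c
            pooled_sums[-1] += acc_s
            edges[-1] = 1.0
        else:
            raise ValidationError("empty GC bin after pooling: too few windows")
    edges[-1] = 1.0
    occupancy = np.array(pooled_counts)
    bin_means = np.array(pooled_sums) / occupancy
    global_mean = depth.mean()
    if global_mean <= 0:
        raise ValidationError("self sample has zero mean depth")
    return GCModel(edges=np.array(edges), factors=bin_means / global_mean,
                   occupancy=occupancy)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def baseline_from_regions(
    windows: pd.DataFrame, model: GCModel, unique_regions
) -> float:
    """Mean GC-corrected depth over non-excluded windows inside known CN=2
    (unique) regions — the scale factor mapping corrected depth to CN 2."""
    from .sd_catalog import coverage_within

    win = windows if "excluded" not in windows.columns else windows[~windows["excluded"]]
    cov = coverage_within(win, [(c, int(s), int(e)) for c, s, e, *_ in unique_regions])
    inside = win[cov >= 1.0]
    if len(inside) == 0:
        raise ValidationError("no non-excluded windows inside unique regions")
    return float(model.apply(inside).mean())


def window_cn(
    windows: pd.DataFrame, model: GCModel, baseline_depth: float
) -> pd.DataFrame:
    """Per-window diploid CN = 2 × corrected depth / baseline.

    Excluded windows carry NaN.
    """
    if baseline_depth <= 0:
        raise ValidationError("baseline depth must be positive")
    out = windows.copy()
    cn = 2.0 * model.apply(out) / baseline_depth
    if "excluded" in out.columns:
        cn = np.where(out["excluded"].to_numpy(), np.nan, cn)
    out["cn"] = cn
    return out


def gene_cn_from_windows(
    genes: pd.DataFrame, window_cn_table: pd.DataFrame
) -> pd.Series:
    """Median CN over windows fully contained in each gene span.

    ``genes`` needs gene_id/chrom/start/end columns.  Genes with no usable
    contained window get NaN (tallied by the caller via ``isna``).
    Windows straddling a gene boundary are not used.
    """
    usable = window_cn_table.dropna(subset=["cn"])
    by_chrom = {c: g.sort_values("start") for c, g in usable.groupby("chrom")}
    out = {}
    for _, gene in genes.iterrows():
        g = by_chrom.get(gene["chrom"])
        if g is None:
            out[gene["gene_id"]] = np.nan
            continue
        contained = g[(g["start"] >= gene["start"]) & (g["end"] <= gene["end"])]
        out[gene["gene_id"]] = (
            float(contained["cn"].median()) if len(contained) else np.nan
        )
    return pd.Series(out, name="cn")


# ---------------------------------------------------------------------------
# assembly-anchored adjustment
# ---------------------------------------------------------------------------

def calibrate_adjustment(
    read_depth_cn: pd.Series,
    assembly_cn: pd.Series,
    max_adjustment: float = MAX_ADJUSTMENT,
) -> pd.DataFrame:
    """Per-gene adjustment factors from a reference-matched sample.

    a_g = assembly CN / read-depth CN on the calibration sample; genes with
    \\|a_g − 1| > ``max_adjustment`` are excluded, as are genes whose
    read-depth CN is 0 while assembly CN is positive.  Returns a table with
    columns gene_id, factor, excluded, reason.
    """
    rows = []
    for gene in assembly_cn.index:
        asm = float(assembly_cn[gene])
        rd = float(read_depth_cn.get(gene, np.nan))
        if np.isnan(rd) or (rd == 0 and asm > 0):
            rows.append((gene, np.nan, True, "zero_or_missing_read_depth"))
            continue
        if rd == 0 and asm == 0:
            rows.append((gene, 1.0, False, ""))
            continue
        a = asm / rd
        if abs(a - 1.0) > max_adjustment:
            rows.append((gene, a, True, "adjustment_over_50pct"))
        else:
            rows.append((gene, a, False, ""))
    return pd.DataFrame(rows, columns=["gene_id", "factor", "excluded", "reason"]
                        ).set_index("gene_id")


def apply_adjustment(
    gene_cn: pd.DataFrame | pd.Series, adjustments: pd.DataFrame
) -> pd.DataFrame | pd.Series:
    """Multiply read-depth gene CN by retained adjustment factors; excluded
    genes are dropped."""
    retained = adjustments[~adjustments["excluded"]]
    if isinstance(gene_cn, pd.Series):
        sub = gene_cn[gene_cn.index.isin(retained.index)]
        return sub * retained.loc[sub.index, "factor"]
    sub = gene_cn.loc[gene_cn.index.isin(retained.index)]
    return sub.mul(retained.loc[sub.index, "factor"], axis=0)


def concordance_r2(assembly_matrix: pd.DataFrame, read_depth_matrix: pd.DataFrame) -> float:
    """R² of the least-squares fit of read-depth CN on assembly CN over all
    matched gene × sample pairs."""
    common_genes = assembly_matrix.index.intersection(read_depth_matrix.index)
    common_samples = assembly_matrix.columns.intersection(read_depth_matrix.columns)
    if len(common_genes) == 0 or len(common_samples) == 0:
        raise ValidationError("no overlapping genes/samples between matrices")
    x = assembly_matrix.loc[common_genes, common_samples].to_numpy(dtype=float).ravel()
    y = read_depth_matrix.loc[common_genes, common_samples].to_numpy(dtype=float).ravel()
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.all(x == x[0]):
        raise ValidationError("constant or insufficient predictor for R²")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)
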