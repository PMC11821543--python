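"""Sequence properties of SD pairs: orientation/dispersion classes, rarity
bands, permutation comparisons, the novel-vs-known proximity test and 2×2
enrichment.

Dispersion classes for same-chromosome pairs are mutually exclusive and
based on the inner gap between mate intervals: clustered (≤ 1 Mb),
interspersed (1–50 Mb) and distant (> 50 Mb); pairs on different
chromosomes are interchromosomal and carry no gap.  Rarity bands follow
the cohort convention of rare = carried by at most five haplotypes (< 3%
allele frequency at a 170-haplotype cohort) and common = carried 6–20
times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GenomeLayout, SDPair, ValidationError

CLUSTERED_MAX_GAP = 1_000_000
DISTANT_MIN_GAP = 50_000_000
RARE_MAX_CARRIERS = 5
COMMON_MIN_CARRIERS = 6
COMMON_MAX_CARRIERS = 20
DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class PairClassification:
    pair: SDPair
    orientation: str                # "direct" | "inverted"
    dispersion: str                 # clustered | interspersed | distant | interchromosomal
    gap_bp: int | None              # same-chromosome pairs only


def classify_pair(pair: SDPair) -> PairClassification:
    """Orientation × dispersion classification of one SD pair."""
    if pair.chrom_a != pair.chrom_b:
        return PairClassification(pair, pair.orientation, "interchromosomal", None)
    gap = max(0,
              max(pair.start_a, pair.start_b) - min(pair.end_a, pair.end_b))
    if gap <= CLUSTERED_MAX_GAP:
        dispersion = "clustered"
    elif gap <= DISTANT_MIN_GAP:
        dispersion = "interspersed"
    else:
        dispersion = "distant"
    return PairClassification(pair, pair.orientation, dispersion, gap)


def rarity_band(haplotype_count: int, cohort_size: int) -> tuple[str, float]:
    """Band an SD by carrier count: rare (≤5), common (6–20), other.

    Returns ``(band, allele_frequency)`` with AF = count / cohort size.
    """
    if not 1 <= haplotype_count <= cohort_size:
        raise ValidationError(
            f"carrier count {haplotype_count} outside [1,{cohort_size}]"
        )
    af = haplotype_count / cohort_size
    if haplotype_count <= RARE_MAX_CARRIERS:
        return "rare", af
    if COMMON_MIN_CARRIERS <= haplotype_count <= COMMON_MAX_CARRIERS:
        return "common", af
    return "other", af


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

_STATISTICS = {
    "mean_diff": lambda a, b: float(np.mean(a) - np.mean(b)),
    "median_diff": lambda a, b: float(np.median(a) - np.median(b)),
}


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p_value: float
    direction: str          # "a_higher" | "b_higher" | "none"
    n_perm: int
    alternative: str


def permutation_compare(
    values_a,
    values_b,
    statistic: str = "mean_diff",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    alternative: str = "auto",
    exact: bool | None = None,
) -> PermutationResult:
    """Label-permutation test for a difference between two groups.

    ``alternative``:

    * ``"auto"`` (default): one-sided toward the observed direction; the
      direction is reported alongside the P value.  Because the direction is
      chosen from the data, this P is exploratory — treating it as a fixed
      α-level test doubles the nominal type-I error.
    * ``"greater"`` / ``"less"``: pre-specified one-sided test of
      statistic(a, b) > 0 (resp. < 0); calibrated at its nominal level.
    * ``"two_sided"``: based on the absolute statistic.

    When ``exact`` (default: automatic for pooled sizes ≤ 10) the full set
    of group assignments is enumerated and P is the exact tail fraction.
    Otherwise ``n_perm`` random relabellings are drawn and P uses the
    add-one estimator ``(1 + #extreme) / (1 + n_perm)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    if n_perm < 100:
        raise ValidationError("n_perm must be ≥ 100")
    if statistic not in _STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}")
    stat = _STATISTICS[statistic]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = stat(a, b)
    pooled = np.concatenate([a, b])
    n_a = a.size
    if exact is None:
        exact = pooled.size <= 10
    if exact:
        from itertools import combinations

        perm_stats = []
        idx_all = set(range(pooled.size))
        for idx in combinations(range(pooled.size), n_a):
            rest = sorted(idx_all - set(idx))
            perm_stats.append(stat(pooled[list(idx)], pooled[rest]))
        perm_stats = np.array(perm_stats)
        denom = len(perm_stats)
        add = 0  # the observed assignment is part of the enumeration
    else:
        perm_stats = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            perm_stats[i] = stat(perm[:n_a], perm[n_a:])
        denom = n_perm + 1
        add = 1

    tol = 1e-12
    if alternative == "auto":
        if observed >= 0:
            extreme = int(np.sum(perm_stats >= observed - tol))
        else:
            extreme = int(np.sum(perm_stats <= observed + tol))
    elif alternative == "greater":
        extreme = int(np.sum(perm_stats >= observed - tol))
    elif alternative == "less":
        extreme = int(np.sum(perm_stats <= observed + tol))
    elif alternative == "two_sided":
        extreme = int(np.sum(np.abs(perm_stats) >= abs(observed) - tol))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    p = (add + extreme) / denom
    direction = "none" if observed == 0 else ("a_higher" if observed > 0 else "b_higher")
    return PermutationResult(observed, p, direction,
                             len(perm_stats) if exact else n_perm, alternative)


# ---------------------------------------------------------------------------
# proximity of novel SDs to known SDs
# ---------------------------------------------------------------------------

def _nearest_distance(starts, ends, known_starts, known_ends) -> np.ndarray:
    """Distance from each query interval to its nearest known interval on
    the same chromosome (0 when overlapping).  Known intervals must be
    sorted and pairwise disjoint (a flattened set)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    idx = np.searchsorted(known_starts, starts, side="right")
    n = len(known_starts)
    dist = np.full(len(starts), np.inf)
    has_left = idx >= 1
    dist[has_left] = np.maximum(0, starts[has_left] - known_ends[idx[has_left] - 1])
    has_right = idx < n
    right_gap = np.maximum(0, known_starts[idx[has_right]] - ends[has_right])
    dist[has_right] = np.minimum(dist[has_right], right_gap)
    return dist


def proximity_permutation(
    novel_regions,
    known_sd,
    layout: GenomeLayout,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Test whether novel SD regions lie closer to known SDs than uniform
    random placement.

    The statistic is the median distance from each novel region to its
    nearest known SD (0 for overlaps).  The null re-places each novel
    region uniformly at random on its own chromosome, length-preserving,
    avoiding the layout's excluded intervals.  The alternative direction is
    fixed in advance (closer than random), so the P value — add-one
    estimator over ``n_perm`` placements — is calibrated at its nominal
    level under the uniform null.
    """
    from .sd_catalog import flatten_union

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    novel = [(c, int(s), int(e)) for c, s, e in novel_regions]
    if not novel:
        raise ValidationError("no novel regions supplied")
    flat_known, _ = flatten_union([(c, int(s), int(e)) for c, s, e, *_ in known_sd])
    known_sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for c, _, _ in flat_known}:
        arr = np.array([(s, e) for c, s, e in flat_known if c == chrom], dtype=np.int64)
        known_sorted[chrom] = (arr[:, 0], arr[:, 1])

    # chromosomes without known SDs get a finite sentinel distance so the
    # median stays well defined under both observed and null placements
    sentinel = float(layout.total_bp)

    def distances(chroms, starts, ends) -> np.ndarray:
        out = np.full(len(starts), sentinel)
        for chrom, (ks, ke) in known_sorted.items():
            mask = chroms == chrom
            if mask.any():
                out[mask] = _nearest_distance(starts[mask], ends[mask], ks, ke)
        return out

    chroms = np.array([c for c, _, _ in novel])
    obs_starts = np.array([s for _, s, _ in novel], dtype=np.int64)
    obs_ends = np.array([e for _, _, e in novel], dtype=np.int64)
    observed = float(np.median(distances(chroms, obs_starts, obs_ends)))

    # allowed placement space per chromosome: gaps between excluded intervals
    allowed: dict[str, list[tuple[int, int]]] = {}
    for chrom, clen in layout.chrom_lengths.items():
        cursor, gaps = 0, []
        for s, e in sorted(layout.excluded_on(chrom)):
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < clen:
            gaps.append((cursor, clen))
        allowed[chrom] = gaps

    # draw all null placements per region at once
    null_starts = np.empty((len(novel), n_perm), dtype=np.int64)
    for i, (chrom, s, e) in enumerate(novel):
        length = e - s
        gaps = [(gs, ge) for gs, ge in allowed.get(chrom, []) if ge - gs >= length]
        if not gaps:
            raise ValidationError(
                f"region of length {length} does not fit on {chrom} after exclusions"
            )
        widths = np.array([ge - gs - length + 1 for gs, ge in gaps], dtype=np.int64)
        cum = np.cumsum(widths)
        u = rng.integers(0, cum[-1], size=n_perm)
        gap_idx = np.searchsorted(cum, u, side="right")
        offset_in_gap = u - (cum[gap_idx] - widths[gap_idx])
        null_starts[i] = np.array([g[0] for g in gaps], dtype=np.int64)[gap_idx] + offset_in_gap

    lengths = (obs_ends - obs_starts)[:, None]
    null_dists = np.full((len(novel), n_perm), sentinel)
    for chrom, (ks, ke) in known_sorted.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        sub_starts = null_starts[mask].ravel()
        sub_ends = (null_starts[mask] + lengths[mask]).ravel()
        null_dists[mask] = _nearest_distance(sub_starts, sub_ends, ks, ke).reshape(
            int(mask.sum()), n_perm
        )
    null_medians = np.median(null_dists, axis=0)
    extreme = int(np.sum(null_medians <= observed))
    p = (1 + extreme) / (1 + n_perm)
    return PermutationResult(observed, p, "closer", n_perm, "less")


# ---------------------------------------------------------------------------
# 2×2 enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    continuity_corrected: bool


def enrichment_2x2(table) -> EnrichmentResult:
    """Sample odds ratio (ad/bc) and two-sided Fisher exact P for a 2×2
    count table.

    A zero row or column margin is an error.  A single zero cell yields a
    Haldane–Anscombe continuity-corrected odds ratio (0.5 added to every
    cell for the point estimate only), flagged in the result; the exact P
    always uses the raw counts.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("expected a nonnegative 2×2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("zero margin in 2×2 table")
    a, b, c, d = t.ravel()
    corrected = False
    if b * c == 0 or a * d == 0:
        odds = float((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
        corrected = True
    else:
        odds = float(a * d) / float(b * c)
    # two-sided exact P: sum of hypergeometric probabilities ≤ observed
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return EnrichmentResult(odds, float(p), corrected)
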