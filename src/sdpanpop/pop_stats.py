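"""Population statistics: Mann–Whitney rank tests, Benjamini–Hochberg
correction, directional binomial tests, and the African vs non-African
copy-number differentiation workflow with two-cohort replication.

The differentiation scheme mirrors the three-way design used for cohort
copy-number analysis: per-family Mann–Whitney across superpopulation
groups restricted to families that are copy-number variable (dispersion
index ≥ 0.1) with mean diploid CN > 2 in African or non-African samples,
BH correction over the eligible set, and a one-sided exact binomial
summary of the direction balance among significant families.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_copy import CopyNumberMatrix, dispersion_index
from .io_formats import PopulationLabels, ValidationError

EXACT_MAX_N = 12
MIN_DISPERSION = 0.1
MIN_MEAN_CN = 2.0
DEFAULT_ALPHA = 0.05


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact by full enumeration of group assignments when the pooled size is
    ≤ 12 (handles ties via average ranks); otherwise the normal
    approximation with tie correction and continuity correction.  Returns
    (U of group a, two-sided P).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    m, n = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:m].sum() - m * (m + 1) / 2)
    if m + n <= EXACT_MAX_N:
        # permutation distribution of U under exchangeability; two-sided by
        # distance of U from its null centre mn/2
        centre = m * n / 2
        obs_dev = abs(u_obs - centre)
        total = 0
        extreme = 0
        for idx in combinations(range(m + n), m):
            u = float(ranks[list(idx)].sum() - m * (m + 1) / 2)
            total += 1
            if abs(u - centre) >= obs_dev - 1e-9:
                extreme += 1
        return u_obs, extreme / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values outside [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_direction(k: int, n: int) -> float:
    """One-sided exact binomial P toward the observed direction.

    P = Pr(X ≥ max(k, n−k)) under X ~ Binomial(n, ½); symmetric in
    (k, n−k).
    """
    if n <= 0:
        raise ValidationError("binomial test requires n > 0")
    if not 0 <= k <= n:
        raise ValidationError(f"k={k} outside [0,{n}]")
    m = max(k, n - k)
    return float(stats.binom.sf(m - 1, n, 0.5))


# ---------------------------------------------------------------------------
# copy-number differentiation
# ---------------------------------------------------------------------------

@dataclass
class DifferentiationSummary:
    results: pd.DataFrame       # per eligible family
    n_eligible: int
    n_significant: int
    n_afr_higher: int
    n_nonafr_higher: int
    direction_binomial_p: float | None

    def significant(self) -> pd.DataFrame:
        return self.results[self.results["significant"]]


def cn_differentiation(
    matrix: CopyNumberMatrix,
    labels: PopulationLabels,
    min_dispersion: float = MIN_DISPERSION,
    min_mean_cn: float = MIN_MEAN_CN,
    alpha: float = DEFAULT_ALPHA,
    strict_alpha: bool = False,
) -> DifferentiationSummary:
    """African vs non-African copy-number differentiation per family.

    Eligibility is evaluated within each superpopulation group and granted
    if either group has dispersion index ≥ ``min_dispersion`` and mean CN
    > ``min_mean_cn``.  Significance is adjusted P ≤ alpha (or < alpha
    with ``strict_alpha``, the convention used for very large read-depth
    cohorts).  Direction is the sign of the AFR − non-AFR mean difference
    among significant families, summarised by a one-sided exact binomial
    test against an even split.
    """
    afr = [s for s in matrix.values.columns if labels.superpop_of.get(s) == "AFR"]
    nonafr = [s for s in matrix.values.columns if labels.superpop_of.get(s) not in (None, "AFR")]
    if len(afr) < 2 or len(nonafr) < 2:
        raise ValidationError("need ≥2 samples per superpopulation group")

    rows = []
    for fam in matrix.values.index:
        va = matrix.values.loc[fam, afr].to_numpy(dtype=float)
        vn = matrix.values.loc[fam, nonafr].to_numpy(dtype=float)
        eligible = False
        for v in (va, vn):
            if v.mean() > min_mean_cn and v.mean() > 0 and dispersion_index(v) >= min_dispersion:
                eligible = True
        if not eligible:
            continue
        u, p = mann_whitney(va, vn)
        rows.append({
            "family_id": fam,
            "statistic": u,
            "raw_p": p,
            "afr_mean": va.mean(),
            "nonafr_mean": vn.mean(),
        })
    if not rows:
        import warnings

        warnings.warn("no eligible families for differentiation", stacklevel=2)
        empty = pd.DataFrame(columns=[
            "family_id", "statistic", "raw_p", "afr_mean", "nonafr_mean",
            "adj_p", "significant", "direction",
        ])
        return DifferentiationSummary(empty, 0, 0, 0, 0, None)
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["raw_p"].to_numpy())
    sig = table["adj_p"] < alpha if strict_alpha else table["adj_p"] <= alpha
    table["significant"] = sig
    table["direction"] = np.where(
        sig,
        np.where(table["afr_mean"] > table["nonafr_mean"], "AFR_higher", "nonAFR_higher"),
        "",
    )
    n_afr_higher = int((table["direction"] == "AFR_higher").sum())
    n_nonafr_higher = int((table["direction"] == "nonAFR_higher").sum())
    n_sig = n_afr_higher + n_nonafr_higher
    binom_p = binomial_direction(n_afr_higher, n_sig) if n_sig > 0 else None
    return DifferentiationSummary(
        results=table,
        n_eligible=len(table),
        n_significant=n_sig,
        n_afr_higher=n_afr_higher,
        n_nonafr_higher=n_nonafr_higher,
        direction_binomial_p=binom_p,
    )


def replication(
    primary: DifferentiationSummary,
    secondary: DifferentiationSummary,
) -> pd.DataFrame:
    """Two-cohort replication of differentiation calls.

    A family significant in the primary cohort replicates iff it is
    significant with the same direction in the secondary cohort.  Returns
    the primary cohort's significant table with a ``replicated`` column.
    """
    sec = secondary.results.set_index("family_id")
    out = primary.significant().copy()
    replicated = []
    for _, row in out.iterrows():
        fam = row["family_id"]
        if fam in sec.index and bool(sec.loc[fam, "significant"]):
            replicated.append(sec.loc[fam, "direction"] == row["direction"])
        else:
            replicated.append(False)
    out["replicated"] = replicated
    return out.reset_index(drop=True)
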