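"""Levins' niche breadth, dispersal proxy, and zone comparisons.

Levins' niche breadth of OTU ``j`` over ``N`` communities is
``B_j = 1 / sum_i P_ij**2`` where ``P_ij`` is the proportion of OTU ``j``'s
reads found in community ``i`` (proportions sum to 1 over communities, so
``1 <= B_j <= N``).  ``B_com`` is the unweighted mean of ``B_j`` over the
OTUs present in a sample.  Dispersal ability of an OTU is the mean pairwise
shared proportion of its read counts, ``2 * min(n_i, n_k) / (n_i + n_k)``
over sample pairs where it occurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist

from .containers import OtuTable
from .ordination import pairwise_regression

__all__ = [
    "levins_niche_breadth",
    "dispersal_ability",
    "subsample_compare",
    "dispersal_vs_factors",
    "SubsampleComparison",
]


def levins_niche_breadth(table: OtuTable) -> tuple[pd.Series, pd.Series]:
    """Per-OTU Levins' B and per-sample community mean B_com.

    OTUs with zero total reads are excluded with a warning (B undefined).
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    empty = np.asarray(table.otu_ids)[totals == 0]
    if empty.size:
        warnings.warn(f"OTUs with zero total excluded from B: {empty.tolist()}")
    keep = totals > 0
    p = counts[:, keep] / totals[keep]
    b = 1.0 / (p ** 2).sum(axis=0)
    b_otu = pd.Series(b, index=np.asarray(table.otu_ids)[keep], name="B")
    presence = counts[:, keep] > 0
    b_com = pd.Series(
        [b[row].mean() if row.any() else np.nan for row in presence],
        index=table.sample_ids, name="B_com")
    return b_otu, b_com


def dispersal_ability(table: OtuTable) -> tuple[pd.Series, float]:
    """Per-OTU mean pairwise shared proportion and its community mean.

    For OTU ``j`` and sample pair ``(i, k)`` the shared proportion is
    ``2 * min(n_ij, n_kj) / (n_ij + n_kj)``; pairs with zero total are
    excluded.  Assumes equal sample depths (rarefy first).
    """
    counts = table.counts.to_numpy(dtype=float)
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    iu = np.triu_indices(n, k=1)
    scores = {}
    for j, otu in enumerate(table.otu_ids):
        c = counts[:, j]
        if c.sum() == 0:
            continue
        mins = np.minimum(c[iu[0]], c[iu[1]])
        sums = c[iu[0]] + c[iu[1]]
        valid = sums > 0
        if not valid.any():
            continue
        scores[otu] = float((2.0 * mins[valid] / sums[valid]).mean())
    per_otu = pd.Series(scores, name="dispersal")
    return per_otu, float(per_otu.mean())


@dataclass
class SubsampleComparison:
    """Down-sampled comparison of a statistic between two sample groups."""

    statistic: str
    group_a_mean: float
    group_b_mean: float
    subsample_means: np.ndarray
    wilcoxon_stat: float
    wilcoxon_p: float
    n_iter: int


def _group_statistic(table: OtuTable, samples, statistic: str) -> pd.Series:
    sub = table.subset_samples(samples).drop_empty_otus()
    if statistic == "B_com":
        _, b_com = levins_niche_breadth(sub)
        return b_com
    if statistic == "dispersal":
        per_otu, _ = dispersal_ability(sub)
        # per-sample value: mean dispersal score of OTUs present in the sample
        pres = sub.counts > 0
        vals = {}
        for s in sub.sample_ids:
            present = pres.loc[s]
            otus = [o for o in present.index[present] if o in per_otu.index]
            vals[s] = float(per_otu[otus].mean()) if otus else np.nan
        return pd.Series(vals, name="dispersal")
    raise ValueError(f"unknown statistic {statistic!r}")


def subsample_compare(
    table: OtuTable,
    group_a_samples,
    group_b_samples,
    statistic: str = "B_com",
    n_iter: int = 1000,
    seed: int = 0,
) -> SubsampleComparison:
    """Compare a community statistic between groups with repeated
    down-sampling of the larger group.

    Both Levins' B and the dispersal proxy depend on the number of
    communities they are computed over, so the two groups must be compared
    at matched size: group B is subsampled ``n_iter`` times to |group A| and
    the statistic recomputed on each subsample.  The reported group-B
    per-sample values (and their mean) are averages over the subsamples in
    which each sample was drawn; the group difference is a Wilcoxon
    rank-sum test of group A's per-sample values against those size-matched
    group-B values.
    """
    a = list(group_a_samples)
    b = list(group_b_samples)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if len(b) < len(a):
        warnings.warn("group_b smaller than group_a; flipping direction")
        a, b = b, a
    stat_a = _group_statistic(table, a, statistic)
    rng = np.random.default_rng(seed)
    means = np.empty(n_iter)
    b_sum = pd.Series(0.0, index=b)
    b_n = pd.Series(0, index=b)
    for i in range(n_iter):
        pick = list(rng.choice(b, size=len(a), replace=False))
        vals = _group_statistic(table, pick, statistic)
        means[i] = float(vals.mean())
        b_sum[pick] += vals.to_numpy()
        b_n[pick] += 1
    stat_b = b_sum / b_n.replace(0, np.nan)
    w = scipy.stats.ranksums(stat_a.dropna(), stat_b.dropna())
    return SubsampleComparison(
        statistic=statistic,
        group_a_mean=float(stat_a.mean()),
        group_b_mean=float(stat_b.mean()),
        subsample_means=means,
        wilcoxon_stat=float(w.statistic),
        wilcoxon_p=float(w.pvalue),
        n_iter=n_iter,
    )


def dispersal_vs_factors(table: OtuTable, metadata: pd.DataFrame,
                         factors: dict | None = None) -> pd.DataFrame:
    """Regress pairwise community dispersal similarity against distance
    factors (depth distance, geographic distance, water-mass distance).

    The per-pair dispersal score is the mean over OTUs of the pairwise
    shared proportion for that pair.  ``factors`` maps factor name to a
    condensed or square pairwise distance; by default depth distance,
    great-circle distance and Euclidean water-mass distance over
    standardised temperature/salinity/dissolved oxygen are derived from the
    metadata.  Returns one OLS row (slope, intercept, r2, p) per factor.
    """
    from .ordination import haversine_matrix

    counts = table.counts.to_numpy(dtype=float)
    n = counts.shape[0]
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mins = np.minimum(counts[iu[0], :], counts[iu[1], :])
        sums = counts[iu[0], :] + counts[iu[1], :]
        shared = np.where(sums > 0, 2.0 * mins / sums, np.nan)
    pair_score = np.nanmean(shared, axis=1)

    md = metadata.loc[table.sample_ids]
    if factors is None:
        factors = {}
        if "depth" in md:
            factors["depth_distance"] = pdist(md[["depth"]].to_numpy())
        if {"latitude", "longitude"} <= set(md.columns):
            geo = haversine_matrix(md["latitude"], md["longitude"])
            factors["geographic_distance"] = geo[iu]
        wm_cols = [c for c in ("temperature", "salinity", "dissolved_oxygen")
                   if c in md.columns]
        if wm_cols:
            z = (md[wm_cols] - md[wm_cols].mean()) / md[wm_cols].std(ddof=1)
            factors["water_mass_distance"] = pdist(z.to_numpy())
    rows = []
    for name, f in factors.items():
        f = np.asarray(f, dtype=float)
        if f.ndim == 2:
            f = f[iu]
        slope, intercept, r2, p = pairwise_regression(pair_score, f)
        rows.append({"factor": name, "slope": slope, "intercept": intercept,
                     "r_squared": r2, "p": p})
    return pd.DataFrame(rows).set_index("factor")
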