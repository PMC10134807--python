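"""Community distances, ordination, group tests and variation partitioning.

Standard community-ecology machinery: Bray-Curtis dissimilarities (relative
abundance based or presence/absence based), principal-coordinate analysis,
ANOSIM and PERMDISP (delegated to scikit-bio), depth-decay regression of
community similarity, alpha diversity (richness, Faith's PD), Moran's
eigenvector maps from geographic coordinates, Kaiser-Guttman PCA axis
retention, and distance-based variation partitioning across four explanatory
blocks with Ezekiel-adjusted R² and permutation tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats import ordination as skb_ordination
from skbio.stats.distance import anosim as _skb_anosim
from skbio.stats.distance import permdisp as _skb_permdisp

from .containers import OtuTable

__all__ = [
    "bray_curtis",
    "pcoa",
    "anosim",
    "permdisp",
    "depth_decay",
    "pairwise_regression",
    "alpha_diversity",
    "faith_pd",
    "haversine_matrix",
    "dbmem_axes",
    "kaiser_guttman_axes",
    "variation_partitioning",
    "VpaResult",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# distances and ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable, presence_absence: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix.

    Computed on per-sample relative abundances; with ``presence_absence`` the
    table is binarised first, giving the Sørensen dissimilarity.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if (table.counts.sum(axis=1) == 0).any():
        empty = table.counts.index[table.counts.sum(axis=1) == 0].tolist()
        raise ValueError(f"distance undefined for all-zero samples: {empty}")
    if presence_absence:
        x = table.presence().to_numpy(dtype=float)
    else:
        x = table.relative_abundance().to_numpy()
    condensed = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def pcoa(dm: DistanceMatrix, warn_negative: bool = False):
    """Principal-coordinate analysis (classical MDS with Gower centering)."""
    if dm.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 samples")
    with warnings.catch_warnings():
        if not warn_negative:
            warnings.simplefilter("ignore", RuntimeWarning)
        return skb_ordination.pcoa(dm, warn_neg_eigval=False)


def _check_groups(groups):
    labels, counts = np.unique(np.asarray(groups), return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")


def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0):
    """Analysis of similarities; returns ``(R, p)``.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4);
    p from ``n_perm`` label permutations.
    """
    _check_groups(groups)
    res = _skb_anosim(dm, list(groups), permutations=n_perm, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


def permdisp(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0):
    """Homogeneity of multivariate dispersions (distance to group spatial
    median in PCoA space); returns ``(F, p)``."""
    _check_groups(groups)
    ndim = min(10, dm.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skb_permdisp(dm, list(groups), permutations=n_perm,
                            dimensions=ndim, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


# ---------------------------------------------------------------------------
# depth decay and generic pairwise regression
# ---------------------------------------------------------------------------

def pairwise_regression(y: np.ndarray, x: np.ndarray, n_perm: int = 0,
                        seed: int = 0):
    """OLS of condensed pairwise ``y`` on condensed pairwise ``x``.

    Returns ``(slope, intercept, r_squared, p)``.  With ``n_perm > 0`` the p
    value is a Mantel-style permutation p (whole samples permuted), otherwise
    the parametric OLS p (which ignores pair non-independence).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    fit = scipy.stats.linregress(x, y)
    r2 = fit.rvalue ** 2
    p = fit.pvalue
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n = int(round((1 + np.sqrt(1 + 8 * len(y))) / 2))
        ymat = squareform(y)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            yp = squareform(ymat[np.ix_(perm, perm)])
            r = scipy.stats.linregress(x, yp).rvalue ** 2
            hits += r >= r2
        p = (hits + 1) / (n_perm + 1)
    return float(fit.slope), float(fit.intercept), float(r2), float(p)


def depth_decay(dm: DistanceMatrix, depths, n_perm: int = 0, seed: int = 0):
    """Regress community similarity (1 - dissimilarity) on pairwise depth
    distance over all sample pairs; returns ``(slope, intercept, r2, p)``."""
    depths = np.asarray(depths, dtype=float)
    if len(depths) != dm.shape[0]:
        raise ValueError("depths must align with the distance matrix")
    if np.ptp(depths) == 0:
        raise ValueError("all depths equal: zero-variance predictor")
    similarity = 1.0 - dm.condensed_form()
    depth_dist = pdist(depths[:, None], metric="euclidean")
    return pairwise_regression(similarity, depth_dist, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def faith_pd(tree: TreeNode, present_tips) -> float:
    """Total branch length of the subtree spanning the present tips,
    including the path to the root."""
    present = set(present_tips)
    if not present:
        return 0.0
    tips = {t.name for t in tree.tips()}
    absent = present - tips
    if absent:
        raise ValueError(f"tips missing from tree: {sorted(absent)}")
    has: dict[int, bool] = {}
    total = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            h = node.name in present
        else:
            h = any(has[id(c)] for c in node.children)
        has[id(node)] = h
        if h:
            total += node.length or 0.0
    return total


def alpha_diversity(table: OtuTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample OTU richness and (if a tree is given) Faith's PD."""
    presence = table.counts > 0
    out = pd.DataFrame({"richness": presence.sum(axis=1)}, index=table.counts.index)
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        absent = [o for o in table.otu_ids if o not in tips]
        if absent:
            raise ValueError(f"OTUs missing from tree: {absent}")
        pd_vals = []
        cols = np.asarray(table.otu_ids)
        for _, row in presence.iterrows():
            pd_vals.append(faith_pd(tree, cols[row.to_numpy()]))
        out["faith_pd"] = pd_vals
    return out


# ---------------------------------------------------------------------------
# spatial eigenvectors (dbMEM)
# ---------------------------------------------------------------------------

def haversine_matrix(latitudes, longitudes) -> np.ndarray:
    """Great-circle distance matrix in km (Earth radius 6371 km)."""
    lat = np.radians(np.asarray(latitudes, dtype=float))
    lon = np.radians(np.asarray(longitudes, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def dbmem_axes(latitudes, longitudes, ids=None) -> pd.DataFrame:
    """Spatial eigenvectors (Moran's eigenvector maps / dbMEM).

    Great-circle distances are truncated at the largest edge of their minimum
    spanning tree (distances beyond it are set to 4x the threshold), the
    truncated matrix is double-centred and eigendecomposed, and the
    orthonormal eigenvectors with positive eigenvalues are returned.
    """
    d = haversine_matrix(latitudes, longitudes)
    n = d.shape[0]
    # distinct locations
    uniq = {(round(a, 9), round(b, 9)) for a, b in zip(latitudes, longitudes)}
    if len(uniq) < 2:
        warnings.warn("all samples co-located: no spatial axes")
        return pd.DataFrame(index=ids if ids is not None else range(n))
    if len(uniq) < 3:
        warnings.warn("fewer than 3 distinct locations: spatial axes unreliable")
    mst = csgraph.minimum_spanning_tree(d).toarray()
    threshold = mst.max()
    trunc = np.where(d <= threshold, d, 4.0 * threshold)
    np.fill_diagonal(trunc, 0.0)
    # Gower double-centering of -0.5 * D^2
    a = -0.5 * trunc ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval).max(), 1.0) * 1e-10
    keep = eigval > tol
    axes = eigvec[:, keep]
    cols = [f"MEM{i + 1}" for i in range(axes.shape[1])]
    return pd.DataFrame(axes, columns=cols,
                        index=ids if ids is not None else range(n))


# ---------------------------------------------------------------------------
# PCA with Kaiser-Guttman retention
# ---------------------------------------------------------------------------

def kaiser_guttman_axes(data: pd.DataFrame, max_axes: int | None = None):
    """PCA on the correlation matrix, retaining axes whose eigenvalue exceeds
    the mean eigenvalue (Kaiser-Guttman); optionally capped at ``max_axes``.

    Returns ``(scores, eigenvalues)`` where ``scores`` holds the retained
    sample scores.
    """
    x = data.astype(float)
    keep_cols = [c for c in x.columns if x[c].std(ddof=0) > 0]
    dropped = [c for c in x.columns if c not in keep_cols]
    if dropped:
        warnings.warn(f"constant variables dropped: {dropped}")
    if len(keep_cols) < 2:
        raise ValueError("need at least 2 non-constant variables")
    x = x[keep_cols]
    z = (x - x.mean()) / x.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retain = np.flatnonzero(eigval > eigval.mean())
    if max_axes is not None:
        retain = retain[:max_axes]
    scores = z.to_numpy() @ eigvec[:, retain]
    cols = [f"PC{i + 1}" for i in retain]
    return pd.DataFrame(scores, columns=cols, index=data.index), eigval


# ---------------------------------------------------------------------------
# variation partitioning
# ---------------------------------------------------------------------------

@dataclass
class VpaResult:
    """Variation partitioning of a community distance matrix.

    ``fractions`` maps a tuple of block names (the blocks sharing that
    fraction) to its Ezekiel-adjusted R² value; ``residual`` is
    1 - total adjusted R².  ``subset_adj_r2`` holds the adjusted R² of every
    block subset; ``unique_p`` the (Bonferroni-corrected) permutation p value
    of each block's unique fraction.
    """

    block_names: list
    fractions: dict
    residual: float
    subset_adj_r2: dict
    unique_p: dict
    n_samples: int

    def total_adj_r2(self) -> float:
        return self.subset_adj_r2[tuple(sorted(self.block_names))]

    def unique_fraction(self, block: str) -> float:
        return self.fractions[(block,)]


def _response_axes(dm: DistanceMatrix) -> np.ndarray:
    ord_res = pcoa(dm)
    eig = ord_res.eigvals.to_numpy()
    keep = eig > max(eig.max(), 1.0) * 1e-10
    return ord_res.samples.to_numpy()[:, keep]


def _redundancy_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Multivariate redundancy statistic: fraction of total response sum of
    squares captured by OLS on ``x`` (with intercept).  Returns (R², rank)."""
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(xc) if xc.size else 0
    if rank == 0:
        return 0.0, 0
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta
    sst = (yc ** 2).sum()
    ssf = (fitted ** 2).sum()
    return float(ssf / sst), int(rank)


def _adjust_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("too few samples for the number of predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variation_partitioning(
    response: DistanceMatrix,
    blocks: dict,
    n_perm: int = 199,
    seed: int = 0,
    bonferroni: bool = True,
) -> VpaResult:
    """Partition community variation among up to four explanatory blocks.

    Distance-based RDA: the response is the set of PCoA axes (positive
    eigenvalues) of the Bray-Curtis matrix; for every subset of blocks the
    redundancy R² is Ezekiel-adjusted, and unique/shared fractions are
    obtained by inclusion-exclusion.  Unique fractions are tested by
    permuting the rows of the corresponding block.
    """
    names = sorted(blocks.keys())
    if not 1 <= len(names) <= 4:
        raise ValueError("need 1 to 4 blocks")
    y = _response_axes(response)
    n = y.shape[0]
    mats = {}
    for name in names:
        x = np.asarray(blocks[name], dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[0] != n:
            raise ValueError(f"block {name!r} not aligned with response")
        if np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
            warnings.warn(f"block {name!r} is rank deficient")
        mats[name] = x
    total_p = sum(m.shape[1] for m in mats.values())
    if n <= total_p + 1:
        raise ValueError("n must exceed the total number of predictors")

    def adj_r2_of(subset) -> float:
        x = np.hstack([mats[b] for b in subset])
        r2, rank = _redundancy_r2(y, x)
        return _adjust_r2(r2, n, rank)

    subsets = []
    for k in range(1, len(names) + 1):
        subsets.extend(itertools.combinations(names, k))
    g = {s: adj_r2_of(s) for s in subsets}

    # solve for individual fractions: g(S) = sum of f(T) over T intersecting S
    a = np.zeros((len(subsets), len(subsets)))
    for i, s in enumerate(subsets):
        for j, t in enumerate(subsets):
            if set(s) & set(t):
                a[i, j] = 1.0
    f = np.linalg.solve(a, np.array([g[s] for s in subsets]))
    fractions = {t: float(v) for t, v in zip(subsets, f)}
    residual = 1.0 - g[tuple(names)]

    # permutation tests on unique fractions
    rng = np.random.default_rng(seed)
    unique_p = {}
    if n_perm > 0:
        full = tuple(names)
        for name in names:
            others = tuple(b for b in names if b != name)
            obs = g[full] - (g[others] if others else 0.0)
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                x_perm = {**mats, name: mats[name][perm]}
                xs = np.hstack([x_perm[b] for b in names])
                r2, rank = _redundancy_r2(y, xs)
                stat = _adjust_r2(r2, n, rank) - (g[others] if others else 0.0)
                hits += stat >= obs
            p = (hits + 1) / (n_perm + 1)
            if bonferroni:
                p = min(1.0, p * len(names))
            unique_p[name] = float(p)
    return VpaResult(block_names=names, fractions=fractions,
                     residual=float(residual), subset_adj_r2=g,
                     unique_p=unique_p, n_samples=n)
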