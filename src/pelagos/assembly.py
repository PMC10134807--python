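"""Community assembly inference.

Three complementary lines of evidence:

* **Sloan neutral community model (NCM)** — predicts an OTU's occurrence
  frequency across local communities from its metacommunity relative
  abundance ``p`` as ``F(p) = 1 - BetaCDF(d; N m p, N m (1 - p))``, with
  ``N`` the local community (read) size, ``m`` the migration probability and
  ``d`` the detection limit (default ``1/N``).  The single free parameter
  ``N m`` is fitted by least squares; goodness of fit R² measures how
  neutral the community looks.
* **Checkerboard C-score** with a fixed-row/fixed-column sequential-swap
  (sim9) null model and a standardized effect size
  ``SES = (obs - null mean) / null SD``; SES > +2 indicates segregation,
  SES < -2 aggregation.
* **Phylogenetic null model** — abundance-weighted β-nearest-taxon index
  (βNTI, tip-label-shuffling null) combined with the Raup-Crick metric on
  Bray-Curtis (RC_bray, probabilistic richness/abundance-preserving null)
  to classify each sample pair into heterogeneous selection, homogeneous
  selection, dispersal limitation, homogenizing dispersal or undominated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from skbio import TreeNode

from .containers import OtuTable

__all__ = [
    "NcmFit",
    "CscoreResult",
    "ProcessPartition",
    "fit_sloan_ncm",
    "c_score",
    "c_score_ses",
    "sim9_null_matrices",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "partition_processes",
    "PROCESS_NAMES",
]

PROCESS_NAMES = [
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
]


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

@dataclass
class NcmFit:
    """Result of fitting Sloan's neutral model to an OTU table."""

    m: float
    Nt_m: float
    N: float
    detection_limit: float
    r_squared: float
    otu_stats: pd.DataFrame  # p, observed_freq, predicted_freq, ci flags
    ci_low: np.ndarray
    ci_high: np.ndarray
    m_ci: tuple

    def __post_init__(self) -> None:
        if not (0.0 < self.m <= 1.0 + 1e-9):
            raise ValueError("fitted m outside (0, 1]")


def _ncm_predicted_freq(p: np.ndarray, ntm: float, d: float) -> np.ndarray:
    a = np.maximum(ntm * p, 1e-12)
    b = np.maximum(ntm * (1.0 - p), 1e-12)
    return 1.0 - scipy.stats.beta.cdf(d, a, b)


def fit_sloan_ncm(
    table: OtuTable,
    detection_limit: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> NcmFit:
    """Fit the Sloan NCM by bounded 1-D least squares on ``N m``.

    ``p`` is each OTU's mean relative abundance, the observed frequency the
    fraction of samples where it is present.  R² = 1 - SSE/SST on the
    untransformed frequencies.  95% confidence bounds on the fitted curve
    (and on ``m``) come from bootstrap resampling OTUs ``n_boot`` times.

    The default detection limit is ``ln(2)/N``: presence in count data means
    "at least one read", a soft binomial threshold whose 50%-detection point
    sits at relative abundance ``1 - 2**(-1/N) ≈ ln(2)/N``, not at ``1/N``.
    Using the hard-cut value ``1/N`` with count-based presence inflates the
    fitted ``N m`` by roughly a quarter; pass ``detection_limit=1/N``
    explicitly for the classic convention.
    """
    counts = table.counts.to_numpy()
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("samples with zero reads")
    N = float(np.mean(totals))
    if not np.allclose(totals, totals[0]):
        warnings.warn("sample depths unequal; using the mean as N "
                      "(rarefy first for a cleaner fit)")
    d = detection_limit if detection_limit is not None else np.log(2.0) / N
    rel = counts / totals[:, None]
    p = rel.mean(axis=0)
    freq = (counts > 0).mean(axis=0)
    keep = p > 0
    p, freq = p[keep], freq[keep]
    otu_ids = np.asarray(table.otu_ids)[keep]
    if len(p) < 3:
        raise ValueError("too few OTUs to fit")

    def sse(log_ntm, pp, ff):
        pred = _ncm_predicted_freq(pp, np.exp(log_ntm), d)
        return ((ff - pred) ** 2).sum()

    def fit_ntm(pp, ff):
        # multistart over a log grid, then local refinement
        grid = np.log(np.logspace(-2, np.log10(max(10.0 * N, 1e3)), 40))
        vals = [sse(g, pp, ff) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = scipy.optimize.minimize_scalar(
            sse, bracket=None, bounds=(g0 - 4.0, g0 + 4.0), args=(pp, ff),
            method="bounded", options={"xatol": 1e-8})
        if not res.success:
            raise RuntimeError(
                "NCM fit failed; objective on grid: "
                + ", ".join(f"{np.exp(g):.3g}:{v:.4g}" for g, v in zip(grid, vals)))
        return float(np.exp(res.x))

    ntm = fit_ntm(p, freq)
    pred = _ncm_predicted_freq(p, ntm, d)
    sst = ((freq - freq.mean()) ** 2).sum()
    r2 = 1.0 - ((freq - pred) ** 2).sum() / sst if sst > 0 else np.nan

    # bootstrap over OTUs: CI band around the fitted curve and CI on m
    rng = np.random.default_rng(seed)
    order = np.argsort(p)
    boot_curves = np.empty((n_boot, len(p)))
    boot_m = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(p), size=len(p))
        try:
            ntm_b = fit_ntm(p[idx], freq[idx])
        except RuntimeError:
            ntm_b = ntm
        boot_curves[b] = _ncm_predicted_freq(p[order], ntm_b, d)
        boot_m[b] = min(ntm_b / N, 1.0)
    if n_boot > 0:
        lo = np.percentile(boot_curves, 2.5, axis=0)
        hi = np.percentile(boot_curves, 97.5, axis=0)
        m_ci = (float(np.percentile(boot_m, 2.5)),
                float(np.percentile(boot_m, 97.5)))
    else:
        lo = hi = _ncm_predicted_freq(p[order], ntm, d)
        m_ci = (np.nan, np.nan)
    lo_full = np.empty(len(p)); hi_full = np.empty(len(p))
    lo_full[order] = lo; hi_full[order] = hi
    stats = pd.DataFrame({
        "p": p,
        "observed_freq": freq,
        "predicted_freq": pred,
        "ci_low": lo_full,
        "ci_high": hi_full,
        "above_ci": freq > hi_full,
        "below_ci": freq < lo_full,
    }, index=otu_ids)
    return NcmFit(m=min(ntm / N, 1.0), Nt_m=ntm, N=N, detection_limit=d,
                  r_squared=float(r2), otu_stats=stats,
                  ci_low=lo, ci_high=hi, m_ci=m_ci)


# ---------------------------------------------------------------------------
# C-score and sim9 null model
# ---------------------------------------------------------------------------

def c_score(presence: np.ndarray) -> float:
    """Mean checkerboard score over all species pairs.

    ``presence`` is a species-by-site binary matrix; for each pair
    ``(i, j)`` the score is ``(R_i - S)(R_j - S)`` with ``R`` the species'
    total occurrences and ``S`` the number of sites holding both.
    """
    b = np.asarray(presence, dtype=np.int64)
    if b.ndim != 2 or b.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 species")
    r = b.sum(axis=1)
    s = b @ b.T
    pair = (r[:, None] - s) * (r[None, :] - s)
    iu = np.triu_indices(b.shape[0], k=1)
    return float(pair[iu].mean())


def _sim9_chain(b: np.ndarray, n_swaps: int, rng) -> None:
    """Run ``n_swaps`` sequential checkerboard-swap attempts in place."""
    n_r, n_c = b.shape
    rows = rng.integers(0, n_r, size=2 * n_swaps)
    cols = rng.integers(0, n_c, size=2 * n_swaps)
    for k in range(n_swaps):
        r1, r2 = rows[2 * k], rows[2 * k + 1]
        if r1 == r2:
            continue
        c1, c2 = cols[2 * k], cols[2 * k + 1]
        if c1 == c2:
            continue
        a = b[r1, c1]
        if a == b[r2, c2] and a != b[r1, c2] and b[r1, c2] == b[r2, c1]:
            b[r1, c1] = b[r2, c2] = 1 - a
            b[r1, c2] = b[r2, c1] = a


def sim9_null_matrices(presence: np.ndarray, n_sim: int, seed: int,
                       burn_in: int | None = None,
                       thin: int | None = None):
    """Yield ``n_sim`` fixed-row/fixed-column null matrices (sim9 swaps).

    Burn-in defaults to 10x the matrix fill (number of occupied cells);
    thinning between saved matrices defaults to the fill.
    """
    b = (np.asarray(presence) > 0).astype(np.int8).copy()
    fill = int(b.sum())
    if burn_in is None:
        burn_in = 10 * max(fill, 1)
    if thin is None:
        thin = max(fill, 1)
    rng = np.random.default_rng(seed)
    _sim9_chain(b, burn_in, rng)
    for _ in range(n_sim):
        _sim9_chain(b, thin, rng)
        yield b


@dataclass
class CscoreResult:
    c_score_obs: float
    c_score_sim_mean: float
    c_score_sim_sd: float
    ses: float
    n_sim: int
    algorithm: str = "sim9_swap"

    @property
    def interpretation(self) -> str:
        if self.ses > 2:
            return "segregation"
        if self.ses < -2:
            return "aggregation"
        return "random"


def c_score_ses(table_or_presence, n_sim: int = 30000, seed: int = 0,
                burn_in: int | None = None, thin: int | None = None) -> CscoreResult:
    """Observed C-score and its standardized effect size against the sim9
    (fixed row and column sums, sequential swap) null model."""
    if isinstance(table_or_presence, OtuTable):
        presence = table_or_presence.presence().to_numpy().T  # species x sites
    else:
        presence = (np.asarray(table_or_presence) > 0).astype(np.int8)
    rows_all = presence.sum(axis=1)
    n_sites = presence.shape[1]
    if ((rows_all == 0) | (rows_all == n_sites)).any():
        warnings.warn("species occurring in no or all sites contribute "
                      "constant C-score pairs")
    obs = c_score(presence)
    sims = np.array([c_score(m) for m in
                     sim9_null_matrices(presence, n_sim, seed,
                                        burn_in=burn_in, thin=thin)])
    sd = float(sims.std(ddof=1))
    if sd == 0:
        raise ValueError("null distribution is degenerate (SD = 0); "
                         "SES undefined")
    return CscoreResult(c_score_obs=obs,
                        c_score_sim_mean=float(sims.mean()),
                        c_score_sim_sd=sd,
                        ses=float((obs - sims.mean()) / sd),
                        n_sim=n_sim)


# ---------------------------------------------------------------------------
# beta-NTI
# ---------------------------------------------------------------------------

def _tip_distance_matrix(tree: TreeNode, otu_ids) -> np.ndarray:
    dm = tree.tip_tip_distances(endpoints=list(otu_ids))
    # reorder to otu_ids
    idx = [dm.index(o) for o in otu_ids]
    return dm.data[np.ix_(idx, idx)]


def beta_mntd(rel: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Abundance-weighted between-community mean nearest-taxon distance.

    For each sample pair, each taxon present in one community contributes its
    relative abundance times the distance to its nearest taxon in the other
    community; the two directed sums are averaged.
    """
    n = rel.shape[0]
    out = np.zeros((n, n))
    present = [np.flatnonzero(rel[i] > 0) for i in range(n)]
    for i in range(n):
        for k in range(i + 1, n):
            ti, tk = present[i], present[k]
            sub = dist[np.ix_(ti, tk)]
            wi = rel[i, ti] / rel[i, ti].sum()
            wk = rel[k, tk] / rel[k, tk].sum()
            v = 0.5 * ((wi * sub.min(axis=1)).sum()
                       + (wk * sub.min(axis=0)).sum())
            out[i, k] = out[k, i] = v
    return out


def beta_nti(table: OtuTable, tree: TreeNode, n_null: int = 1000,
             weighted: bool = True, seed: int = 0) -> pd.DataFrame:
    """Pairwise βNTI: z-score of observed βMNTD against a tip-label
    shuffling null (``taxa.labels``)."""
    rel = table.relative_abundance().to_numpy()
    if not weighted:
        pres = (rel > 0).astype(float)
        rel = pres / pres.sum(axis=1, keepdims=True)
    dist = _tip_distance_matrix(tree, table.otu_ids)
    obs = beta_mntd(rel, dist)
    rng = np.random.default_rng(seed)
    n_taxa = rel.shape[1]
    n = rel.shape[0]
    null_sum = np.zeros((n, n))
    null_sumsq = np.zeros((n, n))
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        d_null = dist[np.ix_(perm, perm)]
        bm = beta_mntd(rel, d_null)
        null_sum += bm
        null_sumsq += bm ** 2
    mean = null_sum / n_null
    var = null_sumsq / n_null - mean ** 2
    sd = np.sqrt(np.maximum(var, 0.0) * n_null / max(n_null - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd == 0] = np.nan
    np.fill_diagonal(z, np.nan)
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def _bray(x: np.ndarray, y: np.ndarray) -> float:
    s = x + y
    t = s.sum()
    return float(np.abs(x - y).sum() / t) if t > 0 else 0.0


def raup_crick_bray(table: OtuTable, n_null: int = 1000,
                    seed: int = 0, sample_pairs=None) -> pd.DataFrame:
    """Pairwise RC_bray in [-1, 1].

    Null communities preserve each sample's richness and total reads: taxa
    are drawn without replacement with probability proportional to regional
    occupancy, then reads are distributed multinomially with probability
    proportional to regional relative abundance.  RC = 2 * (fraction of null
    Bray-Curtis below observed + half the ties) - 1.

    ``sample_pairs`` restricts computation to the given (id, id) pairs;
    entries for unevaluated pairs are NaN.  The occupancy/abundance pool is
    always estimated from the full table.
    """
    counts = table.counts.to_numpy()
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty sample")
    n, n_taxa = counts.shape
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    regional_p = regional / regional.sum()
    occ_p = occupancy / occupancy.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    rng = np.random.default_rng(seed)

    def null_community(rich, total):
        chosen = rng.choice(n_taxa, size=rich, replace=False, p=occ_p)
        vec = np.zeros(n_taxa)
        vec[chosen] = 1.0
        if total > rich:
            pr = regional_p[chosen]
            extra = rng.multinomial(total - rich, pr / pr.sum())
            vec[chosen] += extra
        return vec

    idx_of = {s: i for i, s in enumerate(table.sample_ids)}
    if sample_pairs is None:
        todo = [(i, k) for i in range(n) for k in range(i + 1, n)]
    else:
        todo = [(idx_of[a], idx_of[b]) for a, b in sample_pairs]
    rc = np.full((n, n), np.nan)
    for i, k in todo:
        obs = _bray(counts[i].astype(float), counts[k].astype(float))
        less = ties = 0
        for _ in range(n_null):
            b = _bray(null_community(richness[i], totals[i]),
                      null_community(richness[k], totals[k]))
            if abs(b - obs) < 1e-12:
                ties += 1
            elif b < obs:
                less += 1
        rc[i, k] = rc[k, i] = 2.0 * ((less + 0.5 * ties) / n_null) - 1.0
    np.fill_diagonal(rc, np.nan)
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# five-process classification
# ---------------------------------------------------------------------------

@dataclass
class ProcessPartition:
    bnti: pd.DataFrame
    rc: pd.DataFrame
    labels: pd.DataFrame
    fractions: dict = field(default_factory=dict)
    n_pairs: int = 0
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.fractions:
            total = sum(self.fractions.values())
            if self.n_pairs and abs(total - 1.0) > 1e-12:
                raise ValueError("process fractions must sum to 1")


def classify_pair(bnti: float, rc: float) -> str:
    """Five-process rule: |βNTI| > 2 → selection (sign gives direction);
    otherwise RC > +0.95 → dispersal limitation, RC < -0.95 → homogenizing
    dispersal, else undominated."""
    if np.isnan(bnti):
        return "missing"
    if bnti > 2:
        return "heterogeneous_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if np.isnan(rc):
        return "missing"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def partition_processes(bnti: pd.DataFrame, rc: pd.DataFrame) -> ProcessPartition:
    """Assign every sample pair to one of the five assembly processes and
    report the aggregate fractions."""
    if list(bnti.index) != list(rc.index) or list(bnti.columns) != list(rc.columns):
        raise ValueError("βNTI and RC matrices are not aligned")
    ids = list(bnti.index)
    labels = pd.DataFrame("", index=ids, columns=ids, dtype=object)
    counts = {name: 0 for name in PROCESS_NAMES}
    n_pairs = n_missing = 0
    for i in range(len(ids)):
        for k in range(i + 1, len(ids)):
            lab = classify_pair(float(bnti.iloc[i, k]), float(rc.iloc[i, k]))
            labels.iloc[i, k] = labels.iloc[k, i] = lab
            if lab == "missing":
                n_missing += 1
            else:
                counts[lab] += 1
                n_pairs += 1
    fractions = ({name: counts[name] / n_pairs for name in PROCESS_NAMES}
                 if n_pairs else {})
    return ProcessPartition(bnti=bnti, rc=rc, labels=labels,
                            fractions=fractions, n_pairs=n_pairs,
                            n_missing=n_missing)
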