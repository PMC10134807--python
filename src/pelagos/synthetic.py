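"""Synthetic metacommunities with known ground truth.

Emulates a marine depth-transect study (several stations, depths from the
surface to thousands of metres, photic/aphotic zonation, three co-sampled
microbial groups) with controllable assembly regime so that every inference
stage of the pipeline can be verified by parameter recovery:

* **neutral** assembly follows Sloan's model: local relative abundances are
  drawn from a Dirichlet distribution with parameters ``N*m*p`` (``N`` local
  community size, ``m`` migration probability, ``p`` metacommunity relative
  abundances), whose beta marginals are exactly the model's stationary
  distribution; reads are then multinomial.
* **niche** assembly multiplies metacommunity abundances by Gaussian
  environmental responses ``exp(-(env - optimum)^2 / (2 sigma^2))`` before
  multinomial read sampling; ``sigma = 1/niche_strength``.
* **mixed** applies the Gaussian filter to a neutral (Dirichlet) draw.

Phylogenies are pure-birth (Yule) trees; environmental optima evolve by
Brownian motion scaled by ``trait_signal`` plus i.i.d. noise, so
``trait_signal = 0`` gives no phylogenetic signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import OtuTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TransectStudy",
    "logseries_metacommunity",
    "simulate_neutral_metacommunity",
    "simulate_niche_metacommunity",
    "simulate_phylogeny_with_traits",
    "simulate_correlated_counts",
    "simulate_depth_transect_study",
]

#: Depth layers per station mimicking a west-Pacific transect: three stations
#: sampled at six standard depths and two at eleven, 5 m to 2,000 m.
DEFAULT_STATION_DEPTHS = [
    [5, 75, 200, 500, 1000, 2000],
    [5, 75, 200, 500, 1000, 2000],
    [5, 75, 200, 500, 1000, 2000],
    [5, 75, 100, 150, 200, 300, 500, 600, 800, 1000, 2000],
    [5, 75, 100, 150, 200, 300, 500, 600, 800, 1000, 2000],
]

DEFAULT_STATION_LATITUDES = [2.25, 6.0, 10.0, 14.0, 18.0]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic metacommunity study."""

    n_stations: int = 5
    depths_per_station: list = field(default_factory=lambda: [5, 75, 200, 500, 1000, 2000])
    n_otus: int = 200
    n_reads_per_sample: int = 2000
    migration_m: float = 0.15
    regime: str = "neutral"
    niche_strength: float = 2.0
    trait_signal: float = 1.0
    basis_correlation_spec: list = field(default_factory=list)
    photic_boundary: float = 200.0
    env_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.migration_m <= 1.0):
            raise ValueError("migration_m must be in (0, 1]")
        if self.n_reads_per_sample < 1:
            raise ValueError("n_reads_per_sample must be >= 1")
        if self.niche_strength < 0:
            raise ValueError("niche_strength must be nonnegative")
        if self.regime not in {"neutral", "niche", "mixed"}:
            raise ValueError(f"unknown regime {self.regime!r}")
        depths = self.depths_per_station
        per_station = depths if depths and isinstance(depths[0], (list, tuple)) else [depths]
        for d in per_station:
            arr = np.asarray(d, dtype=float)
            if np.any(arr <= 0):
                raise ValueError("depths must be strictly positive")
            if np.any(np.diff(arr) <= 0):
                raise ValueError("depths must be strictly increasing per station")
        for i, j, rho in self.basis_correlation_spec:
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"correlation rho={rho} outside [-1, 1]")

    @property
    def n_samples(self) -> int:
        depths = self.depths_per_station
        if depths and isinstance(depths[0], (list, tuple)):
            return sum(len(d) for d in depths[: self.n_stations])
        return self.n_stations * len(depths)


@dataclass
class GroundTruth:
    """Truth record emitted alongside every generated table."""

    metacommunity_relative_abundances: np.ndarray
    migration_m: float | None = None
    species_env_optima: np.ndarray | None = None
    true_basis_correlations: np.ndarray | None = None
    regime: object = None

    def __post_init__(self) -> None:
        p = np.asarray(self.metacommunity_relative_abundances, dtype=float)
        if np.any(p < 0):
            raise ValueError("metacommunity abundances must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("metacommunity abundances must sum to 1")
        self.metacommunity_relative_abundances = p


@dataclass
class TransectStudy:
    """Bundle returned by :func:`simulate_depth_transect_study`."""

    tables: dict
    metadata: pd.DataFrame
    trees: dict
    truths: dict


# ---------------------------------------------------------------------------
# metacommunity and local-community generators
# ---------------------------------------------------------------------------

def logseries_metacommunity(n_otus: int, rng, shape: float = 0.998) -> np.ndarray:
    """Logseries-distributed metacommunity relative abundances (descending)."""
    draws = rng.logseries(shape, size=n_otus).astype(float)
    p = np.sort(draws)[::-1]
    return p / p.sum()


def _otu_ids(n: int, prefix: str = "OTU") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(1, n + 1)]


def simulate_neutral_metacommunity(
    config: SimulationConfig,
    metacommunity_p: np.ndarray | None = None,
    n_samples: int | None = None,
    sample_ids=None,
    otu_prefix: str = "OTU",
) -> tuple[OtuTable, GroundTruth]:
    """Assemble local communities under Sloan's neutral model.

    Each sample's composition is a Dirichlet draw with concentration
    ``N*m*p`` (stationary distribution of the neutral birth/death/immigration
    process), followed by a multinomial read draw of ``n_reads_per_sample``.
    ``m = 1`` is the pure-immigration limit where samples are i.i.d.
    multinomial draws from the metacommunity.
    """
    if config.regime != "neutral":
        raise ValueError("config.regime must be 'neutral'")
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_samples if n_samples is None else n_samples
    if metacommunity_p is None:
        p = logseries_metacommunity(config.n_otus, rng)
    else:
        p = np.asarray(metacommunity_p, dtype=float)
        p = p / p.sum()
    N = config.n_reads_per_sample
    m = config.migration_m
    counts = _neutral_counts(rng, p, N, m, n_samples)
    ids = list(sample_ids) if sample_ids is not None else _sample_ids(n_samples)
    table = OtuTable(pd.DataFrame(counts, index=ids, columns=_otu_ids(len(p), otu_prefix)))
    truth = GroundTruth(metacommunity_relative_abundances=p, migration_m=m,
                        regime="neutral")
    return table, truth


def _neutral_counts(rng, p, N, m, n_samples) -> np.ndarray:
    alpha = N * m * p
    # Dirichlet with tiny concentrations underflows to all-zero rows in the
    # gamma representation; fall back to renormalised gamma draws with a floor.
    counts = np.empty((n_samples, len(p)), dtype=np.int64)
    for s in range(n_samples):
        if m >= 1.0:
            pi = p
        else:
            g = rng.gamma(np.maximum(alpha, 1e-300))
            tot = g.sum()
            pi = g / tot if tot > 0 else p
        counts[s] = rng.multinomial(N, pi)
    return counts


def _gaussian_weights(env, optima, niche_strength):
    if niche_strength <= 0:
        return np.ones((len(env), len(optima)))
    sigma = 1.0 / niche_strength
    diff = np.subtract.outer(np.asarray(env, float), np.asarray(optima, float))
    return np.exp(-(diff ** 2) / (2.0 * sigma ** 2))


def simulate_niche_metacommunity(
    config: SimulationConfig,
    env_gradient: np.ndarray,
    metacommunity_p: np.ndarray | None = None,
    optima: np.ndarray | None = None,
    sample_ids=None,
    otu_prefix: str = "OTU",
) -> tuple[OtuTable, GroundTruth]:
    """Assemble communities under Gaussian environmental filtering.

    Expected relative abundance of OTU ``j`` in sample ``s`` is proportional
    to ``p_j * exp(-(env_s - optimum_j)^2 / (2 sigma^2))`` with
    ``sigma = 1/niche_strength``; counts are multinomial.  The ``mixed``
    regime applies the same filter to a neutral Dirichlet draw so both drift
    and selection act.
    """
    if config.regime not in {"niche", "mixed"}:
        raise ValueError("config.regime must be 'niche' or 'mixed'")
    env = np.asarray(env_gradient, dtype=float)
    rng = np.random.default_rng(config.seed)
    if metacommunity_p is None:
        p = logseries_metacommunity(config.n_otus, rng)
    else:
        p = np.asarray(metacommunity_p, dtype=float)
        p = p / p.sum()
    if optima is None:
        optima = rng.normal(0.0, 1.0, size=len(p))
    optima = np.asarray(optima, dtype=float)
    if len(optima) != len(p):
        raise ValueError("optima length must equal number of OTUs")
    weights = _gaussian_weights(env, optima, config.niche_strength)
    N = config.n_reads_per_sample
    counts = np.empty((len(env), len(p)), dtype=np.int64)
    for s in range(len(env)):
        if config.regime == "mixed":
            base = _neutral_counts(rng, p, N, config.migration_m, 1)[0] / N
            expected = base * weights[s]
        else:
            expected = p * weights[s]
        tot = expected.sum()
        if tot <= 0 or not np.isfinite(tot):
            raise ValueError(
                f"degenerate input: zero total expected abundance in sample {s}"
            )
        counts[s] = rng.multinomial(N, expected / tot)
    ids = list(sample_ids) if sample_ids is not None else _sample_ids(len(env))
    table = OtuTable(pd.DataFrame(counts, index=ids, columns=_otu_ids(len(p), otu_prefix)))
    truth = GroundTruth(metacommunity_relative_abundances=p,
                        migration_m=config.migration_m,
                        species_env_optima=optima, regime=config.regime)
    return table, truth


# ---------------------------------------------------------------------------
# phylogeny + traits
# ---------------------------------------------------------------------------

def simulate_phylogeny_with_traits(
    n_otus: int, trait_signal: float, seed: int,
    birth_rate: float = 1.0, otu_prefix: str = "OTU",
) -> tuple[TreeNode, np.ndarray]:
    """Pure-birth tree plus environmental optima with tunable conservatism.

    Optima are a Brownian-motion trait (per-branch variance = branch length,
    scaled by ``trait_signal``) plus unit i.i.d. noise, standardised to mean 0
    and SD 1 across tips.  ``trait_signal = 0`` therefore yields optima that
    are i.i.d. with respect to the tree.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    if trait_signal < 0:
        raise ValueError("trait_signal must be nonnegative")
    rng = np.random.default_rng(seed)
    root = TreeNode(length=0.0)
    active = [root]
    while len(active) < n_otus:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length += dt
        parent = active.pop(int(rng.integers(len(active))))
        children = [TreeNode(length=0.0), TreeNode(length=0.0)]
        for c in children:
            parent.append(c)
        active.extend(children)
    dt = rng.exponential(1.0 / (birth_rate * n_otus))
    for node in active:
        node.length += dt
    root.length = 0.0

    # name tips in random order: traversal order is phylogenetically
    # structured, and OTU ids carry abundance rank downstream, so ordered
    # naming would artificially cluster abundant taxa on the tree
    tips = list(root.tips())
    perm = rng.permutation(len(tips))
    names = _otu_ids(n_otus, otu_prefix)
    for pos, tip in zip(perm, tips):
        tip.name = names[pos]

    # Brownian motion down the tree
    bm = {id(root): 0.0}
    for node in root.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(max(node.length, 0.0)))
        bm[id(node)] = bm[id(node.parent)] + step
    tip_value = {t.name: trait_signal * bm[id(t)] for t in tips}
    optima = np.array([tip_value[name] for name in names])
    optima = optima + rng.normal(0.0, 1.0, size=n_otus)
    optima = (optima - optima.mean()) / optima.std()
    return root, optima


# ---------------------------------------------------------------------------
# compositional counts with planted basis correlations
# ---------------------------------------------------------------------------

def simulate_correlated_counts(
    n_samples: int,
    n_otus: int,
    basis_correlation_spec,
    seed: int,
    n_reads_per_sample: int = 20000,
    log_mean_sd: float = 1.5,
    log_sd: float = 1.0,
) -> tuple[OtuTable, GroundTruth]:
    """Log-normal basis abundances with planted pairwise log correlations.

    Unspecified pairs are independent.  Basis abundances are closed to
    compositions and reads drawn multinomially, so the table carries the
    compositional distortions correlation-network inference must undo.
    """
    corr = np.eye(n_otus)
    for i, j, rho in basis_correlation_spec:
        if not (0 <= i < n_otus and 0 <= j < n_otus) or i == j:
            raise ValueError(f"invalid OTU pair ({i}, {j})")
        if not (-1.0 <= rho <= 1.0):
            raise ValueError(f"rho={rho} outside [-1, 1]")
        corr[i, j] = corr[j, i] = rho
    try:
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_otus))
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, log_mean_sd, size=n_otus)
    z = rng.standard_normal((n_samples, n_otus)) @ chol.T
    log_basis = mu + log_sd * z
    basis = np.exp(log_basis)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, n_otus), dtype=np.int64)
    for s in range(n_samples):
        counts[s] = rng.multinomial(n_reads_per_sample, fractions[s])
    table = OtuTable(pd.DataFrame(counts, index=_sample_ids(n_samples),
                                  columns=_otu_ids(n_otus)))
    p = np.exp(mu) / np.exp(mu).sum()
    truth = GroundTruth(metacommunity_relative_abundances=p,
                        true_basis_correlations=corr, regime="correlated")
    return table, truth


# ---------------------------------------------------------------------------
# full depth-transect study
# ---------------------------------------------------------------------------

def _environment_from_depth(depth, rng, noise):
    """Smooth monotone water-column profiles plus optional noise."""
    d = np.asarray(depth, dtype=float)
    n = len(d)
    env = pd.DataFrame(index=range(n))
    env["temperature"] = 2.0 + 26.0 * np.exp(-d / 250.0)
    env["salinity"] = 34.6 - 0.9 * np.exp(-d / 200.0)
    env["dissolved_oxygen"] = 90.0 + 120.0 * np.exp(-d / 400.0)
    env["bacterial_abundance"] = 1e4 + 9.9e5 * np.exp(-d / 300.0)
    env["viral_abundance"] = 1e5 + 9.9e6 * np.exp(-d / 300.0)
    env["hnf_abundance"] = 10.0 + 1.5e3 * np.exp(-d / 250.0)
    env["pnf_abundance"] = 5.0 + 2.5e3 * np.exp(-d / 150.0)
    if noise > 0:
        for col in env.columns:
            scale = noise * 0.02 * env[col].abs().mean()
            env[col] = env[col] + rng.normal(0.0, scale, size=n)
    return env


def simulate_depth_transect_study(
    config: SimulationConfig,
    regime_photic: str = "niche",
    regime_aphotic: str = "neutral",
    station_depths=None,
    station_latitudes=None,
) -> TransectStudy:
    """Generate the full study: three microbial groups over one transect.

    Emits protist-like, free-living-bacteria-like and particle-associated-
    bacteria-like OTU tables over the same samples, sample metadata (station,
    depth, coordinates, zone, environmental and biotic variables) and one
    phylogeny with trait optima per group.  The photic (depth <= boundary) and
    aphotic halves can be assembled under different regimes; the default pair
    (niche photic, neutral aphotic) mirrors a water column whose sunlit layer
    is under stronger environmental selection.
    """
    if station_depths is None:
        depths = config.depths_per_station
        if depths and isinstance(depths[0], (list, tuple)):
            station_depths = [list(d) for d in depths[: config.n_stations]]
        elif config.n_stations == 5 and list(depths) == DEFAULT_STATION_DEPTHS[0]:
            station_depths = DEFAULT_STATION_DEPTHS
        else:
            station_depths = [list(depths) for _ in range(config.n_stations)]
    if station_latitudes is None:
        lats = DEFAULT_STATION_LATITUDES
        station_latitudes = [lats[i % len(lats)] for i in range(len(station_depths))]

    rows = []
    for s_idx, depth_list in enumerate(station_depths):
        for d in depth_list:
            rows.append({
                "station_id": f"ST{s_idx + 1:02d}",
                "depth": float(d),
                "latitude": station_latitudes[s_idx],
                "longitude": 130.0,
            })
    meta = pd.DataFrame(rows)
    meta.index = [
        f"{r.station_id}_{int(r.depth):04d}m" for r in meta.itertuples()
    ]
    meta.index.name = "sample_id"
    meta["zone"] = np.where(meta["depth"] <= config.photic_boundary,
                            "photic", "aphotic")
    for zone in ("photic", "aphotic"):
        if (meta["zone"] == zone).sum() < 2:
            raise ValueError(f"design error: fewer than 2 samples in {zone} zone")

    seeds = np.random.SeedSequence(config.seed).spawn(8)
    env_rng = np.random.default_rng(seeds[0])
    env = _environment_from_depth(meta["depth"].to_numpy(), env_rng, config.env_noise)
    env.index = meta.index
    meta = pd.concat([meta, env], axis=1)

    # environmental niche axis: standardised log-depth (monotone in depth)
    logd = np.log(meta["depth"].to_numpy())
    env_axis = (logd - logd.mean()) / logd.std()

    tables, trees, truths = {}, {}, {}
    group_prefix = {"protist": "P", "fl": "F", "pa": "A"}
    for g_idx, group in enumerate(["protist", "fl", "pa"]):
        ss = seeds[1 + g_idx].generate_state(2)
        tree, optima = simulate_phylogeny_with_traits(
            config.n_otus, config.trait_signal, seed=int(ss[0] % (2 ** 31)),
            otu_prefix=group_prefix[group],
        )
        rng = np.random.default_rng(int(ss[1] % (2 ** 31)))
        p = logseries_metacommunity(config.n_otus, rng)
        counts = np.empty((len(meta), config.n_otus), dtype=np.int64)
        zone_regime = {"photic": regime_photic, "aphotic": regime_aphotic}
        for zone, regime in zone_regime.items():
            mask = (meta["zone"] == zone).to_numpy()
            sub_env = env_axis[mask]
            sub_cfg = SimulationConfig(
                n_otus=config.n_otus,
                n_reads_per_sample=config.n_reads_per_sample,
                migration_m=config.migration_m,
                regime=regime,
                niche_strength=config.niche_strength,
                trait_signal=config.trait_signal,
                seed=int(rng.integers(2 ** 31)),
            )
            if regime == "neutral":
                tbl, _ = simulate_neutral_metacommunity(
                    sub_cfg, metacommunity_p=p, n_samples=int(mask.sum()))
            else:
                tbl, _ = simulate_niche_metacommunity(
                    sub_cfg, sub_env, metacommunity_p=p, optima=optima)
            counts[mask] = tbl.counts.to_numpy()
        tables[group] = OtuTable(pd.DataFrame(
            counts, index=meta.index,
            columns=_otu_ids(config.n_otus, group_prefix[group])))
        trees[group] = tree
        truths[group] = GroundTruth(
            metacommunity_relative_abundances=p,
            migration_m=config.migration_m,
            species_env_optima=optima,
            regime=dict(zone_regime),
        )
    return TransectStudy(tables=tables, metadata=meta, trees=trees, truths=truths)
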