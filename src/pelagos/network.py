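"""SparCC co-occurrence networks: inference, topology, keystones, robustness.

SparCC estimates correlations between the unobserved ("basis") absolute
abundances underlying compositional count data.  From the log-ratio
variances ``T_ij = var(log(x_i / x_j))`` of Dirichlet-resampled fractions it
solves, under a sparsity assumption, the linear system
``(D-1) w_i + sum_{j != i} w_j = sum_j T_ij`` for the basis variances ``w``
and converts them to correlations; strongly correlated pairs are iteratively
removed from the system and the procedure averaged over resamplings.
Significance is a two-sided pseudo-p from column-shuffled bootstrap data.

Edges with ``|r| >= 0.6`` and BH-FDR-corrected ``p < 0.01`` form the
network.  Keystone candidates are classified from the within-module degree
z-score ``Z_i`` and the participation coefficient
``P_i = 1 - sum_c (k_ic / k_i)^2`` with thresholds 2.50 / 0.62; robustness
is the loss of natural connectivity
``ln((1/n) sum_j exp(lambda_j))`` under targeted or random node removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import OtuTable

__all__ = [
    "sparcc",
    "build_network",
    "topology_summary",
    "detect_modules_and_roles",
    "natural_connectivity",
    "robustness_attack",
    "RobustnessCurve",
    "env_edge_test",
    "complexity_diversity_regression",
    "keystone_overlap",
    "keystones",
]

ROLE_NETWORK_HUB = "network_hub"
ROLE_MODULE_HUB = "module_hub"
ROLE_CONNECTOR = "connector"
ROLE_PERIPHERAL = "peripheral"

Z_THRESHOLD = 2.50
P_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _variation_matrix(frac: np.ndarray) -> np.ndarray:
    """T_ij = var(log(f_i / f_j)) computed via the log covariance matrix."""
    logf = np.log(frac)
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(t_mat: np.ndarray, exclusion_threshold: float,
                        exclusion_rounds: int) -> np.ndarray:
    d = t_mat.shape[0]
    m = np.ones((d, d)) + np.eye(d) * (d - 2.0)
    t_work = t_mat.copy()
    excluded = np.zeros((d, d), dtype=bool)

    def solve() -> np.ndarray:
        t_vec = t_work.sum(axis=1)
        w = np.linalg.solve(m, t_vec)
        w = np.maximum(w, 1e-12)
        outer = np.sqrt(np.outer(w, w))
        corr = (w[:, None] + w[None, :] - t_mat) / (2.0 * outer)
        return np.clip(corr, -1.0, 1.0)

    corr = solve()
    for _ in range(exclusion_rounds):
        tmp = np.abs(corr)
        np.fill_diagonal(tmp, 0.0)
        tmp[excluded] = 0.0
        i, j = np.unravel_index(int(np.argmax(tmp)), tmp.shape)
        if tmp[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        t_work[i, j] = t_work[j, i] = 0.0
        corr = solve()
    np.fill_diagonal(corr, 1.0)
    return corr


def _sparcc_corr(counts: np.ndarray, n_iterations: int,
                 exclusion_threshold: float, exclusion_rounds: int,
                 rng) -> np.ndarray:
    n, d = counts.shape
    acc = np.zeros((d, d))
    for _ in range(n_iterations):
        frac = np.empty((n, d))
        for s in range(n):
            frac[s] = rng.dirichlet(counts[s] + 1.0)
        t_mat = _variation_matrix(frac)
        acc += _basis_correlations(t_mat, exclusion_threshold, exclusion_rounds)
    corr = acc / n_iterations
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def sparcc(
    table: OtuTable,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    n_bootstrap: int = 100,
    seed: int = 0,
    bootstrap_iterations: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SparCC basis correlations and bootstrap pseudo-p values.

    Returns ``(r, p)`` as OTU-by-OTU DataFrames.  ``p`` is the two-sided
    pseudo-p ``(#{|r_boot| >= |r_obs|} + 1) / (n_bootstrap + 1)`` from
    datasets in which every OTU's counts are independently shuffled across
    samples (destroying all correlation but keeping marginals).

    The smallest attainable p is ``1/(n_bootstrap + 1)``, so downstream FDR
    control at level alpha over ``T`` pairs can only ever reject when
    ``n_bootstrap + 1 >= T / (alpha * k)`` for ``k`` discoveries; size
    ``n_bootstrap`` accordingly.  ``bootstrap_iterations`` lets the null
    datasets use fewer Dirichlet resamplings than the observed run (their
    extra estimation noise only widens the null, making p conservative).
    """
    if table.n_otus < 4:
        raise ValueError("SparCC needs at least 4 OTUs (system underdetermined)")
    counts = table.counts.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    r_obs = _sparcc_corr(counts, n_iterations, exclusion_threshold,
                         exclusion_rounds, rng)
    d = counts.shape[1]
    boot_iters = bootstrap_iterations or n_iterations
    exceed = np.zeros((d, d))
    for _ in range(n_bootstrap):
        shuffled = np.empty_like(counts)
        for j in range(d):
            shuffled[:, j] = rng.permutation(counts[:, j])
        r_boot = _sparcc_corr(shuffled, boot_iters, exclusion_threshold,
                              exclusion_rounds, rng)
        exceed += np.abs(r_boot) >= np.abs(r_obs)
    p = (exceed + 1.0) / (n_bootstrap + 1.0)
    np.fill_diagonal(p, 0.0)
    ids = table.otu_ids
    return (pd.DataFrame(r_obs, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    r_min: float = 0.6,
    alpha: float = 0.01,
    node_groups: dict | None = None,
    taxonomy: dict | None = None,
) -> nx.Graph:
    """Keep edges with ``|r| >= r_min`` and BH-adjusted ``p < alpha``.

    BH adjustment runs over the upper triangle.  Isolated nodes are dropped.
    Node attributes ``group`` and ``taxonomy`` are attached when provided;
    edges carry ``r``, ``p_adj`` and ``sign``.
    """
    if list(r.index) != list(p.index) or list(r.columns) != list(p.columns):
        raise ValueError("r and p matrices are not aligned")
    ids = list(r.index)
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    p_flat = p.to_numpy()[iu]
    p_adj = bh_adjust(p_flat)
    r_flat = r.to_numpy()[iu]
    g = nx.Graph()
    keep = (np.abs(r_flat) >= r_min) & (p_adj < alpha)
    for idx in np.flatnonzero(keep):
        i, j = iu[0][idx], iu[1][idx]
        g.add_edge(ids[i], ids[j], r=float(r_flat[idx]),
                   p_adj=float(p_adj[idx]),
                   sign="positive" if r_flat[idx] > 0 else "negative")
    if g.number_of_edges() == 0:
        warnings.warn("no edges survived the |r|/FDR thresholds")
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
        if node_groups:
            g.nodes[node]["group"] = node_groups.get(node, "")
        if taxonomy:
            g.nodes[node]["taxonomy"] = taxonomy.get(node, "")
    return g


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def _powerlaw_fit(degrees) -> tuple[float, float]:
    """OLS fit of log(frequency) on log(degree) over positive-degree bins.

    Returns ``(exponent, r2)`` where the degree distribution is modelled as
    ``freq ~ k^-exponent``.
    """
    degrees = np.asarray([k for k in degrees if k > 0])
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        return np.nan, np.nan
    fit = scipy.stats.linregress(np.log(ks), np.log(counts))
    return float(-fit.slope), float(fit.rvalue ** 2)


def topology_summary(g: nx.Graph, n_random: int = 10, seed: int = 0) -> dict:
    """Standard topology metrics plus Erdős–Rényi random-graph references.

    Average path length is computed on the largest connected component (the
    result is flagged ``path_length_component_restricted`` when the graph is
    disconnected).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n, m = g.number_of_nodes(), g.number_of_edges()
    degrees = [d for _, d in g.degree()]
    components = list(nx.connected_components(g))
    largest = g.subgraph(max(components, key=len))
    apl = (nx.average_shortest_path_length(largest)
           if largest.number_of_nodes() > 1 else 0.0)
    comms = greedy_modularity_communities(g)
    mod = modularity(g, comms) if m > 0 else np.nan
    exponent, fit_r2 = _powerlaw_fit(degrees)
    out = {
        "n_nodes": n,
        "n_edges": m,
        "average_degree": 2.0 * m / n,
        "density": nx.density(g),
        "average_clustering_coefficient": nx.average_clustering(g),
        "average_path_length": apl,
        "path_length_component_restricted": len(components) > 1,
        "modularity": float(mod) if mod == mod else np.nan,
        "degree_powerlaw_exponent": exponent,
        "degree_powerlaw_r2": fit_r2,
    }
    rng = np.random.default_rng(seed)
    rnd_clust, rnd_apl, rnd_mod = [], [], []
    for _ in range(n_random):
        er = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
        rnd_clust.append(nx.average_clustering(er))
        comp = max(nx.connected_components(er), key=len)
        sub = er.subgraph(comp)
        rnd_apl.append(nx.average_shortest_path_length(sub)
                       if sub.number_of_nodes() > 1 else 0.0)
        rnd_mod.append(modularity(er, greedy_modularity_communities(er))
                       if er.number_of_edges() > 0 else np.nan)
    out["random_average_clustering_coefficient"] = float(np.mean(rnd_clust))
    out["random_average_path_length"] = float(np.mean(rnd_apl))
    out["random_modularity"] = float(np.nanmean(rnd_mod))
    return out


# ---------------------------------------------------------------------------
# modules, Zi/Pi roles, keystones
# ---------------------------------------------------------------------------

def detect_modules_and_roles(g: nx.Graph, seed: int = 0) -> pd.DataFrame:
    """Greedy modularity modules plus per-node topological role.

    ``z`` is the within-module degree z-score (within-module links,
    standardised by the module's mean and population SD; 0 for modules whose
    SD is 0), ``p`` the participation coefficient
    ``1 - sum_c (k_ic/k_i)^2``.  Roles follow the 2.50 / 0.62 thresholds:
    network hubs (z > 2.5 and p > 0.62), module hubs (z > 2.5),
    connectors (p > 0.62), peripherals (otherwise).
    """
    if g.number_of_edges() < 1:
        raise ValueError("network has no edges")
    comms = greedy_modularity_communities(g)
    comms = [sorted(c) for c in comms]
    comms.sort(key=lambda c: c[0])  # deterministic module ids
    module_of = {}
    for mid, members in enumerate(comms):
        for node in members:
            module_of[node] = mid
    # within-module degree per node
    kib = {node: sum(1 for nb in g.neighbors(node)
                     if module_of[nb] == module_of[node])
           for node in g.nodes}
    z = {}
    for mid, members in enumerate(comms):
        vals = np.array([kib[n] for n in members], dtype=float)
        mu, sd = vals.mean(), vals.std(ddof=0)
        for node in members:
            z[node] = (kib[node] - mu) / sd if sd > 0 else 0.0
    rows = []
    for node in sorted(g.nodes):
        k = g.degree(node)
        kic = {}
        for nb in g.neighbors(node):
            kic[module_of[nb]] = kic.get(module_of[nb], 0) + 1
        p_i = 1.0 - sum((c / k) ** 2 for c in kic.values()) if k > 0 else 0.0
        zi = z[node]
        if zi > Z_THRESHOLD and p_i > P_THRESHOLD:
            role = ROLE_NETWORK_HUB
        elif zi > Z_THRESHOLD:
            role = ROLE_MODULE_HUB
        elif p_i > P_THRESHOLD:
            role = ROLE_CONNECTOR
        else:
            role = ROLE_PERIPHERAL
        rows.append({"node": node, "module": module_of[node], "degree": k,
                     "within_module_degree": kib[node], "z": zi, "p": p_i,
                     "role": role})
        g.nodes[node].update(module=module_of[node], z=zi, p=p_i, role=role)
    return pd.DataFrame(rows).set_index("node")


def keystones(roles: pd.DataFrame) -> set:
    """Keystone candidates: network hubs, module hubs and connectors."""
    return set(roles.index[roles["role"] != ROLE_PERIPHERAL])


def keystone_overlap(roles_a: pd.DataFrame, roles_b: pd.DataFrame) -> dict:
    """Shared and unique keystone nodes between two networks.

    ``shared_fraction`` is Jaccard: |A ∩ B| / |A ∪ B|.
    """
    a, b = keystones(roles_a), keystones(roles_b)
    union = a | b
    shared = a & b
    return {
        "shared": sorted(shared),
        "unique_a": sorted(a - b),
        "unique_b": sorted(b - a),
        "shared_fraction": len(shared) / len(union) if union else 0.0,
    }


# ---------------------------------------------------------------------------
# natural connectivity and attack robustness
# ---------------------------------------------------------------------------

def natural_connectivity(g) -> float:
    """ln of the average eigenvalue exponential of the adjacency matrix."""
    if isinstance(g, nx.Graph):
        if g.number_of_nodes() == 0:
            raise ValueError("empty graph")
        adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
    else:
        adj = np.asarray(g, dtype=float)
    eig = np.linalg.eigvalsh(adj)
    return float(logsumexp(eig) - np.log(len(eig)))


@dataclass
class RobustnessCurve:
    """Natural connectivity as nodes are removed."""

    fraction_removed: np.ndarray
    connectivity: np.ndarray
    strategy: str
    n_reps: int | None = None

    def normalized(self) -> np.ndarray:
        return self.connectivity / self.connectivity[0]


def _targeted_order(g: nx.Graph, strategy: str, recompute: bool) -> list:
    def rank(graph):
        if strategy == "betweenness":
            score = nx.betweenness_centrality(graph)
        else:
            score = dict(graph.degree())
        return sorted(graph.nodes, key=lambda v: (-score[v], v))

    if not recompute:
        return rank(g)
    order = []
    h = g.copy()
    while h.number_of_nodes() > 0:
        v = rank(h)[0]
        order.append(v)
        h.remove_node(v)
    return order


def _curve_for_order(g: nx.Graph, order) -> np.ndarray:
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = nx.to_numpy_array(g, nodelist=nodes)
    vals = [natural_connectivity(adj)]
    alive = np.ones(len(nodes), dtype=bool)
    for v in order:
        alive[idx[v]] = False
        if alive.sum() < 2:
            break
        vals.append(natural_connectivity(adj[np.ix_(alive, alive)]))
    return np.asarray(vals)


def robustness_attack(
    g: nx.Graph,
    strategy: str = "betweenness",
    n_reps: int | None = None,
    seed: int = 0,
    recompute: bool = False,
) -> RobustnessCurve:
    """Natural-connectivity attack curve under targeted or random removal.

    Targeted strategies use the static initial ranking by default (the
    removal order is predetermined); ``recompute=True`` re-ranks after each
    removal.  ``random`` averages ``n_reps`` independent removal orders.
    The curve starts at the intact network's value and is defined while at
    least 2 nodes remain.
    """
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    if strategy in {"betweenness", "degree"}:
        order = _targeted_order(g, strategy, recompute)
        vals = _curve_for_order(g, order)
        reps = None
    elif strategy == "random":
        if not n_reps:
            raise ValueError("random strategy requires n_reps")
        rng = np.random.default_rng(seed)
        nodes = sorted(g.nodes)
        acc = None
        for _ in range(n_reps):
            order = list(rng.permutation(nodes))
            v = _curve_for_order(g, order)
            acc = v if acc is None else acc + v
        vals = acc / n_reps
        reps = n_reps
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    frac = np.arange(len(vals)) / g.number_of_nodes()
    return RobustnessCurve(fraction_removed=frac, connectivity=vals,
                           strategy=strategy, n_reps=reps)


# ---------------------------------------------------------------------------
# environment edges and diversity-complexity regressions
# ---------------------------------------------------------------------------

def env_edge_test(
    g: nx.Graph,
    table: OtuTable,
    env: pd.DataFrame,
    r_env_min: float = 0.6,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Label each edge taxon-taxon vs taxon-taxon-environment.

    For every network node and environmental variable a Pearson correlation
    on relative abundances is BH-adjusted across all node-variable tests.
    An edge is environmentally mediated when both endpoints correlate
    significantly (|r| >= ``r_env_min``, adjusted p < ``alpha``) with the
    same variable and the product of their correlation signs matches the
    edge sign.  Returns the labelled edge table and per-variable counts.
    """
    rel = table.relative_abundance()
    env = env.loc[rel.index]
    nodes = [n for n in g.nodes if n in rel.columns]
    variables = []
    for col in env.columns:
        if env[col].std(ddof=0) == 0:
            warnings.warn(f"constant environmental variable skipped: {col}")
            continue
        variables.append(col)
    r_mat = pd.DataFrame(index=nodes, columns=variables, dtype=float)
    p_mat = pd.DataFrame(index=nodes, columns=variables, dtype=float)
    for node in nodes:
        x = rel[node].to_numpy()
        for col in variables:
            if np.std(x) == 0:
                r_mat.loc[node, col], p_mat.loc[node, col] = 0.0, 1.0
                continue
            rr, pp = scipy.stats.pearsonr(x, env[col].to_numpy())
            r_mat.loc[node, col], p_mat.loc[node, col] = rr, pp
    if variables and nodes:
        p_adj = bh_adjust(p_mat.to_numpy().ravel()).reshape(p_mat.shape)
        p_adj = pd.DataFrame(p_adj, index=nodes, columns=variables)
        sig = (r_mat.abs() >= r_env_min) & (p_adj < alpha)
    else:
        sig = pd.DataFrame(False, index=nodes, columns=variables)
    rows = []
    var_counts = {v: 0 for v in variables}
    for a, b, attrs in g.edges(data=True):
        label = "taxon-taxon"
        mediating = []
        if a in sig.index and b in sig.index:
            edge_sign = 1.0 if attrs.get("r", 1.0) > 0 else -1.0
            for v in variables:
                if sig.loc[a, v] and sig.loc[b, v]:
                    concordant = (np.sign(r_mat.loc[a, v])
                                  * np.sign(r_mat.loc[b, v]) == edge_sign)
                    if concordant:
                        label = "taxon-taxon-environment"
                        mediating.append(v)
                        var_counts[v] += 1
        g.edges[a, b]["env_label"] = label
        rows.append({"source": a, "target": b, "r": attrs.get("r", np.nan),
                     "label": label, "variables": ",".join(mediating)})
    edges = pd.DataFrame(rows)
    n_env = int((edges["label"] == "taxon-taxon-environment").sum()) if len(edges) else 0
    summary = {
        "n_edges": len(edges),
        "n_env_edges": n_env,
        "fraction_env": n_env / len(edges) if len(edges) else 0.0,
        "per_variable": var_counts,
    }
    return edges, summary


def complexity_diversity_regression(
    g: nx.Graph,
    table: OtuTable,
    alpha_div: pd.DataFrame,
    r2_omit: float = 0.01,
) -> pd.DataFrame:
    """Regress per-sample induced-subgraph size and connectivity on alpha
    diversity.

    For each sample the subgraph induced on the network OTUs present in it
    is counted (nodes, edges); node and edge counts are regressed (OLS) on
    each alpha-diversity column.  Rows with R² < ``r2_omit`` are flagged
    ``omitted`` (reported but conventionally not plotted).
    """
    presence = table.counts > 0
    net_nodes = [n for n in g.nodes if n in table.counts.columns]
    n_nodes, n_edges = [], []
    for s in table.sample_ids:
        present = {n for n in net_nodes if presence.loc[s, n]}
        sub = g.subgraph(present)
        n_nodes.append(sub.number_of_nodes())
        n_edges.append(sub.number_of_edges())
    size = pd.DataFrame({"nodes": n_nodes, "edges": n_edges},
                        index=table.sample_ids)
    rows = []
    for xcol in alpha_div.columns:
        x = alpha_div.loc[table.sample_ids, xcol].to_numpy(dtype=float)
        for ycol in ("nodes", "edges"):
            y = size[ycol].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise ValueError(f"zero variance in predictor {xcol!r}")
            fit = scipy.stats.linregress(x, y)
            r2 = fit.rvalue ** 2
            rows.append({"predictor": xcol, "response": ycol,
                         "slope": float(fit.slope),
                         "intercept": float(fit.intercept),
                         "r_squared": float(r2), "p": float(fit.pvalue),
                         "omitted": bool(r2 < r2_omit)})
    return pd.DataFrame(rows)
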