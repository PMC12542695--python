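"""Spearman co-occurrence networks and their robustness.

Edges connect OTU pairs whose Spearman correlation across samples passes
|ρ| > r_min with a Benjamini–Hochberg-adjusted p-value below alpha.  With
the study's tiny sample count (N = 8) the usual t-approximation for
Spearman p-values is unreliable, so for n ≤ 9 samples the permutation
distribution of ρ is enumerated exactly over all n! orderings (a cached,
vectorised enumeration; tied ranks are handled by per-pair enumeration).

Robustness is quantified by natural connectivity,

    λ̄ = ln( (1/N) Σᵢ exp(λᵢ) )

over the eigenvalues λᵢ of the (unweighted) adjacency matrix, and by a
random-node "attack" simulation: remove a growing fraction of nodes,
track the mean λ̄ of the remnant, and summarise the decay with a linear
slope (steeper = more negative = less robust).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .diversity import LinearFit, linear_fit

log = logging.getLogger(__name__)

__all__ = [
    "write_network",
    "read_network",
    "spearman_edges",
    "exact_spearman_pvalue",
    "induced_subgraph",
    "topology",
    "detect_modules",
    "natural_connectivity",
    "attack_robustness",
    "compare_slopes",
    "RobustnessCurve",
]

EXACT_PERM_MAX_N = 9


@lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int64)


@lru_cache(maxsize=4)
def _tie_free_null(n: int) -> np.ndarray:
    """Null |ρ| distribution for tie-free ranks — identical for all pairs."""
    base = np.arange(1, n + 1, dtype=float)
    perms = _all_permutations(n)
    c = base - base.mean()
    denom = (c**2).sum()
    rhos = (c[perms] @ c) / denom
    return np.abs(rhos)


def exact_spearman_pvalue(x, y) -> tuple[float, float]:
    """Spearman ρ and its exact two-sided permutation p over all n! orders.

    Average ranks are used for ties; with ties the null is enumerated for
    the specific pair, otherwise a cached universal distribution applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > EXACT_PERM_MAX_N:
        raise ValueError(f"exact enumeration limited to n <= {EXACT_PERM_MAX_N}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    tie_free = len(set(rx)) == n and len(set(ry)) == n
    if tie_free:
        null_abs = _tie_free_null(n)
    else:
        perms = _all_permutations(n)
        cy = ry - ry.mean()
        cx = rx - rx.mean()
        denom = np.sqrt((cx**2).sum() * (cy**2).sum())
        null_abs = np.abs((cy[perms] @ cx) / denom)
    p = float((null_abs >= abs(rho) - 1e-12).mean())
    return rho, p


def _spearman_pvalues(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ρ matrix and raw two-sided p matrix for all OTU pairs (rows of ranks)."""
    m, n = ranks.shape
    rho = np.corrcoef(ranks)
    p = np.ones((m, m))
    if n <= EXACT_PERM_MAX_N:
        tie_free = np.array([len(set(r)) == n for r in ranks])
        null_abs = _tie_free_null(n)
        for i in range(m):
            for j in range(i + 1, m):
                if tie_free[i] and tie_free[j]:
                    p[i, j] = p[j, i] = float(
                        (null_abs >= abs(rho[i, j]) - 1e-12).mean()
                    )
                else:
                    _, p_ij = exact_spearman_pvalue(ranks[i], ranks[j])
                    p[i, j] = p[j, i] = p_ij
        log.info("spearman: exact permutation p-values (n = %d samples)", n)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-300, None))
        tail = 2 * sps.t.sf(np.abs(t), df=n - 2)
        iu = np.triu_indices(m, k=1)
        p[iu] = tail[iu]
        p.T[iu] = tail[iu]
    return rho, p


def spearman_edges(
    rel_abund: pd.DataFrame,
    r_min: float = 0.6,
    alpha: float = 0.05,
    node_attrs: pd.DataFrame | None = None,
    signed_threshold: bool = False,
    keep_isolated: bool = False,
) -> nx.Graph:
    """Build the co-occurrence network from an OTU × sample abundance table.

    Pairwise Spearman correlations with BH correction over all tested
    pairs; an edge is kept when |ρ| > r_min (or ρ > r_min with
    ``signed_threshold``) and adjusted p < alpha.  Constant-abundance OTUs
    are excluded (logged).  ``node_attrs`` may provide per-OTU columns such
    as ``niche_class``, ``domain``, ``taxonomy``; module ids and degree are
    attached by :func:`detect_modules` / :func:`topology`.
    """
    if rel_abund.shape[1] < 4:
        raise ValueError("need at least 4 samples for co-occurrence analysis")
    x = rel_abund.to_numpy(dtype=float)
    variable = x.std(axis=1) > 0
    dropped = rel_abund.index[~variable].tolist()
    if dropped:
        log.info("spearman_edges: excluded %d constant OTUs: %s…",
                 len(dropped), dropped[:3])
    ids = rel_abund.index[variable].tolist()
    x = x[variable]
    if len(ids) < 2:
        raise ValueError("fewer than two variable OTUs")
    ranks = np.vstack([sps.rankdata(row) for row in x])
    rho, p = _spearman_pvalues(ranks)
    iu = np.triu_indices(len(ids), k=1)
    p_adj = np.ones_like(p)
    adj_flat = multipletests(p[iu], method="fdr_bh")[1]
    p_adj[iu] = adj_flat
    p_adj.T[iu] = adj_flat

    graph = nx.Graph()
    if keep_isolated:
        graph.add_nodes_from(ids)
    strength = rho if signed_threshold else np.abs(rho)
    for i, j in zip(*iu):
        if strength[i, j] > r_min and p_adj[i, j] < alpha:
            graph.add_edge(
                ids[i],
                ids[j],
                r=float(rho[i, j]),
                p_adj=float(p_adj[i, j]),
                sign=1 if rho[i, j] > 0 else -1,
                weight=float(abs(rho[i, j])),
            )
    if node_attrs is not None:
        for node in graph.nodes:
            if node in node_attrs.index:
                for col in node_attrs.columns:
                    graph.nodes[node][col] = node_attrs.loc[node, col]
    return graph


def induced_subgraph(graph: nx.Graph, niche_class=None, domain=None) -> nx.Graph:
    """Node-induced subgraph of OTUs matching the niche class and/or domain."""
    def match(n):
        data = graph.nodes[n]
        if niche_class is not None and data.get("niche_class") != niche_class:
            return False
        if domain is not None and data.get("domain") != domain:
            return False
        return True

    return graph.subgraph([n for n in graph.nodes if match(n)]).copy()


def detect_modules(graph: nx.Graph, seed=None) -> dict:
    """Greedy modularity maximisation on |ρ| edge weights.

    Deterministic: nodes are processed in sorted order and modules are
    numbered by decreasing size (ties by smallest member).  ``seed`` is
    accepted for interface uniformity; the algorithm itself is
    deterministic.
    """
    if graph.number_of_edges() == 0:
        return {n: 0 for n in graph.nodes}
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(graph.nodes))
    ordered.add_edges_from(
        (u, v, d) for u, v, d in graph.edges(data=True)
    )
    comms = nx.community.greedy_modularity_communities(ordered, weight="weight")
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    return {n: i for i, c in enumerate(comms) for n in c}


def topology(graph: nx.Graph) -> dict:
    """Headline topological properties of a co-occurrence network.

    ``complexity`` is linkage density E/N (the average number of edges per
    node); ``avg_degree`` = 2E/N; ``modularity`` is evaluated on the
    greedy partition with |ρ| weights; ``positive_edge_fraction`` is the
    share of positive correlations.
    """
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    if n == 0:
        log.warning("topology of an empty network")
        return {
            "nodes": 0, "edges": 0, "avg_degree": 0.0, "density": 0.0,
            "complexity": 0.0, "modularity": 0.0, "positive_edge_fraction": 0.0,
        }
    modules = detect_modules(graph)
    if e > 0:
        part = {}
        for node, m in modules.items():
            part.setdefault(m, set()).add(node)
        q = nx.community.modularity(graph, part.values(), weight="weight")
        pos = sum(1 for _, _, d in graph.edges(data=True) if d.get("sign", 1) > 0)
        pos_frac = pos / e
    else:
        q, pos_frac = 0.0, 0.0
    return {
        "nodes": n,
        "edges": e,
        "avg_degree": 2 * e / n,
        "density": 2 * e / (n * (n - 1)) if n > 1 else 0.0,
        "complexity": e / n,
        "modularity": float(q),
        "positive_edge_fraction": pos_frac,
    }


def natural_connectivity(graph: nx.Graph) -> float:
    """λ̄ = ln(mean exp(eigenvalues)) of the unweighted adjacency matrix."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined for an empty graph")
    a = nx.to_numpy_array(graph, weight=None)
    return _natural_connectivity_dense(a)


def _natural_connectivity_dense(a: np.ndarray) -> float:
    eig = np.linalg.eigvalsh(a)
    return float(logsumexp(eig) - math.log(a.shape[0]))


@dataclass
class RobustnessCurve:
    proportions: np.ndarray
    mean_connectivity: np.ndarray
    sd_connectivity: np.ndarray
    n_reps: int
    fit: LinearFit | None
    seed: int | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "proportion_removed": self.proportions,
                "mean_natural_connectivity": self.mean_connectivity,
                "sd_natural_connectivity": self.sd_connectivity,
            }
        )


def attack_robustness(
    graph: nx.Graph,
    proportions=None,
    n_reps: int = 100,
    seed=None,
) -> RobustnessCurve:
    """Random-node attack simulation.

    For each removal proportion, delete that fraction of nodes uniformly
    at random (``n_reps`` independent draws, without replacement within a
    draw), average the remnant's natural connectivity (isolated survivors
    count toward N), and fit a line to mean λ̄ versus proportion.
    """
    if proportions is None:
        proportions = np.arange(0.0, 0.8001, 0.05)
    proportions = np.asarray(proportions, dtype=float)
    if (proportions >= 1).any() or (proportions < 0).any():
        raise ValueError("removal proportions must lie in [0, 1)")
    n = graph.number_of_nodes()
    if n < 5:
        raise ValueError("attack simulation needs at least 5 nodes")
    a = nx.to_numpy_array(graph, weight=None)
    rng = np.random.default_rng(seed)
    means = np.empty(proportions.size)
    sds = np.empty(proportions.size)
    for k, prop in enumerate(proportions):
        n_remove = int(round(prop * n))
        if n_remove == 0:
            means[k] = _natural_connectivity_dense(a)
            sds[k] = 0.0
            continue
        vals = np.empty(n_reps)
        for rep in range(n_reps):
            keep = rng.permutation(n)[n_remove:]
            vals[rep] = _natural_connectivity_dense(a[np.ix_(keep, keep)])
        means[k] = vals.mean()
        sds[k] = vals.std(ddof=1)
    fit = linear_fit(proportions, means) if proportions.size >= 3 else None
    return RobustnessCurve(
        proportions=proportions,
        mean_connectivity=means,
        sd_connectivity=sds,
        n_reps=n_reps,
        fit=fit,
        seed=seed,
    )


def compare_slopes(curve_a: RobustnessCurve, curve_b: RobustnessCurve):
    """Two-sample comparison of attack-curve slopes.

    Pools both curves into one regression with a group × proportion
    interaction; the t-test on the interaction coefficient tests the
    slope difference.  "Steeper" means more negative slope.
    Returns (slope_difference = a − b, t, p).
    """
    if not np.allclose(curve_a.proportions, curve_b.proportions):
        raise ValueError("robustness curves use different proportion grids")
    import statsmodels.api as sm

    x = np.concatenate([curve_a.proportions, curve_b.proportions])
    g = np.concatenate(
        [np.ones_like(curve_a.proportions), np.zeros_like(curve_b.proportions)]
    )
    y = np.concatenate([curve_a.mean_connectivity, curve_b.mean_connectivity])
    design = sm.add_constant(np.column_stack([x, g, x * g]))
    res = sm.OLS(y, design).fit()
    diff = float(res.params[3])
    t = float(res.tvalues[3])
    p = float(res.pvalues[3])
    if not np.isfinite(t):  # identical curves: zero residual interaction
        t, p = 0.0, 1.0
    return diff, t, p


# ---------------------------------------------------------------------------
# persistence

_NODE_COLS = ("niche_class", "domain", "taxonomy", "module", "degree")
_EDGE_COLS = ("r", "p_adj", "sign")


def write_network(graph: nx.Graph, path, fmt: str = "edgelist") -> None:
    """Persist a network as GraphML or as an edge-list + node-list TSV pair.

    Edge rows carry ρ, adjusted p and sign; node rows carry niche class,
    domain, taxonomy, module id and degree.  For ``fmt="edgelist"`` the
    node list is written next to ``path`` with a ``.nodes.tsv`` suffix.
    """
    graph = graph.copy()
    modules = detect_modules(graph)
    for n in graph.nodes:
        graph.nodes[n].setdefault("module", modules[n])
        graph.nodes[n]["degree"] = graph.degree[n]
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return
    if fmt != "edgelist":
        raise ValueError(f"unknown network format {fmt!r}")
    edges = pd.DataFrame(
        [
            {"source": u, "target": v,
             **{c: d.get(c) for c in _EDGE_COLS}}
            for u, v, d in sorted(graph.edges(data=True))
        ],
        columns=["source", "target", *_EDGE_COLS],
    )
    edges.to_csv(path, sep="\t", index=False, encoding="utf-8")
    nodes = pd.DataFrame(
        [
            {"node": n, **{c: graph.nodes[n].get(c) for c in _NODE_COLS}}
            for n in sorted(graph.nodes)
        ],
        columns=["node", *_NODE_COLS],
    )
    nodes.to_csv(str(path) + ".nodes.tsv", sep="\t", index=False, encoding="utf-8")


def read_network(path, fmt: str = "edgelist") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt != "edgelist":
        raise ValueError(f"unknown network format {fmt!r}")
    graph = nx.Graph()
    edges = pd.read_csv(path, sep="\t", encoding="utf-8")
    for _, row in edges.iterrows():
        graph.add_edge(
            row["source"], row["target"],
            r=float(row["r"]), p_adj=float(row["p_adj"]),
            sign=int(row["sign"]), weight=abs(float(row["r"])),
        )
    nodes = pd.read_csv(str(path) + ".nodes.tsv", sep="\t", encoding="utf-8")
    for _, row in nodes.iterrows():
        graph.add_node(row["node"])
        for c in _NODE_COLS:
            if c in row and pd.notna(row[c]):
                graph.nodes[row["node"]][c] = row[c]
    return graph
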