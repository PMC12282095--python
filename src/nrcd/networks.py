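"""Signed microbial co-occurrence networks and their comparison.

The workflow mirrors the sparse inverse-covariance approach that has
become standard for compositional microbiome data:

1. centered log-ratio (CLR) transform of relative abundances;
2. conditional-dependence network estimation by neighborhood selection
   (an L1-penalized regression of each taxon on all others), with the
   penalty chosen by the Stability Approach to Regularization Selection
   (StARS) over subsamples of size ``floor(10 * sqrt(n))``;
3. topology summaries (size, order, density, clustering, path length,
   positive-edge fraction, modularity);
4. keystone detection: nodes whose degree AND betweenness centrality both
   exceed the fitted log-normal 0.90 quantile of the respective metric;
5. robustness under targeted and random node removal on the
   positive-interaction subgraph, tracked by the size of the largest
   connected component (LCC);
6. differential-association networks between two groups via the Fisher Z
   test on pairwise Pearson correlations, FDR-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CooccurrenceNetwork",
    "TopologySummary",
    "AttackCurve",
    "clr_transform",
    "default_lambda_path",
    "infer_network",
    "topology_summary",
    "keystone_taxa",
    "attack_robustness",
    "differential_association",
]


# ---------------------------------------------------------------------------
# CLR transform
# ---------------------------------------------------------------------------

def clr_transform(abundances, pseudocount: float | None = None) -> pd.DataFrame:
    """Centered log-ratio transform of a samples-by-taxa abundance matrix.

    Zeros are replaced by ``pseudocount`` (default: half the smallest
    nonzero value in the table). Each row of the result sums to zero and
    is invariant to rescaling of the corresponding sample.
    """
    df = pd.DataFrame(abundances).astype(float)
    x = df.to_numpy()
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("CLR is undefined for all-zero samples")
    if pseudocount is None:
        pseudocount = 0.5 * x[x > 0].min()
    x = np.where(x > 0, x, pseudocount)
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceNetwork:
    """Signed weighted undirected co-occurrence network over taxa.

    ``graph`` edges carry ``weight`` (signed regression coefficient) and
    ``sign`` (+1/-1). Following the convention of published topology
    tables, ``size`` is the edge count and ``order`` the number of
    non-isolated nodes (taxa participating in at least one edge).
    """

    graph: nx.Graph
    node_abundance: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.graph.number_of_edges()

    @property
    def order(self) -> int:
        return sum(1 for _, d in self.graph.degree() if d > 0)

    def positive_subgraph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from((u, v, d) for u, v, d in self.graph.edges(data=True) if d["sign"] > 0)
        return g

    def to_edge_table(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, "weight": d["weight"], "sign": d["sign"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])


# ---------------------------------------------------------------------------
# neighborhood selection + StARS
# ---------------------------------------------------------------------------

def default_lambda_path(clr: np.ndarray, n_lambda: int = 10,
                        min_ratio: float = 0.01) -> np.ndarray:
    """Geometric penalty path from the empirical maximum correlation down.

    The largest penalty is the maximum absolute off-diagonal entry of the
    correlation matrix of the CLR data (the smallest penalty at which all
    neighborhoods are empty); the path decreases geometrically to
    ``min_ratio`` times that value.

    The default grid is deliberately coarse. Under independence the
    stability-selection instability crosses its budget within the first
    geometric step, so the selected model is empty, while planted
    association structure keeps instability low over several steps and is
    recovered; a fine grid instead lets the selector creep up to the
    instability boundary, where a handful of chance associations survive.
    """
    x = np.asarray(clr, dtype=float)
    c = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(c, 0.0)
    lam_max = float(np.abs(c).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _neighborhood_paths(x: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Directed selection indicators for every node along the penalty path.

    ``x`` is standardized samples-by-taxa data. Returns a boolean array of
    shape (n_lambda, p, p): entry (l, j, k) says taxon k entered the
    neighborhood of taxon j at penalty ``lambdas[l]``.
    """
    n, p = x.shape
    sel = np.zeros((len(lambdas), p, p), dtype=bool)
    for j in range(p):
        others = np.delete(np.arange(p), j)
        # scikit-learn's coordinate-descent lasso: alpha matches the
        # max-correlation parameterization when columns are standardized
        _, coefs, _ = lasso_path(x[:, others], x[:, j], alphas=lambdas,
                                 max_iter=10_000)
        nz = coefs != 0  # (p-1, n_lambda)
        sel[:, j, others] = nz.T
    return sel


def _coef_matrix(x: np.ndarray, lam: float) -> np.ndarray:
    """Directed coefficient matrix at a single penalty."""
    n, p = x.shape
    beta = np.zeros((p, p))
    for j in range(p):
        others = np.delete(np.arange(p), j)
        _, coefs, _ = lasso_path(x[:, others], x[:, j], alphas=[lam],
                                 max_iter=10_000)
        beta[j, others] = coefs[:, 0]
    return beta


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def infer_network(clr, lambda_path=None, stars_subsamples: int = 50,
                  stars_threshold: float = 0.05, rule: str = "AND",
                  seed: int | None = None,
                  node_abundance: dict[str, float] | None = None) -> CooccurrenceNetwork:
    """Infer a signed co-occurrence network from CLR data.

    Each taxon is regressed on all others with an L1 penalty along
    ``lambda_path`` (strictly decreasing). StARS draws
    ``stars_subsamples`` subsamples of size ``floor(10*sqrt(n))``,
    computes the per-pair selection frequency xi at each penalty and the
    total instability ``D = mean(2*xi*(1-xi))``, monotonizes D from the
    sparse end of the path, and selects the densest penalty whose
    monotonized instability stays at or below ``stars_threshold``.

    Under the AND rule an edge requires mutual neighborhood selection
    (OR: either direction). Edge sign follows the larger-magnitude
    directed coefficient; the weight is the mean of the two.
    """
    df = pd.DataFrame(clr)
    taxa = [str(c) for c in df.columns]
    x = df.to_numpy(dtype=float)
    n, p = x.shape
    if n < 10:
        raise ValueError("network inference needs at least 10 samples")
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    if lambda_path is None:
        lambda_path = default_lambda_path(x)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if len(lambda_path) > 1 and not (np.diff(lambda_path) < 0).all():
        raise ValueError("lambda_path must be strictly decreasing")

    rng = np.random.default_rng(seed)
    b = min(n - 1, int(np.floor(10 * np.sqrt(n))))
    freq = np.zeros((len(lambda_path), p, p))
    for _ in range(stars_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        xs = _standardize(x[idx])
        sel = _neighborhood_paths(xs, lambda_path)
        if rule == "AND":
            edges = sel & sel.transpose(0, 2, 1)
        else:
            edges = sel | sel.transpose(0, 2, 1)
        freq += edges
    freq /= stars_subsamples

    iu = np.triu_indices(p, 1)
    xi = freq[:, iu[0], iu[1]]
    instability = (2 * xi * (1 - xi)).mean(axis=1)
    sup_instability = np.maximum.accumulate(instability)  # monotone from sparse end
    ok = np.flatnonzero(sup_instability <= stars_threshold)
    if len(ok) == 0:
        warnings.warn("no penalty met the StARS instability bound; using the densest penalty")
        chosen = len(lambda_path) - 1
    else:
        chosen = int(ok[-1])
    lam = float(lambda_path[chosen])

    beta = _coef_matrix(_standardize(x), lam)
    if rule == "AND":
        adj = (beta != 0) & (beta.T != 0)
    else:
        adj = (beta != 0) | (beta.T != 0)

    g = nx.Graph()
    g.add_nodes_from(taxa)
    for i, j in zip(*np.nonzero(np.triu(adj, 1))):
        bij, bji = beta[i, j], beta[j, i]
        lead = bij if abs(bij) >= abs(bji) else bji
        weight = (bij + bji) / 2.0
        if weight == 0.0:
            weight = lead
        g.add_edge(taxa[i], taxa[j], weight=float(weight), sign=int(np.sign(lead)))

    meta = {
        "lambda_path": lambda_path.tolist(),
        "selected_lambda": lam,
        "selected_index": chosen,
        "instability": instability.tolist(),
        "instability_at_selection": float(sup_instability[chosen]),
        "subsamples": stars_subsamples,
        "subsample_size": b,
        "rule": rule,
        "seed": seed,
    }
    return CooccurrenceNetwork(graph=g, node_abundance=node_abundance or {}, meta=meta)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class TopologySummary:
    size: int
    order: int
    edge_density: float
    clustering_coefficient: float
    average_shortest_path_length: float
    positive_edge_pct: float
    modularity: float
    n_components: int
    keystone_taxa: list[str]

    def to_dict(self) -> dict:
        return {
            "Size": self.size,
            "Order": self.order,
            "Edge density": self.edge_density,
            "Clustering coefficient": self.clustering_coefficient,
            "Average shortest path length": self.average_shortest_path_length,
            "Positive edge %": self.positive_edge_pct,
            "Modularity": self.modularity,
            "Connected components": self.n_components,
            "Keystone taxa": list(self.keystone_taxa),
        }


def edge_density(order: int, size: int) -> float:
    """Density of a simple undirected graph: 2*size / (order*(order-1))."""
    if order < 2:
        warnings.warn("edge density undefined for fewer than 2 nodes; reporting 0")
        return 0.0
    return 2.0 * size / (order * (order - 1))


def positive_edge_pct(n_edges: int, n_positive: int) -> float:
    """Percentage of positive edges among all edges."""
    if n_edges == 0:
        return 0.0
    return 100.0 * n_positive / n_edges


def topology_summary(network: CooccurrenceNetwork, quantile: float = 0.90) -> TopologySummary:
    """Global topology metrics over the non-isolated part of the network.

    The clustering coefficient is the unweighted mean local clustering,
    the path length is averaged over the largest connected component, and
    modularity comes from deterministic greedy agglomeration on the
    unsigned graph.
    """
    g_full = network.graph
    active = [v for v, d in g_full.degree() if d > 0]
    g = g_full.subgraph(active).copy()
    size = g.number_of_edges()
    order = g.number_of_nodes()
    if size == 0:
        raise ValueError("topology summary needs a nonempty network")

    n_pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    components = list(nx.connected_components(g))
    lcc = g.subgraph(max(components, key=len))
    apl = nx.average_shortest_path_length(lcc) if lcc.number_of_nodes() > 1 else 0.0
    communities = nx.community.greedy_modularity_communities(g)
    mod = nx.community.modularity(g, communities)
    return TopologySummary(
        size=size,
        order=order,
        edge_density=edge_density(order, size),
        clustering_coefficient=nx.average_clustering(g),
        average_shortest_path_length=float(apl),
        positive_edge_pct=positive_edge_pct(size, n_pos),
        modularity=float(mod),
        n_components=len(components),
        keystone_taxa=keystone_taxa(network, quantile=quantile),
    )


# ---------------------------------------------------------------------------
# keystone taxa
# ---------------------------------------------------------------------------

def _lognormal_quantile(values: np.ndarray, q: float, label: str) -> float:
    """MLE log-normal quantile of the positive values; empirical fallback.

    With fewer than 3 distinct positive values the log-normal fit is
    degenerate, so the empirical quantile over all values is used.
    """
    pos = values[values > 0]
    if len(np.unique(pos)) < 3:
        warnings.warn(f"degenerate {label} distribution; using the empirical quantile")
        return float(np.quantile(values, q))
    logs = np.log(pos)
    mu, sigma = logs.mean(), logs.std(ddof=0)
    return float(np.exp(mu + sigma * stats.norm.ppf(q)))


def keystone_taxa(network: CooccurrenceNetwork, quantile: float = 0.90) -> list[str]:
    """Hubs-and-bottlenecks keystone detection.

    A node is keystone when its degree and its betweenness centrality both
    strictly exceed the log-normal ``quantile`` fitted (by maximum
    likelihood on the logs) to the positive values of the respective
    metric.
    """
    g = network.graph
    if g.number_of_nodes() < 3:
        raise ValueError("keystone detection needs at least 3 nodes")
    nodes = sorted(g.nodes)
    deg = np.array([g.degree(v) for v in nodes], dtype=float)
    btw_map = nx.betweenness_centrality(g)
    btw = np.array([btw_map[v] for v in nodes], dtype=float)
    deg_thr = _lognormal_quantile(deg, quantile, "degree")
    btw_thr = _lognormal_quantile(btw, quantile, "betweenness")
    return [v for v, d, b in zip(nodes, deg, btw) if d > deg_thr and b > btw_thr]


# ---------------------------------------------------------------------------
# attack robustness
# ---------------------------------------------------------------------------

@dataclass
class AttackCurve:
    strategy: str
    removal_sequence: list
    lcc_sizes: np.ndarray
    replicate_curves: np.ndarray | None = None
    n_replicates: int = 1
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.replicate_curves is None:
            return pd.DataFrame({"strategy": self.strategy,
                                 "step": np.arange(len(self.lcc_sizes)),
                                 "lcc_size": self.lcc_sizes, "replicate": 0})
        frames = []
        for r, curve in enumerate(self.replicate_curves):
            frames.append(pd.DataFrame({"strategy": self.strategy,
                                        "step": np.arange(len(curve)),
                                        "lcc_size": curve, "replicate": r}))
        return pd.concat(frames, ignore_index=True)


def _lcc_size(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))


def _removal_curve(g: nx.Graph, order: list) -> np.ndarray:
    h = g.copy()
    sizes = [_lcc_size(h)]
    for v in order:
        h.remove_node(v)
        sizes.append(_lcc_size(h))
    return np.asarray(sizes)


def _rank_nodes(g: nx.Graph, strategy: str) -> list:
    if strategy == "degree":
        score = dict(g.degree())
    else:
        score = nx.betweenness_centrality(g)
    return sorted(g.nodes, key=lambda v: (-score[v], str(v)))


def attack_robustness(network: CooccurrenceNetwork, strategy: str,
                      n_replicates: int = 1000, ranking: str = "static",
                      seed: int | None = None) -> AttackCurve:
    """LCC decay under sequential node removal on the positive subgraph.

    Negative edges are dropped first. Targeted strategies (``degree``,
    ``betweenness``) remove nodes in descending score order (ties broken
    lexicographically); ``ranking='adaptive'`` re-scores after every
    removal. The ``random`` strategy repeats the removal ``n_replicates``
    times and reports the per-replicate curves alongside their mean. The
    curve starts at the intact LCC size and ends at 0.
    """
    if strategy not in ("degree", "betweenness", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    g = network.positive_subgraph()
    if g.number_of_edges() == 0:
        raise ValueError("attack analysis needs at least one positive edge")

    if strategy == "random":
        rng = np.random.default_rng(seed)
        nodes = sorted(g.nodes, key=str)
        curves = np.empty((n_replicates, len(nodes) + 1), dtype=float)
        for r in range(n_replicates):
            order = [nodes[i] for i in rng.permutation(len(nodes))]
            curves[r] = _removal_curve(g, order)
        return AttackCurve(strategy="random", removal_sequence=[],
                           lcc_sizes=curves.mean(axis=0),
                           replicate_curves=curves, n_replicates=n_replicates, seed=seed)

    if ranking == "static":
        order = _rank_nodes(g, strategy)
        return AttackCurve(strategy=strategy, removal_sequence=order,
                           lcc_sizes=_removal_curve(g, order))
    if ranking != "adaptive":
        raise ValueError("ranking must be 'static' or 'adaptive'")
    h = g.copy()
    order = []
    sizes = [_lcc_size(h)]
    while h.number_of_nodes() > 0:
        v = _rank_nodes(h, strategy)[0]
        h.remove_node(v)
        order.append(v)
        sizes.append(_lcc_size(h))
    return AttackCurve(strategy=strategy, removal_sequence=order,
                       lcc_sizes=np.asarray(sizes, dtype=float))


# ---------------------------------------------------------------------------
# differential association (Fisher Z)
# ---------------------------------------------------------------------------

def differential_association(clr_a, clr_b, q_threshold: float = 0.05
                             ) -> tuple[pd.DataFrame, nx.Graph]:
    """Two-group comparison of pairwise Pearson correlations.

    For every taxon pair the Fisher Z statistic
    ``z = (atanh r_A - atanh r_B) / sqrt(1/(n_A-3) + 1/(n_B-3))``
    is referred to the standard normal (two-sided); p-values are BH
    corrected over all pairs. Returns the full per-pair table and the
    differential network of pairs with q below ``q_threshold`` (edges
    carry both group correlations and the statistic). Correlations with
    ``|r| = 1`` are clamped just inside the open interval.
    """
    a = pd.DataFrame(clr_a)
    b = pd.DataFrame(clr_b)
    if list(a.columns) != list(b.columns):
        raise ValueError("both groups must share the same taxa, in order")
    n_a, n_b = len(a), len(b)
    if n_a < 4 or n_b < 4:
        raise ValueError("Fisher Z needs at least 4 samples per group")
    taxa = [str(c) for c in a.columns]
    ra = np.corrcoef(a.to_numpy(), rowvar=False)
    rb = np.corrcoef(b.to_numpy(), rowvar=False)
    clip = 1 - 1e-12
    if (np.abs(np.triu(ra, 1)) >= 1).any() or (np.abs(np.triu(rb, 1)) >= 1).any():
        warnings.warn("perfect correlation encountered; clamping |r| below 1")
    ra = np.clip(ra, -clip, clip)
    rb = np.clip(rb, -clip, clip)
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    iu = np.triu_indices(len(taxa), 1)
    z = (np.arctanh(ra[iu]) - np.arctanh(rb[iu])) / se
    p = 2 * stats.norm.sf(np.abs(z))
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "taxon_i": [taxa[i] for i in iu[0]],
        "taxon_j": [taxa[j] for j in iu[1]],
        "r_a": ra[iu], "r_b": rb[iu],
        "n_a": n_a, "n_b": n_b,
        "fisher_z": z, "p": p, "q": q,
    })
    g = nx.Graph()
    g.add_nodes_from(taxa)
    for row in table.itertuples():
        if row.q < q_threshold:
            g.add_edge(row.taxon_i, row.taxon_j, r_a=row.r_a, r_b=row.r_b,
                       fisher_z=row.fisher_z, q=row.q)
    g.remove_nodes_from([v for v in list(g.nodes) if g.degree(v) == 0])
    return table, g
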