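"""Significance-thresholded metabolite graphs, class modularity and triads.

The graph induced by a fitted GGM has an edge wherever the partial
correlation is significant (by default significantly *positive*).  Class
modularity Q compares within-class edge mass against its expectation from
class out-degrees,

    Q = sum_i [ A(V_i, V_i)/A(V, V) - (A(V_i, V)/A(V, V))^2 ],

where A(V', V'') sums adjacency entries between the two node sets (so a
within-class edge counts twice).  Significance of an observed Q is assessed
against degree-preserving edge-rewiring null models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ggm import CorrelationResult

__all__ = [
    "ModularityResult",
    "Triad",
    "AnnealSchedule",
    "threshold_graph",
    "relative_outdegree",
    "modularity_Q",
    "rewire",
    "modularity_zscore",
    "anneal_partition",
    "find_triads",
    "class_partition",
    "write_edge_list",
    "write_graphml",
]


def threshold_graph(
    result: CorrelationResult,
    mode: str = "positive",
    weighted: bool = False,
    classes: dict[str, str] | None = None,
) -> nx.Graph:
    """Graph of significant partial correlations.

    ``mode`` selects significantly positive, negative, or both.  Nodes carry
    a ``metabolite_class`` attribute when class labels are available; edges
    carry the partial correlation as ``weight`` (1.0 when ``weighted`` is
    False) and its ``sign``.
    """
    sig = result.significant_partial(mode)
    g = nx.Graph()
    ids = result.metabolite_ids
    labels = classes or result.classes or {}
    for mid in ids:
        g.add_node(mid, metabolite_class=labels.get(mid, ""))
    for i in range(result.m):
        for j in range(i + 1, result.m):
            if sig[i, j]:
                zeta = float(result.Z[i, j])
                g.add_edge(
                    ids[i],
                    ids[j],
                    weight=abs(zeta) if weighted else 1.0,
                    zeta=zeta,
                    sign=1 if zeta > 0 else -1,
                )
    return g


def class_partition(graph: nx.Graph, drop_singletons: bool = True) -> dict[str, str]:
    """Node -> class map from node attributes, optionally dropping singleton classes.

    Classes with a single member carry no modularity information (mirroring
    the exclusion of one-member panels from class statistics); dropped nodes
    are simply absent from the returned partition.
    """
    part = {n: d.get("metabolite_class", "") for n, d in graph.nodes(data=True)}
    if drop_singletons:
        counts: dict[str, int] = {}
        for c in part.values():
            counts[c] = counts.get(c, 0) + 1
        dropped = {c for c, k in counts.items() if k == 1}
        if dropped:
            warnings.warn(f"dropping singleton class(es) {sorted(dropped)} from partition")
        part = {n: c for n, c in part.items() if c not in dropped}
    return part


def _adjacency_sums(
    graph: nx.Graph, partition: dict, weight: str | None
) -> tuple[dict, dict, float, list]:
    """A(V_i, V_j) block sums, A(V_i, V) row sums, A(V, V) total, class order."""
    labels = sorted({partition[n] for n in partition}, key=str)
    lab_idx = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    block = np.zeros((k, k))
    for u, v, d in graph.edges(data=True):
        if u not in partition or v not in partition:
            continue
        w = d.get(weight, 1.0) if weight else 1.0
        ci, cj = lab_idx[partition[u]], lab_idx[partition[v]]
        block[ci, cj] += w
        block[cj, ci] += w  # adjacency is symmetric; within-class counts twice
    row = block.sum(axis=1)
    total = block.sum()
    return block, row, total, labels


def relative_outdegree(
    graph: nx.Graph, partition: dict, weight: str | None = None
) -> tuple[pd.DataFrame, list]:
    """Relative out-degree R_ij = A(V_i, V_j) / A(V_i, V) between classes.

    Rows are stochastic for classes with at least one edge endpoint; classes
    without any edges get a zero row and are returned in the flagged list.
    """
    block, row, _total, labels = _adjacency_sums(graph, partition, weight)
    R = np.zeros_like(block)
    flagged = []
    for i, lab in enumerate(labels):
        if row[i] > 0:
            R[i] = block[i] / row[i]
        else:
            flagged.append(lab)
    return pd.DataFrame(R, index=labels, columns=labels), flagged


def modularity_Q(graph: nx.Graph, partition: dict, weight: str | None = None) -> float:
    """Class-based modularity Q of a (possibly weighted) undirected graph."""
    if graph.number_of_edges() == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    block, row, total, _labels = _adjacency_sums(graph, partition, weight)
    if total == 0:
        raise ValueError("no edges within the partitioned node set")
    return float(np.sum(np.diag(block) / total - (row / total) ** 2))


def rewire(
    graph: nx.Graph,
    seed: int | np.random.Generator | None = None,
    n_swaps: int | None = None,
) -> nx.Graph:
    """Degree-preserving randomization by repeated double-edge swaps.

    Picks two edges (a, b), (c, d) and replaces them with (a, d), (c, b),
    redrawing whenever a swap would create a self-loop or a multi-edge.  The
    default number of accepted swaps is 5 * e.  Edge attributes (weights)
    travel with the stub of the first endpoint, which doubles as the
    neighbor-preserving weighted rewiring variant.  If no valid swap can be
    found the input is returned unchanged with a warning.
    """
    if graph.number_of_edges() < 2:
        warnings.warn("graph has fewer than 2 edges; rewiring is a no-op")
        return graph.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = graph.copy()
    e = g.number_of_edges()
    target = 5 * e if n_swaps is None else int(n_swaps)
    degrees_before = sorted(dict(g.degree()).values())
    accepted = 0
    attempts = 0
    max_attempts = max(100 * target, 1000)
    edges = list(g.edges())
    while accepted < target and attempts < max_attempts:
        attempts += 1
        i1, i2 = rng.integers(0, len(edges), size=2)
        if i1 == i2:
            continue
        a, b = edges[i1]
        c, d = edges[i2]
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        attr1 = dict(g.edges[a, b])
        attr2 = dict(g.edges[c, d])
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        # edge attributes (weights) travel with the first-endpoint stub
        g.add_edge(a, d, **attr1)
        g.add_edge(c, b, **attr2)
        edges[i1] = (a, d)
        edges[i2] = (c, b)
        accepted += 1
    if accepted == 0:
        warnings.warn("no valid double-edge swap exists; returning the input graph")
        return graph.copy()
    assert sorted(dict(g.degree()).values()) == degrees_before, "degree sequence changed"
    assert g.number_of_edges() == e
    return g


@dataclass
class ModularityResult:
    Q: float
    R: pd.DataFrame
    null_mean: float
    null_sd: float
    z_score: float | None
    n_random: int
    flagged_classes: list = field(default_factory=list)


def modularity_zscore(
    graph: nx.Graph,
    partition: dict,
    n_random: int = 1000,
    seed: int | None = None,
    weight: str | None = None,
) -> ModularityResult:
    """Observed Q against degree-preserving rewiring null models.

    z = (Q_obs - mean(Q_null)) / sd(Q_null); when the null sd is zero the
    z-score is reported as None.  Weighted graphs (``weight`` set) use the
    weight-carrying rewiring variant.
    """
    if n_random < 10:
        raise ValueError("need at least 10 randomizations")
    q_obs = modularity_Q(graph, partition, weight)
    R, flagged = relative_outdegree(graph, partition, weight)
    rng = np.random.default_rng(seed)
    q_null = np.empty(n_random)
    for b in range(n_random):
        g_rand = rewire(graph, seed=rng)
        q_null[b] = modularity_Q(g_rand, partition, weight)
    mu, sd = float(q_null.mean()), float(q_null.std(ddof=1))
    z = (q_obs - mu) / sd if sd > 0 else None
    return ModularityResult(
        Q=q_obs, R=R, null_mean=mu, null_sd=sd, z_score=z, n_random=n_random,
        flagged_classes=flagged,
    )


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for partition annealing."""

    t_initial: float = 0.25
    t_final: float = 1e-3
    cooling: float = 0.9
    moves_per_temp: int | None = None  # default: 20 * number of nodes


def anneal_partition(
    graph: nx.Graph,
    seed: int | None = None,
    schedule: AnnealSchedule | None = None,
    initial: dict | None = None,
) -> tuple[dict, float]:
    """Maximize modularity Q over node-class assignments by simulated annealing.

    Proposals move a single node to another (possibly empty) class; worse
    moves are accepted with probability exp(dQ / T) under geometric cooling.
    The best partition seen is returned, so the result never scores below the
    initial partition.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("cannot partition an edgeless graph")
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes())
    if initial is None:
        current = {n: i % max(2, len(nodes) // 3) for i, n in enumerate(nodes)}
    else:
        current = dict(initial)
    n_classes = len(set(current.values())) + 1
    q_cur = modularity_Q(graph, current)
    best, q_best = dict(current), q_cur
    t = schedule.t_initial
    moves = schedule.moves_per_temp or 20 * len(nodes)
    while t > schedule.t_final:
        for _ in range(moves):
            node = nodes[rng.integers(len(nodes))]
            old = current[node]
            new = int(rng.integers(n_classes))
            if new == old:
                continue
            current[node] = new
            q_new = modularity_Q(graph, current)
            if q_new >= q_cur or rng.random() < np.exp((q_new - q_cur) / t):
                q_cur = q_new
                if q_cur > q_best:
                    best, q_best = dict(current), q_cur
            else:
                current[node] = old
        t *= schedule.cooling
    return best, q_best


@dataclass(frozen=True)
class Triad:
    """One-negative/two-positive partial-correlation triple.

    ``negative_pair`` is the pair predicted to be two reaction steps apart.
    """

    nodes: tuple[str, str, str]
    negative_pair: tuple[str, str]


def find_triads(result: CorrelationResult) -> list[Triad]:
    """All unordered triples with two significantly positive and one
    significantly negative partial correlation among their three pairs."""
    pos = result.significant_partial("positive")
    neg = result.significant_partial("negative")
    ids = result.metabolite_ids
    m = result.m
    triads = []
    for i in range(m):
        for j in range(i + 1, m):
            for k in range(j + 1, m):
                pairs = [(i, j), (i, k), (j, k)]
                npos = sum(pos[a, b] for a, b in pairs)
                nneg = sum(neg[a, b] for a, b in pairs)
                if npos == 2 and nneg == 1:
                    (na, nb) = next((a, b) for a, b in pairs if neg[a, b])
                    triads.append(
                        Triad(nodes=(ids[i], ids[j], ids[k]), negative_pair=(ids[na], ids[nb]))
                    )
    return triads


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_edge_list(graph: nx.Graph, path, sep: str = "\t") -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "weight": d.get("weight", 1.0),
            "sign": d.get("sign", 1),
        }
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
        path, sep=sep, index=False
    )


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
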