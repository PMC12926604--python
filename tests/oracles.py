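"""Independent reference computations used only to check fcgraph.metrics.

Distances come from scipy's Floyd-Warshall; most graph quantities come
from networkx; the rest are direct brute-force enumerations of their
defining formulas. None of these share code paths with the package.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def nx_graph(adj):
    g = nx.from_numpy_array(np.asarray(adj, float))
    for _, _, d in g.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    return g


def distances_fw(adj):
    """All-pairs distances on lengths 1/w via scipy Floyd-Warshall."""
    adj = np.asarray(adj, float)
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / adj, 0.0)
    return floyd_warshall(lengths, directed=False, unweighted=False)


def nodal_efficiency_oracle(adj):
    d = distances_fw(adj)
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]) and d[i, j] > 0:
                s += 1.0 / d[i, j]
        out[i] = s / (n - 1)
    return out


def global_efficiency_oracle(adj):
    return float(nodal_efficiency_oracle(adj).mean())


def local_efficiency_oracle(adj):
    adj = np.asarray(adj, float)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size >= 2:
            out[i] = global_efficiency_oracle(adj[np.ix_(nb, nb)])
    return out


def betweenness_oracle(adj):
    g = nx_graph(adj)
    binary = np.all(np.isin(np.asarray(adj), (0.0, 1.0)))
    weight = None if binary else "length"
    bc = nx.betweenness_centrality(g, normalized=False, weight=weight)
    return np.array([bc[i] for i in range(adj.shape[0])])


def clustering_oracle(adj):
    adj = np.asarray(adj, float)
    g = nx_graph(adj)
    binary = np.all(np.isin(adj, (0.0, 1.0)))
    c = nx.clustering(g, weight=None if binary else "weight")
    return np.array([c[i] for i in range(adj.shape[0])])


def transitivity_oracle(adj):
    """Closed (weighted) triples over connected triples, brute force."""
    adj = np.asarray(adj, float)
    n = adj.shape[0]
    binary = np.all(np.isin(adj, (0.0, 1.0)))
    w = adj if binary else adj / adj.max() if adj.max() > 0 else adj
    closed = 0.0
    triples = 0.0
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        triples += nb.size * (nb.size - 1)
        for j, h in itertools.permutations(nb, 2):
            if adj[j, h] > 0:
                closed += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
    return closed / triples if triples > 0 else 0.0


def assortativity_oracle(adj):
    """Pearson r of endpoint (weighted) degrees over directed edges."""
    adj = np.asarray(adj, float)
    k = adj.sum(axis=1)
    xs, ys = [], []
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j] > 0:
                xs.append(k[i])
                ys.append(k[j])
    xs, ys = np.array(xs), np.array(ys)
    if xs.size == 0 or xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def eigenvector_oracle(adj):
    vals, vecs = np.linalg.eigh(np.asarray(adj, float))
    v = vecs[:, -1]
    v = np.abs(v)
    return v / np.linalg.norm(v)


def participation_oracle(adj, partition):
    adj = np.asarray(adj, float)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k == 0:
            continue
        s = 0.0
        for mod in np.unique(partition):
            kis = adj[i][partition == mod].sum()
            s += (kis / k) ** 2
        out[i] = 1.0 - s
    return out


def modularity_oracle(adj, partition):
    g = nx.from_numpy_array(np.asarray(adj, float))
    comms = [
        set(np.flatnonzero(np.asarray(partition) == c))
        for c in np.unique(partition)
    ]
    return nx.algorithms.community.modularity(g, comms, weight="weight")


def best_partition_exhaustive(adj):
    """Maximum-modularity partition by exhaustive search (tiny graphs)."""
    n = np.asarray(adj).shape[0]
    best_q, best = -np.inf, None

    def partitions(elements):
        if not elements:
            yield []
            return
        first, rest = elements[0], elements[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [subset + [first]] + smaller[i + 1 :]
            yield [[first]] + smaller

    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, members in enumerate(part):
            labels[members] = c
        q = modularity_oracle(adj, labels)
        if q > best_q:
            best_q, best = q, labels
    return best, best_q


def average_path_length_oracle(adj):
    d = distances_fw(adj)
    n = d.shape[0]
    vals = [
        d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    ]
    return float(np.mean(vals)) if vals else float("nan")
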