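"""Graph metrics for binary and weighted brain networks.

Implements the 13 network measures used in the analysis — six global
(global efficiency, assortativity, density, modularity, transitivity,
small-world sigma) and seven regional (local efficiency, nodal efficiency,
clustering coefficient, node betweenness, degree, eigenvector centrality,
participation coefficient) — for both binary and weighted undirected
networks.

Conventions (all config-exposed where they matter downstream):

* weighted path length uses edge length 1/w (connection-length convention);
* weighted clustering is the Onnela geometric-mean-of-triangle-weights form;
* betweenness is reported raw (unnormalized);
* the small-world null model is Maslov–Sneppen degree-preserving rewiring;
  weighted networks rewire the topology and shuffle the weight multiset
  over the rewired edges;
* average path length on disconnected networks is taken over reachable
  pairs only, so small-world sigma stays defined at sparse thresholds;
* undefined values (assortativity on regular graphs, eigenvector
  centrality on edgeless graphs, sigma with zero null clustering) are
  carried as NaN, never silently zeroed.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .connectivity import Network, count_components

logger = logging.getLogger(__name__)

__all__ = [
    "ShortestPathMatrix",
    "SmallWorldResult",
    "GlobalMetrics",
    "RegionalMetrics",
    "MetricConfig",
    "shortest_paths",
    "nodal_efficiency",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "transitivity",
    "degree",
    "density",
    "betweenness",
    "eigenvector_centrality",
    "assortativity",
    "detect_communities",
    "modularity",
    "participation_coefficient",
    "average_path_length",
    "rewire_degree_preserving",
    "small_world_sigma",
    "compute_all",
    "REGIONAL_METRICS",
    "GLOBAL_METRICS",
]

REGIONAL_METRICS = (
    "local_efficiency",
    "nodal_efficiency",
    "clustering",
    "betweenness",
    "degree",
    "eigenvector_centrality",
    "participation",
)
GLOBAL_METRICS = (
    "global_efficiency",
    "assortativity",
    "density",
    "modularity_q",
    "transitivity",
    "small_world_sigma",
)


@dataclass
class ShortestPathMatrix:
    """All-pairs shortest-path distances; unreachable pairs are +inf."""

    d: np.ndarray


@dataclass
class SmallWorldResult:
    """Observed and null clustering/path-length with the sigma ratio."""

    c_observed: float
    l_observed: float
    c_random_mean: float
    l_random_mean: float
    sigma: float
    n_null: int
    null_seed: int | None


@dataclass
class GlobalMetrics:
    global_efficiency: float
    assortativity: float
    density: float
    modularity_q: float
    transitivity: float
    small_world_sigma: float
    n_components: int


@dataclass
class RegionalMetrics:
    local_efficiency: np.ndarray
    nodal_efficiency: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray
    degree: np.ndarray
    eigenvector_centrality: np.ndarray
    participation: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "local_efficiency": self.local_efficiency,
            "nodal_efficiency": self.nodal_efficiency,
            "clustering": self.clustering,
            "betweenness": self.betweenness,
            "degree": self.degree,
            "eigenvector_centrality": self.eigenvector_centrality,
            "participation": self.participation,
        }


@dataclass
class MetricConfig:
    """Options shared across metric computations.

    ``metrics`` restricts which measures :func:`compute_all` evaluates
    (None = all 13); unevaluated fields come back as NaN.
    """

    n_null: int = 10
    rewire_factor: float = 10.0
    n_restarts: int = 10
    gamma: float = 1.0
    seed: int | None = 0
    metrics: tuple[str, ...] | None = None


# ---------------------------------------------------------------------------
# Shortest paths


def _adjacency(net: Network | np.ndarray) -> np.ndarray:
    return net.adjacency if isinstance(net, Network) else np.asarray(net, float)


def _is_binary(adj: np.ndarray) -> bool:
    return bool(((adj == 0.0) | (adj == 1.0)).all())


def _bfs_all_pairs(adj_bool: np.ndarray) -> np.ndarray:
    """All-pairs hop counts by synchronous frontier expansion."""
    n = adj_bool.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    level = 0
    while frontier.any():
        level += 1
        frontier = (frontier @ adj_bool) & ~reached
        d[frontier] = level
        reached |= frontier
    return d


def _dijkstra(lengths: list[list[tuple[int, float]]], source: int, n: int) -> np.ndarray:
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        du, u = heapq.heappop(heap)
        if du > dist[u]:
            continue
        for v, w in lengths[u]:
            alt = du + w
            if alt < dist[v]:
                dist[v] = alt
                heapq.heappush(heap, (alt, v))
    return dist


def _length_lists(adj: np.ndarray) -> list[list[tuple[int, float]]]:
    """Adjacency lists with edge length 1/weight."""
    n = adj.shape[0]
    out: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    iu, ju = np.nonzero(adj)
    for i, j in zip(iu.tolist(), ju.tolist()):
        out[i].append((j, 1.0 / adj[i, j]))
    return out


def shortest_paths(net: Network | np.ndarray) -> ShortestPathMatrix:
    """All-pairs shortest paths: BFS hop counts (binary) or Dijkstra on
    edge lengths 1/w (weighted). Unreachable pairs get +inf."""
    adj = _adjacency(net)
    if adj.min() < 0:
        raise ValueError("edge weights must be nonnegative")
    n = adj.shape[0]
    if _is_binary(adj):
        return ShortestPathMatrix(d=_bfs_all_pairs(adj.astype(bool)))
    lengths = _length_lists(adj)
    d = np.vstack([_dijkstra(lengths, s, n) for s in range(n)])
    return ShortestPathMatrix(d=d)


def nodal_efficiency(
    net: Network | np.ndarray, spm: ShortestPathMatrix | None = None
) -> np.ndarray:
    """Mean inverse shortest-path distance from each node to all others.

    E_nodal(i) = (1/(N-1)) * sum_{j != i} 1/d_ij, with 1/inf = 0, so
    isolated nodes score 0.
    """
    adj = _adjacency(net)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    d = (spm or shortest_paths(adj)).d
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(
    net: Network | np.ndarray, spm: ShortestPathMatrix | None = None
) -> float:
    """Mean of nodal efficiencies (mean 1/d over ordered pairs)."""
    return float(nodal_efficiency(net, spm).mean())


def _minplus_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs distances on lengths 1/w by vectorized min-plus relaxation."""
    n = adj.shape[0]
    with np.errstate(divide="ignore"):
        d = np.where(adj > 0, 1.0 / adj, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return d


def local_efficiency(net: Network | np.ndarray) -> np.ndarray:
    """Global efficiency of the subgraph induced on each node's neighbors.

    Nodes with fewer than two neighbors score 0.
    """
    adj = _adjacency(net)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        k = nb.size
        if k < 2:
            continue
        d = _minplus_distances(adj[np.ix_(nb, nb)])
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        inv[np.isinf(d)] = 0.0
        out[i] = inv.sum() / (k * (k - 1))
    return out


def _onnela_cubed(adj: np.ndarray) -> np.ndarray:
    """Diagonal of (W-hat^(1/3))^3 — twice the weighted triangle intensity."""
    w = adj / adj.max()
    cr = np.cbrt(w)
    return np.diag(cr @ cr @ cr)


def clustering_coefficient(net: Network | np.ndarray) -> np.ndarray:
    """Per-node clustering: triangle density around each node.

    Binary: C_i = 2*t_i / (k_i (k_i - 1)). Weighted: Onnela variant with
    geometric-mean triangle intensities on weights rescaled by the maximum,
    normalized by the binary degree. k_i < 2 gives 0.
    """
    adj = _adjacency(net)
    k = (adj > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    if _is_binary(adj):
        tri2 = np.diag(adj @ adj @ adj)  # 2 * triangles per node
    else:
        if adj.max() == 0:
            return np.zeros(adj.shape[0])
        tri2 = _onnela_cubed(adj)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c


def transitivity(net: Network | np.ndarray) -> float:
    """Ratio of (weighted) closed triples to connected triples.

    Binary: 3 * triangles / connected triples. Weighted: the Onnela
    triangle intensities replace the triangle count.
    """
    adj = _adjacency(net)
    k = (adj > 0).sum(axis=1).astype(float)
    triples = (k * (k - 1)).sum()
    if triples == 0:
        return 0.0
    if _is_binary(adj):
        closed = np.trace(adj @ adj @ adj)
    else:
        closed = _onnela_cubed(adj).sum()
    return float(closed / triples)


def degree(net: Network | np.ndarray) -> np.ndarray:
    """Binary degree (neighbor count) or weighted strength (weight sum)."""
    adj = _adjacency(net)
    if _is_binary(adj):
        return adj.sum(axis=1)
    return adj.sum(axis=1)


def density(net: Network | np.ndarray) -> float:
    """Fraction of realized connections: 2|E| / (N(N-1))."""
    adj = _adjacency(net)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    n_edges = np.count_nonzero(np.triu(adj, 1))
    return 2.0 * n_edges / (n * (n - 1))


def betweenness(net: Network | np.ndarray) -> np.ndarray:
    """Raw (unnormalized) shortest-path betweenness, Brandes accumulation.

    Weighted graphs use edge lengths 1/w; multiplicity over equal-length
    paths is shared fractionally. Undirected pair symmetry is accounted
    for (each unordered pair counted once).
    """
    adj = _adjacency(net)
    if _is_binary(adj):
        return _betweenness_binary(adj)
    return _betweenness_weighted(adj)


def _betweenness_binary(adj: np.ndarray) -> np.ndarray:
    """Level-synchronous Brandes over all sources at once.

    With D the BFS hop matrix, path counts satisfy
    sigma[s, v] = sum_u A[u, v] * sigma[s, u] * [D[s, u] = D[s, v] - 1],
    and the dependency accumulation runs the levels backwards — both are
    plain matrix products per level.
    """
    n = adj.shape[0]
    d = _bfs_all_pairs(adj.astype(bool))
    sigma = np.eye(n)
    dmax = int(d[np.isfinite(d)].max()) if n else 0
    levels = [d == lvl for lvl in range(dmax + 1)]
    for lvl in range(1, dmax + 1):
        sigma += ((sigma * levels[lvl - 1]) @ adj) * levels[lvl]
    delta = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        for lvl in range(dmax, 0, -1):
            ratio = np.where(levels[lvl], (1.0 + delta) / sigma, 0.0)
            delta += sigma * (ratio @ adj) * levels[lvl - 1]
    bc = delta.sum(axis=0) - np.diag(delta)  # exclude the source itself
    return bc / 2.0  # undirected: each unordered pair counted from both ends


def _betweenness_weighted(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    bc = np.zeros(n)
    lengths = _length_lists(adj)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        seen = np.zeros(n, dtype=bool)
        heap = [(0.0, s)]
        while heap:
            du, u = heapq.heappop(heap)
            if seen[u]:
                continue
            seen[u] = True
            stack.append(u)
            for v, w in lengths[u]:
                alt = du + w
                if alt < dist[v] - 1e-14:
                    dist[v] = alt
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (alt, v))
                elif not seen[v] and abs(alt - dist[v]) <= 1e-14 and u not in preds[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for w in reversed(stack):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0


def eigenvector_centrality(
    net: Network | np.ndarray, tol: float = 1e-10, max_iter: int = 100000
) -> np.ndarray:
    """Dominant adjacency eigenvector, nonnegative, unit Euclidean norm.

    Power iteration on A + I (the shift breaks the bipartite +/-lambda tie
    without changing eigenvectors). Raises on edgeless graphs.
    """
    adj = _adjacency(net)
    if np.count_nonzero(adj) == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless graph")
    n = adj.shape[0]
    m = adj + np.eye(n)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        nv = m @ v
        nv /= np.linalg.norm(nv)
        if np.abs(nv - v).max() < tol:
            v = nv
            break
        v = nv
    v = np.abs(v)
    return v / np.linalg.norm(v)


def assortativity(net: Network | np.ndarray) -> float:
    """Pearson correlation of endpoint degrees over directed edge instances.

    Weighted networks correlate endpoint strengths over the binary edge
    instances. Returns NaN (undefined) when either endpoint list has zero
    variance, e.g. on regular graphs.
    """
    adj = _adjacency(net)
    iu, ju = np.nonzero(np.triu(adj, 1))
    if iu.size == 0:
        return float("nan")
    k = degree(adj)
    x = np.concatenate([k[iu], k[ju]])
    y = np.concatenate([k[ju], k[iu]])
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Communities


def modularity(
    adj: np.ndarray, partition: np.ndarray, gamma: float = 1.0
) -> float:
    """Newman modularity Q = sum_c [e_c/m - gamma (d_c/2m)^2] (weighted)."""
    adj = np.asarray(adj, float)
    partition = np.asarray(partition)
    m2 = adj.sum()  # = 2m
    if m2 == 0:
        return 0.0
    q = 0.0
    for c in np.unique(partition):
        idx = np.flatnonzero(partition == c)
        sub = adj[np.ix_(idx, idx)]
        e_c = sub.sum() / 2.0
        d_c = adj[idx].sum()
        q += e_c / (m2 / 2.0) - gamma * (d_c / m2) ** 2
    return float(q)


def _louvain_local_move(
    w: np.ndarray, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """One Louvain level: greedy local moving until no gain."""
    n = w.shape[0]
    k = w.sum(axis=1)
    m2 = w.sum()
    comm = list(range(n))
    sigma_tot = k.copy()
    neighbors = [
        [(j, w[i, j]) for j in np.flatnonzero(w[i]).tolist() if j != i]
        for i in range(n)
    ]
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n).tolist():
            ci = comm[i]
            sigma_tot[ci] -= k[i]
            links: dict[int, float] = {ci: 0.0}
            for j, wij in neighbors[i]:
                cj = comm[j]
                links[cj] = links.get(cj, 0.0) + wij
            coef = gamma * k[i] / m2
            stay_gain = links[ci] - coef * sigma_tot[ci]
            best, best_gain = ci, stay_gain
            for c, link in links.items():
                gain = link - coef * sigma_tot[c]
                if gain > best_gain + 1e-12:  # strict: stay put on ties
                    best, best_gain = c, gain
            sigma_tot[best] += k[i]
            if best != ci:
                comm[i] = best
                improved = True
    # canonical relabel 0..K-1
    _, relab = np.unique(comm, return_inverse=True)
    return relab


def _aggregate(w: np.ndarray, partition: np.ndarray) -> np.ndarray:
    n_comm = partition.max() + 1
    ind = np.zeros((w.shape[0], n_comm))
    ind[np.arange(w.shape[0]), partition] = 1.0
    return ind.T @ w @ ind


def detect_communities(
    net: Network | np.ndarray,
    gamma: float = 1.0,
    n_restarts: int = 10,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Louvain-style greedy modularity maximization, best of ``n_restarts``.

    Returns (partition labels 0..K-1 in first-occurrence order, Q).
    """
    adj = _adjacency(net)
    if np.count_nonzero(adj) == 0:
        raise ValueError("community detection requires at least one edge")
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best_part: np.ndarray | None = None
    for _ in range(max(1, n_restarts)):
        part = np.arange(adj.shape[0])
        w = adj.copy()
        mapping = np.arange(adj.shape[0])
        while True:
            level = _louvain_local_move(w, gamma, rng)
            if level.max() + 1 == w.shape[0]:
                break
            mapping = level[mapping]
            w = _aggregate(w, level)
        part = mapping
        q = modularity(adj, part, gamma)
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    assert best_part is not None
    # relabel by first occurrence for determinism
    seen: dict[int, int] = {}
    out = np.empty_like(best_part)
    for i, c in enumerate(best_part):
        out[i] = seen.setdefault(int(c), len(seen))
    return out, float(best_q)


def participation_coefficient(
    net: Network | np.ndarray, partition: np.ndarray
) -> np.ndarray:
    """Diversity of each node's connections across modules.

    P_i = 1 - sum_s (kappa_is / k_i)^2 where kappa_is is node i's (weighted)
    degree into module s; isolated nodes get 0.
    """
    adj = _adjacency(net)
    n = adj.shape[0]
    partition = np.asarray(partition)
    if partition.shape != (n,):
        raise ValueError("partition must assign every node a module")
    n_mod = int(partition.max()) + 1
    ind = np.zeros((n, n_mod))
    ind[np.arange(n), partition] = 1.0
    kappa = adj @ ind  # n x modules
    k = adj.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, kappa / k[:, None], 0.0)
    p = 1.0 - (frac**2).sum(axis=1)
    p[k == 0] = 0.0
    return p


# ---------------------------------------------------------------------------
# Small-world sigma


def average_path_length(
    net: Network | np.ndarray, spm: ShortestPathMatrix | None = None
) -> float:
    """Mean shortest-path distance over reachable ordered pairs (i != j)."""
    adj = _adjacency(net)
    d = (spm or shortest_paths(adj)).d.copy()
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        return float("nan")
    return float(d[finite].mean())


def rewire_degree_preserving(
    net: Network, n_swaps: int, rng: np.random.Generator
) -> tuple[Network, int]:
    """Maslov–Sneppen double-edge swaps preserving the degree sequence.

    Attempts ``n_swaps`` swaps; returns the rewired network and the number
    of successful swaps. Weighted networks rewire the binary topology and
    shuffle the original weight multiset over the rewired edges.
    """
    adj = _adjacency(net).copy()
    n = adj.shape[0]
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    weights = adj[iu, ju].copy()
    present = set(edges)
    n_edges = len(edges)
    successes = 0
    if n_edges >= 2:
        for _ in range(int(n_swaps)):
            e1, e2 = rng.integers(0, n_edges, size=2)
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if rng.random() < 0.5:
                c, d = d, c
            # proposed: (a, d), (c, b)
            if len({a, b, c, d}) < 4:
                continue
            new1 = (min(a, d), max(a, d))
            new2 = (min(c, b), max(c, b))
            if new1 in present or new2 in present:
                continue
            present.discard(edges[e1])
            present.discard(edges[e2])
            present.add(new1)
            present.add(new2)
            edges[e1], edges[e2] = new1, new2
            successes += 1
    if successes == 0 and n_edges >= 2:
        logger.warning(
            "degree-preserving rewiring found no valid swaps; null equals observed"
        )
    out = np.zeros_like(adj)
    if not _is_binary(adj):
        rng.shuffle(weights)
    for (i, j), w in zip(edges, weights):
        out[i, j] = out[j, i] = w
    return (
        Network(
            adjacency=out,
            scheme=net.scheme,
            threshold=net.threshold,
            region_labels=list(net.region_labels),
        ),
        successes,
    )


def small_world_sigma(
    net: Network,
    n_null: int = 10,
    rewire_factor: float = 10.0,
    seed: int | None = None,
) -> SmallWorldResult:
    """Small-world sigma = (C/Cr) / (L/Lr) against rewired null networks.

    C is the mean clustering coefficient and L the average shortest-path
    length over reachable pairs; Cr and Lr are averaged over ``n_null``
    degree-preserving rewired versions of the network
    (``rewire_factor * |E|`` attempted swaps each). ``rewire_factor=0``
    leaves the nulls identical to the observed network, giving sigma = 1
    exactly.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    spm = shortest_paths(net)
    c_obs = float(clustering_coefficient(net).mean())
    l_obs = average_path_length(net, spm)
    if not np.isfinite(l_obs):
        raise ValueError("average path length undefined: no reachable pairs")
    rng = np.random.default_rng(seed)
    n_swaps = int(round(rewire_factor * net.n_edges))
    c_nulls, l_nulls = [], []
    total_swaps = 0
    for _ in range(n_null):
        null, n_ok = rewire_degree_preserving(net, n_swaps, rng)
        total_swaps += n_ok
        c_nulls.append(float(clustering_coefficient(null).mean()))
        l_nulls.append(average_path_length(null))
    if total_swaps == 0:
        # every null is the observed network (no swaps attempted, or none
        # valid, e.g. star-like graphs): sigma = 1 exactly by identity
        c_r, l_r = c_obs, l_obs
    else:
        c_r = float(np.mean(c_nulls))
        l_r = float(np.mean(l_nulls))
    if c_r == 0 or c_obs == 0 or not np.isfinite(l_r):
        sigma = float("nan")
        logger.warning("small-world sigma undefined (zero clustering in nulls)")
    else:
        sigma = (c_obs / c_r) / (l_obs / l_r)
    return SmallWorldResult(
        c_observed=c_obs,
        l_observed=l_obs,
        c_random_mean=c_r,
        l_random_mean=l_r,
        sigma=sigma,
        n_null=n_null,
        null_seed=seed,
    )


# ---------------------------------------------------------------------------
# One-pass bundle


def compute_all(
    net: Network, config: MetricConfig | None = None
) -> tuple[GlobalMetrics, RegionalMetrics]:
    """Compute all requested metrics in one pass with shared intermediates.

    Shortest paths are computed once and shared by the efficiency metrics;
    the community partition from :func:`detect_communities` feeds both
    modularity and the participation coefficient. Metrics excluded by
    ``config.metrics`` (and undefined values) are NaN.
    """
    cfg = config or MetricConfig()
    n = net.n_nodes
    want = set(cfg.metrics) if cfg.metrics is not None else set(
        REGIONAL_METRICS + GLOBAL_METRICS
    )
    nanvec = np.full(n, np.nan)

    need_paths = want & {
        "nodal_efficiency",
        "global_efficiency",
        "betweenness",
        "small_world_sigma",
    }
    spm = shortest_paths(net) if need_paths else None

    e_nodal = nodal_efficiency(net, spm) if "nodal_efficiency" in want or (
        "global_efficiency" in want
    ) else nanvec
    glob_eff = float(e_nodal.mean()) if "global_efficiency" in want else float("nan")

    clust = (
        clustering_coefficient(net)
        if want & {"clustering", "transitivity"}
        else nanvec
    )

    partition = None
    mod_q = float("nan")
    part_coef = nanvec
    if want & {"modularity_q", "participation"}:
        if net.n_edges > 0:
            partition, mod_q = detect_communities(
                net, gamma=cfg.gamma, n_restarts=cfg.n_restarts, seed=cfg.seed
            )
            if "participation" in want:
                part_coef = participation_coefficient(net, partition)
        else:
            logger.warning("edgeless network: modularity/participation undefined")

    if "eigenvector_centrality" in want:
        try:
            eig = eigenvector_centrality(net)
        except ValueError:
            logger.warning("edgeless network: eigenvector centrality undefined")
            eig = nanvec
    else:
        eig = nanvec

    sigma = float("nan")
    if "small_world_sigma" in want and net.n_edges > 0:
        try:
            sigma = small_world_sigma(
                net,
                n_null=cfg.n_null,
                rewire_factor=cfg.rewire_factor,
                seed=cfg.seed,
            ).sigma
        except ValueError:
            logger.warning("small-world sigma undefined for this network")

    glob = GlobalMetrics(
        global_efficiency=glob_eff,
        assortativity=assortativity(net) if "assortativity" in want else float("nan"),
        density=density(net) if "density" in want else float("nan"),
        modularity_q=mod_q if "modularity_q" in want else float("nan"),
        transitivity=transitivity(net) if "transitivity" in want else float("nan"),
        small_world_sigma=sigma,
        n_components=count_components(net),
    )
    reg = RegionalMetrics(
        local_efficiency=local_efficiency(net) if "local_efficiency" in want else nanvec,
        nodal_efficiency=e_nodal if "nodal_efficiency" in want else nanvec,
        clustering=clust if "clustering" in want else nanvec,
        betweenness=betweenness(net) if "betweenness" in want else nanvec,
        degree=degree(net) if "degree" in want else nanvec,
        eigenvector_centrality=eig,
        participation=part_coef if "participation" in want else nanvec,
    )
    return glob, reg
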