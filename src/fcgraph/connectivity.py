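"""Connectivity matrices and thresholded network construction.

Builds the absolute-valued Pearson correlation matrix from retained frames
and derives the three network families used throughout the analysis:

* weighted   — the raw absolute-correlation matrix, used unaltered;
* absolute   — binary, edge kept where |r| meets a fixed cutoff;
* proportional — binary, a fixed fraction of the strongest edges kept.

Threshold sweeps are constrained ranges (absolute 0.10–0.65, proportional
0.25–0.65, step 0.05 by default) with per-threshold component diagnostics
to flag ranges where networks fragment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "Network",
    "ThresholdSweep",
    "correlation_matrix",
    "threshold_absolute",
    "threshold_proportional",
    "make_sweep",
    "count_components",
    "validate_sweep_bounds",
    "DEFAULT_ABSOLUTE_SWEEP",
    "DEFAULT_PROPORTIONAL_SWEEP",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region matrix of absolute Pearson correlations.

    Entries lie in [0, 1]; the diagonal is exactly zero (self-correlations
    are excluded from every construction).
    """

    values: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if len(self.region_labels) != n:
            raise ValueError("label count must match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly zero")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("entries must be absolute correlations in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class Network:
    """Adjacency matrix plus construction metadata.

    ``scheme`` is one of {'weighted', 'absolute', 'proportional'}; binary
    schemes carry the threshold used, the weighted scheme has threshold
    None and real-valued weights in [0, 1].
    """

    adjacency: np.ndarray
    scheme: str
    threshold: float | None
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.scheme not in ("weighted", "absolute", "proportional"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "weighted" and self.threshold is not None:
            raise ValueError("weighted networks carry no threshold")
        if self.scheme != "weighted":
            uniq = np.unique(self.adjacency)
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise ValueError("thresholded networks must be binary")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.adjacency, self.adjacency.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = (self.adjacency + self.adjacency.T) / 2.0

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def is_binary(self) -> bool:
        return self.scheme != "weighted"

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / (n * (n - 1)) if n > 1 else 0.0


@dataclass
class ThresholdSweep:
    """Inclusive arithmetic threshold sequence for one binarization scheme."""

    scheme: str
    lower: float
    upper: float
    step: float
    thresholds: list[float] = field(default_factory=list)


#: Default constrained sweeps: absolute cutoffs 0.10–0.65 (lower bound
#: mitigates spurious edges, upper bound keeps mean/median component count
#: below 2), proportional densities 0.25–0.65 (0.25 limits fragmentation,
#: by 0.65 all networks are fully connected).
DEFAULT_ABSOLUTE_SWEEP = (0.10, 0.65, 0.05)
DEFAULT_PROPORTIONAL_SWEEP = (0.25, 0.65, 0.05)


def correlation_matrix(ts) -> ConnectivityMatrix:
    """Absolute Pearson correlation between every pair of regions.

    Correlations are computed over retained (non-censored) frames only,
    converted to absolute values (preserving strong negative couplings as
    strong edges), and the diagonal is zeroed.
    """
    data = ts.retained()
    if data.shape[0] < 3:
        raise ValueError("need at least 3 retained frames for correlation")
    sd = data.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [ts.region_labels[i] for i in constant]
        raise ValueError(f"constant region(s) with zero variance: {names}")
    r = np.corrcoef(data, rowvar=False)
    vals = np.abs(r)
    np.clip(vals, 0.0, 1.0, out=vals)
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry (corrcoef is
    np.fill_diagonal(vals, 0.0)   # symmetric only to floating tolerance)
    return ConnectivityMatrix(values=vals, region_labels=list(ts.region_labels))


def threshold_absolute(
    cm: ConnectivityMatrix, t: float, strict: bool = False
) -> Network:
    """Binarize by a fixed correlation cutoff.

    An edge is kept where the absolute correlation is >= t (or > t with
    ``strict=True``; the non-strict boundary convention is the default).
    """
    if not 0 <= t <= 1:
        raise ValueError("absolute threshold must lie in [0, 1]")
    adj = (cm.values > t) if strict else (cm.values >= t)
    adj = adj.astype(float)
    np.fill_diagonal(adj, 0.0)
    return Network(
        adjacency=adj,
        scheme="absolute",
        threshold=float(t),
        region_labels=list(cm.region_labels),
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def threshold_proportional(cm: ConnectivityMatrix, p: float) -> Network:
    """Keep the strongest fraction ``p`` of possible edges.

    Exactly k = round-half-away(p * N(N-1)/2) upper-triangle entries become
    edges, ranked by descending weight with ties broken by ascending (i, j)
    lexicographic order, so repeat runs are identical.
    """
    if not 0 < p <= 1:
        raise ValueError("proportional threshold must lie in (0, 1]")
    n = cm.n_regions
    m = n * (n - 1) // 2
    k = _round_half_away(p * m)
    if k == 0:
        raise ValueError(f"p={p} retains zero edges on {n} regions (degenerate)")
    iu, ju = np.triu_indices(n, 1)
    w = cm.values[iu, ju]
    order = np.lexsort((ju, iu, -w))  # primary: weight desc; ties: (i, j) asc
    keep = order[:k]
    adj = np.zeros((n, n))
    adj[iu[keep], ju[keep]] = 1.0
    adj += adj.T
    return Network(
        adjacency=adj,
        scheme="proportional",
        threshold=float(p),
        region_labels=list(cm.region_labels),
    )


def make_sweep(scheme: str, lower: float, upper: float, step: float) -> ThresholdSweep:
    """Build an inclusive arithmetic threshold sequence.

    The span (upper - lower) must be an integer multiple of step to within
    1e-9; the defaults give 12 absolute and 9 proportional thresholds.
    """
    if scheme not in ("absolute", "proportional"):
        raise ValueError(f"sweep scheme must be absolute/proportional, got {scheme!r}")
    if lower > upper:
        raise ValueError("lower must be <= upper")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = (upper - lower) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"(upper - lower) = {upper - lower} is not an integer multiple of "
            f"step = {step}"
        )
    count = int(round(n_steps)) + 1
    thresholds = [round(lower + i * step, 10) for i in range(count)]
    return ThresholdSweep(
        scheme=scheme, lower=lower, upper=upper, step=step, thresholds=thresholds
    )


def count_components(net: Network) -> int:
    """Number of connected components (union-find over edges)."""
    n = net.n_nodes
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    iu, ju = np.nonzero(np.triu(net.adjacency, 1))
    for a, b in zip(iu.tolist(), ju.tolist()):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(i) for i in range(n)})


def validate_sweep_bounds(
    matrices: list[ConnectivityMatrix], sweep: ThresholdSweep
) -> pd.DataFrame:
    """Per-threshold component diagnostics across a cohort of matrices.

    Returns a table with mean and median component counts per threshold,
    a ``flagged`` column where mean or median >= 2, and (proportional
    scheme) ``all_connected`` marking thresholds at which every network in
    the cohort forms a single component.
    """
    if not matrices:
        raise ValueError("need at least one connectivity matrix")
    build = threshold_absolute if sweep.scheme == "absolute" else threshold_proportional
    rows = []
    for t in sweep.thresholds:
        counts = np.array([count_components(build(cm, t)) for cm in matrices])
        rows.append(
            {
                "scheme": sweep.scheme,
                "threshold": t,
                "mean_components": counts.mean(),
                "median_components": float(np.median(counts)),
                "flagged": bool(counts.mean() >= 2 or np.median(counts) >= 2),
                "all_connected": bool((counts == 1).all()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delimited-text I/O


def write_matrix(cm: ConnectivityMatrix, path: str | Path) -> None:
    """Square delimited matrix with a header row of region labels."""
    pd.DataFrame(cm.values, columns=cm.region_labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float), region_labels=list(df.columns)
    )


def write_edgelist(net: Network, path: str | Path) -> None:
    """Edge list (region_i, region_j, weight) plus a sidecar metadata
    record (<path>.meta.json: scheme, threshold, N, density)."""
    iu, ju = np.nonzero(np.triu(net.adjacency, 1))
    df = pd.DataFrame(
        {
            "region_i": [net.region_labels[i] for i in iu],
            "region_j": [net.region_labels[j] for j in ju],
            "weight": net.adjacency[iu, ju],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "scheme": net.scheme,
        "threshold": net.threshold,
        "n_regions": net.n_nodes,
        "n_edges": net.n_edges,
        "density": net.density,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
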