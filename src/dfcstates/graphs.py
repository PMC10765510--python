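"""Binarized brain networks and the six graph indicators.

An FC matrix becomes an undirected, unweighted graph either by keeping the
top proportion of upper-triangle edges ranked by r (density mode, default
0.15) or by keeping edges with r strictly above an absolute cutoff. The six
indicators are mean nodal clustering coefficient, maximum k-core number,
modularity of a greedy modularity-maximising partition, degree assortativity,
global efficiency and local efficiency. Applied per dFC window this yields a
temporal multilayer description of the network ("dynamic graph" sequences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SchemaError
from .windows import DfcSeries, FcMatrix


@dataclass
class BinaryNetwork:
    """0/1 symmetric adjacency with no self-loops plus its threshold rule."""

    adjacency: np.ndarray
    threshold_rule: tuple[str, float]
    source: tuple | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise SchemaError("adjacency must be square")
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise SchemaError("adjacency must be symmetric with zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise SchemaError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def to_networkx(self) -> nx.Graph:
        g = nx.empty_graph(self.n_nodes)
        rows, cols = np.nonzero(np.triu(self.adjacency, k=1))
        g.add_edges_from(zip(rows.tolist(), cols.tolist()))
        return g


@dataclass
class GraphIndicatorSet:
    """The six indicators of one binary network; assortativity may be NaN."""

    k_core: int
    clustering_coefficient: float
    modularity: float
    assortativity: float
    global_efficiency: float
    local_efficiency: float

    def as_dict(self) -> dict[str, float]:
        return {"k_core": self.k_core,
                "clustering_coefficient": self.clustering_coefficient,
                "modularity": self.modularity,
                "assortativity": self.assortativity,
                "global_efficiency": self.global_efficiency,
                "local_efficiency": self.local_efficiency}


INDICATOR_NAMES = ["k_core", "clustering_coefficient", "modularity",
                   "assortativity", "global_efficiency", "local_efficiency"]


def binarize(fc: FcMatrix, mode: str = "density", value: float = 0.15,
             exclude_negative: bool = True) -> BinaryNetwork:
    """Threshold an FC matrix into a binary network.

    density mode keeps the floor(value * N(N-1)/2) strongest upper-triangle
    edges, ties at the cutoff broken by (i, j) lexicographic order; with
    ``exclude_negative`` (default) edges with r <= 0 are never kept, which may
    leave fewer edges. absolute mode keeps edges with r > value.
    """
    n = fc.n_rois
    iu = np.triu_indices(n, k=1)
    r = fc.values[iu]
    adj = np.zeros((n, n), dtype=np.int8)
    if mode == "absolute":
        if not (-1.0 < value < 1.0):
            raise SchemaError(f"absolute threshold must lie in (-1, 1), got {value}")
        keep = r > value
    elif mode == "density":
        if not (0.0 < value):
            raise SchemaError(f"density must lie in (0, 1], got {value}")
        pairs = len(r)
        m = int(np.floor(value * pairs))
        if value > 1.0:
            warnings.warn(f"density {value} > 1 requests more edges than pairs; "
                          "clamping to the complete graph")
            m = pairs
        order = np.lexsort((iu[1], iu[0], -r))  # by -r, then i, then j
        if exclude_negative:
            order = order[r[order] > 0]
        keep = np.zeros(pairs, dtype=bool)
        keep[order[:m]] = True
    else:
        raise SchemaError(f"unknown threshold mode {mode!r}")
    adj[(iu[0][keep], iu[1][keep])] = 1
    adj |= adj.T
    return BinaryNetwork(adj, (mode, float(value)),
                         source=(fc.window_index, fc.start_tr, fc.end_tr))


def indicators(net: BinaryNetwork) -> GraphIndicatorSet:
    """Compute the six indicators of one binary network.

    Conventions: isolated/degree-1 nodes contribute clustering 0; efficiency
    contributions of unreachable pairs are 0; local efficiency of a node is
    the global efficiency of its open neighbourhood subgraph; modularity uses
    greedy (CNM) modularity maximisation and is NaN for an empty graph;
    assortativity is NaN when undefined (e.g. all degrees equal).
    """
    if net.n_nodes < 2:
        raise SchemaError("need at least 2 nodes")
    g = net.to_networkx()
    k_core = int(max(nx.core_number(g).values())) if g.number_of_edges() else 0
    clustering = float(nx.average_clustering(g))
    if g.number_of_edges():
        communities = nx.community.greedy_modularity_communities(g)
        modularity = float(nx.community.modularity(g, communities))
    else:
        modularity = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            assort = float(nx.degree_assortativity_coefficient(g))
        except (ZeroDivisionError, ValueError):
            assort = float("nan")
    geff = float(nx.global_efficiency(g))
    leff = float(nx.local_efficiency(g))
    return GraphIndicatorSet(k_core, clustering, modularity, assort, geff, leff)


@dataclass
class DynamicIndicatorSeries:
    """Per-window indicator sets for one run, in window order."""

    source: tuple[str, str, str]
    window_indices: list[int]
    values: list[GraphIndicatorSet]
    threshold_rule: tuple[str, float]

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([v.as_dict() for v in self.values])
        df.insert(0, "window_index", self.window_indices)
        return df

    def trace(self, metric: str) -> np.ndarray:
        return np.array([getattr(v, metric) for v in self.values], dtype=float)


def dynamic_indicators(dfc: DfcSeries, mode: str = "density", value: float = 0.15,
                       exclude_negative: bool = True) -> DynamicIndicatorSeries:
    """Binarize + indicators for every window of a dFC series, order preserved."""
    vals, idx = [], []
    for w in dfc.windows:
        try:
            vals.append(indicators(binarize(w, mode, value, exclude_negative)))
        except Exception as err:
            raise type(err)(f"window {w.window_index}: {err}") from None
        idx.append(w.window_index)
    return DynamicIndicatorSeries(dfc.source, idx, vals, (mode, float(value)))
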