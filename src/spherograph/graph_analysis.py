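"""Neighbor graph of cells and its homophily statistics.

The Delaunay triangulation of the cell centroids is the dual of the Voronoi
tessellation: two cells are linked iff their Voronoi regions share a facet
(for sites in general position). On this fixed topology four statistics
quantify whether stem cells sit next to stem cells:

* **assortativity** — Newman's attribute assortativity coefficient, the
  Pearson correlation of the phenotype across linked pairs (1 = perfect
  homophily, 0 = none, −1 = perfect heterophily);
* **homophily ratio** — fraction of edges joining same-phenotype cells;
* **stem connected components** — number of connected "paths" in the
  subgraph induced on stem cells;
* **stem mean degree** — mean number of stem neighbors per stem cell in
  that subgraph (isolated stem cells count with degree 0).

Statistics are computed directly from edge arrays so the permutation null
can evaluate them tens of thousands of times cheaply; conversion to
:mod:`networkx` is provided for export and cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay
from scipy.spatial._qhull import QhullError

from .core_io import CellTable
from .tessellation import Tessellation

__all__ = [
    "CellGraph",
    "HomophilyStats",
    "build_graph",
    "assortativity",
    "homophily_ratio",
    "stem_subgraph_stats",
    "compute_stats",
]


@dataclass(frozen=True)
class CellGraph:
    """Simple labeled neighbor graph.

    ``edges`` holds 0-based positional indices into ``cell_ids`` /
    ``positions`` / ``stem``; ``stem`` is a boolean phenotype mask.
    """

    cell_ids: np.ndarray  # (n,) ints
    positions: np.ndarray  # (n, 2) floats, (x, y)
    stem: np.ndarray  # (n,) bool
    edges: np.ndarray  # (m, 2) ints, each row sorted, unique

    def __post_init__(self) -> None:
        cell_ids = np.asarray(self.cell_ids, dtype=int)
        positions = np.asarray(self.positions, dtype=float)
        stem = np.asarray(self.stem, dtype=bool)
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        n = len(cell_ids)
        if positions.shape != (n, 2) or stem.shape != (n,):
            raise ValueError("inconsistent node array shapes")
        if len(edges) and (edges.min() < 0 or edges.max() >= n):
            raise ValueError("edge indices out of range")
        if len(edges):
            edges = np.sort(edges, axis=1)
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            edges = np.unique(edges, axis=0)
        object.__setattr__(self, "cell_ids", cell_ids)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "stem", stem)
        object.__setattr__(self, "edges", edges)

    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_stem(self) -> int:
        return int(self.stem.sum())

    def with_stem(self, stem: np.ndarray) -> "CellGraph":
        return replace(self, stem=np.asarray(stem, dtype=bool))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, cid in enumerate(self.cell_ids):
            g.add_node(
                int(cid),
                phenotype="stem" if self.stem[i] else "differentiated",
                pos=tuple(self.positions[i]),
            )
        g.add_edges_from(
            (int(self.cell_ids[a]), int(self.cell_ids[b])) for a, b in self.edges
        )
        return g


@dataclass(frozen=True)
class HomophilyStats:
    """The four homophily statistics of a labeled cell graph."""

    assortativity: float | None
    homophily_ratio: float | None
    stem_components: int
    stem_mean_degree: float
    n_stem: int
    n_total: int

    def to_dict(self) -> dict:
        return {
            "assortativity": self.assortativity,
            "homophily_ratio": self.homophily_ratio,
            "stem_components": self.stem_components,
            "stem_mean_degree": self.stem_mean_degree,
            "n_stem": self.n_stem,
            "n_total": self.n_total,
        }


def build_graph(
    table: CellTable,
    tess: Tessellation | None = None,
    prune_factor: float | None = None,
) -> CellGraph:
    """Delaunay neighbor graph over classified cell centroids.

    Artificial boundary sites are never nodes — only real cells enter the
    triangulation. ``prune_factor``, if given, removes edges longer than
    that multiple of the median edge length (convex-hull edges can join
    cells that are not true neighbors); pruning is off by default.
    """
    if len(table) < 3:
        raise ValueError("graph requires >= 3 cells")
    unassigned = (table.df["phenotype"] == "unassigned").sum()
    if unassigned:
        raise ValueError(f"{unassigned} cells are unclassified; classify first")
    pts = table.centroids
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate centroid configuration: {exc}") from exc
    simplices = tri.simplices
    pairs = np.vstack(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
    )
    pairs.sort(axis=1)
    edges = np.unique(pairs, axis=0)
    if prune_factor is not None:
        lengths = np.hypot(*(pts[edges[:, 0]] - pts[edges[:, 1]]).T)
        edges = edges[lengths <= prune_factor * np.median(lengths)]
    return CellGraph(
        cell_ids=table.df["cell_id"].to_numpy(dtype=int),
        positions=pts,
        stem=(table.df["phenotype"] == "stem").to_numpy(),
        edges=edges,
    )


def assortativity(graph: CellGraph) -> float | None:
    """Newman attribute assortativity of the phenotype over edges.

    From the symmetric 2×2 edge mixing matrix e:
    ``r = (Σ_i e_ii − Σ_i a_i²) / (1 − Σ_i a_i²)`` with marginals
    ``a_i = Σ_j e_ij``. Returns ``None`` (undefined) when the graph has no
    edges or all nodes share one phenotype.
    """
    if graph.n_edges == 0:
        warnings.warn("assortativity undefined for an edgeless graph", stacklevel=2)
        return None
    s = graph.stem
    a, b = graph.edges[:, 0], graph.edges[:, 1]
    m = graph.n_edges
    e_ss = float(np.sum(s[a] & s[b])) / m
    e_dd = float(np.sum(~s[a] & ~s[b])) / m
    e_sd = 1.0 - e_ss - e_dd  # total cross-type edge fraction
    a_s = e_ss + e_sd / 2.0
    a_d = e_dd + e_sd / 2.0
    denom = 1.0 - (a_s**2 + a_d**2)
    if denom == 0.0:
        return None  # single phenotype across all edge endpoints
    return ((e_ss + e_dd) - (a_s**2 + a_d**2)) / denom


def homophily_ratio(graph: CellGraph) -> float | None:
    """Fraction of edges joining same-phenotype cells; ``None`` if edgeless."""
    if graph.n_edges == 0:
        warnings.warn("homophily ratio undefined for an edgeless graph", stacklevel=2)
        return None
    s = graph.stem
    same = s[graph.edges[:, 0]] == s[graph.edges[:, 1]]
    return float(same.sum()) / graph.n_edges


def stem_subgraph_stats(graph: CellGraph) -> tuple[int, float, np.ndarray]:
    """Connected components, mean degree and degree histogram of the stem
    subgraph (differentiated nodes and their edges removed).

    Isolated stem nodes are their own components and count with degree 0 in
    the mean. Returns ``(0, 0.0, empty histogram)`` when there are no stem
    cells.
    """
    stem_idx = np.flatnonzero(graph.stem)
    k = len(stem_idx)
    if k == 0:
        warnings.warn("no stem cells; stem subgraph is empty", stacklevel=2)
        return 0, 0.0, np.zeros(0, dtype=int)
    remap = -np.ones(graph.n_nodes, dtype=int)
    remap[stem_idx] = np.arange(k)
    e = graph.edges
    keep = graph.stem[e[:, 0]] & graph.stem[e[:, 1]]
    se = remap[e[keep]]
    degrees = np.bincount(se.ravel(), minlength=k) if len(se) else np.zeros(k, int)
    if len(se):
        adj = coo_matrix((np.ones(len(se)), (se[:, 0], se[:, 1])), shape=(k, k))
        n_comp, _ = connected_components(adj, directed=False)
    else:
        n_comp = k
    hist = np.bincount(degrees)
    return int(n_comp), float(degrees.mean()), hist


def compute_stats(graph: CellGraph) -> HomophilyStats:
    """All four homophily statistics of a labeled graph."""
    comps, mean_deg, _ = stem_subgraph_stats(graph)
    return HomophilyStats(
        assortativity=assortativity(graph),
        homophily_ratio=homophily_ratio(graph),
        stem_components=comps,
        stem_mean_degree=mean_deg,
        n_stem=graph.n_stem,
        n_total=graph.n_nodes,
    )
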