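"""Electrode neighbourhood graphs for spatiotemporal clustering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from scipy.spatial.distance import pdist, squareform


@dataclass
class AdjacencyGraph:
    """Symmetric electrode-neighbour relation without self-loops."""

    graph: nx.Graph
    metadata: dict = field(default_factory=dict)

    @property
    def electrodes(self) -> list[str]:
        return list(self.graph.nodes)

    def neighbors(self, label: str) -> set[str]:
        return set(self.graph.neighbors(label))

    def neighbor_index_lists(self, electrode_order: list[str]) -> list[np.ndarray]:
        """Neighbour indices per electrode in the given grid order."""
        pos = {e: i for i, e in enumerate(electrode_order)}
        missing = [e for e in electrode_order if e not in self.graph]
        if missing:
            raise KeyError(f"adjacency graph lacks electrodes: {missing}")
        return [
            np.array(sorted(pos[n] for n in self.graph.neighbors(e) if n in pos), dtype=int)
            for e in electrode_order
        ]

    @property
    def mean_degree(self) -> float:
        degs = [d for _, d in self.graph.degree]
        return float(np.mean(degs)) if degs else 0.0


def build_adjacency(
    positions: pd.DataFrame,
    method: str = "distance",
    distance_threshold: float | None = None,
) -> AdjacencyGraph:
    """Build an electrode neighbourhood graph from sensor coordinates.

    Parameters
    ----------
    positions
        One row per electrode with a ``label`` column and coordinate
        columns ``x, y`` (and optionally ``z``).
    method
        ``"distance"`` connects pairs closer than ``distance_threshold``;
        ``"triangulation"`` connects the edges of the planar (x, y)
        Delaunay triangulation.
    """
    labels = positions["label"].astype(str).tolist()
    coord_cols = [c for c in ("x", "y", "z") if c in positions.columns]
    coords = positions[coord_cols].to_numpy(dtype=float)
    if len(labels) < 2:
        raise ValueError("need at least 2 electrodes")
    if not np.all(np.isfinite(coords)):
        raise ValueError("electrode coordinates must be finite")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate electrode labels")
    d = squareform(pdist(coords))
    if np.any(d[np.triu_indices(len(labels), 1)] == 0):
        raise ValueError("duplicate electrode coordinates")

    g = nx.Graph()
    g.add_nodes_from(labels)
    if method == "distance":
        if distance_threshold is None or distance_threshold <= 0:
            raise ValueError("distance method requires a positive distance_threshold")
        ii, jj = np.nonzero(np.triu(d < distance_threshold, k=1))
        g.add_edges_from((labels[i], labels[j]) for i, j in zip(ii, jj))
    elif method == "triangulation":
        tri = Delaunay(coords[:, :2])
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    g.add_edge(labels[simplex[a]], labels[simplex[b]])
    else:
        raise ValueError(f"unknown adjacency method {method!r}")

    isolated = [n for n, deg in g.degree if deg == 0]
    if isolated:
        warnings.warn(f"isolated electrodes in adjacency graph: {isolated}", stacklevel=2)
    meta = {
        "method": method,
        "distance_threshold": distance_threshold,
        "mean_degree": float(np.mean([deg for _, deg in g.degree])),
    }
    return AdjacencyGraph(graph=g, metadata=meta)


def suggest_distance_threshold(positions: pd.DataFrame, factor: float = 1.5) -> float:
    """``factor`` × the median nearest-neighbour distance of the layout.

    A practical default for the distance method: 1.5 × the typical sensor
    spacing connects each electrode to its immediate ring of neighbours
    without shortcutting across the cap.
    """
    coord_cols = [c for c in ("x", "y", "z") if c in positions.columns]
    coords = positions[coord_cols].to_numpy(dtype=float)
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    return factor * float(np.median(d.min(axis=1)))


def adjacency_from_edges(edges, electrodes=None) -> AdjacencyGraph:
    """Build the graph from explicit (label, label) pairs."""
    g = nx.Graph()
    if electrodes is not None:
        g.add_nodes_from(str(e) for e in electrodes)
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop on electrode {a!r}")
        g.add_edge(str(a), str(b))
    return AdjacencyGraph(graph=g, metadata={"method": "edge_list"})


def read_edge_list(path) -> AdjacencyGraph:
    """Read a two-labels-per-line edge list text file."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two labels, got {line!r}")
            edges.append(tuple(parts))
    return adjacency_from_edges(edges)


def write_edge_list(adj: AdjacencyGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in adj.graph.edges):
            fh.write(f"{a} {b}\n")


def read_layout(path) -> pd.DataFrame:
    """Read a ``label x y [z]`` whitespace-delimited sensor layout file."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{lineno}: expected 'label x y [z]'")
            rows.append([parts[0]] + [float(v) for v in parts[1:]])
    cols = ["label", "x", "y", "z"][: len(rows[0])]
    return pd.DataFrame(rows, columns=cols)


def write_layout(layout: pd.DataFrame, path) -> None:
    cols = [c for c in ("label", "x", "y", "z") if c in layout.columns]
    with open(path, "w", encoding="utf-8") as fh:
        for _, row in layout[cols].iterrows():
            fh.write(" ".join(str(row[c]) for c in cols) + "\n")
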