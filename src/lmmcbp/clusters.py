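"""Spatiotemporal clustering of supra-threshold t-values.

Samples with |t| above the threshold are grouped into connected sets:
two samples connect iff they share a time point and their electrodes are
neighbours, or they share an electrode and are adjacent in time.  No
diagonal (electrode AND time simultaneously) links.  Positive and
negative samples never mix; singletons (below the minimum cluster size)
are discarded.  The cluster statistic is the signed sum of member
t-values (the cluster mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adjacency import AdjacencyGraph
from .fit import DEFAULT_T_THRESHOLD


@dataclass
class Cluster:
    """One connected supra-threshold set on the electrode × time grid."""

    members: frozenset  # of (electrode_index, time_index)
    sign: int           # +1 or -1
    mass: float         # sum of member t-values, sign-consistent

    @property
    def size(self) -> int:
        return len(self.members)

    def electrode_set(self) -> set[int]:
        return {e for e, _ in self.members}

    def time_span(self) -> tuple[int, int]:
        ts = [t for _, t in self.members]
        return min(ts), max(ts)

    def overlap_fraction(self, support: np.ndarray) -> float:
        """Fraction of a boolean support mask covered by this cluster."""
        total = int(support.sum())
        if total == 0:
            return 0.0
        hit = sum(1 for (e, t) in self.members if support[e, t])
        return hit / total


def _label_components(mask: np.ndarray, neighbor_lists) -> list[set]:
    """Connected components of the masked grid under the spatiotemporal
    relation, via iterative depth-first search."""
    n_el, n_ti = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for e0 in range(n_el):
        for t0 in range(n_ti):
            if not mask[e0, t0] or seen[e0, t0]:
                continue
            comp = set()
            stack = [(e0, t0)]
            seen[e0, t0] = True
            while stack:
                e, t = stack.pop()
                comp.add((e, t))
                for t2 in (t - 1, t + 1):  # same electrode, adjacent time
                    if 0 <= t2 < n_ti and mask[e, t2] and not seen[e, t2]:
                        seen[e, t2] = True
                        stack.append((e, t2))
                for e2 in neighbor_lists[e]:  # same time, adjacent electrode
                    if mask[e2, t] and not seen[e2, t]:
                        seen[e2, t] = True
                        stack.append((e2, t))
            comps.append(comp)
    return comps


def find_clusters(
    t_map: np.ndarray,
    adjacency: AdjacencyGraph,
    electrode_order: list[str],
    t_th: float = DEFAULT_T_THRESHOLD,
    min_cluster_size: int = 2,
) -> list[Cluster]:
    """Threshold an electrode × time t-map and extract signed clusters.

    Returns clusters sorted by decreasing |mass|; ties broken by earliest
    (electrode, time) member for determinism.
    """
    t_map = np.asarray(t_map, dtype=float)
    if not np.all(np.isfinite(t_map)):
        bad = np.argwhere(~np.isfinite(t_map))
        raise ValueError(f"non-finite t-values at samples {bad[:10].tolist()}")
    neighbor_lists = adjacency.neighbor_index_lists(electrode_order)
    out: list[Cluster] = []
    for sign in (+1, -1):
        mask = (sign * t_map) > t_th
        for comp in _label_components(mask, neighbor_lists):
            if len(comp) < min_cluster_size:
                continue
            mass = float(sum(t_map[e, t] for e, t in comp))
            out.append(Cluster(members=frozenset(comp), sign=sign, mass=mass))
    out.sort(key=lambda c: (-abs(c.mass), min(c.members)))
    return out


def max_cluster_mass(clusters: list[Cluster]) -> tuple[float, float, float]:
    """(max positive mass, min negative mass, max |mass|); zeros if empty."""
    pos = max((c.mass for c in clusters if c.sign > 0), default=0.0)
    neg = min((c.mass for c in clusters if c.sign < 0), default=0.0)
    return pos, neg, max(pos, -neg)
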