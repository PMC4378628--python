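"""Subfamily co-expression networks.

Edges connect subfamily profiles whose Pearson correlation over the shared
condition axis meets r >= 0.7 with a two-sided p < 0.01 from the exact
t transform t = r sqrt(n-2) / sqrt(1 - r^2) on n - 2 degrees of freedom.
The threshold applies to signed r (positive co-expression) by default; an
absolute-value mode is available.  No multiple-testing correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .expression import SubfamilyProfile


@dataclass(frozen=True)
class CoexpressionEdge:
    subfamily_a: str
    subfamily_b: str
    r: float
    p: float

    def __post_init__(self) -> None:
        if self.subfamily_a > self.subfamily_b:
            a, b = self.subfamily_b, self.subfamily_a
            object.__setattr__(self, "subfamily_a", a)
            object.__setattr__(self, "subfamily_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.subfamily_a, self.subfamily_b)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the exact t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("vectors must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # snap float noise on perfectly collinear input
        r = math.copysign(1.0, r)
        return r, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


@dataclass
class Network:
    nodes: list[str]
    edges: list[CoexpressionEdge]
    components: list[list[str]]
    r_min: float
    p_max: float
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node]) if node in self.graph else 0


def build_network(
    profiles: Sequence[SubfamilyProfile],
    r_min: float = 0.7,
    p_max: float = 0.01,
    use_abs: bool = False,
) -> Network:
    """Thresholded Pearson co-expression network over included profiles.

    An edge exists iff r >= ``r_min`` (or |r| >= r_min with ``use_abs``) and
    p < ``p_max``.  Components partition all nodes, isolated included
    subfamilies forming singletons.  Output ordering is canonical.
    """
    included = sorted((p for p in profiles if p.included), key=lambda p: p.subfamily)
    if len(included) < 2:
        raise ValueError("need at least 2 included profiles")
    axis = included[0].conditions
    for p in included:
        if p.conditions != axis:
            raise ValueError(f"profile {p.subfamily} has a mismatched condition axis")
    graph = nx.Graph()
    graph.add_nodes_from(p.subfamily for p in included)
    edges = []
    for i, pa in enumerate(included):
        for pb in included[i + 1:]:
            r, p = pearson_with_p(pa.values, pb.values)
            stat = abs(r) if use_abs else r
            if stat >= r_min and p < p_max:
                edge = CoexpressionEdge(pa.subfamily, pb.subfamily, r, p)
                edges.append(edge)
                graph.add_edge(edge.subfamily_a, edge.subfamily_b, r=r, p=p)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda comp: (-len(comp), comp),
    )
    return Network(
        nodes=[p.subfamily for p in included],
        edges=sorted(edges, key=lambda e: e.pair),
        components=components,
        r_min=r_min,
        p_max=p_max,
        graph=graph,
    )


def find_hubs(net: Network, min_degree: int) -> list[str]:
    """Nodes with degree >= ``min_degree``, by descending degree then name."""
    hubs = [n for n in net.nodes if net.degree(n) >= min_degree]
    hubs.sort(key=lambda n: (-net.degree(n), n))
    return hubs


def network_intersection(a: Network, b: Network) -> list[tuple[str, str]]:
    """Canonical edge pairs present in both networks, sorted."""
    shared = {e.pair for e in a.edges} & {e.pair for e in b.edges}
    return sorted(shared)


def write_edges_tsv(net: Network, path: str | Path) -> None:
    lines = ["source\ttarget\tr\tp"]
    for e in net.edges:
        lines.append(f"{e.subfamily_a}\t{e.subfamily_b}\t{e.r:.4f}\t{e.p:.3e}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_components_tsv(net: Network, path: str | Path) -> None:
    lines = ["component_id\tsize\tmembers"]
    for cid, comp in enumerate(net.components, 1):
        lines.append(f"{cid}\t{len(comp)}\t" + ",".join(comp))
    Path(path).write_text("\n".join(lines) + "\n")


def write_hubs_tsv(net: Network, min_degree: int, path: str | Path) -> None:
    lines = ["subfamily\tdegree"]
    for hub in find_hubs(net, min_degree):
        lines.append(f"{hub}\t{net.degree(hub)}")
    Path(path).write_text("\n".join(lines) + "\n")
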