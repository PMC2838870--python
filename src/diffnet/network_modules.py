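"""Thresholded networks and (m, epsilon) gene modules.

An edge joins genes *i* and *k* when the magnitude of their connectivity
score is at least ``epsilon`` (the boundary counts as connected).  A module
is a maximal set of at least ``m`` genes in which every pair is joined by a
path of such edges — exactly a connected component of the thresholded graph
with at least ``m`` vertices.  Maximality is automatic for connected
components, and modules are necessarily disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .scores import ScoreMatrix

__all__ = [
    "ThresholdGraph",
    "ModuleSet",
    "build_threshold_graph",
    "find_modules",
    "module_labels",
    "write_sif",
    "write_graphml",
    "plot_network",
]


@dataclass
class ThresholdGraph:
    """An undirected graph over genes with edges where ``|score| >= epsilon``."""

    gene_ids: list[str]
    adjacency: np.ndarray  # boolean p x p, symmetric, zero diagonal
    epsilon: float

    @property
    def edges(self) -> set[frozenset]:
        ii, kk = np.nonzero(np.triu(self.adjacency, k=1))
        return {frozenset((self.gene_ids[i], self.gene_ids[k])) for i, k in zip(ii, kk)}

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, k=1).sum())


@dataclass
class ModuleSet:
    """Disjoint gene modules found in one network under parameters (m, epsilon)."""

    modules: list[frozenset]
    gene_ids: list[str]
    m: int
    epsilon: float
    network_label: str = ""
    _membership: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._membership = {}
        for mod in self.modules:
            for g in mod:
                if g in self._membership:
                    raise ValueError(f"gene {g} belongs to more than one module")
                self._membership[g] = mod

    def __len__(self) -> int:
        return len(self.modules)

    def module_of(self, gene: str):
        """The unique module containing *gene*, or ``None`` if it is in none."""
        if gene not in self.gene_ids:
            raise KeyError(f"unknown gene id: {gene}")
        return self._membership.get(gene)

    @property
    def covered_genes(self) -> frozenset:
        return frozenset(self._membership)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, idx)
            for idx, mod in enumerate(self.modules)
            for g in sorted(mod, key=self.gene_ids.index)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "module_index"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_threshold_graph(s: ScoreMatrix, epsilon: float) -> ThresholdGraph:
    """Connect gene pairs whose score magnitude is at least *epsilon*."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    adj = np.abs(s.values) >= epsilon
    np.fill_diagonal(adj, False)
    adj &= adj.T  # scores are symmetric; enforce exactly
    return ThresholdGraph(list(s.gene_ids), adj, float(epsilon))


def module_labels(s_values: np.ndarray, m: int, epsilon: float) -> np.ndarray:
    """Component label per gene, with -1 for genes in no module.

    Array-level core of :func:`find_modules`, reused by the permutation
    loops.  Labels are renumbered by smallest contained gene index.
    """
    adj = np.abs(s_values) >= epsilon
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    counts = np.bincount(labels, minlength=n_comp)
    out = np.full(labels.shape, -1, dtype=int)
    next_id = 0
    seen: dict[int, int] = {}
    for j, lab in enumerate(labels):
        if counts[lab] < m:
            continue
        if lab not in seen:
            seen[lab] = next_id
            next_id += 1
        out[j] = seen[lab]
    return out


def find_modules(
    s: ScoreMatrix, m: int, epsilon: float, network_label: str = ""
) -> ModuleSet:
    """All modules of size >= *m* in the epsilon-thresholded network.

    Modules are the connected components of :func:`build_threshold_graph`
    with at least *m* vertices; genes in smaller components (including
    isolated genes) belong to no module.  Output is ordered by smallest
    contained gene index for deterministic serialization.
    """
    if m < 1:
        raise ValueError(f"minimum module size m must be >= 1, got {m}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    labels = module_labels(s.values, m, epsilon)
    modules = [
        frozenset(s.gene_ids[j] for j in np.flatnonzero(labels == lab))
        for lab in range(labels.max() + 1)
    ]
    return ModuleSet(modules, list(s.gene_ids), int(m), float(epsilon), network_label)


def write_sif(s: ScoreMatrix, epsilon: float, path) -> None:
    """Export edges as SIF lines ``gene <tab> assoc <tab> gene``."""
    graph = build_threshold_graph(s, epsilon)
    ii, kk = np.nonzero(np.triu(graph.adjacency, k=1))
    with open(path, "w") as fh:
        for i, k in zip(ii, kk):
            fh.write(f"{graph.gene_ids[i]}\tassoc\t{graph.gene_ids[k]}\n")


def write_graphml(s: ScoreMatrix, epsilon: float, path) -> None:
    """Export the thresholded network as GraphML with the score as edge attribute."""
    import networkx as nx

    graph = build_threshold_graph(s, epsilon)
    g = nx.Graph()
    g.add_nodes_from(graph.gene_ids)
    ii, kk = np.nonzero(np.triu(graph.adjacency, k=1))
    for i, k in zip(ii, kk):
        g.add_edge(graph.gene_ids[i], graph.gene_ids[k], score=float(s.values[i, k]))
    nx.write_graphml(g, path)


def plot_network(s: ScoreMatrix, epsilon: float, ax=None, seed: int = 0):
    """Draw the thresholded network with a spring layout (matplotlib axes)."""
    import matplotlib.pyplot as plt
    import networkx as nx

    graph = build_threshold_graph(s, epsilon)
    g = nx.Graph()
    g.add_nodes_from(graph.gene_ids)
    ii, kk = np.nonzero(np.triu(graph.adjacency, k=1))
    g.add_edges_from((graph.gene_ids[i], graph.gene_ids[k]) for i, k in zip(ii, kk))
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(g, seed=seed)
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=120, font_size=6)
    ax.set_axis_off()
    return ax
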