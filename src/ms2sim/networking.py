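"""Molecular network construction from a predicted-similarity matrix.

Spectra become nodes; an edge is a high predicted chemical similarity.  The
linking rule is *mutual top-k*: a candidate edge (i, j) must score at least
``min_score`` (0.85 by default) and each node must rank the other within its
``top_n`` (20) most similar partners; each node then nominates its
``max_links`` (10) best mutual candidates, and the final edge set is the
union of nominations — so a popular node can exceed ``max_links`` edges.
Because predictions cross ionization modes, positive- and negative-mode
spectra land in one unified network.  Networks are exported as GraphML
(Cytoscape-loadable); embeddings can additionally be projected to 2-D with
UMAP for threshold-free visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = ["NetworkConfig", "MolecularNetwork", "build_network", "write_graphml",
           "read_graphml", "project_embeddings_2d"]


@dataclass(frozen=True)
class NetworkConfig:
    min_score: float = 0.85
    top_n: int = 20
    max_links: int = 10
    link_method: str = "mutual"

    def __post_init__(self) -> None:
        if not 0 < self.min_score <= 1:
            raise ValueError("min_score must be in (0, 1]")
        if self.max_links > self.top_n:
            raise ValueError("max_links must not exceed top_n")
        if self.link_method != "mutual":
            raise ValueError("only the 'mutual' link method is supported")

    def to_dict(self) -> dict:
        return {
            "min_score": self.min_score,
            "top_n": self.top_n,
            "max_links": self.max_links,
            "link_method": self.link_method,
        }


@dataclass
class MolecularNetwork:
    """Undirected spectral similarity graph: node metadata + scored edges."""

    nodes: list[dict]
    edges: list[tuple[int, int, float]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges}


def _ranked_partners(scores_row: np.ndarray, self_index: int) -> np.ndarray:
    """Partner indices ordered by (score desc, index asc), self excluded."""
    n = scores_row.size
    order = sorted(
        (j for j in range(n) if j != self_index),
        key=lambda j: (-scores_row[j], j),
    )
    return np.array(order, dtype=int)


def build_network(
    sim: np.ndarray, nodes: Sequence[dict], cfg: NetworkConfig = NetworkConfig()
) -> MolecularNetwork:
    """Apply the mutual top-k linking rule to a symmetric similarity matrix.

    ``nodes`` carries one metadata dict per spectrum (``spectrum_id``,
    ``ionmode``, ``precursor_mz``, optional ``annotation``).
    """
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if sim.shape != (n, n) or (n and not np.allclose(sim, sim.T, atol=1e-9)):
        raise ValueError("similarity matrix must be square and symmetric")
    if len(nodes) != n:
        raise ValueError("one metadata dict per matrix row is required")
    top_sets: list[set[int]] = []
    ranked: list[np.ndarray] = []
    for i in range(n):
        order = _ranked_partners(sim[i], i)
        ranked.append(order)
        top_sets.append(set(order[: cfg.top_n].tolist()))
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        nominations = 0
        for j in ranked[i]:
            if nominations >= cfg.max_links:
                break
            if sim[i, j] < cfg.min_score:
                break  # ranked by score: nothing further can pass the cut-off
            if j in top_sets[i] and i in top_sets[j]:
                edges.add((min(i, int(j)), max(i, int(j))))
                nominations += 1
    edge_list = sorted(edges)
    return MolecularNetwork(
        nodes=list(nodes),
        edges=[(i, j, float(sim[i, j])) for i, j in edge_list],
    )


def write_graphml(net: MolecularNetwork, path: str | Path) -> None:
    """Serialize the network as GraphML; edge scores rounded to 4 decimals."""
    graph = nx.Graph()
    for idx, meta in enumerate(net.nodes):
        attrs = {"spectrum_id": str(meta.get("spectrum_id", idx))}
        if meta.get("ionmode") is not None:
            attrs["ionmode"] = str(meta["ionmode"])
        if meta.get("precursor_mz") is not None:
            attrs["precursor_mz"] = float(meta["precursor_mz"])
        if meta.get("annotation") is not None:
            attrs["annotation"] = str(meta["annotation"])
        graph.add_node(idx, **attrs)
    for i, j, score in net.edges:
        graph.add_edge(i, j, score=round(score, 4))
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> MolecularNetwork:
    """Load a network written by :func:`write_graphml`."""
    graph = nx.read_graphml(str(path))
    relabel = {node: int(node) for node in graph.nodes}
    nodes = [dict(graph.nodes[str(i)]) for i in sorted(relabel.values())]
    edges = sorted(
        (min(relabel[u], relabel[v]), max(relabel[u], relabel[v]),
         float(data["score"]))
        for u, v, data in graph.edges(data=True)
    )
    return MolecularNetwork(nodes=nodes, edges=edges)


def project_embeddings_2d(
    embeddings: np.ndarray, n_neighbors: int = 50, seed: int = 0
) -> np.ndarray:
    """UMAP projection of spectral embeddings to 2-D for chemical-space maps."""
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} embeddings, "
            f"got {embeddings.shape[0]}"
        )
    import umap

    reducer = umap.UMAP(n_neighbors=n_neighbors, n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(embeddings), dtype=float)
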