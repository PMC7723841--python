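"""Molecular network construction and export.

Nodes are consensus spectra; edges carry the modified-cosine score, the
matched-ion count and the signed precursor mass difference. Edges are
kept when cosine ≥ threshold and at least ``min_matched`` fragment ions
align; optional top-K and maximum-component pruning mirror the usual
networking defaults and can be disabled (None). Export goes to GraphML
(Cytoscape-compatible) and node/edge TSV tables with fixed numeric
precision (m/z 4 d.p., cosine 2 d.p., delta mass 3 d.p.).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .consensus import ConsensusSpectrum
from .similarity import SimilarityParams, modified_cosine


@dataclass(frozen=True)
class NetworkEdge:
    node_a: int
    node_b: int
    cosine: float
    n_matched: int
    delta_mass: float  # precursor_a − precursor_b, signed


@dataclass(frozen=True)
class NetworkParams:
    edge_threshold: float = 0.7
    min_matched: int = 6
    top_k: Optional[int] = 10  # None disables
    max_component_size: Optional[int] = 100  # None disables
    similarity: SimilarityParams = SimilarityParams()


@dataclass
class MolecularNetwork:
    """Nodes plus scored edges; downstream stages attach node attributes."""

    nodes: list[ConsensusSpectrum]
    edges: list[NetworkEdge]
    annotations: dict[int, str] = field(default_factory=dict)
    class_flags: dict[int, frozenset[str]] = field(default_factory=dict)
    hypothesis_labels: dict[int, str] = field(default_factory=dict)

    def node(self, node_id: int) -> ConsensusSpectrum:
        return self._index()[node_id]

    def _index(self) -> dict[int, ConsensusSpectrum]:
        return {n.node_id: n for n in self.nodes}

    def neighbors(self, node_id: int) -> list[NetworkEdge]:
        return [e for e in self.edges if node_id in (e.node_a, e.node_b)]

    def subset(self, keep: set[int]) -> "MolecularNetwork":
        return MolecularNetwork(
            nodes=[n for n in self.nodes if n.node_id in keep],
            edges=[e for e in self.edges if e.node_a in keep and e.node_b in keep],
            annotations={k: v for k, v in self.annotations.items() if k in keep},
            class_flags={k: v for k, v in self.class_flags.items() if k in keep},
            hypothesis_labels={
                k: v for k, v in self.hypothesis_labels.items() if k in keep
            },
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(
                n.node_id,
                precursor_mz=round(n.precursor_mz, 4),
                rt=round(n.rt, 2),
                precursor_intensity=n.precursor_intensity,
                precursor_charge=n.precursor_charge,
                groups=",".join(sorted(n.groups)),
                n_members=n.n_members,
                annotation=self.annotations.get(n.node_id, ""),
                class_flags=",".join(sorted(self.class_flags.get(n.node_id, ()))),
                hypothesis=self.hypothesis_labels.get(n.node_id, ""),
            )
        for e in self.edges:
            g.add_edge(
                e.node_a,
                e.node_b,
                cosine=round(e.cosine, 2),
                n_matched=e.n_matched,
                delta_mass=round(e.delta_mass, 3),
            )
        return g


def build_network(
    nodes: Sequence[ConsensusSpectrum], params: NetworkParams = NetworkParams()
) -> MolecularNetwork:
    """All-pairs modified cosine, gated and pruned.

    Pipeline: score every unordered pair; keep edges with cosine ≥
    ``edge_threshold`` and ``n_matched`` ≥ ``min_matched``; apply top-K
    pruning (both endpoints must rank each other within their K best
    neighbors); iteratively drop the weakest edge of any component larger
    than ``max_component_size``. Deterministic for a given node order.
    """
    if not nodes:
        raise ValueError("build_network requires at least one node")
    edges: list[NetworkEdge] = []
    ordered = sorted(nodes, key=lambda n: n.node_id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            res = modified_cosine(a, b, params.similarity)
            if res.score >= params.edge_threshold and res.n_matched >= params.min_matched:
                edges.append(
                    NetworkEdge(
                        node_a=a.node_id,
                        node_b=b.node_id,
                        cosine=res.score,
                        n_matched=res.n_matched,
                        delta_mass=a.precursor_mz - b.precursor_mz,
                    )
                )

    if params.top_k is not None:
        edges = _prune_top_k(edges, params.top_k)
    if params.max_component_size is not None:
        edges = _prune_components(list(ordered), edges, params.max_component_size)
    return MolecularNetwork(nodes=list(ordered), edges=edges)


def _edge_rank_key(e: NetworkEdge):
    return (-e.cosine, -e.n_matched, abs(e.delta_mass))


def _prune_top_k(edges: list[NetworkEdge], k: int) -> list[NetworkEdge]:
    by_node: dict[int, list[NetworkEdge]] = {}
    for e in edges:
        by_node.setdefault(e.node_a, []).append(e)
        by_node.setdefault(e.node_b, []).append(e)
    keep_rank: dict[tuple[int, int], bool] = {}
    for node, incident in by_node.items():
        incident.sort(key=_edge_rank_key)
        for rank, e in enumerate(incident):
            key = (e.node_a, e.node_b)
            keep_rank[key] = keep_rank.get(key, True) and rank < k
    return [e for e in edges if keep_rank[(e.node_a, e.node_b)]]


def _prune_components(
    nodes: list[ConsensusSpectrum], edges: list[NetworkEdge], max_size: int
) -> list[NetworkEdge]:
    edges = list(edges)
    while True:
        g = nx.Graph()
        g.add_nodes_from(n.node_id for n in nodes)
        for e in edges:
            g.add_edge(e.node_a, e.node_b)
        oversized = [c for c in nx.connected_components(g) if len(c) > max_size]
        if not oversized:
            return edges
        # remove the globally weakest edge inside any oversized component
        pool = [
            e
            for e in edges
            if any(e.node_a in c for c in oversized)
        ]
        worst = max(pool, key=_edge_rank_key)
        edges.remove(worst)


def connected_components(net: MolecularNetwork) -> list[set[int]]:
    """Partition of node ids into connected components (order-invariant:
    sorted by (size desc, smallest node id))."""
    g = nx.Graph()
    g.add_nodes_from(n.node_id for n in net.nodes)
    g.add_edges_from((e.node_a, e.node_b) for e in net.edges)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def component_of(net: MolecularNetwork, node_id: int) -> set[int]:
    for comp in connected_components(net):
        if node_id in comp:
            return comp
    raise KeyError(f"node {node_id} not in network")


def export_graphml(
    net: MolecularNetwork, path: str | os.PathLike, config_hash: str = ""
) -> None:
    g = net.to_networkx()
    if config_hash:
        g.graph["config_hash"] = config_hash
    nx.write_graphml(g, os.fspath(path))


def read_graphml(path: str | os.PathLike) -> nx.Graph:
    return nx.read_graphml(os.fspath(path))


def node_table(net: MolecularNetwork) -> pd.DataFrame:
    rows = [
        {
            "node_id": n.node_id,
            "precursor_mz": f"{n.precursor_mz:.4f}",
            "rt": f"{n.rt:.2f}",
            "precursor_intensity": f"{n.precursor_intensity:.4g}",
            "precursor_charge": n.precursor_charge,
            "groups": ",".join(sorted(n.groups)),
            "n_members": n.n_members,
            "annotation": net.annotations.get(n.node_id, ""),
            "class_flags": ",".join(sorted(net.class_flags.get(n.node_id, ()))),
        }
        for n in sorted(net.nodes, key=lambda n: n.node_id)
    ]
    return pd.DataFrame(rows)


def edge_table(net: MolecularNetwork) -> pd.DataFrame:
    rows = [
        {
            "node_a": e.node_a,
            "node_b": e.node_b,
            "cosine": f"{e.cosine:.2f}",
            "n_matched": e.n_matched,
            "delta_mass": f"{e.delta_mass:.3f}",
        }
        for e in sorted(net.edges, key=lambda e: (e.node_a, e.node_b))
    ]
    return pd.DataFrame(rows)


def export_tables(
    net: MolecularNetwork,
    node_tsv: str | os.PathLike,
    edge_tsv: str | os.PathLike,
    config_hash: str = "",
) -> None:
    """Write node/edge TSV twins of the GraphML (stable ordering)."""
    for df, path in ((node_table(net), node_tsv), (edge_table(net), edge_tsv)):
        with open(path, "w", newline="\n") as fh:
            if config_hash:
                fh.write(f"# config_hash={config_hash}\n")
            df.to_csv(fh, sep="\t", index=False)
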