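"""Molecular network construction and family extraction.

Consensus spectra become nodes; all pairs are scored with the modified
cosine and an edge is retained when the score and matched-peak count clear
their thresholds. Two topological filters follow, mirroring classical
molecular networking: an edge survives only if each endpoint ranks in the
other's top-K most similar neighbours, and connected components
("molecular families") larger than the family-size cap shed their
lowest-scoring edges — components recomputed after every single removal —
until no component exceeds the cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .clustering import ConsensusSpectrum
from .similarity import modified_cosine
from .spectra import MEDIA, NetworkingParams

__all__ = [
    "NetworkEdge",
    "MolecularFamily",
    "score_all_pairs",
    "mutual_topk_filter",
    "build_graph",
    "enforce_family_size_cap",
    "extract_families",
    "export_network",
]


@dataclass(frozen=True)
class NetworkEdge:
    """Retained network edge; ``node_a < node_b`` lexically."""

    node_a: str
    node_b: str
    cosine: float
    n_matched: int
    precursor_delta: float

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise ValueError("edge endpoints must satisfy node_a < node_b")

    @property
    def key(self) -> tuple[str, str]:
        return (self.node_a, self.node_b)


@dataclass(frozen=True)
class MolecularFamily:
    family_id: str
    nodes: tuple[str, ...]
    edges: tuple[NetworkEdge, ...]

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def is_singleton(self) -> bool:
        return self.size == 1


def score_all_pairs(
    consensus: Sequence[ConsensusSpectrum],
    params: NetworkingParams,
    *,
    max_precursor_delta: float | None = None,
) -> list[NetworkEdge]:
    """Score every unordered consensus pair; keep threshold-passing edges.

    An edge requires cosine >= ``min_cosine`` and matched peaks >=
    ``min_matched_peaks``. ``max_precursor_delta`` optionally caps the
    precursor difference considered (off by default: all pairs scored).
    """
    ordered = sorted(consensus, key=lambda c: c.consensus_id)
    edges = []
    for i in range(len(ordered)):
        a = ordered[i]
        for j in range(i + 1, len(ordered)):
            b = ordered[j]
            delta = b.precursor_mz - a.precursor_mz
            if max_precursor_delta is not None and abs(delta) > max_precursor_delta:
                continue
            score, n_matched = modified_cosine(a.spectrum, b.spectrum, params.fragment_tol)
            if score >= params.min_cosine and n_matched >= params.min_matched_peaks:
                edges.append(
                    NetworkEdge(a.consensus_id, b.consensus_id, float(score), int(n_matched), float(delta))
                )
    return edges


def mutual_topk_filter(edges: Sequence[NetworkEdge], k: int) -> list[NetworkEdge]:
    """Keep edge (a, b) iff b ranks in a's top-k neighbours and vice versa.

    Neighbours are ranked on the threshold-filtered edge set by descending
    cosine, ties broken by lexical neighbour id, so rank-k cutoffs are
    deterministic.
    """
    neighbours: dict[str, list[tuple[float, str]]] = {}
    for e in edges:
        neighbours.setdefault(e.node_a, []).append((e.cosine, e.node_b))
        neighbours.setdefault(e.node_b, []).append((e.cosine, e.node_a))
    topk: dict[str, set[str]] = {}
    for node, nbrs in neighbours.items():
        nbrs.sort(key=lambda t: (-t[0], t[1]))
        topk[node] = {nid for _, nid in nbrs[:k]}
    return [
        e for e in edges if e.node_b in topk[e.node_a] and e.node_a in topk[e.node_b]
    ]


def build_graph(node_ids: Iterable[str], edges: Sequence[NetworkEdge]) -> nx.Graph:
    """Assemble an undirected graph containing *all* nodes (isolates too)."""
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    for e in edges:
        g.add_edge(e.node_a, e.node_b, cosine=e.cosine, n_matched=e.n_matched,
                   precursor_delta=e.precursor_delta)
    return g


def enforce_family_size_cap(graph: nx.Graph, max_family_size: int) -> nx.Graph:
    """Shed lowest-cosine edges from oversized components until all comply.

    While any connected component exceeds ``max_family_size``, the
    lowest-cosine edge of the first oversized component (ordered by the
    component's smallest node id) is removed — ties broken by the lexical
    (node_a, node_b) edge id — and components are recomputed. Exact but
    O(E·V) in the worst case; correctness over speed at desk scale.
    """
    g = graph.copy()
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_family_size]
        if not oversized:
            return g
        comp = min(oversized, key=lambda c: min(c))
        sub_edges = [
            (data["cosine"], tuple(sorted((u, v))))
            for u, v, data in g.subgraph(comp).edges(data=True)
        ]
        _, (u, v) = min(sub_edges, key=lambda t: (t[0], t[1]))
        g.remove_edge(u, v)


def extract_families(graph: nx.Graph) -> list[MolecularFamily]:
    """Connected components of the capped graph as molecular families.

    Isolated nodes become singleton families. Families are ordered by
    descending size then smallest node id, and numbered ``MF_0000``...
    """
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    families = []
    for idx, comp in enumerate(comps):
        nodes = tuple(sorted(comp))
        edges = tuple(
            sorted(
                (
                    NetworkEdge(*sorted((u, v)), cosine=d["cosine"],
                                n_matched=d["n_matched"], precursor_delta=d["precursor_delta"])
                    for u, v, d in graph.subgraph(comp).edges(data=True)
                ),
                key=lambda e: e.key,
            )
        )
        families.append(MolecularFamily(f"MF_{idx:04d}", nodes, edges))
    return families


def export_network(
    graph: nx.Graph,
    families: Sequence[MolecularFamily],
    consensus: Sequence[ConsensusSpectrum],
    out_dir: str | Path,
    annotations: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write GraphML plus edge/family TSV twins.

    Node attributes: precursor m/z, member count, per-media proportion of
    member spectra, family id, and compound name when annotated.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {c.consensus_id: c for c in consensus}
    fam_of = {node: f.family_id for f in families for node in f.nodes}
    annotations = annotations or {}

    g = graph.copy()
    for node in g.nodes:
        c = by_id[node]
        g.nodes[node]["precursor_mz"] = round(c.precursor_mz, 5)
        g.nodes[node]["n_members"] = c.n_members
        g.nodes[node]["family_id"] = fam_of.get(node, "")
        g.nodes[node]["annotation"] = annotations.get(node, "")
        media_counts = {m: 0.0 for m in MEDIA}
        if c.media_set:
            share = 1.0 / len(c.media_set)
            for m in c.media_set:
                media_counts[m] = share
        for m in MEDIA:
            g.nodes[node][f"prop_{m}"] = media_counts[m]

    graphml_path = out_dir / "network.graphml"
    nx.write_graphml(g, graphml_path)

    edges_path = out_dir / "edges.tsv"
    pd.DataFrame(
        [
            {
                "node_a": u if u < v else v,
                "node_b": v if u < v else u,
                "cosine": round(d["cosine"], 6),
                "n_matched": d["n_matched"],
                "delta": round(d["precursor_delta"], 5),
            }
            for u, v, d in g.edges(data=True)
        ],
        columns=["node_a", "node_b", "cosine", "n_matched", "delta"],
    ).sort_values(["node_a", "node_b"]).to_csv(edges_path, sep="\t", index=False)

    families_path = out_dir / "families.tsv"
    pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "size": f.size,
                "singleton": f.is_singleton,
                "member_ids": ";".join(f.nodes),
            }
            for f in families
        ]
    ).to_csv(families_path, sep="\t", index=False)

    return {"graphml": graphml_path, "edges": edges_path, "families": families_path}
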