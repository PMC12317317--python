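"""Exhaustive 2-/3-node graphlet and node-orbit counting on a multilabel graph.

Connected node triples are enumerated adjacency-first (an edge plus any
third node adjacent to either endpoint), which is near-linear in the number
of connected triples on sparse graphs instead of cubic in ``n``.  Each
triple is encoded with the sorted-pair key and resolved through the catalog
lookup; the owning graphlet's count and each member node's orbit count are
incremented once per triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

from rpigraphlets.catalog import (
    CatalogError,
    GraphletCatalog,
    TriadMatrix,
    encode_subgraph,
    node_orbit_pair,
)
from rpigraphlets.rpi_graph import RPIGraph

__all__ = [
    "CountResults",
    "triad_matrix",
    "enumerate_connected_triples",
    "count_graphlets",
]


def triad_matrix(graph: RPIGraph, triple: tuple[str, str, str]) -> TriadMatrix:
    """Orbit matrix of the induced labeled subgraph on a node triple."""
    rows = []
    for x in triple:
        row = []
        for y in triple:
            if x == y:
                row.append(0)
            else:
                e = graph.edge_between(x, y)
                row.append(0 if e is None else e.orbit_of(x))
        rows.append(tuple(row))
    return tuple(rows)


def enumerate_connected_triples(graph: RPIGraph) -> Iterator[tuple[str, str, str]]:
    """Yield each unordered node triple with a connected induced subgraph once.

    A connected triple necessarily contains an edge (u, v) with the third
    node adjacent to u or v, so iterating edges and their neighborhoods
    covers all of them; a seen-set deduplicates triples discovered through
    multiple edges.  Triples are yielded in sorted node order.
    """
    seen: set[tuple[str, str, str]] = set()
    for e in graph.edges():
        candidates = (graph.neighbors(e.u) | graph.neighbors(e.v)) - {e.u, e.v}
        for w in candidates:
            triple = tuple(sorted((e.u, e.v, w)))
            if triple not in seen:
                seen.add(triple)
                yield triple  # type: ignore[misc]


@dataclass
class CountResults:
    """Graphlet distribution vector and per-node orbit count matrix.

    ``graphlet_counts`` covers every catalog id (zeros included) so that
    distribution vectors are alignable across graphs; ``orbit_counts`` maps
    node -> {orbit id -> count} sparsely.
    """

    graphlet_counts: dict[str, int]
    orbit_counts: dict[str, dict[int, int]]
    n_connected_triples: int
    n_edges: int

    def orbit_count(self, node: str, orbit_id: int) -> int:
        return self.orbit_counts.get(node, {}).get(orbit_id, 0)

    def to_graphlet_frame(self, catalog: GraphletCatalog) -> pd.DataFrame:
        rows = []
        for e in catalog.entries_2node + catalog.entries_3node:
            rows.append(
                {
                    "graphlet_id": e.graphlet_id,
                    "key": e.key_string,
                    "shape": e.shape,
                    "composition": e.composition,
                    "count": self.graphlet_counts[e.graphlet_id],
                }
            )
        return pd.DataFrame(rows)

    def to_orbit_frame(self, catalog: GraphletCatalog) -> pd.DataFrame:
        """Dense node x orbit matrix (rows sorted by node id)."""
        nodes = sorted(self.orbit_counts)
        frame = pd.DataFrame(
            0, index=nodes, columns=list(catalog.orbit_ids), dtype=int
        )
        for node, per_orbit in self.orbit_counts.items():
            for orbit_id, count in per_orbit.items():
                frame.at[node, orbit_id] = count
        frame.index.name = "node"
        return frame

    def write_graphlet_tsv(self, path: str | Path, catalog: GraphletCatalog) -> None:
        self.to_graphlet_frame(catalog).to_csv(path, sep="\t", index=False)

    def write_orbit_tsv(self, path: str | Path, catalog: GraphletCatalog) -> None:
        self.to_orbit_frame(catalog).to_csv(path, sep="\t")


def count_graphlets(
    graph: RPIGraph, catalog: GraphletCatalog, verify: bool = True
) -> CountResults:
    """Count every catalog graphlet occurrence and node-orbit participation.

    With ``verify=True`` (default) the conservation identities are asserted
    after counting: the 2-node total equals the edge count, the 3-node
    total equals the number of connected triples, and for every orbit the
    node-summed count equals class size x graphlet count.
    """
    counts: dict[str, int] = {gid: 0 for gid in catalog.graphlet_ids}
    orbit_counts: dict[str, dict[int, int]] = {n: {} for n in graph.nodes}

    def bump(node: str, orbit_id: int) -> None:
        per = orbit_counts[node]
        per[orbit_id] = per.get(orbit_id, 0) + 1

    for edge in graph.edges():
        entry = catalog.entry_for_edge_type(edge.etype)
        counts[entry.graphlet_id] += 1
        bump(edge.u, entry.pair_to_orbit[edge.orbit_of(edge.u)])
        bump(edge.v, entry.pair_to_orbit[edge.orbit_of(edge.v)])

    n_triples = 0
    for triple in enumerate_connected_triples(graph):
        n_triples += 1
        M = triad_matrix(graph, triple)
        entry = catalog.lookup_key(encode_subgraph(M, validate=False))
        counts[entry.graphlet_id] += 1
        for pos, node in enumerate(triple):
            bump(node, entry.pair_to_orbit[node_orbit_pair(M, pos)])

    results = CountResults(
        graphlet_counts=counts,
        orbit_counts=orbit_counts,
        n_connected_triples=n_triples,
        n_edges=graph.n_edges,
    )
    if verify:
        _verify_conservation(results, catalog)
    return results


def _verify_conservation(results: CountResults, catalog: GraphletCatalog) -> None:
    two_total = sum(
        results.graphlet_counts[e.graphlet_id] for e in catalog.entries_2node
    )
    if two_total != results.n_edges:
        raise CatalogError(
            f"2-node counts sum to {two_total}, expected {results.n_edges} edges"
        )
    three_total = sum(
        results.graphlet_counts[e.graphlet_id] for e in catalog.entries_3node
    )
    if three_total != results.n_connected_triples:
        raise CatalogError(
            f"3-node counts sum to {three_total}, expected "
            f"{results.n_connected_triples} connected triples"
        )
    totals: dict[int, int] = {}
    for per in results.orbit_counts.values():
        for orbit_id, c in per.items():
            totals[orbit_id] = totals.get(orbit_id, 0) + c
    for entry in catalog.entries_2node + catalog.entries_3node:
        for orbit_id, size in zip(entry.orbit_ids, entry.orbit_class_sizes):
            expected = size * results.graphlet_counts[entry.graphlet_id]
            if totals.get(orbit_id, 0) != expected:
                raise CatalogError(
                    f"orbit {orbit_id} sums to {totals.get(orbit_id, 0)}, "
                    f"expected {expected}"
                )
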