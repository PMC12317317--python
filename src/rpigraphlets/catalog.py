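"""Canonical catalog of 2- and 3-node graphlets over the multilabel edge alphabet.

A 3-node labeled subgraph is represented by a 3x3 *orbit matrix* ``M`` where
``M[x][y]`` is the edge orbit of node ``x`` within the pair ``(x, y)``
(0 if the pair carries no edge).  The entry pair ``(M[x][y], M[y][x])`` is
mutually consistent: 1-1 (P), 2-3 (R, 2 on the regulator end), 4-5 (PR),
6-6 (B), 7-7 (PB).

Two independent fingerprints are built from ``M``:

* :func:`canonical_form` — the minimum over all 6 node permutations of the
  serialized matrix; equal iff the subgraphs are related by an
  edge-type-preserving bijection.  This is the authoritative isomorphism
  oracle.
* :func:`encode_subgraph` — the sorted triple of sorted per-node orbit
  pairs.  Cheap to compute while counting; proven at enumeration time to be
  a perfect discriminator (bijective with canonical forms) over the whole
  catalog.

:func:`enumerate_catalog` brute-forces all 8^3 pair-state assignments,
keeps the connected ones, deduplicates by canonical form, partitions node
positions into automorphism orbits, and validates the key/canonical-form
bijection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import permutations, product
from pathlib import Path

from rpigraphlets.rpi_graph import EdgeType

__all__ = [
    "TriadMatrix",
    "GraphletKey",
    "CatalogEntry",
    "GraphletCatalog",
    "CatalogError",
    "REVERSE_ORBIT",
    "ORBIT_EDGE_TYPE",
    "canonical_form",
    "encode_subgraph",
    "enumerate_catalog",
]

TriadMatrix = tuple[tuple[int, int, int], ...]
GraphletKey = tuple[tuple[int, int], ...]

#: orbit of the opposite end of an edge, given one end's orbit
REVERSE_ORBIT: dict[int, int] = {0: 0, 1: 1, 2: 3, 3: 2, 4: 5, 5: 4, 6: 6, 7: 7}

#: edge type implied by a (nonzero) forward orbit value
ORBIT_EDGE_TYPE: dict[int, EdgeType] = {
    1: EdgeType.P,
    2: EdgeType.R,
    3: EdgeType.R,
    4: EdgeType.PR,
    5: EdgeType.PR,
    6: EdgeType.B,
    7: EdgeType.PB,
}

_PERMS_3 = tuple(permutations(range(3)))


class CatalogError(RuntimeError):
    """Internal consistency failure during catalog enumeration."""


def _check_matrix(M: TriadMatrix) -> None:
    if len(M) != 3 or any(len(row) != 3 for row in M):
        raise ValueError("orbit matrix must be 3x3")
    for i in range(3):
        if M[i][i] != 0:
            raise ValueError("diagonal must be 0 (no self-loops)")
        for j in range(i + 1, 3):
            if REVERSE_ORBIT[M[i][j]] != M[j][i]:
                raise ValueError(
                    f"inconsistent half-edges at pair ({i},{j}): {M[i][j]}/{M[j][i]}"
                )


def is_connected(M: TriadMatrix) -> bool:
    """True iff the 3-node labeled graph has no isolated node and one component."""
    deg = [sum(1 for j in range(3) if M[i][j] != 0) for i in range(3)]
    n_edges = sum(deg) // 2
    # on 3 nodes, >= 2 edges with no isolated node implies connectivity
    return n_edges >= 2 and all(d > 0 for d in deg)


def canonical_form(M: TriadMatrix, validate: bool = True) -> str:
    """Minimum serialization of ``M`` over all 6 node permutations.

    Two 3-node labeled subgraphs have equal canonical forms iff there is an
    edge-type-preserving (and orientation-preserving) bijection between
    them.
    """
    if validate:
        _check_matrix(M)
    best = min(
        (M[p[0]][p[1]], M[p[0]][p[2]], M[p[1]][p[2]]) for p in _PERMS_3
    )
    return "-".join(map(str, best))


def _canonical_matrix(M: TriadMatrix) -> TriadMatrix:
    """The permuted matrix realizing the canonical serialization."""
    best_p = min(
        _PERMS_3, key=lambda p: (M[p[0]][p[1]], M[p[0]][p[2]], M[p[1]][p[2]])
    )
    return tuple(
        tuple(M[best_p[i]][best_p[j]] for j in range(3)) for i in range(3)
    )


def node_orbit_pair(M: TriadMatrix, i: int) -> tuple[int, int]:
    """Sorted pair of edge orbits of position ``i`` toward the other two."""
    j, k = [x for x in range(3) if x != i]
    return tuple(sorted((M[i][j], M[i][k])))  # type: ignore[return-value]


def encode_subgraph(M: TriadMatrix, validate: bool = True) -> GraphletKey:
    """Sorted-pair encoding of a connected 3-node labeled subgraph.

    Each node contributes its ascending pair of edge orbits toward the other
    two nodes; the three pairs are sorted lexicographically.  Invariant
    under any relabeling of the three nodes.
    """
    if validate:
        _check_matrix(M)
        if not is_connected(M):
            raise ValueError("subgraph on the triple is not connected")
    return tuple(sorted(node_orbit_pair(M, i) for i in range(3)))


def automorphisms(M: TriadMatrix) -> list[tuple[int, ...]]:
    """All node permutations preserving every typed, oriented edge."""
    autos = []
    for p in _PERMS_3:
        if all(M[p[i]][p[j]] == M[i][j] for i in range(3) for j in range(3)):
            autos.append(p)
    return autos


def orbit_partition(M: TriadMatrix) -> list[tuple[int, ...]]:
    """Automorphism equivalence classes of the 3 node positions.

    Returned classes are disjoint, cover {0,1,2}, and are sorted by their
    smallest member.
    """
    autos = automorphisms(M)
    classes: list[tuple[int, ...]] = []
    assigned: set[int] = set()
    for i in range(3):
        if i in assigned:
            continue
        cls = sorted({p[i] for p in autos})
        classes.append(tuple(cls))
        assigned.update(cls)
    return classes


def edge_multiset(M: TriadMatrix) -> tuple[str, ...]:
    """Sorted multiset of edge-type codes present in the subgraph."""
    types = []
    for i in range(3):
        for j in range(i + 1, 3):
            if M[i][j] != 0:
                types.append(ORBIT_EDGE_TYPE[M[i][j]].value)
    return tuple(sorted(types))


def _composition(types: tuple[str, ...]) -> str:
    etypes = [EdgeType(t) for t in types]
    has_p = any(t.has_physical for t in etypes)
    has_r = any(t.has_regulatory for t in etypes)
    if has_p and has_r:
        return "mixed"
    return "physical_only" if has_p else "regulatory_only"


@dataclass(frozen=True)
class CatalogEntry:
    """One canonical graphlet with its automorphism-orbit bookkeeping.

    ``pair_to_orbit`` maps a node's sorted orbit pair (3-node entries) or
    its single edge orbit (2-node entries) to the global orbit id; for
    3-node entries this map is well defined because orbit classes coincide
    with groupings by sorted pair (validated at enumeration).
    """

    graphlet_id: str
    key: tuple
    n_nodes: int
    shape: str  # "edge" | "line" | "triangle"
    composition: str  # "mixed" | "physical_only" | "regulatory_only"
    edge_types: tuple[str, ...]
    orbit_ids: tuple[int, ...]
    orbit_class_sizes: tuple[int, ...]
    pair_to_orbit: dict
    matrix: TriadMatrix | None = None  # canonical representative (3-node only)

    @property
    def key_string(self) -> str:
        if self.n_nodes == 2:
            return f"({self.key[0]},{self.key[1]})"
        return ";".join(f"({a},{b})" for a, b in self.key)


_TWO_NODE_SPECS = (
    # (edge type, end-orbit key, orbit classes as {orbit: size})
    (EdgeType.P, (1, 1), {1: 2}),
    (EdgeType.R, (2, 3), {2: 1, 3: 1}),
    (EdgeType.PR, (4, 5), {4: 1, 5: 1}),
    (EdgeType.B, (6, 6), {6: 2}),
    (EdgeType.PB, (7, 7), {7: 2}),
)


def _build_two_node_entries() -> tuple[CatalogEntry, ...]:
    entries = []
    specs = sorted(_TWO_NODE_SPECS, key=lambda s: s[1])
    for idx, (etype, key, classes) in enumerate(specs, start=1):
        entries.append(
            CatalogEntry(
                graphlet_id=f"2-{idx:02d}",
                key=key,
                n_nodes=2,
                shape="edge",
                composition=_composition((etype.value,)),
                edge_types=(etype.value,),
                orbit_ids=tuple(classes),
                orbit_class_sizes=tuple(classes.values()),
                pair_to_orbit={o: o for o in classes},
            )
        )
    return tuple(entries)


@dataclass(frozen=True)
class GraphletCatalog:
    """Complete validated catalog with lookups used by the counter."""

    entries_2node: tuple[CatalogEntry, ...]
    entries_3node: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_by_key", {e.key: e for e in self.entries_3node}
        )
        object.__setattr__(
            self,
            "_by_etype",
            {EdgeType(e.edge_types[0]): e for e in self.entries_2node},
        )
        by_id = {e.graphlet_id: e for e in self.entries_2node + self.entries_3node}
        object.__setattr__(self, "_by_id", by_id)
        orbit_owner: dict[int, CatalogEntry] = {}
        for e in self.entries_2node + self.entries_3node:
            for o in e.orbit_ids:
                orbit_owner[o] = e
        object.__setattr__(self, "_orbit_owner", orbit_owner)

    # -- lookups -----------------------------------------------------------
    def lookup_key(self, key: GraphletKey) -> CatalogEntry:
        try:
            return self._by_key[key]
        except KeyError:
            raise CatalogError(f"no catalog entry for key {key}") from None

    def entry_for_edge_type(self, etype: EdgeType) -> CatalogEntry:
        return self._by_etype[etype]

    def entry(self, graphlet_id: str) -> CatalogEntry:
        return self._by_id[graphlet_id]

    def owner_of_orbit(self, orbit_id: int) -> CatalogEntry:
        return self._orbit_owner[orbit_id]

    @property
    def graphlet_ids(self) -> tuple[str, ...]:
        return tuple(e.graphlet_id for e in self.entries_2node + self.entries_3node)

    @property
    def orbit_ids(self) -> tuple[int, ...]:
        out: list[int] = []
        for e in self.entries_2node + self.entries_3node:
            out.extend(e.orbit_ids)
        return tuple(out)

    @property
    def n_orbits_3node(self) -> int:
        return sum(len(e.orbit_ids) for e in self.entries_3node)

    def mixed_orbit_ids(self) -> frozenset[int]:
        return frozenset(
            o
            for e in self.entries_2node + self.entries_3node
            if e.composition == "mixed"
            for o in e.orbit_ids
        )

    # -- export ------------------------------------------------------------
    def to_table_rows(self) -> list[dict]:
        rows = []
        for e in self.entries_2node + self.entries_3node:
            rows.append(
                {
                    "graphlet_id": e.graphlet_id,
                    "key": e.key_string,
                    "n_nodes": e.n_nodes,
                    "shape": e.shape,
                    "composition": e.composition,
                    "edge_types": ",".join(e.edge_types),
                    "orbit_ids": ",".join(map(str, e.orbit_ids)),
                    "orbit_class_sizes": ",".join(map(str, e.orbit_class_sizes)),
                }
            )
        return rows

    def write_tsv(self, path: str | Path) -> None:
        rows = self.to_table_rows()
        cols = list(rows[0])
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_table_rows(), fh, indent=1)
            fh.write("\n")


# the 8 mutually consistent half-edge states of one ordered pair
_PAIR_STATES = tuple(range(8))


def _all_triads():
    """All 512 assignments of pair states to the three node pairs."""
    for ab, ac, bc in product(_PAIR_STATES, repeat=3):
        M = (
            (0, ab, ac),
            (REVERSE_ORBIT[ab], 0, bc),
            (REVERSE_ORBIT[ac], REVERSE_ORBIT[bc], 0),
        )
        yield M


def enumerate_catalog() -> GraphletCatalog:
    """Brute-force the full 2-/3-node catalog and validate its invariants.

    Raises :class:`CatalogError` if the sorted-pair keys fail to be in
    bijection with canonical forms, or if an orbit class does not coincide
    with the positions sharing a sorted orbit pair.
    """
    reps: dict[str, TriadMatrix] = {}
    for M in _all_triads():
        if not is_connected(M):
            continue
        cf = canonical_form(M, validate=False)
        if cf not in reps:
            reps[cf] = _canonical_matrix(M)

    # key <-> canonical form bijection
    key_to_cf: dict[GraphletKey, str] = {}
    for cf, M in reps.items():
        key = encode_subgraph(M, validate=False)
        if key in key_to_cf and key_to_cf[key] != cf:
            raise CatalogError(
                f"two nonisomorphic graphlets share key {key}: "
                f"{key_to_cf[key]} vs {cf}"
            )
        key_to_cf[key] = cf
    if len(key_to_cf) != len(reps):
        raise CatalogError(
            f"{len(reps)} canonical forms map to {len(key_to_cf)} keys"
        )

    entries_2 = _build_two_node_entries()
    next_orbit = max(o for e in entries_2 for o in e.orbit_ids) + 1

    entries_3: list[CatalogEntry] = []
    for idx, key in enumerate(sorted(key_to_cf), start=1):
        M = reps[key_to_cf[key]]
        classes = orbit_partition(M)
        if sum(len(c) for c in classes) != 3:
            raise CatalogError(f"orbit classes do not cover the 3 positions: {classes}")
        # orbit classes must coincide with groupings by sorted orbit pair,
        # otherwise pair_to_orbit would be ill-defined
        pairs = [node_orbit_pair(M, i) for i in range(3)]
        for cls in classes:
            if len({pairs[i] for i in cls}) != 1:
                raise CatalogError(f"orbit class {cls} mixes distinct pairs in {key}")
        for a, b in ((x, y) for x in range(3) for y in range(3) if x < y):
            same_pair = pairs[a] == pairs[b]
            same_class = any(a in c and b in c for c in classes)
            if same_pair and not same_class:
                raise CatalogError(
                    f"positions {a},{b} share pair {pairs[a]} but are not "
                    f"automorphic in {key}"
                )

        classes_sorted = sorted(classes, key=lambda c: pairs[c[0]])
        orbit_ids = tuple(range(next_orbit, next_orbit + len(classes_sorted)))
        next_orbit += len(classes_sorted)
        pair_to_orbit = {
            pairs[cls[0]]: oid for cls, oid in zip(classes_sorted, orbit_ids)
        }
        types = edge_multiset(M)
        entries_3.append(
            CatalogEntry(
                graphlet_id=f"3-{idx:03d}",
                key=key,
                n_nodes=3,
                shape="line" if len(types) == 2 else "triangle",
                composition=_composition(types),
                edge_types=types,
                orbit_ids=orbit_ids,
                orbit_class_sizes=tuple(len(c) for c in classes_sorted),
                pair_to_orbit=pair_to_orbit,
                matrix=M,
            )
        )

    return GraphletCatalog(entries_2node=entries_2, entries_3node=tuple(entries_3))
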