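"""Ingest of physical/regulatory interaction records and the collapsed multilabel graph.

Raw records come in two classes: undirected physical interactions (unordered
protein pairs) and directed regulatory interactions (regulator -> target).
Taking the union of both layers gives a multigraph; we collapse it so that
each node pair carries exactly one edge drawn from a five-letter alphabet:

=====  ==============================================  ==========
code   meaning                                         end orbits
=====  ==============================================  ==========
P      physical edge only                              (1, 1)
R      single regulatory edge                          (2, 3)
PR     physical + single regulatory edge               (4, 5)
B      bidirected regulatory (mutual regulation)       (6, 6)
PB     physical + bidirected regulatory                (7, 7)
=====  ==============================================  ==========

For the oriented types R and PR the first orbit sits on the regulator end
(orbit 4 = physical edge plus outgoing regulatory edge, orbit 5 = physical
edge plus incoming regulatory edge).  Orbit 0 denotes a non-edge.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionClass",
    "InteractionRecord",
    "InteractionTable",
    "EdgeType",
    "Edge",
    "RPIGraph",
    "ParseError",
    "read_interactions",
    "build_rpi_graph",
    "generate_synthetic_network",
    "END_ORBITS",
]


class ParseError(ValueError):
    """Raised when an interaction file cannot be parsed."""


class InteractionClass(str, Enum):
    PHYSICAL = "physical"
    REGULATORY = "regulatory"


class EdgeType(str, Enum):
    """Collapsed edge-type alphabet of the multilabel graph."""

    P = "P"
    R = "R"
    PR = "PR"
    B = "B"
    PB = "PB"

    @property
    def has_physical(self) -> bool:
        return self in (EdgeType.P, EdgeType.PR, EdgeType.PB)

    @property
    def has_regulatory(self) -> bool:
        return self in (EdgeType.R, EdgeType.PR, EdgeType.B, EdgeType.PB)

    @property
    def oriented(self) -> bool:
        return self in (EdgeType.R, EdgeType.PR)

    @property
    def regulatory_multiplicity(self) -> int:
        """Number of underlying directed regulatory records in this edge."""
        if self in (EdgeType.B, EdgeType.PB):
            return 2
        if self in (EdgeType.R, EdgeType.PR):
            return 1
        return 0


#: per-type end orbits; for oriented types the first value is the regulator end
END_ORBITS: dict[EdgeType, tuple[int, int]] = {
    EdgeType.P: (1, 1),
    EdgeType.R: (2, 3),
    EdgeType.PR: (4, 5),
    EdgeType.B: (6, 6),
    EdgeType.PB: (7, 7),
}


@dataclass(frozen=True)
class InteractionRecord:
    """A single deduplicated interaction.

    Physical records are normalized so that ``a <= b``; regulatory records
    keep their orientation (``a`` regulates ``b``).
    """

    a: str
    b: str
    kind: InteractionClass


@dataclass(frozen=True)
class InteractionTable:
    """Deduplicated interaction records plus ingest tallies."""

    records: tuple[InteractionRecord, ...]
    n_duplicates: int = 0
    n_self_loops: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_physical(self) -> int:
        return sum(1 for r in self.records if r.kind is InteractionClass.PHYSICAL)

    @property
    def n_regulatory(self) -> int:
        return sum(1 for r in self.records if r.kind is InteractionClass.REGULATORY)


def normalize_records(
    raw: Iterable[tuple[str, str, InteractionClass]],
) -> InteractionTable:
    """Strip, deduplicate and drop self-loops from raw (a, b, class) triples.

    Physical pairs are unordered (``(A, B)`` and ``(B, A)`` collapse);
    regulatory pairs are ordered (opposite orientations are distinct
    records).  Self-referential records are dropped with a logged tally:
    graphlets are induced subgraphs on distinct nodes, so loops can never
    participate downstream.
    """
    seen: set[tuple[str, str, InteractionClass]] = set()
    records: list[InteractionRecord] = []
    n_dup = 0
    n_self = 0
    for a, b, kind in raw:
        a = a.strip()
        b = b.strip()
        if not a or not b:
            raise ParseError(f"empty identifier in record ({a!r}, {b!r})")
        if a == b:
            n_self += 1
            continue
        if kind is InteractionClass.PHYSICAL and b < a:
            a, b = b, a
        key = (a, b, kind)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        records.append(InteractionRecord(a, b, kind))
    if n_self:
        logger.warning("dropped %d self-referential record(s)", n_self)
    if n_dup:
        logger.info("collapsed %d duplicate record(s)", n_dup)
    return InteractionTable(tuple(records), n_duplicates=n_dup, n_self_loops=n_self)


_HEADER_TOKENS = {
    "id1", "id2", "source", "target", "node1", "node2", "protein1",
    "protein2", "regulator", "regulated", "tf", "type",
}


def _sniff_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return " "


def _iter_rows(path: Path, delimiter: str | None) -> Iterator[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        delim = delimiter
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            if delim == " ":
                fields = line.split()
            else:
                fields = next(csv.reader([line], delimiter=delim))
            yield lineno, [f.strip() for f in fields]


def _looks_like_header(fields: Sequence[str]) -> bool:
    return all(f.lower() in _HEADER_TOKENS for f in fields[:2])


def _parse_edge_file(
    path: Path,
    kind: InteractionClass | None,
    delimiter: str | None,
    header: str | bool,
) -> Iterator[tuple[str, str, InteractionClass]]:
    """Yield raw triples from one file.

    ``kind=None`` selects single-file mode: a third column with values in
    {ppi, physical, reg, regulatory} assigns the class per row.
    """
    first = True
    n_rows = 0
    for lineno, fields in _iter_rows(path, delimiter):
        if first:
            first = False
            if header is True or (header == "auto" and _looks_like_header(fields)):
                continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
        if kind is None:
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: single-file mode requires a type column")
            tok = fields[2].lower()
            if tok in ("ppi", "physical", "p"):
                row_kind = InteractionClass.PHYSICAL
            elif tok in ("reg", "regulatory", "r"):
                row_kind = InteractionClass.REGULATORY
            else:
                raise ParseError(f"{path}:{lineno}: unknown interaction type {fields[2]!r}")
        else:
            row_kind = kind
        n_rows += 1
        yield fields[0], fields[1], row_kind
    if n_rows == 0:
        raise ParseError(f"{path}: no interaction rows found")


def read_interactions(
    physical_path: str | Path | None = None,
    regulatory_path: str | Path | None = None,
    combined_path: str | Path | None = None,
    *,
    delimiter: str | None = None,
    header: str | bool = "auto",
) -> InteractionTable:
    """Read interaction edge lists into a deduplicated :class:`InteractionTable`.

    Two-file mode (``physical_path`` + ``regulatory_path``) is canonical;
    ``combined_path`` accepts a single file with a third type column
    (``ppi``/``reg``).  ``'#'`` comment lines are skipped; the delimiter is
    sniffed per file unless given.
    """
    if combined_path is not None:
        if physical_path is not None or regulatory_path is not None:
            raise ValueError("pass either combined_path or the two per-class paths")
        raw: Iterable[tuple[str, str, InteractionClass]] = _parse_edge_file(
            Path(combined_path), None, delimiter, header
        )
        return normalize_records(raw)
    if physical_path is None and regulatory_path is None:
        raise ValueError("no input paths given")

    def _chain() -> Iterator[tuple[str, str, InteractionClass]]:
        if physical_path is not None:
            yield from _parse_edge_file(
                Path(physical_path), InteractionClass.PHYSICAL, delimiter, header
            )
        if regulatory_path is not None:
            yield from _parse_edge_file(
                Path(regulatory_path), InteractionClass.REGULATORY, delimiter, header
            )

    return normalize_records(_chain())


@dataclass(frozen=True)
class Edge:
    """One collapsed multilabel edge between ``u < v``.

    ``regulator`` names the regulator endpoint for the oriented types R/PR
    and is ``None`` for the symmetric types P/B/PB.
    """

    u: str
    v: str
    etype: EdgeType
    regulator: str | None = None

    def __post_init__(self) -> None:
        if self.u >= self.v:
            raise ValueError("edge endpoints must satisfy u < v")
        if self.etype.oriented:
            if self.regulator not in (self.u, self.v):
                raise ValueError(f"oriented edge {self.etype} needs a regulator endpoint")
        elif self.regulator is not None:
            raise ValueError(f"symmetric edge {self.etype} cannot carry an orientation")

    def orbit_of(self, node: str) -> int:
        """Edge orbit (1-7) of ``node`` within this edge."""
        reg_orbit, tgt_orbit = END_ORBITS[self.etype]
        if not self.etype.oriented:
            return reg_orbit
        return reg_orbit if node == self.regulator else tgt_orbit

    @property
    def end_orbits(self) -> tuple[int, int]:
        """Orbits of (u, v) in endpoint order."""
        return self.orbit_of(self.u), self.orbit_of(self.v)

    def other(self, node: str) -> str:
        return self.v if node == self.u else self.u


class RPIGraph:
    """Multilabel graph: at most one typed edge per node pair, no self-loops."""

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[Edge] = ()) -> None:
        self._nodes: set[str] = set(nodes)
        self._edges: dict[tuple[str, str], Edge] = {}
        self._adj: dict[str, set[str]] = {n: set() for n in self._nodes}
        for e in edges:
            self.add_edge(e)

    def add_node(self, node: str) -> None:
        if node not in self._nodes:
            self._nodes.add(node)
            self._adj[node] = set()

    def add_edge(self, edge: Edge) -> None:
        key = (edge.u, edge.v)
        if key in self._edges:
            raise ValueError(f"pair {key} already carries an edge")
        self.add_node(edge.u)
        self.add_node(edge.v)
        self._edges[key] = edge
        self._adj[edge.u].add(edge.v)
        self._adj[edge.v].add(edge.u)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self) -> Iterator[Edge]:
        return iter(self._edges.values())

    def edge_between(self, a: str, b: str) -> Edge | None:
        if a > b:
            a, b = b, a
        return self._edges.get((a, b))

    def neighbors(self, node: str) -> frozenset[str]:
        return frozenset(self._adj[node])

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    def has_node(self, node: str) -> bool:
        return node in self._nodes

    def edge_type_counts(self) -> dict[EdgeType, int]:
        counts = {t: 0 for t in EdgeType}
        for e in self._edges.values():
            counts[e.etype] += 1
        return counts

    def record_counts(self) -> tuple[int, int]:
        """(physical, regulatory) record counts of the underlying multigraph.

        Re-expands edge types: physical = |P| + |PR| + |PB|; regulatory =
        |R| + |PR| + 2|B| + 2|PB|.  Used to assert the collapse is lossless.
        """
        n_phys = 0
        n_reg = 0
        for e in self._edges.values():
            n_phys += 1 if e.etype.has_physical else 0
            n_reg += e.etype.regulatory_multiplicity
        return n_phys, n_reg

    def induced_subgraph(self, nodes: Iterable[str]) -> "RPIGraph":
        keep = set(nodes)
        missing = keep - self._nodes
        if missing:
            raise KeyError(f"nodes not in graph: {sorted(missing)[:5]}")
        edges = [e for e in self._edges.values() if e.u in keep and e.v in keep]
        return RPIGraph(keep, edges)

    def to_records(self) -> InteractionTable:
        """Re-expand the multilabel graph into interaction records."""
        raw: list[tuple[str, str, InteractionClass]] = []
        for e in self._edges.values():
            if e.etype.has_physical:
                raw.append((e.u, e.v, InteractionClass.PHYSICAL))
            if e.etype in (EdgeType.B, EdgeType.PB):
                raw.append((e.u, e.v, InteractionClass.REGULATORY))
                raw.append((e.v, e.u, InteractionClass.REGULATORY))
            elif e.etype.oriented:
                reg = e.regulator
                tgt = e.other(reg)
                raw.append((reg, tgt, InteractionClass.REGULATORY))
        return normalize_records(raw)

    def write_edge_list(self, path: str | Path) -> None:
        """Export the collapsed edge list as TSV."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id1\tid2\tedge_type\torbit_end1\torbit_end2\n")
            for (u, v), e in sorted(self._edges.items()):
                o1, o2 = e.end_orbits
                fh.write(f"{u}\t{v}\t{e.etype.value}\t{o1}\t{o2}\n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RPIGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"RPIGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def build_rpi_graph(table: InteractionTable) -> RPIGraph:
    """Collapse an interaction table into the five-type multilabel graph.

    For every node pair, the edge type is the unique combination of
    (physical present?) x (regulatory: none / one direction / both).
    """
    phys: set[tuple[str, str]] = set()
    reg: dict[tuple[str, str], set[str]] = {}
    nodes: set[str] = set()
    for r in table.records:
        nodes.add(r.a)
        nodes.add(r.b)
        pair = (r.a, r.b) if r.a < r.b else (r.b, r.a)
        if r.kind is InteractionClass.PHYSICAL:
            phys.add(pair)
        else:
            reg.setdefault(pair, set()).add(r.a)

    graph = RPIGraph(nodes)
    for pair in sorted(phys | set(reg)):
        u, v = pair
        has_p = pair in phys
        regulators = reg.get(pair, set())
        if len(regulators) == 2:
            etype = EdgeType.PB if has_p else EdgeType.B
            graph.add_edge(Edge(u, v, etype))
        elif len(regulators) == 1:
            etype = EdgeType.PR if has_p else EdgeType.R
            graph.add_edge(Edge(u, v, etype, regulator=next(iter(regulators))))
        else:
            graph.add_edge(Edge(u, v, EdgeType.P))
    return graph


def generate_synthetic_network(
    n_nodes: int,
    p_physical: float,
    p_regulatory: float,
    p_mutual: float = 0.0,
    seed: int | np.random.Generator | None = None,
    planted_seed_fraction: float = 0.0,
) -> tuple[InteractionTable, frozenset[str]]:
    """Random mixed network emulating the input edge lists.

    Erdos-Renyi-style layers: each unordered pair receives a physical edge
    with probability ``p_physical``; each ordered pair receives a regulatory
    edge with probability ``p_regulatory``, which is made reciprocal with
    probability ``p_mutual``.  A planted seed set of
    ``round(planted_seed_fraction * n_nodes)`` nodes is drawn uniformly.
    Deterministic for a fixed ``seed``.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    for name, p in (
        ("p_physical", p_physical),
        ("p_regulatory", p_regulatory),
        ("p_mutual", p_mutual),
        ("planted_seed_fraction", planted_seed_fraction),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes - 1))
    names = [f"n{i:0{width}d}" for i in range(n_nodes)]

    raw: list[tuple[str, str, InteractionClass]] = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_physical:
                raw.append((names[i], names[j], InteractionClass.PHYSICAL))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i == j:
                continue
            if rng.random() < p_regulatory:
                raw.append((names[i], names[j], InteractionClass.REGULATORY))
                if p_mutual and rng.random() < p_mutual:
                    raw.append((names[j], names[i], InteractionClass.REGULATORY))
    table = normalize_records(raw)
    n_seeds = round(planted_seed_fraction * n_nodes)
    seed_nodes = frozenset(rng.choice(names, size=n_seeds, replace=False)) if n_seeds else frozenset()
    return table, seed_nodes
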