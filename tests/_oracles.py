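"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's orbit-matrix machinery: a 3-node
subgraph is described at the *record* level (a set of undirected physical
pairs plus a set of directed regulatory arcs) and canonicalized by
minimizing the relabeled record set over all 6 node permutations.  Since
the per-pair collapse is a bijection, record-level isomorphism coincides
with edge-type-preserving isomorphism.
"""

from __future__ import annotations

from itertools import combinations, permutations

from rpigraphlets.rpi_graph import EdgeType, RPIGraph

Records = tuple[frozenset[tuple[str, str]], frozenset[tuple[str, str]]]


def records_of_triple(graph: RPIGraph, triple) -> Records:
    """(physical pairs, regulatory arcs) of the induced subgraph."""
    phys = set()
    reg = set()
    for a, b in combinations(triple, 2):
        e = graph.edge_between(a, b)
        if e is None:
            continue
        if e.etype.has_physical:
            phys.add((min(a, b), max(a, b)))
        if e.etype in (EdgeType.B, EdgeType.PB):
            reg.add((a, b))
            reg.add((b, a))
        elif e.etype.oriented:
            reg.add((e.regulator, e.other(e.regulator)))
    return frozenset(phys), frozenset(reg)


def oracle_canonical(records: Records, nodes) -> str:
    """Minimum serialization of the record set over all node relabelings."""
    phys, reg = records
    nodes = list(nodes)
    best = None
    for perm in permutations(range(len(nodes))):
        relabel = {n: str(perm[i]) for i, n in enumerate(nodes)}
        p = sorted(
            (min(relabel[a], relabel[b]), max(relabel[a], relabel[b]))
            for a, b in phys
        )
        r = sorted((relabel[a], relabel[b]) for a, b in reg)
        ser = (tuple(p), tuple(r))
        if best is None or ser < best:
            best = ser
    phys_s = ",".join(f"{a}-{b}" for a, b in best[0])
    reg_s = ",".join(f"{a}>{b}" for a, b in best[1])
    return f"P[{phys_s}]R[{reg_s}]"


def is_connected_records(records: Records, triple) -> bool:
    phys, reg = records
    adj = {n: set() for n in triple}
    for a, b in phys:
        adj[a].add(b)
        adj[b].add(a)
    for a, b in reg:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    stack = [next(iter(triple))]
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(adj[n] - seen)
    return len(seen) == len(list(triple))


def entry_records(entry) -> Records:
    """Record-level view of a 3-node catalog entry's canonical matrix."""
    M = entry.matrix
    phys = set()
    reg = set()
    names = [str(i) for i in range(3)]
    for i in range(3):
        for j in range(i + 1, 3):
            fwd = M[i][j]
            if fwd == 0:
                continue
            etype = {1: "P", 2: "R", 3: "R", 4: "PR", 5: "PR", 6: "B", 7: "PB"}[fwd]
            if etype in ("P", "PR", "PB"):
                phys.add((names[i], names[j]))
            if etype in ("B", "PB"):
                reg.add((names[i], names[j]))
                reg.add((names[j], names[i]))
            elif etype in ("R", "PR"):
                if fwd in (2, 4):
                    reg.add((names[i], names[j]))
                else:
                    reg.add((names[j], names[i]))
    return frozenset(phys), frozenset(reg)


def brute_force_counts(graph: RPIGraph, catalog) -> tuple[dict, dict]:
    """All-C(n,3) counting by canonical record matching.

    Returns (graphlet_counts over 3-node catalog ids, orbit counts as
    node -> orbit id -> count over 3-node orbits).  Orbits are resolved by
    explicitly searching for a record-preserving bijection onto the
    catalog's stored representative.
    """
    canon_to_entry = {}
    for entry in catalog.entries_3node:
        rec = entry_records(entry)
        canon_to_entry[oracle_canonical(rec, ["0", "1", "2"])] = entry

    from rpigraphlets.catalog import node_orbit_pair

    counts = {e.graphlet_id: 0 for e in catalog.entries_3node}
    orbit_counts: dict[str, dict[int, int]] = {n: {} for n in graph.nodes}
    for triple in combinations(sorted(graph.nodes), 3):
        rec = records_of_triple(graph, triple)
        if not (rec[0] or rec[1]):
            continue
        if not is_connected_records(rec, triple):
            continue
        entry = canon_to_entry[oracle_canonical(rec, triple)]
        counts[entry.graphlet_id] += 1
        target = entry_records(entry)
        # find an explicit isomorphism triple -> canonical positions
        found = None
        for perm in permutations(range(3)):
            relabel = {triple[i]: str(perm[i]) for i in range(3)}
            phys = frozenset(
                (min(relabel[a], relabel[b]), max(relabel[a], relabel[b]))
                for a, b in rec[0]
            )
            reg = frozenset((relabel[a], relabel[b]) for a, b in rec[1])
            if (phys, reg) == target:
                found = perm
                break
        assert found is not None, "canonical match without explicit isomorphism"
        for i, node in enumerate(triple):
            pos = found[i]
            oid = entry.pair_to_orbit[node_orbit_pair(entry.matrix, pos)]
            per = orbit_counts[node]
            per[oid] = per.get(oid, 0) + 1
    return counts, orbit_counts
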