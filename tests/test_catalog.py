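import json
from itertools import combinations, permutations, product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpigraphlets.catalog import (
    REVERSE_ORBIT,
    CatalogError,
    canonical_form,
    encode_subgraph,
    enumerate_catalog,
    is_connected,
    node_orbit_pair,
    orbit_partition,
)

from _oracles import entry_records, is_connected_records, oracle_canonical


def triad(ab, ac, bc):
    """Orbit matrix from the three forward pair states."""
    return (
        (0, ab, ac),
        (REVERSE_ORBIT[ab], 0, bc),
        (REVERSE_ORBIT[ac], REVERSE_ORBIT[bc], 0),
    )


def permuted(M, p):
    return tuple(tuple(M[p[i]][p[j]] for j in range(3)) for i in range(3))


class TestEncodeSubgraph:
    def test_p_path(self):
        # A - B - C with both edges physical, B in the middle
        M = triad(1, 0, 1)
        assert encode_subgraph(M) == ((0, 1), (0, 1), (1, 1))

    def test_p_triangle(self):
        M = triad(1, 1, 1)
        assert encode_subgraph(M) == ((1, 1), (1, 1), (1, 1))

    def test_directed_chain(self):
        # A -> B -> C single regulatory edges
        M = triad(2, 0, 2)
        assert encode_subgraph(M) == ((0, 2), (0, 3), (2, 3))

    def test_relabeling_invariance_example(self):
        M = triad(4, 0, 2)
        for p in permutations(range(3)):
            assert encode_subgraph(permuted(M, p)) == encode_subgraph(M)

    def test_disconnected_rejected(self):
        with pytest.raises(ValueError, match="not connected"):
            encode_subgraph(triad(1, 0, 0))

    def test_inconsistent_half_edges_rejected(self):
        M = ((0, 2, 0), (2, 0, 1), (0, 1, 0))  # 2 must pair with 3
        with pytest.raises(ValueError, match="inconsistent"):
            encode_subgraph(M)


class TestCanonicalForm:
    def test_directed_cycle_reflection(self):
        # A->B->C->A vs its reversal A->C->B->A are isomorphic
        cycle = triad(2, 3, 2)
        reverse = triad(3, 2, 3)
        assert canonical_form(cycle) == canonical_form(reverse)

    def test_edge_types_distinguished(self):
        p_path = triad(1, 0, 1)
        r_path = triad(2, 0, 2)
        assert canonical_form(p_path) != canonical_form(r_path)

    def test_relabeling_invariance(self):
        M = triad(5, 6, 1)
        for p in permutations(range(3)):
            assert canonical_form(permuted(M, p)) == canonical_form(M)


@settings(max_examples=100, deadline=None)
@given(
    st.tuples(
        st.integers(0, 7), st.integers(0, 7), st.integers(0, 7)
    ).filter(lambda t: is_connected(triad(*t))),
    st.permutations(range(3)),
)
def test_fingerprints_are_relabeling_invariant(states, perm):
    M = triad(*states)
    P = permuted(M, tuple(perm))
    assert canonical_form(P) == canonical_form(M)
    assert encode_subgraph(P) == encode_subgraph(M)


class TestEnumerateCatalog:
    def test_two_node_entries(self, catalog):
        assert len(catalog.entries_2node) == 5
        orbits = sorted(o for e in catalog.entries_2node for o in e.orbit_ids)
        assert orbits == [1, 2, 3, 4, 5, 6, 7]

    def test_three_node_total(self, catalog):
        assert len(catalog.entries_3node) == 98

    def test_shape_split(self, catalog):
        lines = [e for e in catalog.entries_3node if e.shape == "line"]
        triangles = [e for e in catalog.entries_3node if e.shape == "triangle"]
        assert len(lines) == 28
        assert len(triangles) == 70

    def test_composition_split(self, catalog):
        comp = {"mixed": 0, "physical_only": 0, "regulatory_only": 0}
        for e in catalog.entries_3node:
            comp[e.composition] += 1
        assert comp == {"mixed": 83, "physical_only": 2, "regulatory_only": 13}

    def test_total_three_node_orbits(self, catalog):
        assert catalog.n_orbits_3node == 259

    def test_orbit_ids_contiguous(self, catalog):
        ids = catalog.orbit_ids
        assert list(ids) == list(range(1, 7 + 259 + 1))

    def test_keys_pairwise_distinct(self, catalog):
        keys = [e.key for e in catalog.entries_3node]
        assert len(set(keys)) == 98

    def test_key_bijective_with_canonical_form(self, catalog):
        forms = {canonical_form(e.matrix) for e in catalog.entries_3node}
        assert len(forms) == 98
        # every connected triad maps to the key of its isomorphism class
        for e in catalog.entries_3node:
            for p in permutations(range(3)):
                assert encode_subgraph(permuted(e.matrix, p)) == e.key

    def test_orbit_class_sizes_sum_to_three(self, catalog):
        for e in catalog.entries_3node:
            assert sum(e.orbit_class_sizes) == 3

    def test_orbit_classes_match_sorted_pairs(self, catalog):
        for e in catalog.entries_3node:
            pairs = {node_orbit_pair(e.matrix, i) for i in range(3)}
            assert pairs == set(e.pair_to_orbit)
            assert len(e.orbit_ids) == len(pairs)

    def test_orbit_partition_is_automorphism_based(self, catalog):
        for e in catalog.entries_3node:
            classes = orbit_partition(e.matrix)
            assert sorted(len(c) for c in classes) == sorted(e.orbit_class_sizes)


@pytest.fixture(scope="module")
def oracle_classes():
    # a pair state is (physical?, set of regulatory arc directions)
    pair_states = [
        (phys, frozenset(arcs))
        for phys in (False, True)
        for arcs in ({}, {"fwd"}, {"bwd"}, {"fwd", "bwd"})
    ]
    nodes = ("x", "y", "z")
    pair_list = list(combinations(nodes, 2))
    classes = {}
    for assignment in product(pair_states, repeat=3):
        phys, reg = set(), set()
        for (a, b), (has_p, arcs) in zip(pair_list, assignment):
            if has_p:
                phys.add((a, b))
            if "fwd" in arcs:
                reg.add((a, b))
            if "bwd" in arcs:
                reg.add((b, a))
        rec = (frozenset(phys), frozenset(reg))
        if not (phys or reg):
            continue
        touched = {n for p in phys for n in p} | {n for a in reg for n in a}
        if touched != set(nodes) or not is_connected_records(rec, nodes):
            continue
        key = oracle_canonical(rec, nodes)
        classes.setdefault(key, rec)
    return classes


class TestAgainstIndependentOracle:
    """Record-level enumeration with a canonicalizer the package never uses."""

    def test_class_count_matches(self, catalog, oracle_classes):
        assert len(oracle_classes) == len(catalog.entries_3node) == 98

    def test_catalog_entries_in_bijection_with_oracle(self, catalog, oracle_classes):
        entry_forms = {
            oracle_canonical(entry_records(e), ["0", "1", "2"])
            for e in catalog.entries_3node
        }
        assert entry_forms == set(oracle_classes)

    def test_shape_split_matches_oracle(self, oracle_classes):
        n_lines = sum(
            1 for phys, reg in oracle_classes.values()
            if len(phys | {tuple(sorted(a)) for a in reg}) == 2
        )
        assert n_lines == 28

    def test_composition_split_matches_oracle(self, oracle_classes):
        mixed = sum(1 for phys, reg in oracle_classes.values() if phys and reg)
        phys_only = sum(1 for phys, reg in oracle_classes.values() if phys and not reg)
        reg_only = sum(1 for phys, reg in oracle_classes.values() if reg and not phys)
        assert (mixed, phys_only, reg_only) == (83, 2, 13)


class TestExport:
    def test_tsv_and_json_roundtrip(self, catalog, tmp_path):
        catalog.write_tsv(tmp_path / "catalog.tsv")
        catalog.write_json(tmp_path / "catalog.json")
        lines = (tmp_path / "catalog.tsv").read_text().splitlines()
        assert len(lines) == 1 + 5 + 98
        data = json.loads((tmp_path / "catalog.json").read_text())
        assert len(data) == 103
        assert {row["graphlet_id"] for row in data} == set(catalog.graphlet_ids)

    def test_deterministic_export(self, catalog, tmp_path):
        c2 = enumerate_catalog()
        catalog.write_tsv(tmp_path / "a.tsv")
        c2.write_tsv(tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
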