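import numpy as np
import pytest

from rpigraphlets.null_models import (
    RandomizationConfig,
    graphlet_overrepresentation,
    summarize_enrichment,
    switch_randomize,
)
from rpigraphlets.rpi_graph import (
    EdgeType,
    build_rpi_graph,
    generate_synthetic_network,
)

from conftest import make_graph


def typed_degrees(graph):
    """node -> (type, role) -> degree; role splits regulator/target ends."""
    deg = {n: {} for n in graph.nodes}

    def bump(node, key):
        deg[node][key] = deg[node].get(key, 0) + 1

    for e in graph.edges():
        if e.etype.oriented:
            bump(e.regulator, (e.etype, "out"))
            bump(e.other(e.regulator), (e.etype, "in"))
        else:
            bump(e.u, (e.etype, "und"))
            bump(e.v, (e.etype, "und"))
    return deg


@pytest.fixture
def mixed_graph():
    table, _ = generate_synthetic_network(30, 0.12, 0.06, 0.3, seed=5)
    return build_rpi_graph(table)


class TestSwitchRandomize:
    @pytest.mark.parametrize("seed", range(5))
    def test_typed_degrees_preserved(self, mixed_graph, seed):
        out = switch_randomize(mixed_graph, RandomizationConfig(rng_seed=seed))
        assert typed_degrees(out) == typed_degrees(mixed_graph)

    def test_edge_counts_and_nodes_preserved(self, mixed_graph):
        out = switch_randomize(mixed_graph, RandomizationConfig(rng_seed=1))
        assert out.nodes == mixed_graph.nodes
        assert out.edge_type_counts() == mixed_graph.edge_type_counts()

    def test_actually_rewires(self, mixed_graph):
        out = switch_randomize(mixed_graph, RandomizationConfig(rng_seed=2))
        original = {(e.u, e.v) for e in mixed_graph.edges()}
        rewired = {(e.u, e.v) for e in out.edges()}
        assert rewired != original

    def test_p_four_cycle_stays_two_regular(self):
        g = make_graph(phys=[("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        for seed in range(10):
            out = switch_randomize(g, RandomizationConfig(rng_seed=seed))
            assert all(out.degree(n) == 2 for n in out.nodes)
            assert out.n_edges == 4
            types = {e.etype for e in out.edges()}
            assert types == {EdgeType.P}

    def test_single_b_edge_untouched(self):
        g = make_graph(reg=[("A", "B"), ("B", "A")])
        out = switch_randomize(g, RandomizationConfig(rng_seed=0))
        assert out == g

    def test_reproducible(self, mixed_graph):
        a = switch_randomize(mixed_graph, RandomizationConfig(rng_seed=77))
        b = switch_randomize(mixed_graph, RandomizationConfig(rng_seed=77))
        assert a == b

    def test_no_self_loops_or_pair_collisions(self, mixed_graph):
        out = switch_randomize(mixed_graph, RandomizationConfig(rng_seed=4))
        pairs = [(e.u, e.v) for e in out.edges()]
        assert all(u != v for u, v in pairs)
        assert len(pairs) == len(set(pairs))

    def test_saturation_diagnostics(self):
        table, _ = generate_synthetic_network(60, 0.1, 0.0, seed=8)
        g = build_rpi_graph(table)
        diag = {}
        switch_randomize(
            g,
            RandomizationConfig(rng_seed=3, swaps_per_edge=20,
                                saturation_window=50,
                                saturation_tolerance=1e-6),
            diagnostics=diag,
        )
        traj = diag["P"]
        assert traj, "no saturation samples recorded"
        assert all(0.0 <= f <= 1.0 for f in traj)
        # new-edge fraction climbs toward a plateau on average
        half = len(traj) // 2 or 1
        assert np.mean(traj[half:]) >= np.mean(traj[:half]) - 1e-9
        assert traj[-1] > 0.3

    def test_raw_layer_scope_preserves_raw_degrees(self, mixed_graph):
        def raw_degrees(graph):
            deg = {n: [0, 0, 0] for n in graph.nodes}  # phys, reg-out, reg-in
            for r in graph.to_records().records:
                if r.kind.value == "physical":
                    deg[r.a][0] += 1
                    deg[r.b][0] += 1
                else:
                    deg[r.a][1] += 1
                    deg[r.b][2] += 1
            return deg

        config = RandomizationConfig(rng_seed=6, swap_scope="raw_layers")
        out = switch_randomize(mixed_graph, config)
        assert raw_degrees(out) == raw_degrees(mixed_graph)


class TestSignificanceArithmetic:
    def test_nine_of_thousand_significant(self):
        nulls = np.concatenate([np.full(9, 11), np.full(991, 5)])
        exceed, p, sig = summarize_enrichment(10, nulls, 1000)
        assert (exceed, p, sig) == (9, 0.009, True)

    def test_ten_of_thousand_not_significant(self):
        nulls = np.concatenate([np.full(10, 11), np.full(990, 5)])
        exceed, p, sig = summarize_enrichment(10, nulls, 1000)
        assert (exceed, p, sig) == (10, 0.010, False)

    def test_ties_do_not_exceed_under_strict_rule(self):
        nulls = np.full(1000, 10)
        exceed, p, sig = summarize_enrichment(10, nulls, 1000)
        assert (exceed, p) == (0, 0.0)
        assert sig  # observed > 0 and no replicate strictly above

    def test_greater_equal_rule(self):
        nulls = np.concatenate([np.full(15, 10), np.full(985, 3)])
        exceed, _, _ = summarize_enrichment(10, nulls, 1000,
                                            exceed_rule="greater_equal")
        assert exceed == 15

    def test_zero_observed_never_significant(self):
        nulls = np.zeros(1000)
        exceed, p, sig = summarize_enrichment(0, nulls, 1000)
        assert exceed == 0 and p == 0.0
        assert not sig

    def test_pseudo_count_option(self):
        nulls = np.concatenate([np.full(9, 11), np.full(991, 5)])
        _, p, _ = summarize_enrichment(10, nulls, 1000, pseudo_count=True)
        assert p == pytest.approx(10 / 1001)


class TestGraphletOverrepresentation:
    def test_result_structure_and_reproducibility(self, catalog):
        table, _ = generate_synthetic_network(20, 0.15, 0.08, seed=10)
        g = build_rpi_graph(table)
        config = RandomizationConfig(n_replicates=10, rng_seed=42)
        r1 = graphlet_overrepresentation(g, catalog, config)
        r2 = graphlet_overrepresentation(g, catalog, config)
        assert r1.empirical_p == r2.empirical_p
        assert set(r1.graphlet_ids) == set(catalog.graphlet_ids)
        for gid in r1.graphlet_ids:
            assert 0.0 <= r1.empirical_p[gid] <= 1.0
            assert len(r1.null_counts[gid]) == 10
            if r1.observed[gid] == 0:
                assert not r1.significant[gid]

    def test_frame_export(self, catalog, tmp_path):
        table, _ = generate_synthetic_network(15, 0.2, 0.05, seed=1)
        g = build_rpi_graph(table)
        result = graphlet_overrepresentation(
            g, catalog, RandomizationConfig(n_replicates=5, rng_seed=0)
        )
        result.write_tsv(tmp_path / "enrich.tsv", catalog)
        frame = result.to_frame(catalog)
        assert list(frame.columns) == [
            "graphlet_id", "key", "observed", "null_mean", "null_sd",
            "exceed_count", "p", "significant",
        ]
        assert len(frame) == 103


def test_config_validation():
    with pytest.raises(ValueError):
        RandomizationConfig(n_replicates=0)
    with pytest.raises(ValueError):
        RandomizationConfig(saturation_tolerance=1.5)
    with pytest.raises(ValueError):
        RandomizationConfig(swap_scope="bogus")
    with pytest.raises(ValueError):
        RandomizationConfig(exceed_rule="between")
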