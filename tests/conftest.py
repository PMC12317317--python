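from __future__ import annotations

import pytest

from rpigraphlets.catalog import enumerate_catalog
from rpigraphlets.rpi_graph import (
    InteractionClass,
    RPIGraph,
    build_rpi_graph,
    normalize_records,
)


@pytest.fixture(scope="session")
def catalog():
    return enumerate_catalog()


def make_graph(phys=(), reg=()) -> RPIGraph:
    """Build a collapsed graph from physical pairs and regulatory arcs."""
    raw = [(a, b, InteractionClass.PHYSICAL) for a, b in phys]
    raw += [(a, b, InteractionClass.REGULATORY) for a, b in reg]
    return build_rpi_graph(normalize_records(raw))


@pytest.fixture
def p_path():
    """A - B - C with both edges physical."""
    return make_graph(phys=[("A", "B"), ("B", "C")])


@pytest.fixture
def p_triangle():
    return make_graph(phys=[("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def p_star():
    """Center c with physical leaves x, y, z."""
    return make_graph(phys=[("c", "x"), ("c", "y"), ("c", "z")])
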