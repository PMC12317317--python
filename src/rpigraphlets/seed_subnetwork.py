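"""Random walk with restart from a seed set and coverage-based subnetwork extraction.

Scores are the fixed point of ``s = (1 - alpha) * T s + alpha * r`` with
``r`` uniform over the seeds present in the graph and ``T`` the
column-normalized transition matrix of the chosen traversal mode
(``symmetric`` walks every labeled edge both ways; ``directed_forward``
restricts single regulatory edges to their regulator -> target direction).
Mass reaching dangling nodes is redirected to the restart vector so the
scores remain a probability distribution.

The subnetwork is the induced multilabel subgraph on the smallest
score-ranked node prefix containing ``ceil(coverage * |present seeds|)``
seeds (ties broken lexicographically for determinism).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from rpigraphlets.rpi_graph import EdgeType, RPIGraph

logger = logging.getLogger(__name__)

__all__ = [
    "RWRConfig",
    "SeedSubnetwork",
    "read_seed_list",
    "rwr_scores",
    "extract_subnetwork",
]


@dataclass(frozen=True)
class RWRConfig:
    restart_probability: float = 0.85
    tolerance: float = 1e-10
    max_iterations: int = 1000
    traversal: str = "symmetric"  # or "directed_forward"

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_probability < 1.0:
            raise ValueError("restart_probability must lie in (0, 1)")
        if self.traversal not in ("symmetric", "directed_forward"):
            raise ValueError(f"unknown traversal mode {self.traversal!r}")


def read_seed_list(path: str | Path) -> list[str]:
    """Read a seed list (one identifier per line, '#' comments skipped)."""
    seeds: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                seeds.append(token)
    return seeds


def _walk_arcs(graph: RPIGraph, traversal: str):
    """Yield walkable ordered arcs (u, v) under the traversal mode."""
    for e in graph.edges():
        if traversal == "symmetric" or e.etype is not EdgeType.R:
            yield e.u, e.v
            yield e.v, e.u
        else:
            reg = e.regulator
            yield reg, e.other(reg)


def rwr_scores(
    graph: RPIGraph,
    seeds: set[str] | frozenset[str] | list[str],
    config: RWRConfig | None = None,
) -> pd.Series:
    """Stationary RWR score for every node (sums to 1 within tolerance).

    Seeds absent from the graph are logged and ignored; if none remain a
    ``ValueError`` is raised.
    """
    config = config or RWRConfig()
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("graph has no nodes")
    index = {n: i for i, n in enumerate(nodes)}
    present = sorted(set(seeds) & graph.nodes)
    missing = sorted(set(seeds) - graph.nodes)
    if missing:
        logger.warning("%d seed(s) absent from the graph ignored: %s",
                       len(missing), missing[:5])
    if not present:
        raise ValueError("no seed is present in the graph")

    n = len(nodes)
    rows, cols = [], []
    for u, v in _walk_arcs(graph, config.traversal):
        rows.append(index[v])
        cols.append(index[u])
    out_degree = np.zeros(n)
    np.add.at(out_degree, cols, 1.0)
    dangling = out_degree == 0
    weights = 1.0 / out_degree[cols]
    T = sparse.csr_matrix((weights, (rows, cols)), shape=(n, n))

    r = np.zeros(n)
    r[[index[s] for s in present]] = 1.0 / len(present)
    alpha = config.restart_probability
    s = r.copy()
    for _ in range(config.max_iterations):
        walk = T @ s + s[dangling].sum() * r
        s_next = (1.0 - alpha) * walk + alpha * r
        if np.abs(s_next - s).sum() < config.tolerance:
            s = s_next
            break
        s = s_next
    else:
        logger.warning("RWR did not converge within %d iterations",
                       config.max_iterations)
    return pd.Series(s, index=nodes, name="score")


@dataclass
class SeedSubnetwork:
    """Score-ranked node prefix covering the target seed fraction."""

    member_nodes: tuple[str, ...]  # descending score, ties lexicographic
    coverage_achieved: float
    induced_graph: RPIGraph
    n_present_seeds: int
    target_coverage: float
    warning: str | None = None

    def score_table(self, scores: pd.Series, seeds: set[str]) -> pd.DataFrame:
        order = _ranked_nodes(scores)
        return pd.DataFrame(
            {
                "node": order,
                "score": [scores[n] for n in order],
                "is_seed": [n in seeds for n in order],
                "rank": range(1, len(order) + 1),
                "in_subnetwork": [n in set(self.member_nodes) for n in order],
            }
        )


def _ranked_nodes(scores: pd.Series) -> list[str]:
    return sorted(scores.index, key=lambda n: (-scores[n], n))


def extract_subnetwork(
    graph: RPIGraph,
    scores: pd.Series,
    seeds: set[str] | frozenset[str] | list[str],
    coverage: float = 0.8,
) -> SeedSubnetwork:
    """Smallest score-ranked prefix whose induced subgraph covers the seeds.

    The prefix stops as soon as ``ceil(coverage * |present seeds|)`` seeds
    are inside.  A warning is attached when zero-score nodes had to be
    included to reach the target.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    present = set(seeds) & graph.nodes
    if not present:
        raise ValueError("no seed is present in the graph")
    required = math.ceil(coverage * len(present))
    order = _ranked_nodes(scores)
    members: list[str] = []
    covered = 0
    warning = None
    for node in order:
        members.append(node)
        if node in present:
            covered += 1
            if scores[node] == 0.0:
                warning = "zero-score seeds included to reach target coverage"
            if covered >= required:
                break
    achieved = covered / len(present)
    return SeedSubnetwork(
        member_nodes=tuple(members),
        coverage_achieved=achieved,
        induced_graph=graph.induced_subgraph(members),
        n_present_seeds=len(present),
        target_coverage=coverage,
        warning=warning,
    )
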