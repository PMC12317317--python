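"""Median-based orbit overrepresentation test via random node-set sampling.

For each orbit the observed median count over the query node set is compared
with the medians of ``n_samples`` uniformly drawn node sets of the same size
(without replacement, from all matrix nodes).  An orbit is significantly
overrepresented when fewer than ``alpha`` of the null medians are equal to
or larger than the observed median.  Even-sized medians use the standard
mean-of-central-values convention for both observed and null values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from rpigraphlets.catalog import GraphletCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "OrbitEnrichmentResult",
    "orbit_overrepresentation",
    "export_orbit_members",
    "summarize_median_test",
]


def summarize_median_test(
    observed_median: float,
    null_medians: np.ndarray,
    alpha: float = 0.01,
) -> tuple[int, float, bool]:
    """Median-test arithmetic for one orbit: (ge_count, p, significant).

    An orbit is significant when fewer than ``alpha`` of the null medians
    are equal to or larger than the observed median.
    """
    nulls = np.asarray(null_medians)
    ge = int(np.sum(nulls >= observed_median))
    p = ge / len(nulls)
    return ge, p, p < alpha


@dataclass
class OrbitEnrichmentResult:
    """Per-orbit observed/null medians, empirical p and member nodes."""

    orbit_ids: tuple[int, ...]
    observed_median: dict[int, float]
    null_medians: dict[int, np.ndarray]
    ge_count: dict[int, int]
    empirical_p: dict[int, float]
    significant: dict[int, bool]
    member_nodes: dict[int, tuple[str, ...]]
    n_samples: int
    alpha: float
    query_size: int

    def to_frame(self, catalog: GraphletCatalog) -> pd.DataFrame:
        rows = []
        for oid in self.orbit_ids:
            entry = catalog.owner_of_orbit(oid)
            rows.append(
                {
                    "orbit_id": oid,
                    "graphlet_id": entry.graphlet_id,
                    "key": entry.key_string,
                    "composition": entry.composition,
                    "observed_median": self.observed_median[oid],
                    "null_median_mean": float(np.mean(self.null_medians[oid])),
                    "ge_count": self.ge_count[oid],
                    "p": self.empirical_p[oid],
                    "significant": self.significant[oid],
                    "n_members": len(self.member_nodes[oid]),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path, catalog: GraphletCatalog) -> None:
        self.to_frame(catalog).to_csv(path, sep="\t", index=False)


def orbit_overrepresentation(
    orbit_matrix: pd.DataFrame,
    query_set: set[str] | frozenset[str] | list[str],
    n_samples: int = 1000,
    rng_seed: int | np.random.Generator | None = None,
    alpha: float = 0.01,
) -> OrbitEnrichmentResult:
    """Median-sampling orbit overrepresentation for a query node set.

    ``orbit_matrix`` is the dense node x orbit count matrix (rows indexed by
    node id).  Query members absent from the matrix are logged and dropped;
    an empty query after filtering is an error.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    nodes = list(orbit_matrix.index)
    node_pos = {n: i for i, n in enumerate(nodes)}
    query = sorted(set(query_set) & set(nodes))
    dropped = sorted(set(query_set) - set(nodes))
    if dropped:
        logger.warning("%d query node(s) absent from the orbit matrix dropped",
                       len(dropped))
    if not query:
        raise ValueError("query set empty after filtering against matrix nodes")

    values = orbit_matrix.to_numpy(dtype=float)
    orbit_ids = tuple(int(c) for c in orbit_matrix.columns)
    query_idx = np.array([node_pos[n] for n in query])
    observed = np.median(values[query_idx], axis=0)

    rng = np.random.default_rng(rng_seed)
    k = len(query)
    null = np.empty((n_samples, len(orbit_ids)))
    for s in range(n_samples):
        sample_idx = rng.choice(len(nodes), size=k, replace=False)
        null[s] = np.median(values[sample_idx], axis=0)

    summaries = [
        summarize_median_test(observed[i], null[:, i], alpha=alpha)
        for i in range(len(orbit_ids))
    ]
    ge = np.array([s[0] for s in summaries])
    pvals = np.array([s[1] for s in summaries])
    members = {
        oid: tuple(n for n in query if orbit_matrix.at[n, col] > 0)
        for oid, col in zip(orbit_ids, orbit_matrix.columns)
    }
    return OrbitEnrichmentResult(
        orbit_ids=orbit_ids,
        observed_median={oid: float(observed[i]) for i, oid in enumerate(orbit_ids)},
        null_medians={oid: null[:, i] for i, oid in enumerate(orbit_ids)},
        ge_count={oid: int(ge[i]) for i, oid in enumerate(orbit_ids)},
        empirical_p={oid: float(pvals[i]) for i, oid in enumerate(orbit_ids)},
        significant={oid: bool(pvals[i] < alpha) for i, oid in enumerate(orbit_ids)},
        member_nodes=members,
        n_samples=n_samples,
        alpha=alpha,
        query_size=k,
    )


def export_orbit_members(
    result: OrbitEnrichmentResult,
    out_dir: str | Path,
    catalog: GraphletCatalog,
    significant_only: bool = True,
    mixed_only: bool = True,
) -> list[Path]:
    """Write one plain-text identifier list per retained orbit.

    Filters restrict the export to significant orbits and/or orbits
    belonging to mixed graphlets; the member list of an orbit is exactly the
    query-set nodes with a nonzero count there.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mixed = catalog.mixed_orbit_ids()
    written: list[Path] = []
    for oid in result.orbit_ids:
        if significant_only and not result.significant[oid]:
            continue
        if mixed_only and oid not in mixed:
            continue
        members = result.member_nodes[oid]
        if not members:
            continue
        path = out_dir / f"orbit_{oid:03d}_members.txt"
        path.write_text("\n".join(members) + "\n", encoding="utf-8")
        written.append(path)
    if not written:
        logger.info("no orbit passed the export filters; nothing written")
    return written
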