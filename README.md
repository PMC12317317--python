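# rpigraphlets

Graphlet and orbit analysis of mixed interaction networks that combine
undirected **physical** (protein–protein) and directed **regulatory**
(regulator → target) edges.

The two input layers are collapsed into a multilabel graph with at most one
typed edge per node pair, drawn from a five-letter alphabet: `P` (physical
only), `R` (single regulatory), `PR` (physical + single regulatory), `B`
(mutual regulation), `PB` (physical + mutual regulation). On this graph the
package provides:

- **Catalog** — exhaustive enumeration of all 5 two-node and 98 three-node
  graphlets (28 lines + 70 triangles; 83 of them mixed) together with their
  automorphism orbits (7 two-node + 259 three-node), a cheap sorted-pair
  encoding, and a brute-force canonical form proven equivalent at
  enumeration time.
- **Counting** — graphlet distribution vector and per-node orbit count
  matrix by enumeration of connected node triples.
- **Null model** — degree-preserving edge-swap randomization within each
  edge-type layer and empirical graphlet overrepresentation (a graphlet is
  significant when fewer than `ceil(0.01 · replicates)` randomized networks
  beat its observed count).
- **Seed subnetworks** — random walk with restart (restart probability
  0.85 by default) from a seed protein list and extraction of the smallest
  score-ranked node prefix covering 80% of the seeds.
- **Orbit enrichment** — median orbit count of a query protein set versus
  1000 random node sets of the same size, with per-orbit member-list export
  for downstream annotation tools.
- **Synthetic networks** — seeded Erdős–Rényi-style generators for both
  layers, used throughout the test suite.

## Command line

```bash
# export the full graphlet/orbit catalog (TSV + JSON)
rpigraphlets catalog --out-dir out/catalog

# generate a synthetic fixture
rpigraphlets synth --nodes 60 --p-physical 0.08 --p-regulatory 0.03 \
    --seed 7 --out-dir out/synth

# count graphlets and orbits
rpigraphlets count --ppi out/synth/physical.tsv --reg out/synth/regulatory.tsv \
    --out-dir out/counts

# RWR seed subnetwork at 80% seed coverage
rpigraphlets subnetwork --ppi out/synth/physical.tsv --reg out/synth/regulatory.tsv \
    --seeds out/synth/seeds.txt --out-dir out/subnetwork

# graphlet overrepresentation vs the edge-swap null
rpigraphlets enrich-graphlets --ppi out/synth/physical.tsv \
    --reg out/synth/regulatory.tsv --seeds out/synth/seeds.txt \
    --replicates 1000 --seed 1 --out-dir out/enrich

# orbit overrepresentation of a protein set
rpigraphlets enrich-orbits --ppi out/synth/physical.tsv \
    --reg out/synth/regulatory.tsv --seeds out/synth/seeds.txt \
    --samples 1000 --seed 1 --out-dir out/orbits
```

Inputs are plain TSV/CSV edge lists (`id1<TAB>id2`, `#` comments, optional
header), either one file per layer or a single file with a third
`ppi`/`reg` column. Every command writes a `manifest.json` (version,
configuration, input checksums) next to its outputs. Exit codes: 0 success,
2 input error, 3 internal consistency failure.

## Layout

```
src/rpigraphlets/
  rpi_graph.py        ingest, multilabel collapse, synthetic generator
  catalog.py          graphlet enumeration, encoding, canonical forms, orbits
  counting.py         triple enumeration and graphlet/orbit counting
  null_models.py      edge-swap randomization and graphlet enrichment
  seed_subnetwork.py  RWR scoring and coverage-prefix extraction
  orbit_enrichment.py median-sampling orbit test and member export
  cli.py              command-line interface
tests/                pytest suite (unit, property and acceptance tests)
scripts/acceptance.py acceptance report
```
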