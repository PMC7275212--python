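# Methods

## The pipeline model

The package treats a multi-herb formula as a four-layer relation:
disease → drugs (herbs) → ingredients → protein targets, with the PPI
and enrichment stages operating on the target layer. Every stage is a
pure function of local files; nothing queries a web service, and all
randomness is confined to the synthetic-data generators.

### ADME screening

An ingredient record carries oral bioavailability (OB, percent scale:
33 means 33 %) and a drug-likeness index (DL, unitless in [0, 1]).
The screen keeps records with OB ≥ `ob_min` and DL ≥ `dl_min`, defaults
33 and 0.18 — the conventional TCMSP-style cut-offs. Both comparisons
are inclusive: the shipped reference table's minimum retained values
(OB 34.55, DL 0.19) do not discriminate between the readings, but the
hub-screen analogue below does, and the two screens are kept consistent.
The same molecule may be listed under several herbs; it is kept as one
record per (molecule, herb) pair at the table level and merged into a
single node only when the network is built, so per-herb ingredient
counts sum across herbs.

### Target sets and the key-target intersection

Gene symbols are canonicalized by trim/uppercase/whitespace-collapse
plus an optional exact-match alias table (the hook for injecting
UniProt-derived renames; the package does not call UniProt). Disease
records from score-carrying sources are filtered at functionality score
≥ 30 (inclusive); records from catalogue-style sources carry no score
and always pass. The key-target set is the union over herbs of
(herb targets ∩ disease targets), reported per herb Venn-style and then
deduplicated.

### Tetrapartite network

Ingredients whose screened target sets are disjoint from the key
targets are pruned, and only key targets reachable through a retained
ingredient become target nodes — this is what shrinks an active
ingredient list further in the final network. Node ids: labels for the
disease and drugs, molecule ids for ingredients, gene symbols for
targets; cross-class collisions are rejected. Export is SIF
(`treats`/`contains`/`targets` interaction labels) plus a node-attribute
TSV, the minimal dialect Cytoscape ingests; a GraphML writer carries
the same attributes.

### Centralities and the hub screen

Degree is the neighbor count in the simple undirected PPI graph after
confidence filtering (score ≥ 0.4 inclusive, matching the "medium
confidence (0.400)" convention of STRING-style exports; unscored edges
are trusted). Closeness is **harmonic centrality**, Σ_{u≠v} 1/d(v,u)
over unit-distance BFS, with unreachable pairs contributing zero so
disconnected graphs are legal. The textbook "inverse of the summed
distance" (1/Σd) is bounded by 1/(n−1)·… ≤ 1 on connected graphs of
this size and cannot produce values like 64.33333 on an 83-node graph;
the harmonic form — which hub-screening tools such as cytoHubba
actually compute — produces exactly such magnitudes, with denominators
dividing small lcms (….33333, ….16667). The implementation sums exact
`Fraction`s and rounds to 5 decimals only when writing tables.

Hubs satisfy degree ≥ 20 AND closeness ≥ 48.33 (both inclusive,
configurable). Inclusivity is forced by the data: the reference hub
table contains records at exactly degree 20 and closeness 48.33333, so
strict thresholds would contradict the screen's own published output.
Source texts for this kind of screen sometimes state the closeness
cut-off as 48.8 in one place and 48.3 in another; the default follows
the value consistent with the reference table (48.33), and the
discrepancy is surfaced here rather than resolved.

Useful invariants, asserted in tests: 0 ≤ closeness ≤ n−1, and
closeness ≥ degree on every graph (each neighbor contributes exactly 1
to the harmonic sum; all other reachable nodes contribute positively).

### Over-representation analysis

The term statistic is the upper-tail hypergeometric probability
P[X ≥ k] (computed via scipy's stable survival function; tests check it
against exhaustive draw enumeration). Multiple testing uses
Benjamini–Hochberg across all tested terms (those with k ≥ 1) before
any filtering; the adjustment procedure in the emulated web services is
unstated, and BH is consistent with the q/p gaps those services print.
Filters follow the conventional caption exactly: strict p < 0.01,
inclusive count ≥ 3, strict enrichment factor > 1.5. The "%" column is
100·k/n rounded half-up to two decimals.

**Background choice.** `background="auto"` uses the union of all term
members. This is convenient but conditions retained input genes on
being annotated, which inflates overlaps; an explicit background file
covering the whole measured universe is recommended and is what the
calibration studies use. Input genes outside the background are dropped
with a logged warning and n reduced.

**Term clustering.** Enriched terms are linked when Cohen's kappa of
their binary membership vectors over the input gene list is ≥ 0.3 (the
conventional default); clusters are connected components of that link
graph, labeled by their lowest-p member and numbered in order of that
representative's p. This is a deliberate simplification of the
hierarchical merge used by web services like Metascape: connected
components at the same kappa threshold, deterministic and
order-independent.

## Synthetic data

The generators emulate the *statistical shape* of the inputs, not their
biology — symbols are drawn from an artificial universe (`G000001`…,
fillers `B…`/`D…`), so no real gene is implied. One integer seed drives
everything; each generator derives a sub-seed by stable SHA-256 hashing
of its own name, so later additions cannot shift earlier streams, and
identical configs produce byte-identical files.

Defaults mirror the study scale: 3 herbs × 15 ingredients, ADME pass
fraction 0.5 (passers uniform on OB ∈ [33, 110], DL ∈ [0.18, 0.95];
failers violate ≥ 1 threshold), geometric per-ingredient target counts
(mean 8) over a 300-gene universe — few ingredients with many targets,
many with few — a disease list of 150 with 50 % herb-target overlap
(all planted overlap genes pass the score filter; 80 % of fillers do),
and an Erdős–Rényi PPI over the planted key targets whose default edge
probability reproduces the 729-edges-on-83-nodes expectation
(p = 2·729/(83·82)); a Barabási–Albert alternative is available.

Decoy annotation terms draw 5–20 members uniformly from a 2000-gene
universe, i.e. 0.25–1 % of the background — the scaled-down analogue of
real annotation-term fractions (a median GO term holds ~30 of ~20 000
genes). At this size the enrichment stage is well calibrated: with no
planted term, ~95 % of seeded replicates report zero terms passing the
standard cut-offs. Larger decoy terms (≥ 1.5 % of the universe) sit
just under p = 0.01 at k = 3–4 by discreteness and would make random
26-gene lists "enriched" far more often. Planted terms contain a
configured number of input-destined genes padded with background
fillers to a configured size; the default calibration study plants 20
of 26 input genes in a 40-gene term among 50 decoys and recovers it at
rank 1 in 100/100 replicates.

What the generators do **not** emulate: real symbol vocabularies and
aliasing noise, curation biases of compound-target databases,
degree-correlated PPI confidence scores, or the hierarchical/nested
structure of real ontologies. Passing the synthetic end-to-end tests
therefore shows the machinery is correct and calibrated under the
planted model, not that any biological conclusion transfers.

## Numerical choices

- Harmonic closeness: exact rationals internally; 5-decimal fixed-point
  only at output. Ties in hub ordering break by degree desc, closeness
  desc, then symbol asc.
- Hypergeometric tail: `hypergeom.sf(k−1, N, K, n)`; count
  inconsistencies (k > K, n > N, …) raise validation errors rather than
  clamping.
- Percent column: decimal half-up rounding (not banker's), matching the
  printed tables.
- BH: step-up with cumulative-minimum monotonicity, input order
  preserved; empty input yields empty output.
- Kappa on two constant-and-equal vectors is defined as 1 (agreement is
  perfect; the chance-correction denominator vanishes).
- Graph building drops self-loops (counted, warned) and collapses
  duplicate/reversed edges; edges to nodes outside the declared node
  set are errors, not silent additions.
- Average degree is exact 2|E|/|V|; rounding to one decimal happens in
  reports only.

## Problem sizes in the checks

The verification studies use sizes chosen to keep the full suite fast
while exercising every code path: the BFS-oracle comparison covers 200
random graphs up to n = 40 plus exhaustive sweeps (every graph on
n ≤ 5; all n = 6 graphs with 7 edges; all n = 7 graphs with 5 edges —
~28 000 graphs, ~190 000 node evaluations), the enumeration check
covers every hypergeometric configuration with N ≤ 12, and the
calibration studies run 100 replicates each. These are the package's
own choices of scale; the properties they check are size-independent.

## Known limitations

- The pipeline consumes database *exports*; it does not reproduce any
  provider's internal scoring (functionality scores, STRING confidence,
  proprietary enrichment backgrounds), so absolute p/q values from web
  services are not reproducible — only the statistic's definition is.
- One common background per enrichment run; per-category backgrounds
  are not supported.
- Kappa clustering is single-threshold connected components, not a
  hierarchical merge.
- The optional connected-components report on the PPI is a structural
  convenience, not a module-detection method.
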