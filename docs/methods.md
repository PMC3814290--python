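# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what validation on synthetic data does and does
not establish.

## Expression data model

The unit of analysis is the probeset: one normalized intensity per sample,
on the **linear** scale.  All absolute-intensity rules (notably the
low-intensity filter at 50) are defined on that scale; a convenience flag
on the reader (`assume_log2=True`) exponentiates log2 input on load.
Matrices must be complete — RMA-style summarization yields no missing
values, and the readers treat holes, duplicate identifiers and stray text
in the value region as hard errors rather than repairing them.  Trailing
annotation columns in `.expression` files are detected as columns that
are non-numeric *throughout*; a column mixing numbers and text is
reported as a corrupt value cell with its row and column.

## Coexpression graph

Edges are inclusive at the threshold (r ≥ r_min); negative correlations
are never edges, matching the positive-cutoff convention of
correlation-graph atlas analyses.  Zero-variance probesets have undefined
correlations and are dropped with a warning.  Components smaller than the
minimum size (default 5) are pruned after graph assembly.

Blocked computation is a memory contract only: rows are z-scored once,
then block-by-matrix products produce exact Pearson coefficients, clipped
to [−1, 1] to absorb floating-point overshoot.  The unit suite asserts
bit-level equality of the edge set across block sizes against a naive
double loop.

Boundary semantics are deliberately asymmetric across the two filters
that mention the number 50:

* intensity filter — *retain* iff max > 50 (a maximum of exactly 50
  "never exceeded" 50, so it is removed);
* reference accretion — *add* iff best bitscore ≤ 50 (a score of exactly
  50 is not "in excess of" 50).

## Markov clustering

The MCL iteration is implemented directly on `scipy.sparse` matrices:

* similarities: raw Pearson r as edge weight (binary weights available by
  passing a graph with unit weights);
* self-loops: added at each node's maximum incident weight — the
  canonical guard against parity effects; isolated nodes get weight 1;
* expansion exponent 2; inflation per configuration (2.2 / 1.7 / 6);
* pruning: entries < 1e-5 zeroed after inflation, columns renormalized —
  required for sparse scaling on graphs with ~10⁶ edges;
* convergence: largest absolute entry change < 1e-6, cap 100 iterations;
  non-convergence returns the current interpretation with a warning and
  `converged=False` on the assignment.

Cluster read-out: attractors are nodes with positive diagonal mass; each
attractor row's support is a candidate cluster, identical supports are
merged, and a node covered by several candidates goes to the candidate
with the largest transition-matrix entry, remaining ties to the candidate
containing the smallest node identifier.  Nodes are processed in sorted
order throughout, so the partition is independent of graph assembly order
and fully deterministic.  Clusters are renamed 1..k by descending size,
ties broken by smallest member identifier; single-member groups are held
separately because cluster counts in this literature are quoted for
n > 1.

Validation: exact separation of disjoint cliques, agreement with an
independently written dense-numpy attractor analysis on 30-node planted
graphs, and recovery of planted atlas clusters (below).  Column-sum
conservation (±1e-9) and the no-cluster-spans-components invariant are
asserted directly.

## 3-D layout

Weighted Fruchterman–Reingold in three dimensions, with edge weights
(correlations) as spring strengths, via networkx's spring-layout
implementation; a single node is placed at the origin by convention.  The
layout is seeded and reproducible but is a visualization aid only: no
quantitative result depends on coordinates, and the only assertions made
are determinism, finiteness and the qualitative property that planted
cliques land closer to themselves than to each other.

## Synthetic atlas

The generator emulates the structures the pipeline is meant to find:

* **tissue-specific clusters** — a shared per-tissue profile, high in the
  target tissues by `fold_change` (default 16) over a baseline (default
  20), baseline elsewhere;
* **pathway clusters** — a shared profile varying smoothly over all
  tissues (uniform ±2 on log2), i.e. correlated across tissues at a range
  of levels;
* **housekeeping clusters** — flat at baseline, so near-uniform after
  noise;
* **unique-profile genes** — genes *defined* as correlating with
  nothing: their linear-scale tissue profiles are rejection-sampled to
  |r| < 0.6 against every planted base profile.  The screen runs on the
  linear scale because exponentiation concentrates variance in the top
  tissue, so log-scale decorrelation alone still yields high linear
  correlations with spike-like tissue profiles.  Chance pairings *among*
  unique genes are left in, as in real data, and are what the
  minimum-component-size filter exists to suppress.

Every gene carries a scale factor drawn log-uniformly over one decade, so
clusters contain members at very different absolute intensities and the
intensity filter at 50 bites meaningfully (baseline 20 × scale up to 10 ×
fold 16 spans both sides of it).  Noise is multiplicative log-normal:
Gaussian with standard deviation `noise_sd_log2` (default 0.25) added on
log2, then exponentiated — the natural noise model for normalized
intensity data.  Replicates within a tissue share the tissue profile and
differ only by noise.

What this does **not** emulate: batch and array-spatial artefacts,
probe-level effects, correlated noise between genes, heavy-tailed
outliers, or partially overlapping cluster membership.  Recovery results
on synthetic data therefore demonstrate the pipeline's correctness and
its behaviour under the stated noise model, not its performance on any
particular real dataset.

The recovery study conditions are 8 tissues × 2 replicates, five 50-gene
tissue-specific clusters at 16-fold, 100 unique genes, noise 0.25; at
r ≥ 0.8 / MCL 2.2 the planted partition is recovered with adjusted Rand
index ≈ 0.96 (the acceptance script recomputes this).  For scoring, each
unique-profile gene is its own ground-truth class (they are defined as
belonging to nothing), and genes absent from the graph count as
singletons.

The signature-mixture fixture expresses each signature gene at level L in
pure source samples and fraction × L in target samples (background genes
flat everywhere); with zero noise the max-ratio statistic inverts the
fraction exactly, and with noise 0.1 log2 over 20 seeds the estimate
stays within a few percent of truth.

## Two-pass regional analysis

The exclusion of pass-1 clusters (contamination, no regional pattern) is
a config-driven list of cluster ids rather than an interactive step:
what was a manual inspect-and-remove becomes explicit and reproducible.
With an empty exclusion list, pass 2 is the identity on pass 1 — asserted
in the suite.

## Signature fraction

The mean over genes of max(source)/max(target) is arithmetic, matching
the plain reading of an "average ratio"; a geometric-mean option exists
because a handful of strongly repressed genes can dominate the arithmetic
mean.  The implied fraction is exactly the reciprocal of whichever mean
was used.  Genes whose target maximum is zero are excluded with a
warning; the "under-expressed" report returns genes above
`fold_cutoff` × mean ratio (default 2 — a gene twice as diluted as the
average is a repression candidate).

## Annotation procedures

The annotation engine consumes precomputed BLAST tabular hits joined to a
subject → (species, symbol) table; it does not run BLAST.  Within each
species the best hit is lowest e-value, ties by higher bitscore, then
subject id.  The e-value cutoff of 1e-9 is stated only for the human tier
in the source procedure; whether it extends to the other symbol tiers is
ambiguous, so the engine applies it to every symbol tier by default with
a flag (`apply_cutoff_all_symbol_tiers=False`) to restrict it to the
human tier.  LOC-prefixed symbols are skipped at all symbol tiers and
usable only in the fallback tier's fixed species order.  The final
"everything else" step accepts any remaining hit, so a query with any
symbol-bearing hit is never left unannotated.

Reference accretion filters each iteration's hits to subjects present in
the reference *at that iteration*, which reproduces sequential
re-alignment semantics from static hit tables; the procedure is
order-sensitive by design and the suite asserts that permuting iterations
changes the outcome on a constructed fixture.

PSR tiling uses n = clamp(round(L/150), 1, 25) near-equal regions
(lengths differing by ≤ 1 nt, exact cover, 0-based half-open
coordinates).  The count formula is an inference from the stated ~150 nt
region size and the 20–25 probes-per-transcript aim; the
`min_psrs_for_probes` parameter records that aim but does not enter the
formula.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
deliberately small scale — a few hundred genes, 10–24 samples, graphs of
a few thousand edges — chosen so the full study (simulation, network,
clustering, both composite analyses, QC) completes in seconds while
exercising every code path, including the chunked-correlation memory
contract at block sizes from 1 to 1000.  The published-census
integration tests run at full scale (~47k probesets, 1.25M edges) when
the deposited matrices are supplied.

## Known limitations

* MCL cluster censuses are sensitive to pruning and self-loop choices;
  agreement with other implementations is expected only up to ~10% in
  cluster counts on large graphs.
* The attractor read-out assigns overlap deterministically; true MCL
  overlap (rare, symmetric graphs) is therefore broken by a tie rule
  rather than reported.
* The layout is a generic weighted force-directed embedding; no attempt
  is made to match any particular tool's "modified" variant.
* The signature-fraction estimate assumes the signature genes are
  expressed *only* by the cell type of interest in the target tissue and
  ignores compositional effects beyond simple dilution.
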