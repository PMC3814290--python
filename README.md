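# pigatlas

Coexpression-network analysis for multi-tissue expression atlases.

Large expression atlases — hundreds of arrays over dozens of tissues and
purified cell populations — are most informative when transcripts are
grouped by the *shape* of their expression profile rather than by
per-tissue lists: genes that rise and fall together across the body tend
to act in the same cell type or pathway (guilt by association).  This
package implements that workflow as a tested, reusable library for
normalized probeset × sample intensity matrices, of the kind produced by
RMA summarization of a tissue-atlas microarray experiment (the motivating
dataset is a pig expression atlas spanning ~60 tissue/cell types,
including a 15-site gastrointestinal series).

## What it computes

**Coexpression graph.** For probesets *g*, *h* with intensity profiles
x_g, x_h over samples, compute the Pearson correlation r(g,h); the graph
G(V,E) keeps an undirected edge {g,h} with weight r whenever
r(g,h) ≥ r_min (0.8 for the whole atlas, 0.9 for the regional analysis;
negative correlations are never edges), and discards connected components
with fewer than 5 nodes.  Correlation is computed in row blocks, so peak
memory is O(chunk × n_probesets) and a ~50k-probeset atlas fits on a
desktop; the edge set is provably independent of the block size.

**Markov clustering (MCL), from scratch.** Build the column-stochastic
matrix M from edge weights (self-loops at each node's maximum incident
weight), then iterate expansion M ← M², inflation (M_ij ← M_ij^I followed
by column renormalization), and pruning of entries < 1e-5, until the flow
converges; clusters are the attractor systems of the limit matrix.  The
inflation exponent I sets granularity: 2.2 for atlas and
transcription-factor networks, 1.7 for the coarser second
gastrointestinal pass, 6 for sample QC.  Clusters are named by descending
size ("Cluster 1" is the largest).

**Sample QC.** A sample–sample correlation graph (edges at r > 0.91, all
probesets) clustered at inflation 6 flags samples that fail to group with
any sample of their own tissue (`mismatched`) or with anything at all
(`isolated`).  Flags are advisory — genuinely distinct samples can sit
apart legitimately.

**Cluster profiling.** Per-cluster mean profiles; block profiles with each
tissue expressed as percent of the maximal tissue, rounded half-up to
multiples of 10; a collapsed graph whose nodes are the largest clusters
and whose edge weights count cross-cluster correlations; a two-pass
regional analysis (intensity filter at 50 → network → MCL → explicit,
config-driven cluster exclusion → second network + MCL pass); and a
transcription-factor sub-network (the standard pipeline restricted to a
TF probeset list).

**Signature fraction.** For a cell-type signature gene set, the per-gene
ratio max(pure population) / max(composite tissue) measures dilution; the
reciprocal of the mean ratio estimates the cell type's share of the
tissue's mRNA (mean ratio ≈ 5 ⇒ ≈ 20%).

**Array annotation.** The array-design procedures over precomputed BLAST
tables: iterative reference accretion (a query joins the reference iff no
alignment against the current reference has bitscore in excess of 50),
probe-selection-region tiling (~150 nt, ≤ 25 per transcript), and the
species-priority symbol assignment (human HGNC at e < 1e-9 first, then a
fixed species order, then any species, with provisional LOC names demoted
to a fallback tier).

**Synthetic atlas.** A first-class generator plants tissue-specific,
housekeeping and pathway clusters plus unique-profile genes, with
per-gene scale factors and multiplicative log-normal noise, and returns
the ground-truth partition — so every stage above can be validated by
recovery, not by eyeball.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
import pigatlas as pa

config = pa.AtlasSimConfig(
    n_tissues=8, replicates_per_tissue=2,
    planted_clusters=tuple(
        pa.PlantedCluster(50, "tissue_specific", (t,), 16.0) for t in range(5)
    ),
    noise_sd_log2=0.25, n_unique_genes=100, seed=0,
)
matrix, meta, truth = pa.generate_atlas(config)
edges = pa.pairwise_pearson(matrix, min_r=0.8)
graph = pa.build_graph(edges, min_component_size=5)
assignment = pa.mcl(graph, pa.MCLParams(inflation=2.2))
```

Running `python examples/01_simulate_and_recover.py` (the script above,
plus scoring) prints:

```
simulated 350 genes x 16 samples
graph: 321 nodes, 6325 edges
MCL: 17 clusters (n>1), largest 50 members
adjusted Rand index vs planted truth: 0.968
(> 0.9 means the planted clusters were essentially recovered intact)
```

All five planted 50-gene clusters come back intact (the largest cluster
has exactly 50 members); the extra small clusters are chance groupings
among the unique-profile genes.  The other scripts in `examples/` walk
sample QC, the two-pass regional analysis, the signature-fraction
statistic and the annotation procedures the same way.

A thin CLI mirrors the library (`pigatlas simulate | qc | network |
cluster | profile | gi | tf | fraction`); run `pigatlas --help`.

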