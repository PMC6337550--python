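# Methods

This note documents the algorithmic conventions, the synthetic-data
model, and the reasoning behind the default parameters.

## ADME screen

A compound passes when all five parameters meet their thresholds
(inclusive `>=`): oral bioavailability ≥ 30 %, drug-likeness ≥ 0.18,
Caco-2 ≥ −0.4, blood-brain barrier ≥ −0.3, half-life ≥ 4 h. Records
with missing or NaN parameters raise a validation error naming the
compound and field — silent drops would corrupt downstream counts.
A whitelist of literature-supported compounds rescues screen failures;
the active set is the disjoint union of passes and rescues.

## Centrality conventions

All six measures follow the conventions of the CytoNCA plugin so that
median-threshold hub screening behaves as in published formula studies:

- **DC** — raw degree (integer, not normalized).
- **BC** — betweenness without normalization
  (`networkx.betweenness_centrality(normalized=False)`).
- **CC** — closeness with the Wasserman-Faust component correction
  (`wf_improved=True`), so disconnected graphs stay comparable.
- **EC** — the leading eigenvector of A + I, computed by power
  iteration from the all-ones vector, L2-normalized, tolerance 1e−10,
  at most 1000 iterations (`ConvergenceError` carries the iteration
  count). Shifting by I makes the matrix primitive on bipartite
  components; when the leading eigenspace is degenerate the limit is
  the normalized projection of the start vector onto that eigenspace,
  which is what the implementation converges to and what the test
  oracle computes directly from a dense eigendecomposition.
- **NC** — sum over incident edges of the edge clustering coefficient
  z(u,v) / min(deg u − 1, deg v − 1), where z is the number of
  triangles through the edge; a zero denominator contributes 0.
- **LAC** — the mean degree of the subgraph induced by a node's
  neighborhood, i.e. average within-neighborhood connectivity.

Every measure is verified against brute-force oracles (explicit
shortest-path enumeration, dense eigensolve, triangle counting) on 200
random graphs with at most 12 nodes at absolute tolerance 1e−8.

## Hub screening

Default: a node survives when each of the six features strictly exceeds
the feature's network-wide median (numpy median; even counts give the
midpoint of the central pair). The classic degree rule — degree
strictly greater than twice the median degree — is available standalone
or as a prefilter. Strict comparison means a perfectly regular network
has no hubs, which is the intended reading of "above the median".

## Enrichment

Right-tail hypergeometric p-values are computed in log space with
`math.lgamma` and a manual log-sum-exp, exact to ~1e−13 relative error
against integer arithmetic over every valid (k, K, n, N) with N ≤ 60.
Multiple-testing corrections (Benjamini-Hochberg, Holm) come from
`statsmodels.stats.multitest.multipletests`. Significant terms are
grouped by Cohen's κ on 2×2 membership tables over the universe
(degenerate chance agreement p_e = 1 yields κ = 1 for identical sets,
0 otherwise), single linkage at κ ≥ 0.4; each group's representative is
its lowest-p member.

## Synthetic data model

One seed drives five independent `numpy` generator streams (compound
table, interactome, target map, disease genes, annotations) via
`SeedSequence([seed, stream])`, so regenerating any one input is stable
against changes in the others.

- **Compound table** — exactly `round(pass_fraction * n_compounds)`
  compounds pass; each failing compound has a known sub-threshold
  parameter, cycling through all five so every boundary is exercised;
  exactly `n_whitelisted` failures carry the rescue flag.
- **Interactome** — Barabási-Albert preferential attachment
  (`ba_m = 3`) over 500 nodes; hub screening is only informative on
  heavy-tailed degree distributions. A random subset of
  `planted_module_size` nodes receives extra edges until its induced
  density reaches `planted_module_density` (0.9).
- **Target map** — exactly `n_ct_edges` distinct (compound, target)
  pairs over the active compounds, covering all `n_targets` pool
  proteins; 60 % of the planted module lies in the target pool.
- **Disease genes** — exact planted overlaps with the module and the
  target pool (module picks prefer genes that are also targets, so one
  gene can satisfy both quotas); the remainder are fresh symbols absent
  from the interactome, as real disease lists always exceed any one
  interactome.
- **Annotations** — every term includes each universe gene with
  probability 0.05; the planted term multiplies the membership odds by
  50 inside the module.

### Default scale and the module-size choice

The defaults mirror a 16-herb formula study: 1005 compounds, 63 passes,
31 rescues, 287 targets, 1846 compound-target associations, 354 disease
genes, 41 shared symbols.

The planted module size (60 of 500 nodes) is a design parameter of the
recoverability contract, not a fit to any dataset. The six-feature
median filter necessarily admits a background of high-degree
Barabási-Albert hubs: in the sparse core PPI network the NC and LAC
medians are zero, so roughly two dozen well-connected background nodes
pass every median no matter where the module sits. Hub/module agreement
(Jaccard) therefore scales like `module_size / (module_size + ~25)`. A
module of 60 nodes puts the expected agreement comfortably above 0.7
while remaining a small minority (12 %) of the interactome; a module
half that size would sit at the edge of the background noise floor and
make recovery a coin flip rather than a property of the algorithm.

## Pipeline and determinism

`run_pipeline` executes screen → targets → CT network → PPI expansion
(depth 1 by default, both sides) → intersection merge → centrality →
median-filter hubs → enrichment, writing every intermediate artifact.
A stage failure aborts with the stage name; completed artifacts are
retained. Every writer sorts its output, the report contains no
timestamps, and the provenance block (config digest + seed) makes
reruns with the same configuration byte-identical.

## Limitations

Synthetic symbols and uniform ADME draws carry no biology; the 500-node
interactome cannot reproduce the network sizes of database-scale
studies, which depend on external interaction snapshots. Those figures
are treated as documented reference values, not reproduction targets.
The generator plants one enriched term and one dense module; real
pathway structure is overlapping and hierarchical.
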