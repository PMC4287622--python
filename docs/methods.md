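# Methods

## Problem and model

The package analyses muscle-invasive bladder cancer (MIBC) as a *disease
module*: the hypothesis that genes reported altered across heterogeneous
molecular studies are not scattered over the interactome but concentrate in a
connected neighbourhood, whose pathway annotations describe the disease
process. The pipeline is a funnel:

studies → screened studies → raw features → unique symbol catalogue →
network-present members → connected subgraph → enriched pathways →
known/novel split → literature-relevance ranking.

## Study screening and consolidation

A study is retained iff its sample size is at least 50 (inclusive) and, for
profiling layers, its reported maximum absolute fold change exceeds 2
(strict). Literature curation and DNA mutation screens have no fold-change
semantics and are exempt; a profiling study that reports no fold change is
rejected, since the rule cannot be verified. Raw identifiers are mapped to
official uppercase symbols by a layer-dictated route — metabolomics features
enter as enzymes of the altered metabolites (`metabolite_enzyme`), miRNA
features as their targets (`mirna_target`), all others directly. Unmappable
identifiers are reported, never silently dropped. Consolidation unions
provenance triples (study, layer, route) per symbol; the catalogue records
both the input count and the unique count. `exclude_indirect` removes
symbols supported *only* by indirect routes before network analysis, on the
grounds that enzyme- and target-inference carry weaker evidence of direct
involvement.

## Interactome and connectivity filter

Source edge lists are merged into one simple undirected graph over symbols
with per-edge source provenance. Self-loops are removed at merge time but
their endpoint node is kept, so the node set is exactly the union of endpoint
symbols and a self-interaction can never satisfy the connectivity filter.
The induced subgraph keeps only edges with both endpoints in the feature set
(no neighbour expansion); the connectivity filter then drops members with
degree 0 in a single pass — removing an isolated node cannot isolate another.

## Enrichment statistics

Per term, the p-value is the exact two-sided minimum-likelihood
hypergeometric tail: with X ~ Hypergeometric(N, K, n) and observed overlap k,
p = Σ P(X = x) over all achievable x with P(X = x) ≤ P(X = k). It is
computed from the log-pmf over the full support with a log-sum-exp reduction.
Numerical choices:

- **Tie tolerance.** Probability-mass ties at symmetric support points are
  exact in rational arithmetic but not in floating point; a pmf value is
  included if log P(X=x) ≤ log P(X=k) + log(1 + 10⁻⁹). For integer-ratio
  pmfs, accidental near-ties at that tolerance are a measure-zero concern.
- **Degenerate support.** When every support point ties with the observation
  the function returns exactly 1.0 rather than the rounded log-space sum.
- **Cross-check.** The test suite and the acceptance script compare the
  implementation against an independent oracle that enumerates the support
  with integer binomial coefficients (`math.comb`) and sums as an exact
  `Fraction`; the observed maximum absolute deviation over 1,000 random
  tuples with N ≤ 500 is below 10⁻¹².
- A tail-doubling variant (2·min(lower, upper tail), capped at 1) is
  available via `EnrichmentConfig.two_sided_method = "doubling"`.

**Family size.** Bonferroni correction multiplies by m = the number of
*candidate* terms: every term that survives the name blacklist and the
optional size filters and has at least one gene in the background. The
reporting threshold `min_overlap` (default 3) governs which terms appear in
the output, **not** the family size. This is a deliberate design choice: if
m counted only terms with k ≥ min_overlap, the family would be selected by
the data — terms enter precisely because their overlap is in the upper tail,
and are then corrected over that small family alone. In a null simulation
(uniform 30-gene queries from a 500-gene background, 100 terms of size
10–40, 500 replicates) that variant produced a false positive in 8.2% of
replicates at α = 0.05; counting all candidates restores control (1.4%
observed). A term is significant iff p·m ≤ α **and** k > nK/N (enrichment
direction only; depletion is reported but never called significant).

**Blacklist and classification.** Umbrella disease terms (e.g. generic
cancer pathways) are removed by case-insensitive substring blacklist before
testing, so they neither appear nor consume family size. Known/novel labels
come from normalized term-name matching against a literature pathway list;
normalization lowercases, strips punctuation, collapses whitespace and
harmonizes the British/American "signalling"/"signaling" spellings, which
the source tables mix.

**Pathway-overlap network.** Nodes are the significant terms (weight k);
an edge joins two terms iff their query-overlap gene sets share ≥ 1 gene,
annotated with the shared symbols — a coarse proxy for cross-pathway
interaction.

## Literature evidence

A gene2pubmed-style table (taxon-filtered to 9606) is joined to symbols via
a gene-ID map and restricted to a phenotype-relevant publication list.
Pathway relevance is the fraction of member genes with ≥ 1 relevant
publication; pathways are ranked by (ratio desc, k desc, term_id asc), genes
by (publication count desc, symbol asc). Ties are broken deterministically
everywhere (stable sorts with full key chains), so all outputs are
reproducible.

## Synthetic benchmark

`mibcnet.synthetic` generates a fully self-contained input bundle with known
ground truth:

- **Network:** Barabási–Albert scale-free graph (default n = 2,000, m = 3;
  an Erdős–Rényi option exists). A 50-gene module is planted and forced
  connected by adding a random spanning path among its members.
- **Studies:** 10 studies cycling through 7 omics layers; each reports a
  module gene with probability π = 0.8 and a background gene with
  ρ = 0.01, with metadata that passes the screening rules.
- **Pathways:** 200 terms of size 10–50; 5 planted terms draw half their
  members from the module, the rest uniformly from the background.
- **Literature:** module genes receive Poisson(3) relevant publications with
  probability 0.9; background genes are linked at rate 0.01.

The defaults *are* the benchmark conditions; they model a strong-signal
regime and are not tuned to the pipeline. What the generator does **not**
emulate: realistic interactome topology beyond the degree distribution
(no clustering structure, no literature-bias in edge coverage), correlated
study errors, identifier-mapping ambiguity (the raw→symbol map is a
bijection), or overlapping/nested pathway hierarchies. Recovery numbers on
this benchmark are therefore upper bounds on real-data behaviour.

## Problem sizes used in verification

The null-FWER simulation runs 500 replicates on a 500-gene background with
100 terms (query 30); planted recovery runs 20 seeded pipelines at the
default strong-signal regime. These sizes were chosen to give informative
binomial bounds while staying well inside the runtime budget; they are the
package's own verification conditions, fixed before the measurements and not
adjusted afterwards. All derived seeds are drawn below 2³¹.

## Bundled published tables and their internal inconsistencies

`mibcnet.published` stores the printed KEGG pathway member lists of the MIBC
interactome literature verbatim, alongside the printed per-row counts. The
two disagree for several rows (Endocytosis counted 16 vs 13 listed;
Neurotrophin 13 vs 12; Serotonergic 12 vs 11; multi-study Focal adhesion 16
vs 11). Additionally the source prose claims Endocytosis and Serotonergic
synapse share no protein-coding gene while HRAS appears in both printed
lists — jointly impossible with the prose's other overlap claims. The
package keeps both representations but computes every derived quantity from
the member lists; the contradiction is documented by an intentionally red
acceptance test.

## Limitations

- The exact 1,279 → 72 consolidation funnel of the original MIBC corpus
  cannot be recomputed here: the per-study supplementary workbooks are not
  redistributable and are not bundled. The funnel machinery is instead
  verified on hand-traced and synthetic fixtures.
- Bonferroni is conservative under correlated terms (KEGG pathways overlap
  heavily); no FDR option is provided because the reported analyses used
  family-wise control.
- The connectivity filter is a one-shot degree filter, not a module-finding
  algorithm; it cannot recover features whose interactions are simply
  missing from the source databases (literature bias).
- Known/novel classification is name-based; pathways renamed between
  database releases must be harmonized upstream.
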