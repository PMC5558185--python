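# Methods

## Model

`pdrank` treats rare-disease gene prioritization as evidence accumulation
over a typed knowledge graph. Nodes are genes, diseases and phenotype/process
terms; a node may be both disease and phenotype (a phenotype that has its own
downstream phenotypes). Edges are gene→disease (GD, causal or correlated
association), disease→phenotype (DP), and process-hierarchy (PH) edges from
more general to more specific terms. Only the PH sub-graph is required to be
acyclic; GD and DP edges are exempt. Role flags are declared in the node
table and cross-checked against incident edges at load time, because
dual-role nodes cannot be inferred from edges alone.

A run takes a phenotype set *P* (mapped from free text / identifiers) and a
gene set *G* (variants surviving the filter cascade) and proceeds:

1. *Candidate diseases.* D = all diseases one GD edge from a gene in G, each
   carrying back-references to its implicating genes.
2. *Constrained shortest paths.* From each phenotype in P, a breadth-first
   search finds all shortest paths into each disease of D, where a move is
   either a DP edge traversed phenotype→disease or a PH edge traversed in
   either direction, no intermediate node may belong to D (other than the
   start phenotype itself), the final move must be a DP traversal, and depth
   is capped at `max_path_length` = 4 edges. PH edges are deliberately
   traversed both up and down: a phenotype often reaches a disease by
   generalizing one step and specializing again (e.g. unilateral renal
   agenesis → dysgenesis → unilateral renal dysgenesis → disease).
3. *Scoring and ranking.* S(d) = Σ w_s·w_p over connected phenotypes, with
   w_s = 1/(1 + b·log10(max(1, N))) and w_p = a^(L−1). Each phenotype counts
   once per disease at its shortest length even when several equal-length
   paths exist; all shortest paths are retained for the evidence
   sub-network. Diseases connected to no phenotype within the cap are
   dropped. The logarithm makes w_s respond to the order of magnitude of a
   phenotype's disease count without suppressing unspecific phenotypes
   entirely; the geometric path decay encodes falling confidence per
   traversed link.

Restricting the search to D (rather than scoring all diseases and
intersecting with G afterwards) is an efficiency device only; with D fixed,
both computations give identical scores, and a test asserts this.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `a` | 0.75 | path-weight decay per extra edge, in (0, 1] |
| `b` | 1.0 | specificity decay per decade of disease count, ≥ 0 |
| `max_path_length` | 4 | admissible path cap (edges) |
| `table_limit` | 50 | disease/gene pairs kept in the result table |
| `variants_per_gene_limit` | 5 | variant rows shown per pair |

All are dimensionless. `a` near 1 floods the ranking with loosely connected
diseases; small `a` reduces the method to direct-match counting. Parameters
come from a flat YAML config; explicit overrides beat the config, which
beats defaults.

Boundary conventions: w_p is exactly 1 at L = 1 (direct links, and the case
where the phenotype *is* the candidate disease — recorded as L = 1 with a
degenerate one-node evidence path). For a phenotype-as-disease candidate,
w_s is still computed from the node's own DP in-degree; forcing it to 1 was
the open alternative, but computing it keeps w_s a pure function of the
node and we document rather than special-case it. w_s is exactly 1 for
N ∈ {0, 1}.

## Term mapping

Surfaces are canonicalized by case-folding, mapping hyphens/underscores to
spaces, and collapsing whitespace; matching is then exact lookup with
precedence identifier > primary name > synonym. Identifier-shaped inputs
(`HP:0000213`-style, including the generator's `HPX:` ids) resolve against
primary then alternate identifiers and do not fall through to name lookup.
Same-kind surface collisions onto different nodes are detected at lexicon
build time and resolve to "no match" with a diagnostic — silent arbitrary
resolution would corrupt scores. Edit-distance matching is out of scope:
normalization plus synonyms is the documented matching behaviour, and
anything stronger belongs in an interactive front end.

## Variant filtering

Filters are pointwise predicates, so the survivor set is order-independent
and only the trace depends on the canonical order confidence → common →
deleterious → (de novo). Conventions: call quality is the VCF QUAL column;
quality exactly 20 is retained, missing quality removed. A variant is
common if *any* population source exceeds 0.5% (configurable to all-source
mode); frequency exactly at the threshold is retained; absent frequencies
count as rare. The de-novo filter requires both parents explicitly
homozygous-reference; a missing parental genotype removes the variant.
Multi-allelic records are decomposed per alt without left-normalization
(inputs are assumed normalized); each decomposed record projects the
genotype onto its own alt. Recessive-consistency uses gene-level counting
(≥ 2 distinct heterozygous variants) as a compound-heterozygosity proxy —
phase is not assessed, and the output labels reflect only this proxy.

## Result table

Rows are unique disease–gene–variant combinations, replicated per gene and
per variant; rows of one disease share its score and breakdown. Truncation
counts disease/gene *pairs* (limit 50) and always keeps a prefix of the
full ranking; within a pair at most 5 variants are shown, ordered
pathogenic > likely pathogenic > DM > loss/gain-of-function > missense,
then by position. Ranking ties break by contribution count, then
lexicographic disease id; contributions are summed in phenotype-id order in
double precision, making repeated runs byte-identical. The per-run
JSON-lines log records mapping results, filter traces, |D| and drop counts.

## Synthetic data

The generator emulates the structural statistics of a large curated
knowledge base at roughly 1/20 node scale with degree means preserved:
240 diseases, 290 phenotypes, 900 genes, Poisson(43.4) phenotypes per
disease, Poisson(6.8) diseases per gene (both clamped to ≥ 1), 6% of
phenotypes dual-role with a few downstream phenotypes, and a 4-level random
PH forest. Preserving the disease/phenotype ratio keeps the mean diseases
per phenotype near 36, so specificity weights span a realistic range.
Poisson is a minimal-assumption choice — only means and maxima of the
reference statistics are known, not distribution shapes — so any
heavy-tail-sensitive conclusion would need a different generator; node
counts, means and the dual-role fraction are all parameters.

Planted cases draw `n_true` phenotypes (default 5, a typical physician
list) from a chosen disease's DP neighbours, optionally swap some for PH
neighbours to exercise hierarchy traversal, add uniform noise phenotypes
sampled outside the disease's own phenotype set (so "noise" is
well-defined), and emit a toy VCF whose causal-gene variant passes every
filter alongside filter-passing decoy variants in distinct random genes.
Generated lexicons are collision-free by construction. Everything is a pure
function of (params, seed) via `numpy.random.default_rng`.

What passing recovery tests shows — and does not. Recovery experiments
demonstrate that the implementation recovers planted signal under the
generator's idealized conditions: complete and correct phenotype
annotation, independent Poisson attachment, noiseless variant annotation.
Real knowledge bases have hub structure, correlated phenotypes, annotation
gaps and literature bias, so recovery fractions here say nothing
quantitative about clinical sensitivity; they validate the machinery, not
the knowledge content.

## Numerical and degenerate-input choices

Scores are double precision; score-vs-breakdown agreement is asserted to
1e-12. Ranking compares floats exactly after deterministic summation.
Degenerate inputs have named outcomes rather than silent empties: empty
phenotype list, zero mapped terms, zero surviving variants, and an
unconnectable candidate set each raise a distinct error (CLI exit code 3
for empty-result conditions, 2 for malformed input). Unknown gene ids in
the candidate query are reported and skipped, not fatal. The brute-force
path-enumeration oracle used in tests explicitly forbids revisiting any
node, which matches shortest-path semantics (a shortest path can never
repeat a node).

## Problem sizes used in the test suite

Oracle-equivalence checks run on 200 random graphs of at most 60 nodes —
small enough for exhaustive enumeration of all admissible simple paths up
to length 4 to stay trivially fast while covering dual-role nodes, forests
and dense DP attachment. Recovery experiments use the default 1/20-scale
network with 50 replicates (zero-noise) and 200 replicates (moderate
noise); these sizes give binomial standard errors below 0.04 on the
reported fractions.

## Known limitations

No gene–gene relationship expansion (a gene without a curated GD edge can
never be ranked, so novel disease genes are out of reach by design); no
probabilistic interpretation of S; variant-level evidence is deliberately
kept out of the score and shown alongside it; structural variants and
annotation services are out of scope; OBO ingestion covers `is_a`
hierarchy only.
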