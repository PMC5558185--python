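# pdrank

Phenotype-driven ranking of candidate diseases and genes for rare-disease
sequencing analysis.

Given (1) a patient's observed phenotypes and (2) the genes carrying rare,
predicted-deleterious variants after a standard filter cascade, `pdrank`
scores every disease implicated by those genes against the phenotypes using
a phenotype–disease–gene knowledge graph, and returns a rank-ordered table
of disease / gene / variant candidates with a per-phenotype score breakdown
and an evidence sub-network. It is aimed at clinical-genomics analysts and
method developers who need a transparent, deterministic phenotype-match
score rather than a black-box prioritizer.

## The score

The knowledge graph has gene→disease (GD), disease→phenotype (DP) and
general-term→specific-term hierarchy (PH) edges; some phenotypes act as
diseases themselves. For a candidate disease *d* (implicated via a GD edge by
a variant-impacted gene) and the mapped phenotype set *P*:

```
S(d) = Σ_{i ∈ P connected to d}  w_s(i) · w_p(i)

w_s(i) = 1 / (1 + b·log10(max(1, N_i)))     specificity weight
w_p(i) = a^(L_i − 1)                        path weight
```

where `N_i` is the number of diseases directly associated with phenotype
*i* (its DP in-degree) and `L_i` is the length of the shortest admissible
path from *i* to *d*: DP edges traversed phenotype→disease, PH edges in
either direction, no other candidate disease en route, final edge a DP
traversal, and `L ≤ 4` (diseases reachable only beyond that are dropped).
Defaults `a = 0.75`, `b = 1`. Specific phenotypes (small `N`) and direct
associations (`L = 1`) therefore dominate the score; a phenotype that is
itself a candidate disease counts as a direct link.

Upstream of scoring, variants pass a confidence filter (call quality ≥ 20),
a common-variant filter (population allele frequency ≤ 0.5% in 1000
Genomes / EVS / ExAC / AFC), a predicted-deleterious filter (published
pathogenic or likely pathogenic, HGMD DM, loss/gain-of-function
consequence, or missense) and, optionally, a trio de-novo restriction.

## Worked example

`python examples/worked_case.py` builds an 11-node graph in which one
syndrome explains five observed phenotypes — one of them only through two
intermediate hierarchy terms — and prints:

```
rank  disease     score     gene    moi       consistent
1     SYNDROME_X  4.3311    GENE_A  dominant  yes
2     SYNDROME_Y  0.7686    GENE_B  unknown   unknown

score breakdown of the top disease (w_s * w_p per phenotype):
  hirsutism                   N=2 L=1 -> 0.7686
  meningomyelocele            N=1 L=1 -> 1.0000
  prominent_nose              N=1 L=1 -> 1.0000
  renal_agenesis              N=0 L=3 -> 0.5625
  retrognathia                N=1 L=1 -> 1.0000
```

Four phenotypes are direct, specific matches (contribution 1.0 each);
`hirsutism` is shared with the competitor disease so its specificity weight
drops to 1/(1+log10 2) ≈ 0.769; `renal_agenesis` connects only through a
three-edge hierarchy path and contributes 0.75² = 0.5625. The causal pair
tops the table and the evidence sub-network names the two intermediate
terms. The other examples show the filter cascade trace
(`examples/filter_cascade.py`) and a planted-case recovery experiment
(`examples/simulate_recovery.py`).

## Library and CLI

The primary interface is the Python API (`pdrank.rank_case`,
`pdrank.run_pdr`, plus the module-level operations it composes:
`load_graph`, `Lexicon.map_phenotype_list`, `apply_filter_cascade`,
`constrained_shortest_paths`, `score_candidates`, `evidence_subnetwork`,
`generate_network`, `plant_case`, `recovery_experiment`). A thin `pdrank`
CLI wraps it with subcommands `build-graph`, `map-terms`,
`filter-variants`, `rank` and `simulate` (exit codes: 0 success, 2 input
error, 3 empty result). File formats are plain TSV node/edge/lexicon
tables, a one-term-per-line phenotype file, and VCF 4.x with a TSV
annotation sidecar; see `docs/methods.md` for details and for all scoring
parameters.

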