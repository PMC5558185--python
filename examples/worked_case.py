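"""Rank candidate diseases for a small clinic-like case.

Builds a miniature knowledge graph in which one syndrome explains five
observed phenotypes — one of them only through two intermediate hierarchy
terms — while a competitor disease shares a single phenotype, then runs the
full ranking and prints the table plus the evidence sub-network of the top
hit.
"""

from pdrank import (KnowledgeGraph, Lexicon, LexiconEntry, NetworkEdge,
                    NetworkNode, AnnotatedVariant, evidence_subnetwork,
                    rank_case)


def node(nid, role, name=None):
    return NetworkNode(id=nid, name=name or nid, is_gene=role == "g",
                       is_disease=role == "d", is_phenotype=role == "p")


nodes = [
    node("GENE_A", "g"), node("GENE_B", "g"),
    node("SYNDROME_X", "d"), node("SYNDROME_Y", "d"),
    node("meningomyelocele", "p"), node("renal_agenesis", "p"),
    node("prominent_nose", "p"), node("hirsutism", "p"),
    node("retrognathia", "p"), node("dysgenesis", "p"),
    node("unilateral_renal_dysgenesis", "p"),
]
edges = [NetworkEdge(*e) for e in [
    ("GENE_A", "SYNDROME_X", "GD", "causal", "dominant"),
    ("GENE_B", "SYNDROME_Y", "GD"),
    ("SYNDROME_X", "meningomyelocele", "DP"),
    ("SYNDROME_X", "prominent_nose", "DP"),
    ("SYNDROME_X", "hirsutism", "DP"),
    ("SYNDROME_X", "retrognathia", "DP"),
    ("SYNDROME_X", "unilateral_renal_dysgenesis", "DP"),
    # renal agenesis reaches SYNDROME_X only via the hierarchy:
    # up to "dysgenesis", down to "unilateral renal dysgenesis", then DP
    ("dysgenesis", "renal_agenesis", "PH"),
    ("dysgenesis", "unilateral_renal_dysgenesis", "PH"),
    ("SYNDROME_Y", "hirsutism", "DP"),
]]
graph = KnowledgeGraph(nodes, edges)

lexicon = Lexicon([
    LexiconEntry("Meningomyelocele", "meningomyelocele", "primary_name"),
    LexiconEntry("Unilateral renal agenesis", "renal_agenesis", "primary_name"),
    LexiconEntry("Prominent nose", "prominent_nose", "primary_name"),
    LexiconEntry("Hirsutism", "hirsutism", "primary_name"),
    LexiconEntry("excess body hair", "hirsutism", "synonym"),
    LexiconEntry("Retrognathia", "retrognathia", "primary_name"),
])

observed = ["Meningomyelocele", "Unilateral renal agenesis", "Prominent nose",
            "excess body hair", "Retrognathia"]

# one de-novo-like pathogenic variant per gene survives the filter cascade
variants = [
    AnnotatedVariant(chrom="22", pos=41513, ref="C", alt="T", call_quality=88,
                     genotype="het", classification="pathogenic",
                     consequence="stop_gain", gene="GENE_A"),
    AnnotatedVariant(chrom="3", pos=9200, ref="G", alt="A", call_quality=71,
                     genotype="het", consequence="missense", gene="GENE_B"),
]

table, mapping, trace = rank_case(graph, lexicon, observed, variants)

print(f"mapped {len(mapping.mapped)}/{len(mapping.matches)} phenotype terms")
print("\nrank  disease     score     gene    moi       consistent")
for row in table.rows:
    print(f"{row.rank:<5} {row.disease:<11} {row.score:<9.4f} {row.gene:<7} "
          f"{row.moi:<9} {row.moi_consistent}")

top = table.scores[0]
print("\nscore breakdown of the top disease (w_s * w_p per phenotype):")
for c in top.contributions:
    print(f"  {c.phenotype:<27} N={c.n_diseases} L={c.shortest_length} "
          f"-> {c.contribution:.4f}")

sub = evidence_subnetwork(top, graph)
inter = sorted(n for n, r in sub.nodes.items() if r == "intermediate")
print(f"\nevidence sub-network: {len(sub.nodes)} nodes, {len(sub.edges)} edges")
print(f"intermediate hierarchy terms on the paths: {', '.join(inter)}")
print("\nThe syndrome matching all five phenotypes ranks first; the phenotype")
print("routed through two hierarchy terms contributes 0.75^2 = 0.5625, and the")
print("phenotype shared with the competitor is down-weighted by its specificity.")
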