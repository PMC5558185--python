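"""Planted-case recovery experiment on a synthetic knowledge graph.

Generates a seeded network whose degree structure mimics a curated
knowledge base at small scale, plants solved patient cases (the causal
disease's phenotypes plus uniform noise terms, one causal variant among
decoys), runs the full pipeline on each replicate, and reports how often the
planted causal gene is recovered in the top ranks.
"""

from pdrank import NetworkGenParams, PlantedCaseParams, recovery_experiment

gen = NetworkGenParams(n_genes=300, n_diseases=120, n_phenotypes=150,
                       mean_phenotypes_per_disease=20.0,
                       mean_diseases_per_gene=4.0, seed=42)

for label, case in [
    ("no noise, no decoys",
     PlantedCaseParams(n_true_phenotypes=5, seed=1000)),
    ("5 noise terms, 20 decoy genes",
     PlantedCaseParams(n_true_phenotypes=5, n_noise_phenotypes=5,
                       decoy_variant_count=20, seed=1000)),
]:
    res = recovery_experiment(gen, case, n_reps=50, k_list=(1, 5, 10))
    print(f"\n{label} (50 replicates):")
    for k, (frac, se) in res.fractions.items():
        print(f"  causal gene in top {k:>2}: {frac:5.2f} +/- {se:.2f}")

print("\nWith clean phenotype lists the causal gene is found immediately;")
print("noise phenotypes and decoy genes dilute the ranking but the gene")
print("stays near the top because direct, specific phenotype matches")
print("outweigh the incidental long-path matches of decoy diseases.")
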