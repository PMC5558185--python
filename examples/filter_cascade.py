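"""Run the variant filter cascade on a toy VCF and show the trace.

Writes a six-variant single-sample VCF plus its annotation sidecar, reads
them back, and applies the confidence (quality >= 20), common-variant
(allele frequency <= 0.5% in every population source) and
predicted-deleterious filters, printing how many variants each step removes
and the resulting variant-impacted gene set.
"""

import tempfile
from pathlib import Path

from pdrank import (AnnotatedVariant, apply_filter_cascade, read_variants,
                    variant_genes, write_sidecar, write_vcf)

variants = [
    AnnotatedVariant("1", 1000, "A", "G", call_quality=12.0, genotype="het",
                     consequence="missense", gene="GENE1"),      # low quality
    AnnotatedVariant("1", 2000, "C", "T", call_quality=80.0, genotype="het",
                     freqs={"KG1000": 0.03}, consequence="missense",
                     gene="GENE2"),                              # common
    AnnotatedVariant("2", 3000, "G", "A", call_quality=55.0, genotype="het",
                     classification="vus", consequence="other",
                     gene="GENE3"),                              # not deleterious
    AnnotatedVariant("2", 4000, "T", "C", call_quality=90.0, genotype="het",
                     classification="pathogenic", consequence="missense",
                     freqs={"EXAC": 0.0001}, gene="GENE4"),      # survives
    AnnotatedVariant("3", 5000, "A", "T", call_quality=60.0, genotype="hom_alt",
                     consequence="frameshift", gene="GENE5"),    # survives (LoF)
    AnnotatedVariant("3", 6000, "G", "C", call_quality=60.0, genotype="het",
                     hgmd_dm=True, consequence="other", gene="GENE5"),  # survives (DM)
]

with tempfile.TemporaryDirectory() as tmp:
    vcf, sidecar = Path(tmp) / "case.vcf", Path(tmp) / "sidecar.tsv"
    write_vcf(variants, vcf)
    write_sidecar(variants, sidecar)
    loaded = read_variants(vcf, sidecar)

survivors, trace = apply_filter_cascade(loaded)
print("filter step            in -> out   removed")
for step in trace.steps:
    print(f"{step.name:<22} {step.n_in:>2} -> {step.n_out:<2}    "
          f"{', '.join(step.removed_keys) or '-'}")

genes, _ = variant_genes(survivors)
print("\nvariant-impacted gene set G:")
for gene, gvs in genes.items():
    print(f"  {gene}: {', '.join(v.key for v in gvs)}")
print("\nEach step removes variants for one reason only (quality, population")
print("frequency, predicted impact); the survivors define the genes whose")
print("diseases the ranking algorithm will score.")
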