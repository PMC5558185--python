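"""Variant filter cascade producing the variant-impacted gene set.

Mirrors the pre-configured rare-disease cascade: a confidence filter (call
quality < 20 removed), a common-variant filter (population allele frequency
> 0.5% in any of 1000 Genomes, NHLBI-EVS, ExAC, or the Allele Frequency
Community removes the variant), a predicted-deleterious filter (keep
published pathogenic/likely-pathogenic, HGMD DM, loss/gain-of-function
consequences, or missense), and an optional trio de-novo restriction.

Variants arrive as VCF 4.x plus a TSV annotation sidecar keyed by
chrom:pos:ref:alt; pathogenicity classification is consumed as annotation,
never computed here. Multi-allelic sites are decomposed without
left-normalization — inputs are assumed normalized.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import pysam

FREQ_SOURCES = ("KG1000", "EVS", "EXAC", "AFC")
_SIDECAR_FREQ_COLS = {"freq_1000g": "KG1000", "freq_evs": "EVS",
                      "freq_exac": "EXAC", "freq_afc": "AFC"}
SIDECAR_COLUMNS = ["key", "gene", "classification", "hgmd_dm", "consequence",
                   "freq_1000g", "freq_evs", "freq_exac", "freq_afc"]

CLASSIFICATIONS = ("pathogenic", "likely_pathogenic", "vus",
                   "likely_benign", "benign")
LOF_CONSEQUENCES = frozenset({"frameshift", "start_loss", "start_gain",
                              "stop_loss", "stop_gain", "splice_site"})
CONSEQUENCES = tuple(sorted(LOF_CONSEQUENCES)) + ("missense", "other")

GENOTYPES = ("het", "hom_alt", "hemi", "hom_ref", "missing")


class VariantError(Exception):
    pass


class TrioDataMissingError(VariantError):
    """Parental genotypes unavailable; skip the optional de-novo filter."""


@dataclass(frozen=True)
class AnnotatedVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    call_quality: float | None = None
    genotype: str = "missing"
    freqs: dict[str, float] = field(default_factory=dict)
    classification: str | None = None  # None = absent annotation
    hgmd_dm: bool = False
    consequence: str | None = None
    gene: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        if not self.alt:
            raise ValueError("empty alt allele")
        for src, f in self.freqs.items():
            if src not in FREQ_SOURCES:
                raise ValueError(f"unknown frequency source {src!r}")
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency {f} outside [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class TrioGenotypes:
    """Per-variant-key genotypes for proband, mother, father."""

    proband: dict[str, str]
    mother: dict[str, str]
    father: dict[str, str]


@dataclass
class FilterStep:
    name: str
    n_in: int
    n_out: int
    removed_keys: list[str]


@dataclass
class FilterTrace:
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, before: list[AnnotatedVariant],
            after: list[AnnotatedVariant]) -> None:
        kept = {v.key for v in after}
        self.steps.append(FilterStep(
            name=name, n_in=len(before), n_out=len(after),
            removed_keys=[v.key for v in before if v.key not in kept]))


def _classify_genotype(alleles: tuple) -> str:
    called = [a for a in alleles if a is not None]
    if not called:
        return "missing"
    if len(called) < len(alleles):
        return "missing"  # partial call treated as missing
    if len(called) == 1:
        return "hemi" if called[0] > 0 else "hom_ref"
    n_alt = sum(1 for a in called if a > 0)
    if n_alt == 0:
        return "hom_ref"
    return "hom_alt" if all(a > 0 for a in called) else "het"


def _read_sidecar(path: str | Path) -> dict[str, dict]:
    rows: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != SIDECAR_COLUMNS:
            raise VariantError(
                f"{path}:1: expected header {SIDECAR_COLUMNS}, got {reader.fieldnames}")
        for line_no, row in enumerate(reader, start=2):
            key = row["key"]
            if key in rows:
                raise VariantError(f"{path}:{line_no}: duplicate sidecar key {key!r}")
            if row["classification"] and row["classification"] not in CLASSIFICATIONS:
                raise VariantError(
                    f"{path}:{line_no}: unknown classification {row['classification']!r}")
            if row["consequence"] and row["consequence"] not in CONSEQUENCES:
                raise VariantError(
                    f"{path}:{line_no}: unknown consequence {row['consequence']!r}")
            rows[key] = row
    return rows


def read_variants(vcf: str | Path, sidecar: str | Path | None = None,
                  sample: str | None = None) -> list[AnnotatedVariant]:
    """Read a VCF (plain or bgzipped) and join the annotation sidecar.

    One record per bi-allelic alt: multi-allelic sites are decomposed, each
    alt keeping the site QUAL and a genotype computed against that alt alone.
    Variants with no sidecar row carry absent annotations throughout.
    """
    annotations = _read_sidecar(sidecar) if sidecar is not None else {}
    out: list[AnnotatedVariant] = []
    try:
        vf = pysam.VariantFile(str(vcf))
    except (OSError, ValueError) as exc:
        raise VariantError(f"cannot read VCF {vcf}: {exc}") from None
    with vf:
        sample_names = list(vf.header.samples)
        if sample is not None and sample not in sample_names:
            raise VariantError(f"sample {sample!r} not in VCF ({sample_names})")
        use_sample = sample or (sample_names[0] if sample_names else None)
        for rec in vf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                genotype = "missing"
                if use_sample is not None:
                    raw = rec.samples[use_sample].get("GT", (None,))
                    # project the call onto this alt: other alts count as ref
                    projected = tuple(
                        None if a is None else (1 if a == alt_index else 0)
                        for a in raw)
                    genotype = _classify_genotype(projected)
                key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                ann = annotations.get(key)
                freqs: dict[str, float] = {}
                classification = consequence = gene = None
                hgmd_dm = False
                if ann is not None:
                    gene = ann["gene"] or None
                    classification = ann["classification"] or None
                    consequence = ann["consequence"] or None
                    hgmd_dm = ann["hgmd_dm"] in ("1", "true", "True", "yes")
                    for col, src in _SIDECAR_FREQ_COLS.items():
                        if ann[col]:
                            freqs[src] = float(ann[col])
                try:
                    out.append(AnnotatedVariant(
                        chrom=str(rec.chrom), pos=rec.pos, ref=rec.ref, alt=alt,
                        call_quality=rec.qual, genotype=genotype, freqs=freqs,
                        classification=classification, hgmd_dm=hgmd_dm,
                        consequence=consequence, gene=gene))
                except ValueError as exc:
                    raise VariantError(f"{vcf}: record {key}: {exc}") from None
    return out


def read_trio_genotypes(vcf: str | Path, proband: str, mother: str,
                        father: str) -> TrioGenotypes:
    """Collect per-variant genotypes for a proband/mother/father sample
    triple, resolved against the VCF sample columns."""
    maps: dict[str, dict[str, str]] = {proband: {}, mother: {}, father: {}}
    with pysam.VariantFile(str(vcf)) as vf:
        samples = list(vf.header.samples)
        for name in (proband, mother, father):
            if name not in samples:
                raise TrioDataMissingError(
                    f"sample {name!r} not in VCF ({samples}); "
                    "skip the optional de-novo filter")
        for rec in vf:
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                for name in (proband, mother, father):
                    raw = rec.samples[name].get("GT", (None,))
                    projected = tuple(
                        None if a is None else (1 if a == alt_index else 0)
                        for a in raw)
                    maps[name][key] = _classify_genotype(projected)
    return TrioGenotypes(proband=maps[proband], mother=maps[mother],
                         father=maps[father])


# -- filter predicates --------------------------------------------------------

def confidence_filter(vs: list[AnnotatedVariant], min_quality: float = 20.0,
                      trace: FilterTrace | None = None) -> list[AnnotatedVariant]:
    """Remove low-quality calls (quality < threshold); the boundary value is
    retained. Missing quality is removed (conservative)."""
    out = [v for v in vs if v.call_quality is not None and v.call_quality >= min_quality]
    if trace is not None:
        trace.add("confidence", vs, out)
    return out


def common_variant_filter(vs: list[AnnotatedVariant], max_freq: float = 0.005,
                          mode: str = "any",
                          trace: FilterTrace | None = None) -> list[AnnotatedVariant]:
    """Remove common variants. In the default ``any`` mode a variant is
    removed as soon as one source reports a frequency above ``max_freq``; in
    ``all`` mode every reported source must exceed it. Absent frequencies
    count as rare. Frequency exactly at the threshold is retained."""
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")

    def common(v: AnnotatedVariant) -> bool:
        over = [f > max_freq for f in v.freqs.values()]
        if not over:
            return False
        return any(over) if mode == "any" else all(over)

    out = [v for v in vs if not common(v)]
    if trace is not None:
        trace.add("common_variant", vs, out)
    return out


def deleterious_filter(vs: list[AnnotatedVariant],
                       trace: FilterTrace | None = None) -> list[AnnotatedVariant]:
    """Keep variants published as pathogenic or likely pathogenic, tagged as
    HGMD disease-causing (DM), carrying a loss/gain-of-function consequence
    (frameshift, start/stop loss or gain, splice site), or missense."""

    def keep(v: AnnotatedVariant) -> bool:
        return (v.classification in ("pathogenic", "likely_pathogenic")
                or v.hgmd_dm
                or v.consequence in LOF_CONSEQUENCES
                or v.consequence == "missense")

    out = [v for v in vs if keep(v)]
    if trace is not None:
        trace.add("predicted_deleterious", vs, out)
    return out


def denovo_filter(vs: list[AnnotatedVariant], trio: TrioGenotypes,
                  trace: FilterTrace | None = None) -> list[AnnotatedVariant]:
    """Keep variants carried by the proband and absent from both parents.

    A parental genotype that is missing (or absent from the trio map) removes
    the variant — de-novo status cannot be established conservatively.
    """
    if not trio.mother or not trio.father:
        raise TrioDataMissingError(
            "parental genotype data absent; skip the optional de-novo filter")

    def de_novo(v: AnnotatedVariant) -> bool:
        if v.genotype not in ("het", "hom_alt", "hemi"):
            return False
        return (trio.mother.get(v.key) == "hom_ref"
                and trio.father.get(v.key) == "hom_ref")

    out = [v for v in vs if de_novo(v)]
    if trace is not None:
        trace.add("de_novo", vs, out)
    return out


def apply_filter_cascade(
    vs: list[AnnotatedVariant],
    min_quality: float = 20.0,
    max_freq: float = 0.005,
    freq_mode: str = "any",
    trio: TrioGenotypes | None = None,
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Canonical order: confidence → common variant → predicted deleterious
    (→ de novo when a trio is supplied). The survivor set is order-independent
    (pointwise predicates); only the trace depends on the order."""
    trace = FilterTrace()
    out = confidence_filter(vs, min_quality, trace)
    out = common_variant_filter(out, max_freq, freq_mode, trace)
    out = deleterious_filter(out, trace)
    if trio is not None:
        out = denovo_filter(out, trio, trace)
    return out, trace


def variant_genes(vs: list[AnnotatedVariant]) -> tuple[dict[str, list[AnnotatedVariant]], int]:
    """Group surviving variants by gene: the variant-impacted gene set G.

    Returns ``(genes, n_unassigned)``; variants without a gene assignment are
    excluded and counted. Output is sorted by gene id and within a gene by
    coordinates, so it is invariant under input permutation.
    """
    genes: dict[str, list[AnnotatedVariant]] = {}
    unassigned = 0
    for v in vs:
        if v.gene is None:
            unassigned += 1
            continue
        genes.setdefault(v.gene, []).append(v)
    ordered = {}
    for gene in sorted(genes):
        ordered[gene] = sorted(genes[gene], key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return ordered, unassigned
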