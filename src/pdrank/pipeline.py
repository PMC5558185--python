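"""End-to-end ranking pipeline and the rank-ordered result table.

Pipeline: map the patient's phenotype terms onto graph nodes, run the variant
filter cascade, collect the variant-impacted gene set G, take the candidate
diseases implicated by G, score them against the mapped phenotype set, and
assemble a table of unique disease-gene-variant rows ordered by disease score.
The table is truncated at ``table_limit`` disease/gene pairs, with at most
``variants_per_gene_limit`` variant rows per pair.

Restricting scoring to diseases with variant-impacted genes is equivalent to
scoring everything and intersecting afterwards, provided the candidate set D
that constrains the path search is the same in both computations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .graph import KnowledgeGraph
from .mapping import Lexicon, MappingReport
from .scoring import DiseaseScore, ScoringParams, score_candidates
from .variants import (AnnotatedVariant, FilterTrace, TrioGenotypes,
                       apply_filter_cascade, variant_genes)


class PipelineError(Exception):
    exit_code = 2


class NoPhenotypesMappedError(PipelineError):
    """No input term mapped to a phenotype node."""
    exit_code = 3


class NoVariantsError(PipelineError):
    """No variant survived the filter cascade (or none carried a gene)."""
    exit_code = 3


class NoDiseasesError(PipelineError):
    """No candidate disease could be connected to any mapped phenotype."""
    exit_code = 3


# variant display order within a gene: strongest evidence first
_SEVERITY_CLASS = {"pathogenic": 0, "likely_pathogenic": 1}


def variant_severity_key(v: AnnotatedVariant):
    from .variants import LOF_CONSEQUENCES

    if v.classification in _SEVERITY_CLASS:
        tier = _SEVERITY_CLASS[v.classification]
    elif v.hgmd_dm:
        tier = 2
    elif v.consequence in LOF_CONSEQUENCES:
        tier = 3
    elif v.consequence == "missense":
        tier = 4
    else:
        tier = 5
    return (tier, v.chrom, v.pos, v.ref, v.alt)


@dataclass(frozen=True)
class ResultRow:
    rank: int  # disease rank (rows of one disease share it)
    disease: str
    disease_name: str
    score: float
    gene: str
    variant: str | None  # chrom:pos:ref:alt
    classification: str | None
    causal: str  # "causal" | "correlated" | "unknown"
    moi: str  # "dominant" | "recessive" | "unknown"
    moi_consistent: str  # "yes" | "no" | "unknown"
    breakdown: str  # phenotype:contribution pairs, ';'-separated


@dataclass
class ResultTable:
    rows: list[ResultRow]
    pairs_shown: int
    pairs_total: int
    scores: list[DiseaseScore] = field(default_factory=list)


@dataclass
class RunLog:
    """Structured account of one pipeline run (JSON-lines serializable)."""

    records: list[dict] = field(default_factory=list)

    def add(self, event: str, **payload) -> None:
        self.records.append({"event": event, **payload})

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def moi_consistency(moi: str, gene_variants: list[AnnotatedVariant]) -> str:
    """Genotype/mode-of-inheritance consistency for one disease-gene pair.

    Dominant: at least one het (or hemizygous) variant. Recessive: a
    homozygous-alt variant, or >= 2 distinct het variants in the gene — a
    gene-level proxy for compound heterozygosity (phase is not assessed).
    Unknown mode of inheritance yields "unknown".
    """
    if moi == "dominant":
        ok = any(v.genotype in ("het", "hemi", "hom_alt") for v in gene_variants)
    elif moi == "recessive":
        n_het = len({v.key for v in gene_variants if v.genotype == "het"})
        ok = any(v.genotype == "hom_alt" for v in gene_variants) or n_het >= 2
    else:
        return "unknown"
    return "yes" if ok else "no"


def build_table(
    ranked: list[DiseaseScore],
    genes: dict[str, list[AnnotatedVariant]],
    g: KnowledgeGraph,
    params: ScoringParams = ScoringParams(),
) -> ResultTable:
    """Assemble the rank-ordered result table.

    Rows are replicated per disease-gene-variant combination; truncation
    counts disease/gene pairs (not rows) and keeps a prefix of the full
    ranking; within a gene, at most ``variants_per_gene_limit`` variants are
    shown, strongest classification first.
    """
    rows: list[ResultRow] = []
    pairs_total = sum(
        len([x for x in s.implicating_genes if x in genes]) for s in ranked)
    pairs_shown = 0
    for rank, s in enumerate(ranked, start=1):
        breakdown = ";".join(f"{c.phenotype}:{c.contribution:.6f}"
                             for c in s.contributions)
        if pairs_shown >= params.table_limit:
            break
        for gene in sorted(s.implicating_genes):
            if gene not in genes:
                continue
            if pairs_shown >= params.table_limit:
                break
            pairs_shown += 1
            causal, moi = g.gd_attrs.get((gene, s.disease), (None, None))
            gene_vars = genes[gene]
            consistent = moi_consistency(moi or "unknown", gene_vars)
            shown = sorted(gene_vars, key=variant_severity_key)
            shown = shown[: params.variants_per_gene_limit]
            for v in shown:
                rows.append(ResultRow(
                    rank=rank, disease=s.disease,
                    disease_name=g.nodes[s.disease].name, score=s.score,
                    gene=gene, variant=v.key, classification=v.classification,
                    causal=causal or "unknown", moi=moi or "unknown",
                    moi_consistent=consistent, breakdown=breakdown))
    return ResultTable(rows=rows, pairs_shown=pairs_shown,
                       pairs_total=pairs_total, scores=ranked)


def rank_case(
    g: KnowledgeGraph,
    lexicon: Lexicon,
    terms: list[str],
    variants: list[AnnotatedVariant],
    params: ScoringParams = ScoringParams(),
    trio: TrioGenotypes | None = None,
    min_quality: float = 20.0,
    max_freq: float = 0.005,
    freq_mode: str = "any",
    log: RunLog | None = None,
) -> tuple[ResultTable, MappingReport, FilterTrace]:
    """Run the full pipeline on in-memory inputs.

    Deterministic for fixed inputs. Raises a named, remediable error for each
    empty-result condition: no phenotype mapped, no variant surviving, or no
    candidate disease connectable to the phenotypes.
    """
    log = log if log is not None else RunLog()
    P, mapping_report = lexicon.map_phenotype_list(terms)
    log.add("phenotype_mapping", mapped=sorted(P),
            unmapped=mapping_report.unmapped,
            mapped_fraction=mapping_report.mapped_fraction)
    if not P:
        raise NoPhenotypesMappedError(
            "no phenotypes mapped — check spelling or supply HPO-style ids "
            f"(unmapped: {mapping_report.unmapped})")

    survivors, trace = apply_filter_cascade(
        variants, min_quality=min_quality, max_freq=max_freq,
        freq_mode=freq_mode, trio=trio)
    for step in trace.steps:
        log.add("filter", name=step.name, n_in=step.n_in, n_out=step.n_out,
                removed=step.removed_keys)
    genes, n_unassigned = variant_genes(survivors)
    log.add("variant_genes", genes=sorted(genes), unassigned=n_unassigned)
    if not genes:
        raise NoVariantsError(
            "no variant survived the filter cascade with a gene assignment — "
            "relax thresholds or check the annotation sidecar")

    candidates, skipped = g.candidate_diseases(set(genes))
    log.add("candidate_diseases", n=len(candidates), skipped_genes=skipped)
    ranked = score_candidates(g, P, candidates, params)
    log.add("scoring", n_scored=len(ranked),
            n_dropped=len(candidates) - len(ranked))
    if not ranked:
        raise NoDiseasesError(
            "no candidate disease connects to any mapped phenotype within "
            f"{params.max_path_length} edges — review phenotype terms or gene list")
    table = build_table(ranked, genes, g, params)
    return table, mapping_report, trace


def run_pdr(
    graph: KnowledgeGraph,
    lexicon: Lexicon,
    phenotype_file: str | Path,
    vcf: str | Path,
    sidecar: str | Path,
    params: ScoringParams = ScoringParams(),
    trio_samples: tuple[str, str, str] | None = None,
    log: RunLog | None = None,
    **filter_kwargs,
) -> tuple[ResultTable, MappingReport, FilterTrace]:
    """File-based front end over :func:`rank_case`."""
    from .mapping import read_phenotype_file
    from .variants import read_trio_genotypes, read_variants

    terms = read_phenotype_file(phenotype_file)
    sample = trio_samples[0] if trio_samples else None
    variants = read_variants(vcf, sidecar, sample=sample)
    trio = read_trio_genotypes(vcf, *trio_samples) if trio_samples else None
    return rank_case(graph, lexicon, terms, variants, params=params,
                     trio=trio, log=log, **filter_kwargs)


TABLE_COLUMNS = ["rank", "disease", "score", "gene", "variant",
                 "classification", "causal", "moi", "moi_consistent",
                 "breakdown"]


def _row_cells(row: ResultRow) -> list[str]:
    return [str(row.rank), row.disease, f"{row.score:.6f}", row.gene,
            row.variant or "", row.classification or "", row.causal,
            row.moi, row.moi_consistent, row.breakdown]


def write_table(table: ResultTable, path: str | Path, fmt: str = "tsv") -> None:
    """Serialize the table as TSV or JSON; output is byte-identical across
    repeated runs on identical input (floats fixed at 6 decimals)."""
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(TABLE_COLUMNS) + "\n")
            for row in table.rows:
                fh.write("\t".join(_row_cells(row)) + "\n")
    elif fmt == "json":
        payload = {
            "pairs_shown": table.pairs_shown,
            "pairs_total": table.pairs_total,
            "rows": [dict(zip(TABLE_COLUMNS, _row_cells(r))) for r in table.rows],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_table_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
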