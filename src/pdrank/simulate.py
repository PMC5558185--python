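"""Seeded synthetic networks, lexicons, and planted patient cases.

The generator emulates the structural properties of a curated
phenotype-disease-gene knowledge base at roughly 1/20 scale while preserving
its degree means: diseases carry tens of phenotypes (Poisson around 43.4),
genes implicate several diseases (Poisson around 6.8), a multi-level term
hierarchy connects general to specific phenotype terms, and a small fraction
of phenotypes also act as diseases themselves. Planted cases emulate a
solved rare-disease patient: phenotypes sampled from a chosen causal
disease's associations (optionally swapped for hierarchy neighbours, plus
uniform noise terms) and a toy VCF containing one qualifying variant in the
causal gene among decoys.

Everything is a pure function of (params, seed): identical inputs produce
byte-identical output tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .graph import KnowledgeGraph, NetworkEdge, NetworkNode, save_graph
from .mapping import Lexicon, LexiconEntry, save_lexicon
from .pipeline import rank_case
from .scoring import ScoringParams
from .variants import AnnotatedVariant


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class NetworkGenParams:
    """Synthetic network shape. Defaults scale the reference knowledge base
    down ~20x with degree means preserved (so phenotype sharing across
    diseases — the quantity the specificity weight responds to — stays
    realistic at ~36 diseases per phenotype)."""

    n_genes: int = 900
    n_diseases: int = 240
    n_phenotypes: int = 290
    hierarchy_depth: int = 4
    mean_phenotypes_per_disease: float = 43.4
    mean_diseases_per_gene: float = 6.8
    dual_role_fraction: float = 0.06
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_diseases", "n_phenotypes", "hierarchy_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.mean_phenotypes_per_disease <= 0 or self.mean_diseases_per_gene <= 0:
            raise ValueError("mean degrees must be positive")
        if not (0 <= self.dual_role_fraction <= 1):
            raise ValueError("dual_role_fraction must lie in [0, 1]")
        if self.mean_phenotypes_per_disease > self.n_phenotypes:
            raise ValueError("mean phenotypes per disease exceeds phenotype count")
        if self.mean_diseases_per_gene > self.n_diseases:
            raise ValueError("mean diseases per gene exceeds disease count")


@dataclass(frozen=True)
class PlantedCaseParams:
    """One simulated patient. ``n_true_phenotypes`` defaults to 5, the size
    of a typical physician-reported phenotype list for a solved case."""

    n_true_phenotypes: int = 5
    n_noise_phenotypes: int = 0
    decoy_variant_count: int = 0  # decoy genes, one filter-passing variant each
    failing_decoy_count: int = 0  # extra decoys constructed to fail the cascade
    hierarchy_swap_fraction: float = 0.0  # chance a true term is swapped for a PH neighbour
    causal_call_quality: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.n_true_phenotypes < 1:
            raise ValueError("n_true_phenotypes must be >= 1")
        if self.n_noise_phenotypes < 0 or self.decoy_variant_count < 0:
            raise ValueError("counts must be >= 0")
        if not (0 <= self.hierarchy_swap_fraction <= 1):
            raise ValueError("hierarchy_swap_fraction must lie in [0, 1]")


@dataclass
class PlantedCase:
    causal_disease: str
    causal_gene: str
    observed_phenotypes: list[str]  # surfaces as a clinician might enter them
    true_phenotype_nodes: list[str]
    noise_phenotype_nodes: list[str]
    variants: list[AnnotatedVariant]
    params: PlantedCaseParams

    def truth(self) -> dict:
        return {
            "causal_disease": self.causal_disease,
            "causal_gene": self.causal_gene,
            "true_phenotypes": self.true_phenotype_nodes,
            "noise_phenotypes": self.noise_phenotype_nodes,
            "n_variants": len(self.variants),
            "seed": self.params.seed,
        }


def _poisson_at_least_1(rng: np.random.Generator, mean: float) -> int:
    return max(1, int(rng.poisson(mean)))


def generate_network(params: NetworkGenParams) -> tuple[KnowledgeGraph, list[LexiconEntry]]:
    """Build a seeded synthetic knowledge graph plus its synonym lexicon.

    Hierarchy: a random forest of the stated depth over the phenotype terms,
    PH edges running general → specific. DP and GD edge counts are Poisson
    (clamped to >= 1) around the stated means. Dual-role phenotypes receive
    their own DP edges to a few downstream phenotypes. Lexicon surfaces are
    collision-free by construction: a primary name, a synthetic ``HPX:`` id,
    an alternate id for every third term, and 1-3 synonyms per phenotype.
    """
    rng = np.random.default_rng(params.seed)
    nodes: list[NetworkNode] = []
    edges: list[NetworkEdge] = []
    lexicon: list[LexiconEntry] = []

    phen_ids = [f"T{i:04d}" for i in range(params.n_phenotypes)]
    n_dual = int(round(params.dual_role_fraction * params.n_phenotypes))
    dual = set(rng.choice(params.n_phenotypes, size=n_dual, replace=False).tolist()) if n_dual else set()

    # forest: term i > 0 may attach under a previous term of level < depth-1
    n_roots = max(1, params.n_phenotypes // 30)
    levels: dict[int, int] = {}
    for i in range(params.n_phenotypes):
        if i < n_roots:
            levels[i] = 0
            continue
        parent = int(rng.integers(0, i))
        if levels[parent] >= params.hierarchy_depth - 1:
            levels[i] = 0  # parent already at max depth: start a new root
            continue
        levels[i] = levels[parent] + 1
        edges.append(NetworkEdge(phen_ids[parent], phen_ids[i], "PH"))

    for i, pid in enumerate(phen_ids):
        name = f"Phenotype finding {i:04d}"
        nodes.append(NetworkNode(id=pid, name=name, is_phenotype=True,
                                 is_disease=(i in dual)))
        lexicon.append(LexiconEntry(name, pid, "primary_name"))
        lexicon.append(LexiconEntry(f"HPX:{i:07d}", pid, "primary_id"))
        if i % 3 == 0:
            lexicon.append(LexiconEntry(f"HPX:{9000000 + i:07d}", pid, "alternate_id"))
        for s in range(int(rng.integers(1, 4))):
            lexicon.append(LexiconEntry(f"synonym {s} of finding {i:04d}", pid, "synonym"))

    dis_ids = [f"D{i:04d}" for i in range(params.n_diseases)]
    moi_choices = ["dominant", "recessive", "unknown"]
    disease_moi = {d: moi_choices[int(rng.integers(0, 3))] for d in dis_ids}
    for i, did in enumerate(dis_ids):
        name = f"Syndrome {i:04d}"
        nodes.append(NetworkNode(id=did, name=name, is_disease=True))
        lexicon.append(LexiconEntry(name, did, "primary_name"))
        k = min(_poisson_at_least_1(rng, params.mean_phenotypes_per_disease),
                params.n_phenotypes)
        for j in rng.choice(params.n_phenotypes, size=k, replace=False):
            edges.append(NetworkEdge(did, phen_ids[int(j)], "DP"))

    # dual-role phenotypes act as diseases of a few downstream phenotypes
    for i in sorted(dual):
        k = min(_poisson_at_least_1(rng, 3.0), params.n_phenotypes - 1)
        targets = [int(j) for j in rng.choice(params.n_phenotypes, size=k + 1,
                                              replace=False) if int(j) != i][:k]
        for j in targets:
            edges.append(NetworkEdge(phen_ids[i], phen_ids[j], "DP"))
        disease_moi[phen_ids[i]] = moi_choices[int(rng.integers(0, 3))]

    all_disease_ids = dis_ids + [phen_ids[i] for i in sorted(dual)]
    gene_ids = [f"G{i:04d}" for i in range(params.n_genes)]
    for i, gid in enumerate(gene_ids):
        nodes.append(NetworkNode(id=gid, name=f"GENE{i:04d}", is_gene=True))
        k = min(_poisson_at_least_1(rng, params.mean_diseases_per_gene),
                len(all_disease_ids))
        for j in rng.choice(len(all_disease_ids), size=k, replace=False):
            did = all_disease_ids[int(j)]
            causal = "causal" if rng.random() < 0.5 else "correlated"
            edges.append(NetworkEdge(gid, did, "GD", causal=causal,
                                     moi=disease_moi[did]))

    graph = KnowledgeGraph(nodes, edges)
    report = graph.validate()
    if not report.ok:  # constructive validity: should never fire
        raise SimulationError("generated graph failed validation:\n" + report.summary())
    return graph, lexicon


def _phenotype_surface(rng: np.random.Generator, lexicon_by_node: dict[str, list[LexiconEntry]],
                       node: str) -> str:
    """Pick how the 'clinician' writes the term: name, synonym, or id."""
    entries = lexicon_by_node[node]
    return str(entries[int(rng.integers(0, len(entries)))].surface)


def plant_case(graph: KnowledgeGraph, lexicon_entries: list[LexiconEntry],
               params: PlantedCaseParams) -> PlantedCase:
    """Plant a solved case: a causal disease/gene pair, an observed phenotype
    list, and a toy variant set whose only causal-gene variant passes the
    filter cascade (unless ``causal_call_quality`` says otherwise).

    True phenotypes are sampled without replacement from the causal disease's
    DP neighbours; with probability ``hierarchy_swap_fraction`` a sampled term
    is swapped for a random PH parent or child, exercising hierarchy
    traversal. Noise phenotypes are sampled uniformly outside the causal
    disease's own phenotype set. Decoy variants are placed in distinct random
    non-causal genes and constructed to pass every filter; failing decoys get
    call quality below threshold.
    """
    rng = np.random.default_rng(params.seed)
    by_node: dict[str, list[LexiconEntry]] = {}
    for e in lexicon_entries:
        by_node.setdefault(e.node, []).append(e)

    eligible = sorted(
        d for d, phens in graph.dp_out.items()
        if len(phens) >= params.n_true_phenotypes and graph.gd_in.get(d))
    if not eligible:
        raise SimulationError(
            f"no disease has >= {params.n_true_phenotypes} phenotypes and a gene; "
            "regenerate the network or lower n_true_phenotypes")
    causal_disease = eligible[int(rng.integers(0, len(eligible)))]
    gene_pool = sorted(graph.gd_in[causal_disease])
    causal_gene = gene_pool[int(rng.integers(0, len(gene_pool)))]

    disease_phens = sorted(graph.dp_out[causal_disease])
    idx = rng.choice(len(disease_phens), size=params.n_true_phenotypes, replace=False)
    true_nodes = [disease_phens[int(i)] for i in idx]
    for k, node in enumerate(true_nodes):
        if rng.random() < params.hierarchy_swap_fraction:
            neighbours = sorted(graph.ph_up.get(node, set()) | graph.ph_down.get(node, set()))
            neighbours = [n for n in neighbours if graph.nodes[n].is_phenotype]
            if neighbours:
                true_nodes[k] = neighbours[int(rng.integers(0, len(neighbours)))]

    exclude = set(graph.dp_out[causal_disease]) | set(true_nodes)
    noise_pool = sorted(
        n.id for n in graph.nodes.values()
        if n.is_phenotype and n.id not in exclude and n.id in by_node)
    n_noise = min(params.n_noise_phenotypes, len(noise_pool))
    noise_nodes = [noise_pool[int(i)] for i in
                   rng.choice(len(noise_pool), size=n_noise, replace=False)] if n_noise else []

    observed = [_phenotype_surface(rng, by_node, n) for n in true_nodes + noise_nodes]

    variants: list[AnnotatedVariant] = [AnnotatedVariant(
        chrom="1", pos=1000, ref="A", alt="G",
        call_quality=params.causal_call_quality, genotype="het",
        freqs={"EXAC": 0.0001}, classification="pathogenic", hgmd_dm=True,
        consequence="missense", gene=causal_gene)]
    other_genes = sorted(gid for gid, n in graph.nodes.items()
                         if n.is_gene and gid != causal_gene)
    n_decoy = min(params.decoy_variant_count, len(other_genes))
    decoy_idx = rng.choice(len(other_genes), size=n_decoy, replace=False) if n_decoy else []
    for k, i in enumerate(decoy_idx):
        variants.append(AnnotatedVariant(
            chrom="2", pos=2000 + 10 * k, ref="C", alt="T",
            call_quality=60.0, genotype="het", freqs={"KG1000": 0.001},
            classification="vus", consequence="missense",
            gene=other_genes[int(i)]))
    for k in range(params.failing_decoy_count):
        gene = other_genes[int(rng.integers(0, len(other_genes)))] if other_genes else None
        variants.append(AnnotatedVariant(
            chrom="3", pos=3000 + 10 * k, ref="G", alt="A",
            call_quality=10.0, genotype="het", consequence="missense", gene=gene))

    return PlantedCase(causal_disease=causal_disease, causal_gene=causal_gene,
                       observed_phenotypes=observed, true_phenotype_nodes=true_nodes,
                       noise_phenotype_nodes=noise_nodes, variants=variants,
                       params=params)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pdrank-simulate
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPROBAND
"""

_GT = {"het": "0/1", "hom_alt": "1/1", "hemi": "1", "missing": "./."}


def write_vcf(variants: list[AnnotatedVariant], path: str | Path) -> None:
    """Emit a minimal single-sample VCF 4.2 for the toy variants."""
    contigs = "".join(f"##contig=<ID={c}>\n" for c in
                      sorted({v.chrom for v in variants}))
    lines = [_VCF_HEADER.format(contigs=contigs)]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        qual = f"{v.call_quality:g}" if v.call_quality is not None else "."
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t.\t.\tGT\t"
                     f"{_GT.get(v.genotype, './.')}\n")
    Path(path).write_text("".join(lines), encoding="utf-8")


def write_sidecar(variants: list[AnnotatedVariant], path: str | Path) -> None:
    from .variants import SIDECAR_COLUMNS, _SIDECAR_FREQ_COLS

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SIDECAR_COLUMNS) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            freq_cells = [
                (f"{v.freqs[src]:g}" if src in v.freqs else "")
                for col, src in _SIDECAR_FREQ_COLS.items()]
            fh.write("\t".join([
                v.key, v.gene or "", v.classification or "",
                "1" if v.hgmd_dm else "", v.consequence or "",
                *freq_cells]) + "\n")


def write_case(case: PlantedCase, out_dir: str | Path,
               graph: KnowledgeGraph | None = None,
               lexicon_entries: list[LexiconEntry] | None = None) -> dict[str, Path]:
    """Write a self-contained case directory: phenotypes.txt, case.vcf,
    sidecar.tsv, truth.json (+ network tables when given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": out / "phenotypes.txt",
        "vcf": out / "case.vcf",
        "sidecar": out / "sidecar.tsv",
        "truth": out / "truth.json",
    }
    paths["phenotypes"].write_text(
        "# observed phenotypes (planted case)\n"
        + "".join(t + "\n" for t in case.observed_phenotypes), encoding="utf-8")
    write_vcf(case.variants, paths["vcf"])
    write_sidecar(case.variants, paths["sidecar"])
    paths["truth"].write_text(json.dumps(case.truth(), indent=1, sort_keys=True) + "\n",
                              encoding="utf-8")
    if graph is not None:
        paths["nodes"], paths["edges"] = out / "nodes.tsv", out / "edges.tsv"
        save_graph(graph, paths["nodes"], paths["edges"])
    if lexicon_entries is not None:
        paths["lexicon"] = out / "lexicon.tsv"
        save_lexicon(lexicon_entries, paths["lexicon"])
    return paths


@dataclass
class RecoveryResult:
    """Planted-gene recovery across replicates. ``ranks`` holds the causal
    gene's rank per replicate (None when it never enters the table)."""

    ranks: list[int | None]
    fractions: dict[int, tuple[float, float]]  # k -> (fraction, binomial SE)
    n_reps: int


def gene_rank(ranked_scores, causal_gene: str) -> int | None:
    """Rank of a gene = position of its first appearance when genes are
    ordered by their best-ranked disease (full ranking, before table
    truncation). None when the gene implicates no scored disease."""
    seen: list[str] = []
    for s in ranked_scores:
        for g in sorted(s.implicating_genes):
            if g not in seen:
                seen.append(g)
    return seen.index(causal_gene) + 1 if causal_gene in seen else None


def recovery_experiment(
    gen_params: NetworkGenParams,
    case_params: PlantedCaseParams,
    n_reps: int,
    k_list: tuple[int, ...] = (1, 5, 10),
    scoring: ScoringParams = ScoringParams(),
) -> RecoveryResult:
    """Plant ``n_reps`` cases on one generated network (replicate i uses seed
    ``case_params.seed + i``), run the full pipeline on each, and report
    top-k recovery fractions with binomial standard errors."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    graph, lexicon_entries = generate_network(gen_params)
    lexicon = Lexicon(lexicon_entries)
    ranks: list[int | None] = []
    for i in range(n_reps):
        case = plant_case(graph, lexicon_entries,
                          replace(case_params, seed=case_params.seed + i))
        table, _, _ = rank_case(graph, lexicon, case.observed_phenotypes,
                                case.variants, params=scoring)
        ranks.append(gene_rank(table.scores, case.causal_gene))
    fractions = {}
    for k in k_list:
        frac = sum(1 for r in ranks if r is not None and r <= k) / n_reps
        fractions[k] = (frac, math.sqrt(frac * (1 - frac) / n_reps))
    return RecoveryResult(ranks=ranks, fractions=fractions, n_reps=n_reps)
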