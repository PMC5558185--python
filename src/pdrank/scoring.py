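"""Heuristic disease scoring over the phenotype-disease-gene network.

Given a patient phenotype set P and a candidate disease set D (the diseases
implicated by variant-impacted genes), each disease is scored as

    S = sum_i  w_s(i) * w_p(i)        over phenotypes i in P connected to it,

where the specificity weight w_s = 1 / (1 + b*log10(max(1, N))) down-weights
phenotypes attached to many (N) diseases, and the path weight w_p = a**(L-1)
down-weights phenotypes whose shortest admissible path to the disease has
length L > 1. Defaults a = 0.75, b = 1; paths longer than 4 edges are never
considered, so a candidate disease reachable only beyond that cap is dropped.

Admissible paths start at a phenotype, traverse DP edges against their stored
disease→phenotype direction (i.e. phenotype→disease), traverse hierarchy (PH)
edges in either direction, never pass through another candidate disease, and
end with a DP traversal into the candidate. A phenotype that is itself a
candidate disease counts as directly connected (L = 1, path weight 1); its
specificity weight is still computed from its own DP in-degree.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .graph import KnowledgeGraph


@dataclass(frozen=True)
class ScoringParams:
    """Tunable parameters of the ranking heuristic.

    a: path-weight decay per extra edge, in (0, 1].
    b: specificity decay per decade of disease count, >= 0.
    max_path_length: hard cap on admissible path length (edges).
    table_limit: disease/gene pairs kept in the result table.
    variants_per_gene_limit: variant rows shown per disease/gene pair.
    """

    a: float = 0.75
    b: float = 1.0
    max_path_length: int = 4
    table_limit: int = 50
    variants_per_gene_limit: int = 5

    def __post_init__(self):
        if not (0 < self.a <= 1):
            raise ValueError("a must be in (0, 1]")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        for name in ("max_path_length", "table_limit", "variants_per_gene_limit"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")


_PARAM_TYPES = {"a": float, "b": float, "max_path_length": int,
                "table_limit": int, "variants_per_gene_limit": int}


def load_params(config: str | Path | None = None, **overrides) -> ScoringParams:
    """Resolve parameters: explicit overrides > config file > defaults.

    The config file is a flat YAML mapping (``a: 0.75`` etc.); unknown keys
    are rejected.
    """
    values: dict = {}
    if config is not None:
        loaded = yaml.safe_load(Path(config).read_text(encoding="utf-8")) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{config}: expected a flat key-value mapping")
        for key, val in loaded.items():
            if key not in _PARAM_TYPES:
                raise ValueError(f"{config}: unknown parameter {key!r}")
            values[key] = _PARAM_TYPES[key](val)
    for key, val in overrides.items():
        if val is None:
            continue
        if key not in _PARAM_TYPES:
            raise ValueError(f"unknown parameter {key!r}")
        values[key] = _PARAM_TYPES[key](val)
    return ScoringParams(**values)


def specificity_weight(N: int, b: float = 1.0) -> float:
    """w_s = 1 / (1 + b*log10(max(1, N))); equals 1 for N in {0, 1}."""
    if N < 0:
        raise ValueError("N must be >= 0")
    if b < 0:
        raise ValueError("b must be >= 0")
    return 1.0 / (1.0 + b * math.log10(max(1, N)))


def path_weight(L: int, a: float = 0.75, max_path_length: int = 4) -> float:
    """w_p = a**(L-1) for 1 <= L <= max_path_length; exactly 1 at L = 1."""
    if L < 1 or L > max_path_length:
        raise ValueError(f"path length {L} outside [1, {max_path_length}]")
    if L == 1:
        return 1.0
    return a ** (L - 1)


@dataclass(frozen=True)
class PhenotypePath:
    """One admissible shortest path from a phenotype to a candidate disease.

    ``nodes`` holds L+1 node ids in traversal order and ``edge_kinds`` the L
    traversed kinds, except in the degenerate phenotype-is-the-disease case,
    where nodes == (phenotype,), edge_kinds == () and length == 1 by
    convention (direct-link path weight).
    """

    phenotype: str
    disease: str
    length: int
    nodes: tuple[str, ...]
    edge_kinds: tuple[str, ...]

    @property
    def is_self(self) -> bool:
        return len(self.nodes) == 1


def constrained_shortest_paths(
    g: KnowledgeGraph,
    phenotype: str,
    D: set[str] | frozenset[str],
    params: ScoringParams = ScoringParams(),
) -> dict[str, tuple[int, list[PhenotypePath]]]:
    """All shortest admissible paths from one phenotype into each reachable
    candidate disease (algorithm step 2).

    Breadth-first search from ``phenotype``; moves are reverse-DP
    (phenotype→disease) and PH in either direction. Candidate diseases other
    than the start node are never expanded, and are reached only by a
    terminal reverse-DP move. Depth is capped at ``params.max_path_length``.

    Returns {disease: (L, shortest paths)}; diseases beyond the cap are
    simply absent. If the start phenotype itself belongs to D it is reported
    with the degenerate L = 1 self path.
    """
    node = g.node(phenotype)  # raises UnknownNodeError
    if not node.is_phenotype:
        raise ValueError(f"{phenotype!r} is not a phenotype node")
    D = set(D)
    lmax = params.max_path_length

    # layered BFS over expandable nodes; preds[v] = [(u, kind), ...] on some
    # shortest path, terminal[d][dist] = {u: last-hop predecessors}
    dist: dict[str, int] = {phenotype: 0}
    preds: dict[str, list[tuple[str, str]]] = {phenotype: []}
    terminal: dict[str, dict[int, set[str]]] = {}
    queue: deque[str] = deque([phenotype])

    while queue:
        u = queue.popleft()
        du = dist[u]
        if du >= lmax:
            continue
        moves: list[tuple[str, str]] = [(d, "DP") for d in g.dp_in.get(u, ())]
        moves += [(v, "PH") for v in g.ph_up.get(u, ())]
        moves += [(v, "PH") for v in g.ph_down.get(u, ())]
        for v, kind in moves:
            if kind == "DP" and v in D:
                terminal.setdefault(v, {}).setdefault(du + 1, set()).add(u)
                continue  # candidates are terminal, never expanded
            if v in D:
                continue  # candidate reached via PH: neither terminal nor intermediate
            if v not in dist:
                dist[v] = du + 1
                preds[v] = [(u, kind)]
                queue.append(v)
            elif dist[v] == du + 1:
                preds[v].append((u, kind))

    def backtrack(v: str) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
        # all shortest (nodes, kinds) prefixes ending at v; BFS layering makes
        # the predecessor relation acyclic so plain recursion terminates
        if not preds[v]:
            return [((v,), ())]
        out = []
        for u, kind in preds[v]:
            for nodes_u, kinds_u in backtrack(u):
                out.append((nodes_u + (v,), kinds_u + (kind,)))
        return out

    result: dict[str, tuple[int, list[PhenotypePath]]] = {}
    if phenotype in D:
        result[phenotype] = (1, [PhenotypePath(phenotype, phenotype, 1,
                                               (phenotype,), ())])
    for d, arrivals in terminal.items():
        if d == phenotype:
            continue  # self-case already recorded with L = 1
        L = min(arrivals)
        paths = []
        for u in sorted(arrivals[L]):
            for nodes_u, kinds_u in backtrack(u):
                paths.append(PhenotypePath(phenotype, d, L,
                                           nodes_u + (d,), kinds_u + ("DP",)))
        paths.sort(key=lambda p: p.nodes)
        result[d] = (L, paths)
    return result


@dataclass(frozen=True)
class PhenotypeContribution:
    phenotype: str
    n_diseases: int  # N_i
    shortest_length: int  # L_i
    specificity_weight: float  # w_s
    path_weight: float  # w_p
    contribution: float  # w_s * w_p


@dataclass
class DiseaseScore:
    disease: str
    score: float
    contributions: list[PhenotypeContribution]
    implicating_genes: frozenset[str]
    evidence_paths: list[PhenotypePath] = field(default_factory=list)


def score_disease(
    g: KnowledgeGraph,
    disease: str,
    paths_by_phenotype: dict[str, dict[str, tuple[int, list[PhenotypePath]]]],
    params: ScoringParams = ScoringParams(),
    implicating_genes: frozenset[str] | None = None,
) -> DiseaseScore:
    """Score one candidate disease from per-phenotype shortest-path results.

    Each connected phenotype contributes once, at its shortest length, even
    when several equal-length paths exist; all shortest paths are kept as
    evidence. Contributions are summed in phenotype-id order for
    reproducibility. Calling this for a disease no phenotype connects to is a
    contract violation.
    """
    contributions: list[PhenotypeContribution] = []
    evidence: list[PhenotypePath] = []
    for p in sorted(paths_by_phenotype):
        hit = paths_by_phenotype[p].get(disease)
        if hit is None:
            continue
        L, paths = hit
        N = g.direct_disease_count(p)
        ws = specificity_weight(N, params.b)
        wp = path_weight(L, params.a, params.max_path_length)
        contributions.append(PhenotypeContribution(
            phenotype=p, n_diseases=N, shortest_length=L,
            specificity_weight=ws, path_weight=wp, contribution=ws * wp))
        evidence.extend(paths)
    if not contributions:
        raise ValueError(f"disease {disease!r} has no connected phenotype")
    score = sum(c.contribution for c in contributions)
    if implicating_genes is None:
        implicating_genes = frozenset(g.gd_in.get(disease, ()))
    return DiseaseScore(disease=disease, score=score, contributions=contributions,
                        implicating_genes=implicating_genes, evidence_paths=evidence)


def score_candidates(
    g: KnowledgeGraph,
    P: set[str],
    candidates: dict[str, set[str]],
    params: ScoringParams = ScoringParams(),
) -> list[DiseaseScore]:
    """Run steps 2-3 for a candidate set: paths, scores, drop unconnected,
    rank. ``candidates`` maps disease -> implicating genes (step 1 output)."""
    D = set(candidates)
    paths_by_phenotype = {
        p: constrained_shortest_paths(g, p, D, params) for p in sorted(P)
    }
    scores = []
    for d in sorted(D):
        if any(d in paths_by_phenotype[p] for p in paths_by_phenotype):
            scores.append(score_disease(g, d, paths_by_phenotype, params,
                                        frozenset(candidates[d])))
    return rank_diseases(scores)


def rank_diseases(scores: list[DiseaseScore]) -> list[DiseaseScore]:
    """Descending score; ties broken by contribution count (desc) then
    disease id (asc), so the ordering is stable across runs and input order."""
    return sorted(scores, key=lambda s: (-s.score, -len(s.contributions), s.disease))


@dataclass
class Subnetwork:
    """Evidence sub-network for one scored disease: all shortest paths plus
    the GD edges of the implicating genes, with display roles per node."""

    nodes: dict[str, str]  # id -> role: gene | disease | phenotype | intermediate
    edges: list[tuple[str, str, str]]  # stored orientation (source, target, kind)


def evidence_subnetwork(score: DiseaseScore, g: KnowledgeGraph) -> Subnetwork:
    if not score.evidence_paths:
        raise ValueError("score carries no evidence paths")
    roles: dict[str, str] = {score.disease: "disease"}
    edges: set[tuple[str, str, str]] = set()
    for path in score.evidence_paths:
        roles.setdefault(path.phenotype, "phenotype")
        for nid in path.nodes[1:-1]:
            roles.setdefault(nid, "intermediate")
        for u, v, kind in zip(path.nodes, path.nodes[1:], path.edge_kinds):
            if kind == "DP":
                edges.add((v, u, "DP"))  # traversed against storage direction
            else:
                edges.add((u, v, "PH") if v in g.ph_down.get(u, ()) else (v, u, "PH"))
    for gene in sorted(score.implicating_genes):
        roles[gene] = "gene"
        edges.add((gene, score.disease, "GD"))
    return Subnetwork(nodes=roles, edges=sorted(edges))


def write_subnetwork(sub: Subnetwork, node_path: str | Path, edge_path: str | Path) -> None:
    """Emit the sub-network as a node/edge TSV pair for external viewers."""
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("id\trole\n")
        for nid in sorted(sub.nodes):
            fh.write(f"{nid}\t{sub.nodes[nid]}\n")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tkind\n")
        for s, t, k in sub.edges:
            fh.write(f"{s}\t{t}\t{k}\n")


def write_scores(scores: list[DiseaseScore], path: str | Path) -> None:
    """Module-level score table: disease, score, n_phenotypes, genes,
    per-phenotype breakdown (6 decimal places)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\tscore\tn_phenotypes\tgenes\tbreakdown\n")
        for s in scores:
            breakdown = ";".join(f"{c.phenotype}:{c.contribution:.6f}"
                                 for c in s.contributions)
            genes = ",".join(sorted(s.implicating_genes))
            fh.write(f"{s.disease}\t{s.score:.6f}\t{len(s.contributions)}\t"
                     f"{genes}\t{breakdown}\n")
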