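"""Shared fixtures: tiny hand-built graphs, a worked-case fixture, and the
brute-force path-enumeration oracle used to cross-check the BFS search."""

from __future__ import annotations

import numpy as np
import pytest

from pdrank import (KnowledgeGraph, Lexicon, LexiconEntry, NetworkEdge,
                    NetworkNode)


def make_graph(nodes, edges):
    """nodes: (id, roles) with roles a subset of 'gdp'; edges: (s, t, kind)."""
    return KnowledgeGraph(
        [NetworkNode(id=i, name=i, is_gene="g" in r, is_disease="d" in r,
                     is_phenotype="p" in r) for i, r in nodes],
        [NetworkEdge(*e) for e in edges],
    )


@pytest.fixture
def minimal_graph():
    """gene g1 -> disease d1 -> phenotype p1."""
    return make_graph(
        [("g1", "g"), ("d1", "d"), ("p1", "p")],
        [("g1", "d1", "GD"), ("d1", "p1", "DP")],
    )


@pytest.fixture
def worked_case_graph():
    """A small clinic-like case: five observed phenotypes, one of which
    reaches the causal disease only through two intermediate hierarchy terms
    (agenesis -> dysgenesis -> unilateral dysgenesis -> disease), plus a
    competitor disease matching a single phenotype."""
    nodes = [
        ("GENE_A", "g"), ("GENE_B", "g"),
        ("SYNDROME_X", "d"), ("SYNDROME_Y", "d"),
        ("meningomyelocele", "p"), ("renal_agenesis", "p"),
        ("prominent_nose", "p"), ("hirsutism", "p"), ("retrognathia", "p"),
        ("dysgenesis", "p"), ("unilateral_renal_dysgenesis", "p"),
    ]
    edges = [
        ("GENE_A", "SYNDROME_X", "GD"), ("GENE_B", "SYNDROME_Y", "GD"),
        ("SYNDROME_X", "meningomyelocele", "DP"),
        ("SYNDROME_X", "prominent_nose", "DP"),
        ("SYNDROME_X", "hirsutism", "DP"),
        ("SYNDROME_X", "retrognathia", "DP"),
        # renal agenesis reaches the disease only via the hierarchy:
        # renal_agenesis -PH(up)-> dysgenesis -PH(down)-> unilateral_renal_dysgenesis -DP-> SYNDROME_X
        ("dysgenesis", "renal_agenesis", "PH"),
        ("dysgenesis", "unilateral_renal_dysgenesis", "PH"),
        ("SYNDROME_X", "unilateral_renal_dysgenesis", "DP"),
        ("SYNDROME_Y", "hirsutism", "DP"),
    ]
    return make_graph(nodes, edges)


@pytest.fixture
def worked_case_lexicon():
    entries = [
        LexiconEntry("Meningomyelocele", "meningomyelocele", "primary_name"),
        LexiconEntry("HP:0000213", "meningomyelocele", "primary_id"),
        LexiconEntry("Unilateral renal agenesis", "renal_agenesis", "primary_name"),
        LexiconEntry("Prominent nose", "prominent_nose", "primary_name"),
        LexiconEntry("Hirsutism", "hirsutism", "primary_name"),
        LexiconEntry("Retrognathia", "retrognathia", "primary_name"),
        LexiconEntry("excess body hair", "hirsutism", "synonym"),
    ]
    return Lexicon(entries)


# -- independent oracle: exhaustive constrained path enumeration --------------

def enumerate_constrained_paths(g, phenotype, D, lmax=4):
    """All simple admissible paths (length <= lmax) from one phenotype into
    every candidate disease, by exhaustive DFS over the same move set the BFS
    uses: reverse-DP and bidirectional PH; intermediates never in D except
    the start; last move reverse-DP into a member of D. Returns
    {disease: (min length, sorted shortest node-tuples)} plus the degenerate
    self case at L=1."""
    found = {}

    def record(d, nodes):
        found.setdefault(d, []).append(nodes)

    def moves(u):
        out = [(d, "DP") for d in g.dp_in.get(u, ())]
        out += [(v, "PH") for v in g.ph_up.get(u, ())]
        out += [(v, "PH") for v in g.ph_down.get(u, ())]
        return out

    def dfs(u, nodes):
        if len(nodes) - 1 >= lmax:
            return
        for v, kind in moves(u):
            if v in nodes:
                continue  # simple paths only
            if kind == "DP" and v in D:
                record(v, nodes + (v,))
                continue
            if v in D:
                continue
            dfs(v, nodes + (v,))

    dfs(phenotype, (phenotype,))
    result = {}
    if phenotype in D:
        result[phenotype] = (1, [(phenotype,)])
    for d, paths in found.items():
        if d == phenotype:
            continue
        L = min(len(p) - 1 for p in paths)
        result[d] = (L, sorted(p for p in paths if len(p) - 1 == L))
    return result


def random_small_graph(seed, max_nodes=60):
    """A random well-formed mixed graph for oracle cross-checks."""
    rng = np.random.default_rng(seed)
    n_phen = int(rng.integers(8, max(9, max_nodes - 25)))
    n_dis = int(rng.integers(3, 12))
    n_gene = int(rng.integers(2, 8))
    nodes = []
    phen = [f"p{i}" for i in range(n_phen)]
    dis = [f"d{i}" for i in range(n_dis)]
    genes = [f"g{i}" for i in range(n_gene)]
    dual = set(rng.choice(n_phen, size=max(1, n_phen // 8), replace=False).tolist())
    for i, p in enumerate(phen):
        nodes.append((p, "pd" if i in dual else "p"))
    nodes += [(d, "d") for d in dis]
    nodes += [(g, "g") for g in genes]
    edges = set()
    # PH forest over phenotype terms (ancestor -> descendant keeps it acyclic)
    for i in range(1, n_phen):
        if rng.random() < 0.7:
            edges.add((phen[int(rng.integers(0, i))], phen[i], "PH"))
    for d in dis:
        for j in rng.choice(n_phen, size=int(rng.integers(1, 5)), replace=False):
            edges.add((d, phen[int(j)], "DP"))
    for i in sorted(dual):  # dual-role phenotypes get downstream phenotypes
        for j in rng.choice(n_phen, size=2, replace=False):
            if int(j) != i:
                edges.add((phen[i], phen[int(j)], "DP"))
    all_dis = dis + [phen[i] for i in sorted(dual)]
    for g_ in genes:
        for j in rng.choice(len(all_dis), size=int(rng.integers(1, 4)), replace=False):
            edges.add((g_, all_dis[int(j)], "GD"))
    return make_graph(nodes, sorted(edges)), phen, all_dis, genes
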