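"""Phenotype-disease-gene knowledge graph: loading, validation, indexing.

The graph holds three node roles (gene, disease, phenotype; a node may hold
several roles at once — some phenotypes act as diseases themselves) and three
directed edge kinds:

* ``GD`` — gene → disease (causal or correlated association),
* ``DP`` — disease → phenotype,
* ``PH`` — process-hierarchy, general term → more specific term.

The PH sub-graph must be acyclic; GD and DP edges are exempt from that check.
Role flags are declared in the node table and cross-checked against incident
edges rather than inferred, because dual-role nodes cannot be recovered from
edges alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

EDGE_KINDS = ("GD", "DP", "PH")

NODE_COLUMNS = ["id", "name", "is_gene", "is_disease", "is_phenotype"]
EDGE_COLUMNS = ["source", "target", "kind"]
# extended edge-table dialect: optional GD annotations
EDGE_OPTIONAL_COLUMNS = ["causal", "moi"]


class GraphError(Exception):
    """Base class for graph loading/validation failures."""


class GraphLoadError(GraphError):
    """A node or edge table is malformed; message carries the line number."""


class GraphValidationError(GraphError):
    """The loaded graph violates a structural invariant."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__("graph validation failed:\n" + report.summary())


class UnknownNodeError(GraphError, KeyError):
    """A query referenced a node id absent from the graph."""


@dataclass(frozen=True)
class NetworkNode:
    id: str
    name: str
    is_gene: bool = False
    is_disease: bool = False
    is_phenotype: bool = False

    def __post_init__(self):
        if not (self.is_gene or self.is_disease or self.is_phenotype):
            raise ValueError(f"node {self.id!r}: at least one role flag must be set")


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    kind: str
    causal: str | None = None  # GD only: "causal" | "correlated" | None (unknown)
    moi: str | None = None  # GD only: "dominant" | "recessive" | None

    def __post_init__(self):
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source!r}")


@dataclass
class Violation:
    kind: str
    detail: str


@dataclass
class ValidationReport:
    errors: list[Violation] = field(default_factory=list)
    warnings: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.errors + self.warnings:
            out[v.kind] = out.get(v.kind, 0) + 1
        return out

    def summary(self) -> str:
        lines = [f"[error] {v.kind}: {v.detail}" for v in self.errors]
        lines += [f"[warning] {v.kind}: {v.detail}" for v in self.warnings]
        return "\n".join(lines) if lines else "(valid)"


class KnowledgeGraph:
    """Indexed phenotype-disease-gene network.

    Adjacency indices (all plain dict-of-set, keyed by node id):

    ``dp_in``    phenotype → {diseases with a DP edge into it} (N_i source)
    ``dp_out``   disease → {its phenotypes}
    ``ph_up``    term → {more general PH parents}
    ``ph_down``  term → {more specific PH children}
    ``gd_out``   gene → {its diseases}
    ``gd_in``    disease → {its genes}
    """

    def __init__(self, nodes: list[NetworkNode], edges: list[NetworkEdge]):
        self.nodes: dict[str, NetworkNode] = {}
        for n in nodes:
            if n.id in self.nodes:
                raise GraphLoadError(f"duplicate node id {n.id!r}")
            self.nodes[n.id] = n
        self.edges: list[NetworkEdge] = list(edges)

        self.dp_in: dict[str, set[str]] = {}
        self.dp_out: dict[str, set[str]] = {}
        self.ph_up: dict[str, set[str]] = {}
        self.ph_down: dict[str, set[str]] = {}
        self.gd_out: dict[str, set[str]] = {}
        self.gd_in: dict[str, set[str]] = {}
        self.gd_attrs: dict[tuple[str, str], tuple[str | None, str | None]] = {}

        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise GraphLoadError(
                        f"edge {e.source}->{e.target} ({e.kind}) references "
                        f"missing node {endpoint!r}"
                    )
            key = (e.source, e.target, e.kind)
            if key in seen:
                raise GraphLoadError(f"duplicate edge {key}")
            seen.add(key)
            if e.kind == "DP":
                self.dp_out.setdefault(e.source, set()).add(e.target)
                self.dp_in.setdefault(e.target, set()).add(e.source)
            elif e.kind == "PH":
                self.ph_down.setdefault(e.source, set()).add(e.target)
                self.ph_up.setdefault(e.target, set()).add(e.source)
            else:  # GD
                self.gd_out.setdefault(e.source, set()).add(e.target)
                self.gd_in.setdefault(e.target, set()).add(e.source)
                self.gd_attrs[(e.source, e.target)] = (e.causal, e.moi)

    # -- queries -------------------------------------------------------------

    def node(self, node_id: str) -> NetworkNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise UnknownNodeError(node_id) from None

    def direct_disease_count(self, phenotype: str) -> int:
        """N_i: number of distinct diseases with a DP edge into ``phenotype``."""
        self.node(phenotype)
        return len(self.dp_in.get(phenotype, ()))

    def candidate_diseases(
        self, genes: set[str] | list[str]
    ) -> tuple[dict[str, set[str]], list[str]]:
        """Diseases one GD edge away from the input genes (algorithm step 1).

        Returns ``(diseases, skipped)`` where ``diseases`` maps each candidate
        disease to the set of input genes implicating it, and ``skipped``
        lists inputs that are unknown or not gene nodes (reported, not fatal).
        """
        diseases: dict[str, set[str]] = {}
        skipped: list[str] = []
        for g in sorted(set(genes)):
            n = self.nodes.get(g)
            if n is None or not n.is_gene:
                skipped.append(g)
                continue
            for d in self.gd_out.get(g, ()):
                diseases.setdefault(d, set()).add(g)
        return diseases, skipped

    # -- validation ----------------------------------------------------------

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        err = report.errors.append
        warn = report.warnings.append
        for e in self.edges:
            s, t = self.nodes[e.source], self.nodes[e.target]
            if e.kind == "GD":
                if not s.is_gene:
                    err(Violation("GD-source-not-gene", f"{e.source}->{e.target}"))
                if not t.is_disease:
                    err(Violation("GD-target-not-disease", f"{e.source}->{e.target}"))
            elif e.kind == "DP":
                if not s.is_disease:
                    err(Violation("DP-source-not-disease", f"{e.source}->{e.target}"))
                if not t.is_phenotype:
                    err(Violation("DP-target-not-phenotype", f"{e.source}->{e.target}"))
            else:
                if not s.is_phenotype:
                    err(Violation("PH-source-not-term", f"{e.source}->{e.target}"))
                if not t.is_phenotype:
                    err(Violation("PH-target-not-term", f"{e.source}->{e.target}"))
        ph = nx.DiGraph(
            (e.source, e.target) for e in self.edges if e.kind == "PH"
        )
        if ph.number_of_edges() and not nx.is_directed_acyclic_graph(ph):
            cycle = nx.find_cycle(ph)
            err(Violation("PH-cycle", " -> ".join(u for u, _ in cycle)))
        for n in self.nodes.values():
            if n.is_gene and n.id not in self.gd_out:
                warn(Violation("gene-without-GD-edge", n.id))
            incident = (
                n.id in self.dp_in or n.id in self.dp_out
                or n.id in self.ph_up or n.id in self.ph_down
                or n.id in self.gd_in or n.id in self.gd_out
            )
            if not incident:
                warn(Violation("isolated-node", n.id))
        return report


def _parse_flag(value: str, line_no: int, path: str) -> bool:
    if value not in ("0", "1"):
        raise GraphLoadError(f"{path}:{line_no}: role flag must be 0 or 1, got {value!r}")
    return value == "1"


def load_graph(node_table: str | Path, edge_table: str | Path, *,
               validate: bool = True) -> KnowledgeGraph:
    """Load a graph from node/edge TSVs and (by default) enforce invariants.

    Node table header: ``id  name  is_gene  is_disease  is_phenotype``.
    Edge table header: ``source  target  kind`` with kind in GD/DP/PH, plus
    optional ``causal`` / ``moi`` columns on GD rows.

    Schema problems raise :class:`GraphLoadError` with the offending line
    number; invariant violations raise :class:`GraphValidationError`.
    """
    nodes: list[NetworkNode] = []
    seen_ids: set[str] = set()
    with open(node_table, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != NODE_COLUMNS:
            raise GraphLoadError(
                f"{node_table}:1: expected header {NODE_COLUMNS}, got {reader.fieldnames}"
            )
        for line_no, row in enumerate(reader, start=2):
            nid = row["id"]
            if not nid:
                raise GraphLoadError(f"{node_table}:{line_no}: empty node id")
            if nid in seen_ids:
                raise GraphLoadError(f"{node_table}:{line_no}: duplicate node id {nid!r}")
            seen_ids.add(nid)
            try:
                nodes.append(NetworkNode(
                    id=nid, name=row["name"],
                    is_gene=_parse_flag(row["is_gene"], line_no, str(node_table)),
                    is_disease=_parse_flag(row["is_disease"], line_no, str(node_table)),
                    is_phenotype=_parse_flag(row["is_phenotype"], line_no, str(node_table)),
                ))
            except ValueError as exc:
                raise GraphLoadError(f"{node_table}:{line_no}: {exc}") from None

    edges: list[NetworkEdge] = []
    with open(edge_table, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        base_ok = reader.fieldnames and list(reader.fieldnames[:3]) == EDGE_COLUMNS
        extra = list(reader.fieldnames[3:]) if reader.fieldnames else []
        if not base_ok or any(c not in EDGE_OPTIONAL_COLUMNS for c in extra):
            raise GraphLoadError(
                f"{edge_table}:1: expected header {EDGE_COLUMNS} "
                f"(optionally + {EDGE_OPTIONAL_COLUMNS}), got {reader.fieldnames}"
            )
        for line_no, row in enumerate(reader, start=2):
            kind = row["kind"]
            if kind not in EDGE_KINDS:
                raise GraphLoadError(
                    f"{edge_table}:{line_no}: unknown edge kind {kind!r}"
                )
            try:
                edges.append(NetworkEdge(
                    source=row["source"], target=row["target"], kind=kind,
                    causal=(row.get("causal") or None),
                    moi=(row.get("moi") or None),
                ))
            except ValueError as exc:
                raise GraphLoadError(f"{edge_table}:{line_no}: {exc}") from None

    g = KnowledgeGraph(nodes, edges)
    if validate:
        report = g.validate()
        if not report.ok:
            raise GraphValidationError(report)
    return g


def save_graph(g: KnowledgeGraph, node_table: str | Path, edge_table: str | Path) -> None:
    """Write the graph back to the TSV dialect ``load_graph`` reads."""
    with open(node_table, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(NODE_COLUMNS)
        for n in g.nodes.values():
            w.writerow([n.id, n.name, int(n.is_gene), int(n.is_disease),
                        int(n.is_phenotype)])
    has_attrs = any(e.causal or e.moi for e in g.edges)
    with open(edge_table, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EDGE_COLUMNS + (EDGE_OPTIONAL_COLUMNS if has_attrs else []))
        for e in g.edges:
            row = [e.source, e.target, e.kind]
            if has_attrs:
                row += [e.causal or "", e.moi or ""]
            w.writerow(row)


def from_obo(path: str | Path):
    """Import an OBO ontology as a PH-only graph plus a lexicon.

    ``is_a`` relations become PH edges parent→child (general → specific).
    Every term is flagged as a phenotype. Returns ``(KnowledgeGraph,
    lexicon_entries)`` where entries are ``(surface, node, entry_kind)``
    triples covering primary ids, alternate ids, names and synonyms.
    """
    import obonet

    onto = obonet.read_obo(str(path))
    nodes, edges, lexicon = [], [], []
    for term, data in onto.nodes(data=True):
        name = data.get("name", term)
        nodes.append(NetworkNode(id=term, name=name, is_phenotype=True))
        lexicon.append((term, term, "primary_id"))
        lexicon.append((name, term, "primary_name"))
        for alt in data.get("alt_id", []):
            lexicon.append((alt, term, "alternate_id"))
        for syn in data.get("synonym", []):
            # obonet keeps raw synonym lines: "text" TYPE [xrefs]
            text = syn.split('"')[1] if '"' in syn else syn
            lexicon.append((text, term, "synonym"))
    # obonet stores is_a as child -> parent; PH edges run parent -> child
    for child, parent, key in onto.edges(keys=True):
        if key == "is_a":
            edges.append(NetworkEdge(source=parent, target=child, kind="PH"))
    return KnowledgeGraph(nodes, edges), lexicon
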