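"""Map free-text phenotype terms and ontology identifiers onto graph nodes.

Matching is normalization + exact lookup: spacing, capitalization and
hyphenation are normalized, then the term is resolved against identifiers,
primary names, and synonyms with deterministic precedence id > name >
synonym. Edit-distance fuzzy matching is intentionally absent.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

ENTRY_KINDS = ("primary_name", "synonym", "primary_id", "alternate_id")

# identifier-shaped inputs (e.g. HP:0000213, HPX:0000042) take the id route
_ID_PATTERN = re.compile(r"[A-Za-z][A-Za-z0-9]*:\d+")
_WS_RUN = re.compile(r"\s+")


class MappingError(Exception):
    pass


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    node: str
    entry_kind: str

    def __post_init__(self):
        if not self.surface:
            raise ValueError("empty lexicon surface")
        if self.entry_kind not in ENTRY_KINDS:
            raise ValueError(f"unknown entry kind {self.entry_kind!r}")


@dataclass(frozen=True)
class TermMatch:
    query: str
    normalized_query: str
    matched_node: str | None
    match_kind: str  # "id" | "exact_name" | "synonym" | "none"
    note: str | None = None


@dataclass
class MappingReport:
    matches: list[TermMatch]
    mapped: set[str]
    unmapped: list[str]

    @property
    def mapped_fraction(self) -> float:
        total = len(self.matches)
        return (total - len(self.unmapped)) / total if total else 0.0


def normalize(term: str) -> str:
    """Canonical surface form: case-folded, -/_ become spaces, whitespace
    collapsed and stripped. Idempotent by construction."""
    return _WS_RUN.sub(" ", term.casefold().replace("-", " ").replace("_", " ")).strip()


class Lexicon:
    """Indexed synonym lexicon.

    Four indices keyed by normalized surface (ids are upper-cased instead of
    normalized, preserving the ``HP:0000213`` shape). Surfaces of the same
    entry kind that collide onto different nodes are recorded as ambiguous at
    build time and resolve to no match, with a diagnostic.
    """

    def __init__(self, entries: list[LexiconEntry]):
        self.entries = list(entries)
        self._by_kind: dict[str, dict[str, str]] = {k: {} for k in ENTRY_KINDS}
        self.ambiguous: dict[tuple[str, str], set[str]] = {}
        for e in self.entries:
            key = e.surface.upper() if e.entry_kind.endswith("_id") else normalize(e.surface)
            index = self._by_kind[e.entry_kind]
            prior = index.get(key)
            if prior is not None and prior != e.node:
                self.ambiguous.setdefault((key, e.entry_kind), {prior}).add(e.node)
            else:
                index[key] = e.node

    def _lookup(self, key: str, kind: str) -> str | None:
        if (key, kind) in self.ambiguous:
            return None
        return self._by_kind[kind].get(key)

    def map_term(self, term: str) -> TermMatch:
        """Resolve one input term; no-match is a result, not an error."""
        raw = term.strip()
        norm = normalize(term)
        if _ID_PATTERN.fullmatch(raw):
            key = raw.upper()
            for kind in ("primary_id", "alternate_id"):
                if (key, kind) in self.ambiguous:
                    return TermMatch(term, norm, None, "none",
                                     note=f"ambiguous {kind} {key!r}")
                node = self._by_kind[kind].get(key)
                if node is not None:
                    return TermMatch(term, norm, node, "id")
            return TermMatch(term, norm, None, "none")
        for kind, label in (("primary_name", "exact_name"), ("synonym", "synonym")):
            if (norm, kind) in self.ambiguous:
                return TermMatch(term, norm, None, "none",
                                 note=f"ambiguous {kind} {norm!r}")
            node = self._by_kind[kind].get(norm)
            if node is not None:
                note = None
                if label == "exact_name" and self._by_kind["synonym"].get(norm) not in (None, node):
                    note = "name match shadows a synonym of a different node"
                return TermMatch(term, norm, node, label, note=note)
        return TermMatch(term, norm, None, "none")

    def map_phenotype_list(self, terms: list[str]) -> tuple[set[str], MappingReport]:
        """Map a patient phenotype list to a deduplicated node set P.

        Order-independent: P and the unmapped report do not depend on input
        ordering. Raises :class:`MappingError` on an empty input list.
        """
        terms = [t for t in terms if t.strip()]
        if not terms:
            raise MappingError("no phenotypes supplied")
        matches = [self.map_term(t) for t in terms]
        mapped = {m.matched_node for m in matches if m.matched_node is not None}
        unmapped = [m.query for m in matches if m.matched_node is None]
        return mapped, MappingReport(matches=matches, mapped=mapped, unmapped=unmapped)


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a lexicon TSV with header ``surface  node  entry_kind``."""
    entries: list[LexiconEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        expected = ["surface", "node", "entry_kind"]
        if reader.fieldnames != expected:
            raise MappingError(f"{path}:1: expected header {expected}, got {reader.fieldnames}")
        for line_no, row in enumerate(reader, start=2):
            try:
                entries.append(LexiconEntry(row["surface"], row["node"], row["entry_kind"]))
            except ValueError as exc:
                raise MappingError(f"{path}:{line_no}: {exc}") from None
    return Lexicon(entries)


def save_lexicon(entries: list[LexiconEntry], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["surface", "node", "entry_kind"])
        for e in entries:
            w.writerow([e.surface, e.node, e.entry_kind])


def read_phenotype_file(path: str | Path) -> list[str]:
    """One term or identifier per line; ``#`` comment lines and blanks skipped."""
    terms = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.append(line)
    return terms
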