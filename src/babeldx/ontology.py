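"""Ontology loading, hierarchy traversal, and multilingual label lookup.

Ontologies are consumed as OBO-Graph JSON (the exchange format both HPO and
Mondo publish).  Only ``is_a`` edges are interpreted; every other edge type is
ignored with a debug log entry.  Translations are consumed from a simple
tab-separated table with columns ``term_id``, ``language``, ``type``
(``label`` or ``synonym``) and ``text``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: The ten language codes the toolkit ships template packs for.
STUDY_LANGUAGES = ("en", "zh", "cs", "nl", "fr", "de", "it", "ja", "es", "tr")

_CURIE_RE = re.compile(r"^[A-Z0-9]+:[^\s:]+$")
_IRI_RE = re.compile(r"^https?://.*/([A-Za-z0-9]+)_([A-Za-z0-9.-]+)$")


class OntologyError(Exception):
    """Raised for structural problems in an ontology file."""


class TermId(str):
    """A CURIE of the form ``PREFIX:LOCAL`` (e.g. ``MONDO:0007947``).

    Behaves as a plain string (hashable, JSON-serialisable) but validates
    its shape on construction.
    """

    __slots__ = ()

    def __new__(cls, curie: str) -> "TermId":
        if not isinstance(curie, str) or not _CURIE_RE.match(curie):
            raise ValueError(f"not a valid CURIE: {curie!r}")
        return super().__new__(cls, curie)

    @property
    def prefix(self) -> str:
        return self.partition(":")[0]

    @property
    def local(self) -> str:
        return self.partition(":")[2]


def _curie_from_node_id(raw: str) -> TermId | None:
    """Map an OBO-Graph node id (CURIE or OBO PURL) to a TermId, or None."""
    m = _IRI_RE.match(raw)
    if m:
        raw = f"{m.group(1)}:{m.group(2)}"
    try:
        return TermId(raw)
    except ValueError:
        return None


@dataclass
class OntologyTerm:
    id: TermId
    label: str
    synonyms: list[str] = field(default_factory=list)
    parents: list[TermId] = field(default_factory=list)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if self.id in self.parents:
            raise OntologyError(f"term {self.id} lists itself as a parent")
        if not self.label and not self.obsolete:
            raise OntologyError(f"non-obsolete term {self.id} has no label")


class OntologyGraph:
    """An in-memory is-a DAG with label/synonym lookup.

    Parent references must resolve within the graph and the is-a closure must
    be acyclic; both are verified on construction.
    """

    def __init__(self, terms: dict[TermId, OntologyTerm], version: str = ""):
        self.terms = terms
        self.version = version
        self._children: dict[TermId, list[TermId]] = {t: [] for t in terms}
        for term in terms.values():
            for p in term.parents:
                if p not in terms:
                    raise OntologyError(
                        f"term {term.id} references unknown parent {p}"
                    )
                self._children[p].append(term.id)
        cycle = self._find_cycle()
        if cycle is not None:
            raise OntologyError(f"is_a cycle detected involving {cycle}")

    def _find_cycle(self) -> TermId | None:
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {t: WHITE for t in self.terms}
        for start in self.terms:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[TermId, int]] = [(start, 0)]
            colour[start] = GREY
            while stack:
                node, idx = stack[-1]
                parents = self.terms[node].parents
                if idx < len(parents):
                    stack[-1] = (node, idx + 1)
                    nxt = parents[idx]
                    if colour[nxt] == GREY:
                        return nxt
                    if colour[nxt] == WHITE:
                        colour[nxt] = GREY
                        stack.append((nxt, 0))
                else:
                    colour[node] = BLACK
                    stack.pop()
        return None

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def label(self, term_id: TermId) -> str:
        return self.terms[term_id].label

    def ancestors(self, term_id: TermId) -> set[TermId]:
        """Transitive is-a closure of ``term_id``, excluding the term itself."""
        if term_id not in self.terms:
            raise KeyError(term_id)
        seen: set[TermId] = set()
        stack = list(self.terms[term_id].parents)
        while stack:
            node = stack.pop()
            if node not in seen:
                seen.add(node)
                stack.extend(self.terms[node].parents)
        return seen

    def descendants(self, term_id: TermId) -> set[TermId]:
        """Transitive inverse is-a closure, excluding the term itself."""
        if term_id not in self.terms:
            raise KeyError(term_id)
        seen: set[TermId] = set()
        stack = list(self._children[term_id])
        while stack:
            node = stack.pop()
            if node not in seen:
                seen.add(node)
                stack.extend(self._children[node])
        return seen

    def children(self, term_id: TermId) -> list[TermId]:
        return list(self._children[term_id])

    def roots(self) -> list[TermId]:
        return sorted(t.id for t in self.terms.values() if not t.parents)


def load_obograph(path) -> OntologyGraph:
    """Load an OBO-Graph JSON file into an :class:`OntologyGraph`.

    Nodes whose id cannot be interpreted as a CURIE (directly or via an OBO
    PURL) are skipped.  Edges with a predicate other than ``is_a`` /
    ``rdfs:subClassOf`` are ignored.
    """
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise OntologyError(f"malformed OBO-Graph JSON in {path}: {exc}") from exc

    graphs = doc.get("graphs")
    if not graphs:
        raise OntologyError(f"{path}: no 'graphs' array")
    g = graphs[0]
    version = g.get("meta", {}).get("version", "") or ""

    terms: dict[TermId, OntologyTerm] = {}
    raw_to_curie: dict[str, TermId] = {}
    for node in g.get("nodes", []):
        if node.get("type") not in (None, "CLASS"):
            continue
        curie = _curie_from_node_id(node.get("id", ""))
        if curie is None:
            logger.debug("skipping non-CURIE node %r", node.get("id"))
            continue
        meta = node.get("meta") or {}
        synonyms = [s["val"] for s in meta.get("synonyms", []) if s.get("val")]
        terms[curie] = OntologyTerm(
            id=curie,
            label=node.get("lbl", "") or "",
            synonyms=synonyms,
            obsolete=bool(meta.get("deprecated", False)),
        )
        raw_to_curie[node["id"]] = curie

    for edge in g.get("edges", []):
        pred = edge.get("pred")
        if pred not in ("is_a", "rdfs:subClassOf"):
            logger.debug("ignoring edge predicate %r", pred)
            continue
        sub = raw_to_curie.get(edge.get("sub")) or _curie_from_node_id(edge.get("sub", ""))
        obj = raw_to_curie.get(edge.get("obj")) or _curie_from_node_id(edge.get("obj", ""))
        if sub is None or obj is None:
            continue
        if sub not in terms:
            raise OntologyError(f"edge subject {edge.get('sub')!r} not among nodes")
        if obj not in terms:
            raise OntologyError(
                f"term {sub} references unknown parent {edge.get('obj')!r}"
            )
        if obj not in terms[sub].parents:
            terms[sub].parents.append(obj)

    return OntologyGraph(terms, version=version)


def save_obograph(graph: OntologyGraph, path) -> None:
    """Serialise a graph back to OBO-Graph JSON (is-a edges only)."""
    nodes = []
    edges = []
    for term in sorted(graph, key=lambda t: t.id):
        node: dict = {"id": str(term.id), "lbl": term.label, "type": "CLASS"}
        meta: dict = {}
        if term.synonyms:
            meta["synonyms"] = [
                {"pred": "hasExactSynonym", "val": s} for s in term.synonyms
            ]
        if term.obsolete:
            meta["deprecated"] = True
        if meta:
            node["meta"] = meta
        nodes.append(node)
        for p in term.parents:
            edges.append({"sub": str(term.id), "pred": "is_a", "obj": str(p)})
    doc = {
        "graphs": [
            {
                "id": "babeldx",
                "meta": {"version": graph.version},
                "nodes": nodes,
                "edges": edges,
            }
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=1)


# ---------------------------------------------------------------------------
# Translations
# ---------------------------------------------------------------------------


class MissingTranslationError(KeyError):
    """A (term, language) pair has no translation and fallback is disabled."""


@dataclass
class TranslationEntry:
    term: TermId
    language: str
    label: str
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError(f"empty translated label for {self.term}/{self.language}")


class TranslationTable:
    """Primary labels and synonyms per (term, language).

    English entries act as the fallback tier: :meth:`translate` returns the
    English label (with a logged warning) when the requested language has no
    entry and ``fallback`` is enabled.
    """

    def __init__(self) -> None:
        self.entries: dict[tuple[TermId, str], TranslationEntry] = {}

    def add(self, term: TermId, language: str, text: str, *, synonym: bool = False) -> None:
        key = (term, language)
        entry = self.entries.get(key)
        if synonym:
            if entry is None:
                raise ValueError(
                    f"synonym for {term}/{language} before its primary label"
                )
            entry.synonyms.append(text)
        else:
            if entry is not None:
                raise ValueError(f"duplicate primary label for {term}/{language}")
            self.entries[key] = TranslationEntry(term, language, text)

    def has(self, term: TermId, language: str) -> bool:
        return (term, language) in self.entries

    def languages(self) -> set[str]:
        return {lang for (_, lang) in self.entries}

    def terms(self) -> set[TermId]:
        return {term for (term, _) in self.entries}

    @property
    def coverage(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for (_, lang) in self.entries:
            counts[lang] = counts.get(lang, 0) + 1
        return counts

    def translate(self, term: TermId, language: str, *, fallback: bool = True) -> str:
        """Return the primary label of ``term`` in ``language``.

        Falls back to the English label with a warning when enabled;
        otherwise raises :class:`MissingTranslationError`.  A term with no
        entry in any language raises ``KeyError``.
        """
        entry = self.entries.get((term, language))
        if entry is not None:
            return entry.label
        english = self.entries.get((term, "en"))
        if english is None:
            raise KeyError(term)
        if not fallback:
            raise MissingTranslationError(f"no {language} translation for {term}")
        logger.warning("no %s translation for %s; falling back to English", language, term)
        return english.label


def load_translation_tsv(path) -> TranslationTable:
    """Read a translation table (term_id, language, type, text; tab-separated)."""
    table = TranslationTable()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["term_id", "language", "type", "text"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            term_id, language, kind, text = parts
            if kind not in ("label", "synonym"):
                raise ValueError(f"{path}:{lineno}: bad type {kind!r}")
            table.add(TermId(term_id), language, text, synonym=kind == "synonym")
    return table


def save_translation_tsv(table: TranslationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tlanguage\ttype\ttext\n")
        for (term, lang) in sorted(table.entries):
            entry = table.entries[(term, lang)]
            fh.write(f"{term}\t{lang}\tlabel\t{entry.label}\n")
            for syn in entry.synonyms:
                fh.write(f"{term}\t{lang}\tsynonym\t{syn}\n")
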