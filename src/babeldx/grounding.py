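"""Parse raw model replies into ordered differentials and ground them.

Grounding is exact matching of normalised candidate strings against an index
built from the labels and synonyms of every non-obsolete disease term.  A
candidate that cannot be grounded keeps its rank with ``failure=True`` —
failures are part of the accounting, not errors.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field

from .ontology import OntologyGraph, TermId

logger = logging.getLogger(__name__)

_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―−"), "-")
_APOSTROPHES = dict.fromkeys(map(ord, "‘’‛ʼ`´"), "'")
_QUOTES = dict.fromkeys(map(ord, "“”„"), '"')
_EDGE_PUNCT = " \t\"'.,;:!?()[]{}"
_WS_RE = re.compile(r"\s+")


def normalize_label(s: str) -> str:
    """Canonicalise a disease name for exact-match lookup.

    NFKC, case fold, typographic dash/apostrophe mapping, whitespace collapse
    and edge-punctuation stripping.  Idempotent by construction.
    """
    s = unicodedata.normalize("NFKC", s)
    s = s.translate(_DASHES).translate(_APOSTROPHES).translate(_QUOTES)
    s = s.casefold()
    s = _WS_RE.sub(" ", s).strip()
    s = s.strip(_EDGE_PUNCT)
    return s


@dataclass
class GroundingIndex:
    """Normalised-string -> TermId map with a documented collision policy.

    A primary label beats a synonym; among entries of equal kind the
    lexicographically smallest TermId wins.  Collisions are logged.
    """

    entries: dict[str, TermId] = field(default_factory=dict)
    is_label: dict[str, bool] = field(default_factory=dict)
    collisions: list[tuple[str, TermId, TermId]] = field(default_factory=list)

    def _insert(self, key: str, term_id: TermId, as_label: bool) -> None:
        if not key:
            return
        current = self.entries.get(key)
        if current is None:
            self.entries[key] = term_id
            self.is_label[key] = as_label
            return
        if current == term_id:
            self.is_label[key] = self.is_label[key] or as_label
            return
        self.collisions.append((key, current, term_id))
        incumbent_label = self.is_label[key]
        if as_label and not incumbent_label:
            winner, winner_label = term_id, True
        elif incumbent_label and not as_label:
            winner, winner_label = current, True
        else:
            winner, winner_label = min(current, term_id), incumbent_label
        logger.debug("grounding collision on %r: %s vs %s -> %s", key, current, term_id, winner)
        self.entries[key] = winner
        self.is_label[key] = winner_label

    def lookup(self, raw: str) -> TermId | None:
        return self.entries.get(normalize_label(raw))

    def __len__(self) -> int:
        return len(self.entries)


def build_grounding_index(graph: OntologyGraph) -> GroundingIndex:
    """Index every non-obsolete term's normalised label and synonyms."""
    index = GroundingIndex()
    for term in sorted(graph, key=lambda t: t.id):
        if term.obsolete:
            continue
        index._insert(normalize_label(term.label), term.id, True)
        for synonym in term.synonyms:
            index._insert(normalize_label(synonym), term.id, False)
    return index


# ---------------------------------------------------------------------------
# Reply parsing
# ---------------------------------------------------------------------------

_NUMBERED_RE = re.compile(r"^\s*\d+\s*[.)\]:-]\s*(.+)$")
_BULLET_RE = re.compile(r"^\s*[-*•]\s+(.+)$")
_TRAILING_PAREN_RE = re.compile(r"\s*\([^()]*\)\s*$")

# plain one-candidate-per-line blocks: short noun phrases only, so prose such
# as an apology never parses as a differential
_MAX_PLAIN_WORDS = 10


def parse_differential(raw: str) -> list[str]:
    """Extract ordered candidate strings from a raw reply.

    Recognises numbered lists, bulleted lists, and short one-candidate-per-line
    blocks, in that order of precedence.  An empty extraction means refusal
    and is returned as an empty list.
    """
    lines = [ln for ln in raw.splitlines() if ln.strip()]
    numbered = []
    for ln in lines:
        m = _NUMBERED_RE.match(ln)
        if m:
            numbered.append(m.group(1).strip())
    if numbered:
        return numbered
    bulleted = []
    for ln in lines:
        m = _BULLET_RE.match(ln)
        if m:
            bulleted.append(m.group(1).strip())
    if bulleted:
        return bulleted
    if len(lines) >= 1:
        plain = [ln.strip().rstrip(".") for ln in lines]
        if all(0 < len(p.split()) <= _MAX_PLAIN_WORDS for p in plain):
            return plain
    return []


@dataclass
class CandidateDiagnosis:
    rank: int
    raw_text: str
    grounded: TermId | None = None
    failure: bool = False

    def __post_init__(self) -> None:
        if (self.grounded is None) == (not self.failure):
            raise ValueError("exactly one of grounded/failure must hold")


@dataclass
class DifferentialResult:
    case_id: str
    language: str
    candidates: list[CandidateDiagnosis]
    refusal: bool

    def __post_init__(self) -> None:
        if self.refusal != (len(self.candidates) == 0):
            raise ValueError("refusal must coincide with an empty candidate list")
        for i, c in enumerate(self.candidates, start=1):
            if c.rank != i:
                raise ValueError("candidate ranks must be consecutive from 1")


def ground(raw_candidates: list[str], index: GroundingIndex) -> list[CandidateDiagnosis]:
    """Ground each candidate string; misses keep their rank as failures.

    A single terminal parenthetical (gene symbol, OMIM id, ...) is stripped
    before lookup; if the stripped form misses, the unstripped form is tried.
    """
    out: list[CandidateDiagnosis] = []
    for rank, raw in enumerate(raw_candidates, start=1):
        stripped = _TRAILING_PAREN_RE.sub("", raw)
        hit = index.lookup(stripped) if stripped else None
        if hit is None and stripped != raw:
            hit = index.lookup(raw)
        if hit is None:
            out.append(CandidateDiagnosis(rank=rank, raw_text=raw, failure=True))
        else:
            out.append(CandidateDiagnosis(rank=rank, raw_text=raw, grounded=hit))
    return out


def ground_reply(
    case_id: str, language: str, raw: str, index: GroundingIndex
) -> DifferentialResult:
    """Parse + ground one raw reply into a :class:`DifferentialResult`."""
    raw_candidates = parse_differential(raw)
    return DifferentialResult(
        case_id=case_id,
        language=language,
        candidates=ground(raw_candidates, index),
        refusal=not raw_candidates,
    )
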