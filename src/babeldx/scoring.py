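"""Ontology-aware correctness scoring and per-language aggregation.

A diagnosis and its genetic subtypes are treated as interchangeable: the
equivalence class of a diagnosis always includes its descendants, and climbs
to a parent (plus that parent's descendants) only when the parent looks like
a clinical grouping term for the diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .grounding import DifferentialResult
from .ontology import OntologyGraph, TermId


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention used for reported percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EquivalenceClass:
    diagnosis: TermId
    members: set[TermId]
    grouping_anchor: TermId | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in self.members:
            raise ValueError("diagnosis must be a member of its own equivalence class")


def build_equivalence(
    graph: OntologyGraph,
    diagnosis: TermId,
    grouping_terms: frozenset[TermId] | set[TermId] = frozenset(),
) -> EquivalenceClass:
    """Compute the set of term ids accepted as correct for ``diagnosis``.

    Members are the diagnosis, its descendants, and — for each parent that is
    either explicitly configured as a grouping term or whose label is a prefix
    of the diagnosis label (e.g. a "... syndrome" parent of "... syndrome
    type 1") — the parent and all of its descendants.
    """
    if diagnosis not in graph:
        raise KeyError(diagnosis)
    members = {diagnosis} | graph.descendants(diagnosis)
    anchor: TermId | None = None
    diagnosis_label = graph.label(diagnosis)
    for parent in graph.terms[diagnosis].parents:
        is_grouping = parent in grouping_terms or (
            bool(graph.label(parent)) and diagnosis_label.startswith(graph.label(parent))
        )
        if is_grouping:
            members |= {parent} | graph.descendants(parent)
            if anchor is None or parent < anchor:
                anchor = parent
    return EquivalenceClass(diagnosis=diagnosis, members=members, grouping_anchor=anchor)


@dataclass
class CaseScore:
    case_id: str
    language: str
    correct_rank: int | None
    refusal: bool
    n_candidates: int
    n_grounding_failures: int

    def __post_init__(self) -> None:
        if self.refusal and (self.correct_rank is not None or self.n_candidates):
            raise ValueError("a refusal carries no candidates and no correct rank")


def score_case(diff: DifferentialResult, eq: EquivalenceClass) -> CaseScore:
    """Best (minimum) rank at which any equivalence-class member appears."""
    correct_rank = None
    for candidate in diff.candidates:
        if candidate.grounded is not None and candidate.grounded in eq.members:
            correct_rank = candidate.rank
            break  # candidates are rank-ordered, first hit is minimal
    return CaseScore(
        case_id=diff.case_id,
        language=diff.language,
        correct_rank=correct_rank,
        refusal=diff.refusal,
        n_candidates=len(diff.candidates),
        n_grounding_failures=sum(1 for c in diff.candidates if c.failure),
    )


@dataclass
class LanguageSummary:
    """Per-language counts in the cumulative convention of the result tables."""

    language: str
    n_total: int
    top1: int
    top3: int
    top10: int
    beyond10: int
    not_ranked: int
    no_diagnosis: int

    def __post_init__(self) -> None:
        if not self.top1 <= self.top3 <= self.top10:
            raise ValueError("cumulative counts must be monotone: top1 <= top3 <= top10")
        if self.top10 + self.beyond10 + self.not_ranked + self.no_diagnosis != self.n_total:
            raise ValueError("counts must partition the total")


def aggregate_language(scores: list[CaseScore]) -> LanguageSummary:
    if not scores:
        raise ValueError("no scores to aggregate")
    languages = {s.language for s in scores}
    if len(languages) > 1:
        raise ValueError(f"mixed languages in aggregation: {sorted(languages)}")
    ranks = [s.correct_rank for s in scores]
    return LanguageSummary(
        language=scores[0].language,
        n_total=len(scores),
        top1=sum(1 for r in ranks if r is not None and r <= 1),
        top3=sum(1 for r in ranks if r is not None and r <= 3),
        top10=sum(1 for r in ranks if r is not None and r <= 10),
        beyond10=sum(1 for r in ranks if r is not None and r > 10),
        no_diagnosis=sum(1 for s in scores if s.refusal),
        not_ranked=sum(1 for s in scores if s.correct_rank is None and not s.refusal),
    )


def grounding_failure_rate(scores: list[CaseScore]) -> float:
    """Grounding failures as a fraction of all candidates across cases."""
    n_candidates = sum(s.n_candidates for s in scores)
    if n_candidates == 0:
        return 0.0
    return sum(s.n_grounding_failures for s in scores) / n_candidates


def topn_frequency(
    summary: LanguageSummary, n: int, denominator: str = "exclude_refusals"
) -> float:
    """Top-N percentage, rounded half-up to one decimal.

    ``exclude_refusals`` divides by ``n_total - no_diagnosis`` (the figure
    convention); ``all`` divides by ``n_total``.
    """
    if n not in (1, 3, 10):
        raise ValueError("n must be 1, 3 or 10")
    top = {1: summary.top1, 3: summary.top3, 10: summary.top10}[n]
    if denominator == "exclude_refusals":
        denom = summary.n_total - summary.no_diagnosis
    elif denominator == "all":
        denom = summary.n_total
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if denom == 0:
        raise ZeroDivisionError("no cases left in the denominator")
    return round_half_up(100.0 * top / denom, 1)


@dataclass
class ScoringConfig:
    grouping_terms: frozenset[TermId] = frozenset()


def score_run(
    differentials: list[DifferentialResult],
    diagnoses: dict[str, TermId],
    graph: OntologyGraph,
    config: ScoringConfig | None = None,
) -> dict[str, LanguageSummary]:
    """Score a whole run and aggregate per language.

    ``diagnoses`` maps case_id to the true diagnosis term.  Equivalence
    classes are cached per diagnosis.
    """
    config = config or ScoringConfig()
    eq_cache: dict[TermId, EquivalenceClass] = {}
    per_language: dict[str, list[CaseScore]] = {}
    for diff in differentials:
        diagnosis = diagnoses[diff.case_id]
        eq = eq_cache.get(diagnosis)
        if eq is None:
            eq = build_equivalence(graph, diagnosis, config.grouping_terms)
            eq_cache[diagnosis] = eq
        per_language.setdefault(diff.language, []).append(score_case(diff, eq))
    return {lang: aggregate_language(scores) for lang, scores in sorted(per_language.items())}


def score_run_cases(
    differentials: list[DifferentialResult],
    diagnoses: dict[str, TermId],
    graph: OntologyGraph,
    config: ScoringConfig | None = None,
) -> list[CaseScore]:
    """Per-case scores for a whole run (input to the rank-based statistics)."""
    config = config or ScoringConfig()
    eq_cache: dict[TermId, EquivalenceClass] = {}
    out = []
    for diff in differentials:
        diagnosis = diagnoses[diff.case_id]
        if diagnosis not in eq_cache:
            eq_cache[diagnosis] = build_equivalence(graph, diagnosis, config.grouping_terms)
        out.append(score_case(diff, eq_cache[diagnosis]))
    return out
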