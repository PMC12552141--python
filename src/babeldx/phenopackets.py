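"""Read/write the subset of the GA4GH Phenopacket Schema v2 the pipeline uses.

Only subject sex/age, phenotypic features (with ``excluded`` flags and onset
ages) and the disease diagnosis are mapped.  Genetic and variant information
present in a file is deliberately dropped so it can never leak into prompts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .ontology import OntologyGraph, TermId, TranslationTable


class PhenopacketError(ValueError):
    """Raised when a phenopacket file violates the supported subset."""


class Sex(str, Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"
    UNKNOWN = "UNKNOWN"


_DURATION_RE = re.compile(
    r"^P(?:(?P<years>\d+)Y)?(?:(?P<months>\d+)M)?(?:(?P<weeks>\d+)W)?(?:(?P<days>\d+)D)?$"
)


def parse_iso8601_duration(value: str) -> dict[str, int]:
    """Parse the date part of an ISO-8601 duration into unit counts.

    Returns a dict with ``years``/``months``/``weeks``/``days`` keys.  Time
    components are not supported; an empty or malformed duration raises
    ``ValueError``.
    """
    m = _DURATION_RE.match(value)
    if not m or value == "P":
        raise ValueError(f"unparseable ISO-8601 duration: {value!r}")
    return {k: int(v) if v else 0 for k, v in m.groupdict().items()}


@dataclass
class SubjectInfo:
    sex: Sex = Sex.UNKNOWN
    age: str | None = None  # ISO-8601 duration, kept verbatim

    def __post_init__(self) -> None:
        if self.age is not None:
            parse_iso8601_duration(self.age)


@dataclass
class PhenotypeObservation:
    term: TermId
    excluded: bool = False
    onset: str | None = None  # ISO-8601 duration

    def __post_init__(self) -> None:
        if self.term.prefix != "HP":
            raise PhenopacketError(f"phenotypic feature with non-HP term {self.term}")
        if self.onset is not None:
            parse_iso8601_duration(self.onset)


@dataclass
class CaseRecord:
    """One patient vignette: demographics, features, and the true diagnosis."""

    id: str
    subject: SubjectInfo
    features: list[PhenotypeObservation]
    diagnosis: TermId
    diagnosis_label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise PhenopacketError("case id must be non-empty")
        if not any(not f.excluded for f in self.features):
            raise PhenopacketError(
                f"case {self.id}: at least one observed (non-excluded) feature required"
            )

    @property
    def observed(self) -> list[PhenotypeObservation]:
        return [f for f in self.features if not f.excluded]

    @property
    def excluded(self) -> list[PhenotypeObservation]:
        return [f for f in self.features if f.excluded]


def _feature_from_json(obj: dict) -> PhenotypeObservation:
    try:
        term = TermId(obj["type"]["id"])
    except (KeyError, ValueError) as exc:
        raise PhenopacketError(f"bad phenotypic feature: {obj!r}") from exc
    onset = None
    onset_obj = obj.get("onset", {})
    if isinstance(onset_obj, dict):
        onset = onset_obj.get("age", {}).get("iso8601duration")
    return PhenotypeObservation(
        term=term, excluded=bool(obj.get("excluded", False)), onset=onset
    )


def _diagnosis_from_json(doc: dict) -> tuple[TermId, str]:
    # Prefer the `diseases` block; fall back to interpretations[0].diagnosis.
    diseases = doc.get("diseases") or []
    if diseases:
        term = diseases[0].get("term", {})
    else:
        interp = doc.get("interpretations") or []
        term = (
            interp[0].get("diagnosis", {}).get("disease", {}) if interp else {}
        )
    if not term.get("id"):
        raise PhenopacketError("phenopacket carries no disease diagnosis")
    try:
        return TermId(term["id"]), term.get("label", "")
    except ValueError as exc:
        raise PhenopacketError(f"bad diagnosis id {term['id']!r}") from exc


def phenopacket_to_record(doc: dict, default_id: str = "case") -> CaseRecord:
    subject_obj = doc.get("subject", {})
    sex = Sex(subject_obj.get("sex", "UNKNOWN") or "UNKNOWN")
    age = (
        subject_obj.get("timeAtLastEncounter", {})
        .get("age", {})
        .get("iso8601duration")
    )
    try:
        subject = SubjectInfo(sex=sex, age=age)
    except ValueError as exc:
        raise PhenopacketError(str(exc)) from exc
    features = [_feature_from_json(f) for f in doc.get("phenotypicFeatures", [])]
    diagnosis, label = _diagnosis_from_json(doc)
    return CaseRecord(
        id=doc.get("id") or default_id,
        subject=subject,
        features=features,
        diagnosis=diagnosis,
        diagnosis_label=label,
    )


def record_to_phenopacket(record: CaseRecord) -> dict:
    subject: dict = {"sex": record.subject.sex.value}
    if record.subject.age is not None:
        subject["timeAtLastEncounter"] = {
            "age": {"iso8601duration": record.subject.age}
        }
    features = []
    for f in record.features:
        obj: dict = {"type": {"id": str(f.term)}}
        if f.excluded:
            obj["excluded"] = True
        if f.onset is not None:
            obj["onset"] = {"age": {"iso8601duration": f.onset}}
        features.append(obj)
    return {
        "id": record.id,
        "subject": subject,
        "phenotypicFeatures": features,
        "diseases": [
            {"term": {"id": str(record.diagnosis), "label": record.diagnosis_label}}
        ],
        "metaData": {"phenopacketSchemaVersion": "2.0"},
    }


def read_phenopacket(path) -> CaseRecord:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise PhenopacketError(f"unreadable phenopacket JSON {path}: {exc}") from exc
    return phenopacket_to_record(doc, default_id=Path(path).stem)


def write_phenopacket(record: CaseRecord, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record_to_phenopacket(record), fh, ensure_ascii=False, indent=1)


def read_corpus(directory) -> list[CaseRecord]:
    """Read every ``*.json`` phenopacket in a directory, sorted by filename."""
    return [read_phenopacket(p) for p in sorted(Path(directory).glob("*.json"))]


@dataclass
class CorpusValidationReport:
    results: dict[str, bool] = field(default_factory=dict)
    missing: dict[str, list[tuple[TermId, str]]] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return sum(self.results.values())

    @property
    def n_excluded(self) -> int:
        return len(self.results) - self.n_retained

    def retained_ids(self) -> list[str]:
        return [cid for cid, ok in self.results.items() if ok]


def validate_corpus(
    records: list[CaseRecord],
    graph: OntologyGraph,
    table: TranslationTable,
    languages: list[str],
) -> CorpusValidationReport:
    """Flag records whose feature terms are not fully translated.

    A record passes only if every feature term (observed and excluded) is in
    the ontology and has a translation in every requested language.  An empty
    language list retains everything.
    """
    report = CorpusValidationReport()
    for record in records:
        gaps: list[tuple[TermId, str]] = []
        for feature in record.features:
            if feature.term not in graph:
                gaps.append((feature.term, "<ontology>"))
                continue
            for lang in languages:
                if not table.has(feature.term, lang):
                    gaps.append((feature.term, lang))
        report.results[record.id] = not gaps
        if gaps:
            report.missing[record.id] = gaps
    return report
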