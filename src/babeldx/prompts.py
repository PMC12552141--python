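"""Render case records into narrative zero-shot prompts from template packs.

A template pack is a per-language YAML file of pre-inflected sentence frames;
adding a language requires no code.  The example output block is always
English, and non-English packs carry an explicit instruction to reply in
English so that downstream grounding can use an English disease-name index.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .ontology import MissingTranslationError, TermId, TranslationTable
from .phenopackets import CaseRecord, Sex, parse_iso8601_duration

SEXES = ("FEMALE", "MALE", "UNKNOWN")
AGE_CLASSES = ("aged", "unaged")


class TemplatePackError(ValueError):
    """A template pack fails the schema or placeholder audit."""


@dataclass
class TemplatePack:
    language: str
    header_text: str
    example_output_block: str
    english_reply_instruction: str
    sex_age_frames: dict[str, dict[str, str]]  # sex -> age-class -> frame
    observed_frame: str
    excluded_frame: str
    onset_frame: str
    list_separator: str
    final_conjunction: str
    age_phrase_rules: dict[str, str]  # year|month|day -> phrase with {n}

    def __post_init__(self) -> None:
        self._audit()

    def _audit(self) -> None:
        """Verify every frame exists and contains exactly the expected slots."""
        if not self.language:
            raise TemplatePackError("missing field: language")
        for name in ("header_text", "example_output_block", "observed_frame",
                     "excluded_frame", "onset_frame"):
            if not getattr(self, name):
                raise TemplatePackError(f"missing field: {name}")
        if self.language != "en" and not self.english_reply_instruction:
            raise TemplatePackError(
                "missing field: english_reply_instruction (required for non-English packs)"
            )
        for sex in SEXES:
            frames = self.sex_age_frames.get(sex)
            if not frames:
                raise TemplatePackError(f"missing field: sex_age_frames.{sex}")
            for age_class in AGE_CLASSES:
                frame = frames.get(age_class)
                if frame is None:
                    raise TemplatePackError(
                        f"missing field: sex_age_frames.{sex}.{age_class}"
                    )
                needs_age = age_class == "aged"
                if ("{age}" in frame) != needs_age:
                    raise TemplatePackError(
                        f"placeholder audit failed: sex_age_frames.{sex}.{age_class}"
                    )
        if "{features}" not in self.observed_frame:
            raise TemplatePackError("placeholder audit failed: observed_frame")
        if "{features}" not in self.excluded_frame:
            raise TemplatePackError("placeholder audit failed: excluded_frame")
        if "{onset}" not in self.onset_frame or "{features}" not in self.onset_frame:
            raise TemplatePackError("placeholder audit failed: onset_frame")
        for unit in ("year", "month", "day"):
            rule = self.age_phrase_rules.get(unit)
            if not rule or "{n}" not in rule:
                raise TemplatePackError(f"placeholder audit failed: age_phrase_rules.{unit}")


def _pack_from_mapping(doc: dict, source: str) -> TemplatePack:
    try:
        return TemplatePack(
            language=doc["language"],
            header_text=doc["header_text"],
            example_output_block=doc["example_output_block"],
            english_reply_instruction=doc.get("english_reply_instruction", ""),
            sex_age_frames=doc["sex_age_frames"],
            observed_frame=doc["observed_frame"],
            excluded_frame=doc["excluded_frame"],
            onset_frame=doc["onset_frame"],
            list_separator=doc["list_separator"],
            final_conjunction=doc["final_conjunction"],
            age_phrase_rules=doc["age_phrase_rules"],
        )
    except KeyError as exc:
        raise TemplatePackError(f"{source}: missing field: {exc.args[0]}") from exc


def load_template_pack(path) -> TemplatePack:
    """Load and audit one template pack YAML file."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise TemplatePackError(f"{path}: not a mapping")
    return _pack_from_mapping(doc, str(path))


def get_template_pack(language: str) -> TemplatePack:
    """Load one of the shipped per-language packs by ISO 639-1 code."""
    ref = resources.files("babeldx").joinpath(f"data/templates/{language}.yaml")
    if not ref.is_file():
        raise TemplatePackError(f"no shipped template pack for language {language!r}")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _pack_from_mapping(doc, f"<shipped:{language}>")


def render_age_phrase(age: str, pack: TemplatePack) -> str:
    """Localise an ISO-8601 duration as an age phrase.

    Mixed-unit durations truncate to the largest populated unit: years if
    >= 1 year, else months if >= 1 month, else days (weeks fold into days).
    """
    parts = parse_iso8601_duration(age)
    if parts["years"] >= 1:
        return pack.age_phrase_rules["year"].format(n=parts["years"])
    if parts["months"] >= 1:
        return pack.age_phrase_rules["month"].format(n=parts["months"])
    return pack.age_phrase_rules["day"].format(n=parts["days"] + 7 * parts["weeks"])


def _format_list(items: list[str], pack: TemplatePack) -> str:
    if len(items) == 1:
        return items[0]
    return pack.list_separator.join(items[:-1]) + pack.final_conjunction + items[-1]


def _onset_sort_key(onset: str) -> tuple:
    p = parse_iso8601_duration(onset)
    days = p["years"] * 365 + p["months"] * 30 + p["weeks"] * 7 + p["days"]
    return (days, onset)


@dataclass
class PromptText:
    case_id: str
    language: str
    text: str
    term_manifest: list[tuple[TermId, str, str]] = field(default_factory=list)

    @property
    def sha256(self) -> str:
        return hashlib.sha256(self.text.encode("utf-8")).hexdigest()


def render_prompt(
    record: CaseRecord,
    pack: TemplatePack,
    table: TranslationTable,
    *,
    fallback: bool = False,
) -> PromptText:
    """Render one case into a prompt in the pack's language.

    The diagnosis never appears in the text.  Features sharing an identical
    onset are grouped into one onset sentence (earliest onset first); features
    without onset form a single presentation sentence; excluded features form
    a single exclusion sentence.
    """
    lang = pack.language
    missing = [
        str(f.term)
        for f in record.features
        if not table.has(f.term, lang) and not fallback
    ]
    if missing:
        raise MissingTranslationError(
            f"case {record.id}: no {lang} translation for: " + ", ".join(sorted(set(missing)))
        )

    def label_of(term: TermId) -> str:
        return table.translate(term, lang, fallback=fallback)

    sentences: list[str] = []
    sex = record.subject.sex.value if isinstance(record.subject.sex, Sex) else str(record.subject.sex)
    if record.subject.age is not None:
        frame = pack.sex_age_frames[sex]["aged"]
        sentences.append(frame.format(age=render_age_phrase(record.subject.age, pack)))
    else:
        sentences.append(pack.sex_age_frames[sex]["unaged"])

    manifest: list[tuple[TermId, str, str]] = []

    with_onset = [f for f in record.observed if f.onset is not None]
    groups: dict[str, list] = {}
    for f in with_onset:
        groups.setdefault(f.onset, []).append(f)
    for onset in sorted(groups, key=_onset_sort_key):
        labels = [label_of(f.term) for f in groups[onset]]
        for f, lbl in zip(groups[onset], labels):
            manifest.append((f.term, lbl, "observed"))
        sentences.append(
            pack.onset_frame.format(
                onset=render_age_phrase(onset, pack),
                features=_format_list(labels, pack),
            )
        )

    no_onset = [f for f in record.observed if f.onset is None]
    if no_onset:
        labels = [label_of(f.term) for f in no_onset]
        for f, lbl in zip(no_onset, labels):
            manifest.append((f.term, lbl, "observed"))
        sentences.append(pack.observed_frame.format(features=_format_list(labels, pack)))

    if record.excluded:
        labels = [label_of(f.term) for f in record.excluded]
        for f, lbl in zip(record.excluded, labels):
            manifest.append((f.term, lbl, "excluded"))
        sentences.append(pack.excluded_frame.format(features=_format_list(labels, pack)))

    blocks = [pack.header_text.strip(), " ".join(sentences), pack.example_output_block.strip()]
    if pack.english_reply_instruction:
        blocks.append(pack.english_reply_instruction.strip())
    text = "\n\n".join(blocks) + "\n"
    return PromptText(case_id=record.id, language=lang, text=text, term_manifest=manifest)


def leaked_strings(prompt: PromptText, record: CaseRecord) -> list[str]:
    """Substring scan for diagnosis leakage; returns offending strings."""
    suspects = [str(record.diagnosis)]
    if record.diagnosis_label:
        suspects.append(record.diagnosis_label)
    return [s for s in suspects if s and s in prompt.text]


def write_prompts(prompts: list[PromptText], directory) -> Path:
    """Write one UTF-8 ``<case_id>_<lang>.txt`` per prompt plus a manifest TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.tsv"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        fh.write("case_id\tlanguage\tterm_count\tsha256\n")
        for prompt in prompts:
            (directory / f"{prompt.case_id}_{prompt.language}.txt").write_text(
                prompt.text, encoding="utf-8"
            )
            fh.write(
                f"{prompt.case_id}\t{prompt.language}\t{len(prompt.term_manifest)}\t{prompt.sha256}\n"
            )
    return manifest_path
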