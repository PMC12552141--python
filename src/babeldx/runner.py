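"""Batch dispatch of prompts to a pluggable model backend.

Responses are appended to a JSONL log as they arrive, keyed by the SHA-256 of
the dispatched prompt, so an interrupted batch resumes without re-dispatching
completed prompts.  A deterministic mock backend stands in for live APIs in
tests and simulations.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Protocol

import numpy as np

from .ontology import OntologyGraph, TermId, TranslationTable
from .prompts import PromptText

REFUSAL_SENTENCE = (
    "I'm sorry but based on the information provided, "
    "I cannot return a confident diagnosis"
)
FAILURE_MARKER = "<<BACKEND-FAILURE>>"


@dataclass
class RunConfig:
    model_name: str = "mock"
    temperature: float = 1.0
    seed: int | None = None
    max_output_tokens: int | None = None
    extra_params: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.max_output_tokens is not None and self.max_output_tokens <= 0:
            raise ValueError("max_output_tokens must be positive")


#: Reproduction settings mirroring the two documented live runs.
GPT_LIKE_CONFIG = RunConfig(model_name="gpt-like", temperature=1.0)
MEDITRON_LIKE_CONFIG = RunConfig(
    model_name="meditron-like", temperature=0.0, seed=1234, max_output_tokens=2048,
    extra_params={"task_type": "mcq"},
)


@dataclass
class ResponseRecord:
    case_id: str
    language: str
    prompt_sha256: str
    raw_text: str
    model_name: str
    timestamp: str
    config: RunConfig
    failed: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "case_id": self.case_id,
                "language": self.language,
                "prompt_sha256": self.prompt_sha256,
                "raw_text": self.raw_text,
                "model_name": self.model_name,
                "timestamp": self.timestamp,
                "failed": self.failed,
                "config": {
                    "model_name": self.config.model_name,
                    "temperature": self.config.temperature,
                    "seed": self.config.seed,
                    "max_output_tokens": self.config.max_output_tokens,
                    "extra_params": self.config.extra_params,
                },
            },
            ensure_ascii=False,
        )

    @staticmethod
    def from_json(line: str) -> "ResponseRecord":
        obj = json.loads(line)
        cfg = obj.get("config", {})
        return ResponseRecord(
            case_id=obj["case_id"],
            language=obj["language"],
            prompt_sha256=obj["prompt_sha256"],
            raw_text=obj["raw_text"],
            model_name=obj["model_name"],
            timestamp=obj["timestamp"],
            failed=obj.get("failed", False),
            config=RunConfig(
                model_name=cfg.get("model_name", "unknown"),
                temperature=cfg.get("temperature", 1.0),
                seed=cfg.get("seed"),
                max_output_tokens=cfg.get("max_output_tokens"),
                extra_params=cfg.get("extra_params", {}),
            ),
        )


class ModelBackend(Protocol):
    """Contract a backend must satisfy: (prompt, config) -> reply text."""

    def complete(self, prompt: PromptText, config: RunConfig) -> str: ...


@dataclass
class AccuracyProfile:
    """Outcome probabilities driving the mock backend.

    ``rank_probabilities[r-1]`` is the probability that the correct diagnosis
    appears at rank r; the remaining mass (after refusal) yields a reply
    without the correct diagnosis anywhere.
    """

    rank_probabilities: tuple[float, ...]
    refusal_probability: float = 0.0
    garble_probability: float = 0.0
    subtype_swap_probability: float = 0.0
    ignore_english_probability: float = 0.0

    def __post_init__(self) -> None:
        probs = list(self.rank_probabilities) + [
            self.refusal_probability,
            self.garble_probability,
            self.subtype_swap_probability,
            self.ignore_english_probability,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.rank_probabilities) + self.refusal_probability > 1 + 1e-12:
            raise ValueError("rank probabilities plus refusal must sum to <= 1")

    @property
    def n_ranks(self) -> int:
        return len(self.rank_probabilities)


def _stream_seed(seed: int, case_id: str, language: str) -> int:
    digest = hashlib.sha256(f"{seed}|{case_id}|{language}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


class MockBackend:
    """Deterministic test double standing in for a live LLM API.

    Replies are a pure function of (profile, seed, case_id, language): the
    per-case random stream is derived by a stable hash, so any subset of a
    batch is independently reproducible.  Replies are numbered English lists
    built from the true diagnosis label and a distractor label pool, or the
    stock refusal sentence.
    """

    def __init__(
        self,
        profile: AccuracyProfile,
        ontology: OntologyGraph,
        diagnoses: dict[str, TermId],
        seed: int,
        distractor_pool: list[str] | None = None,
        translations: TranslationTable | None = None,
    ) -> None:
        self.profile = profile
        self.ontology = ontology
        self.diagnoses = diagnoses
        self.seed = seed
        self.translations = translations
        if distractor_pool is None:
            # exclude anything that could fall into a diagnosis's equivalence
            # class: the term, its ancestors/descendants, and every direct
            # parent's descendants (sibling subtypes under a grouping term)
            correct: set[TermId] = set()
            for d in diagnoses.values():
                correct.add(d)
                correct |= ontology.ancestors(d)
                correct |= ontology.descendants(d)
                for parent in ontology.terms[d].parents:
                    correct |= ontology.descendants(parent)
            distractor_pool = sorted(
                t.label for t in ontology if t.id not in correct and not t.obsolete and t.label
            )
        if len(distractor_pool) < profile.n_ranks:
            raise ValueError("distractor pool smaller than the reply list length")
        self.distractor_pool = list(distractor_pool)

    def _correct_label(self, diagnosis: TermId, rng: np.random.Generator) -> str:
        label = self.ontology.label(diagnosis)
        if self.profile.subtype_swap_probability > 0 and rng.random() < self.profile.subtype_swap_probability:
            # emit a sibling subtype (or the parent grouping) label instead
            for parent in self.ontology.terms[diagnosis].parents:
                siblings = [
                    s for s in sorted(self.ontology.children(parent)) if s != diagnosis
                ]
                if siblings:
                    pick = siblings[int(rng.integers(len(siblings)))]
                    return self.ontology.label(pick)
        return label

    def complete(self, prompt: PromptText, config: RunConfig) -> str:
        rng = np.random.default_rng(_stream_seed(self.seed, prompt.case_id, prompt.language))
        p = self.profile
        u = rng.random()
        if u < p.refusal_probability:
            return REFUSAL_SENTENCE
        u -= p.refusal_probability
        correct_rank = None
        for r, pr in enumerate(p.rank_probabilities, start=1):
            if u < pr:
                correct_rank = r
                break
            u -= pr

        diagnosis = self.diagnoses[prompt.case_id]
        picks = rng.choice(len(self.distractor_pool), size=p.n_ranks, replace=False)
        lines = [self.distractor_pool[int(i)] for i in picks]
        for i in range(len(lines)):
            if p.garble_probability > 0 and rng.random() < p.garble_probability:
                lines[i] = f"zyqvex condition {int(rng.integers(10_000, 99_999))}"
        if correct_rank is not None:
            label = self._correct_label(diagnosis, rng)
            if (
                p.ignore_english_probability > 0
                and prompt.language != "en"
                and self.translations is not None
                and self.translations.has(diagnosis, prompt.language)
                and rng.random() < p.ignore_english_probability
            ):
                label = self.translations.translate(diagnosis, prompt.language)
            lines[correct_rank - 1] = label
        return "\n".join(f"{i}. {line}" for i, line in enumerate(lines, start=1))


class OpenAICompatibleBackend:
    """Thin adapter for an OpenAI-style chat-completions endpoint.

    Interface-only in the test suite (no network); retries 3 times with
    exponential backoff before giving up.
    """

    def __init__(self, base_url: str, api_key: str = "", model: str | None = None,
                 max_retries: int = 3) -> None:
        self.base_url = base_url.rstrip("/")
        self.api_key = api_key
        self.model = model
        self.max_retries = max_retries

    def complete(self, prompt: PromptText, config: RunConfig) -> str:
        import urllib.request

        payload = {
            "model": self.model or config.model_name,
            "temperature": config.temperature,
            "messages": [{"role": "user", "content": prompt.text}],
        }
        if config.seed is not None:
            payload["seed"] = config.seed
        if config.max_output_tokens is not None:
            payload["max_tokens"] = config.max_output_tokens
        request = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=json.dumps(payload).encode(),
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {self.api_key}",
            },
        )
        last_error: Exception | None = None
        for attempt in range(self.max_retries):
            try:
                with urllib.request.urlopen(request, timeout=120) as resp:
                    body = json.load(resp)
                return body["choices"][0]["message"]["content"]
            except Exception as exc:  # noqa: BLE001 - network errors are retried
                last_error = exc
                time.sleep(2**attempt)
        raise RuntimeError(f"backend unreachable after {self.max_retries} retries: {last_error}")


def run_batch(
    prompts: list[PromptText],
    backend: ModelBackend,
    config: RunConfig,
    log_path=None,
) -> list[ResponseRecord]:
    """Dispatch prompts in order; one record per prompt, never skipped.

    When ``log_path`` is given, records are appended as JSONL as they arrive
    and prompts whose hash is already in the log are not re-dispatched
    (crash-safe resume).  Backend failures are recorded with an error marker.
    """
    seen_keys = set()
    for prompt in prompts:
        key = (prompt.case_id, prompt.language)
        if key in seen_keys:
            raise ValueError(f"duplicate case/language in batch: {key}")
        seen_keys.add(key)

    done: dict[str, ResponseRecord] = {}
    log_fh = None
    if log_path is not None:
        log_path = Path(log_path)
        if log_path.exists():
            with open(log_path, encoding="utf-8") as fh:
                for line in fh:
                    if line.strip():
                        rec = ResponseRecord.from_json(line)
                        done[rec.prompt_sha256] = rec
        log_fh = open(log_path, "a", encoding="utf-8")

    records: list[ResponseRecord] = []
    try:
        for prompt in prompts:
            cached = done.get(prompt.sha256)
            if cached is not None:
                records.append(cached)
                continue
            failed = False
            try:
                raw_text = backend.complete(prompt, config)
            except Exception:  # noqa: BLE001 - failures become records, not crashes
                raw_text = FAILURE_MARKER
                failed = True
            record = ResponseRecord(
                case_id=prompt.case_id,
                language=prompt.language,
                prompt_sha256=prompt.sha256,
                raw_text=raw_text,
                model_name=config.model_name,
                timestamp=datetime.now(timezone.utc).isoformat(),
                config=config,
                failed=failed,
            )
            records.append(record)
            if log_fh is not None:
                log_fh.write(record.to_json() + "\n")
                log_fh.flush()
    finally:
        if log_fh is not None:
            log_fh.close()
    return records


def read_response_log(path) -> list[ResponseRecord]:
    with open(path, encoding="utf-8") as fh:
        return [ResponseRecord.from_json(line) for line in fh if line.strip()]
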