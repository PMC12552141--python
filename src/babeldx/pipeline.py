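"""End-to-end convenience wiring: corpus -> prompts -> mock run -> scores."""

from __future__ import annotations

from dataclasses import dataclass

from .fixtures import CorpusSpec, MiniOntologies, gen_cases, gen_mini_ontologies
from .grounding import DifferentialResult, build_grounding_index, ground_reply
from .prompts import get_template_pack, render_prompt
from .runner import AccuracyProfile, MockBackend, RunConfig, run_batch
from .scoring import (
    CaseScore,
    LanguageSummary,
    ScoringConfig,
    grounding_failure_rate,
    score_run,
    score_run_cases,
)


@dataclass
class PipelineResult:
    ontologies: MiniOntologies
    summaries: dict[str, LanguageSummary]
    case_scores: dict[str, list[CaseScore]]
    differentials: dict[str, list[DifferentialResult]]
    failure_rates: dict[str, float]


def run_mock_pipeline(
    spec: CorpusSpec,
    profile: AccuracyProfile,
    languages: list[str],
    run_seed: int,
    *,
    translation_fallback: bool = False,
) -> PipelineResult:
    """Generate a corpus, render prompts, run the mock backend, ground, score.

    Every stage is deterministic in (spec.seed, profile, run_seed).
    """
    onts = gen_mini_ontologies(spec)
    cases = gen_cases(spec, onts)
    diagnoses = {c.id: c.diagnosis for c in cases}
    backend = MockBackend(
        profile=profile,
        ontology=onts.disease_graph,
        diagnoses=diagnoses,
        seed=run_seed,
        translations=onts.translations,
    )
    index = build_grounding_index(onts.disease_graph)
    config = RunConfig(model_name="mock", temperature=0.0, seed=run_seed)

    summaries: dict[str, LanguageSummary] = {}
    case_scores: dict[str, list[CaseScore]] = {}
    differentials: dict[str, list[DifferentialResult]] = {}
    failure_rates: dict[str, float] = {}
    for lang in languages:
        pack = get_template_pack(lang)
        prompts = [
            render_prompt(c, pack, onts.translations, fallback=translation_fallback)
            for c in cases
        ]
        records = run_batch(prompts, backend, config)
        diffs = [
            ground_reply(r.case_id, r.language, r.raw_text, index) for r in records
        ]
        differentials[lang] = diffs
        summaries[lang] = score_run(diffs, diagnoses, onts.disease_graph)[lang]
        scores = score_run_cases(diffs, diagnoses, onts.disease_graph)
        case_scores[lang] = scores
        failure_rates[lang] = grounding_failure_rate(scores)
    return PipelineResult(
        ontologies=onts,
        summaries=summaries,
        case_scores=case_scores,
        differentials=differentials,
        failure_rates=failure_rates,
    )
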