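# babeldx

Benchmarking harness for multilingual LLM differential diagnosis on rare-disease
cases. The pipeline:

1. **simulate** — generate a synthetic world: a mini phenotype ontology, a mini
   disease ontology (clinical grouping terms with genetic subtypes plus
   distractor diseases), per-language translation tables, and a corpus of
   GA4GH Phenopacket JSON case vignettes with the statistical shape of a real
   rare-disease corpus (≈14 phenotype terms per case, observed and excluded
   features, onset ages, an unspecified-sex fraction).
2. **prompts** — render each case into a narrative zero-shot prompt in any of
   ten languages (en, zh, cs, nl, fr, de, it, ja, es, tr) from data-driven
   template packs; the example output block stays English and non-English packs
   ask for an English reply.
3. **run** — dispatch prompts to a backend (a deterministic mock with a
   configurable accuracy profile, or an OpenAI-compatible endpoint) with a
   crash-safe resumable JSONL response log.
4. **ground** — parse each reply into an ordered candidate list and ground
   free-text disease names to ontology ids by normalised exact matching over
   labels and synonyms (misses are kept as grounding failures at their rank).
5. **score** — judge correctness with subtype-equivalence rollup (a clinical
   disease and its genetic subtypes are interchangeable), aggregate per-language
   Top-1/3/10 / Not-ranked / No-diagnosis counts, compute frequencies under both
   denominator conventions, and run a tie-corrected Kruskal–Wallis H-test across
   languages.

## CLI

```bash
babeldx simulate --spec spec.yaml --out corpus/          # synthetic inputs
babeldx prompts  --corpus corpus/ --languages en,de,ja --out prompts/
babeldx run      --prompts prompts/ --backend mock --corpus corpus/ \
                 --seed 1 --out responses.jsonl
babeldx ground   --responses responses.jsonl \
                 --diseases corpus/diseases.obographs.json --out grounded.jsonl
babeldx score    --grounded grounded.jsonl --corpus corpus/ --out report/
```

`spec.yaml` holds `CorpusSpec` fields (`n_cases`, `n_diseases`,
`subtypes_per_disease`, `mean_features_per_case`, `excluded_feature_fraction`,
`untranslated_term_fraction`, `seed`, ...); all have defaults.

## Python API

```python
from babeldx.fixtures import CorpusSpec, ENGLISH_OPERATING_PROFILE
from babeldx.pipeline import run_mock_pipeline

result = run_mock_pipeline(CorpusSpec(n_cases=2000, seed=42),
                           ENGLISH_OPERATING_PROFILE, ["en", "de"], run_seed=7)
print(result.summaries["en"])
```

## Data formats

- Ontologies: OBO-Graph JSON (`is_a` edges only).
- Translations: TSV with columns `term_id`, `language`, `type` (`label` |
  `synonym`), `text`.
- Cases: GA4GH Phenopacket Schema v2 JSON (subject, phenotypicFeatures,
  diseases subset); genetic/variant content is deliberately dropped on read.
- Template packs: one YAML per language under `src/babeldx/data/templates/`.
- Responses / grounded differentials: JSONL.
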