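"""Deterministic synthetic inputs: mini ontologies, translations, corpora.

Everything the pipeline consumes can be generated here with the statistical
shape of the study corpus (about 14 phenotype terms per case, observed and
excluded features, onset ages, a sizeable unspecified-sex fraction, diseases
with genetic subtypes under clinical grouping terms), so the full pipeline
runs and is tested without downloading any real ontology or corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .ontology import (
    STUDY_LANGUAGES,
    OntologyGraph,
    OntologyTerm,
    TermId,
    TranslationTable,
    save_obograph,
    save_translation_tsv,
)
from .phenopackets import CaseRecord, PhenotypeObservation, Sex, SubjectInfo, write_phenopacket
from .runner import AccuracyProfile
from .stats import read_counts_tsv

__all__ = [
    "AccuracyProfile",
    "CorpusSpec",
    "MiniOntologies",
    "gen_mini_ontologies",
    "gen_cases",
    "write_corpus",
    "gen_regression_fixture",
    "ENGLISH_OPERATING_PROFILE",
]

#: Mock-backend operating point echoing a strong general-purpose model in
#: English: cumulative 20% at rank 1, 27% by rank 3, 31% by rank 10, 1%
#: refusals.
ENGLISH_OPERATING_PROFILE = AccuracyProfile(
    rank_probabilities=(0.20, 0.035, 0.035) + (0.04 / 7,) * 7,
    refusal_probability=0.01,
)

# study corpus sex mix: 1590 female / 1826 male / 1500 unspecified of 4916
_SEX_DEFAULT = (1590 / 4916, 1826 / 4916, 1500 / 4916)

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def _pseudo_word(rng: np.random.Generator, n_syllables: int = 3) -> str:
    return "".join(
        _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
        + _VOWELS[int(rng.integers(len(_VOWELS)))]
        for _ in range(n_syllables)
    )


@dataclass
class CorpusSpec:
    n_cases: int = 100
    n_diseases: int = 10
    subtypes_per_disease: tuple[int, int] = (2, 6)
    n_distractor_diseases: int = 40
    mean_features_per_case: float = 14.0
    n_phenotype_leaves: int | None = None  # default: 5x mean_features_per_case
    excluded_feature_fraction: float = 0.15
    onset_fraction: float = 0.3
    sex_probabilities: tuple[float, float, float] = _SEX_DEFAULT
    age_fraction: float = 0.9
    untranslated_term_fraction: dict[str, float] = field(default_factory=dict)
    pool_size: int = 25
    pool_draw_probability: float = 0.8
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if abs(sum(self.sex_probabilities) - 1.0) > 1e-9:
            raise ValueError("sex probabilities must sum to 1")
        for p in (self.excluded_feature_fraction, self.onset_fraction, self.age_fraction,
                  self.pool_draw_probability, *self.untranslated_term_fraction.values()):
            if not 0 <= p <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class MiniOntologies:
    phenotype_graph: OntologyGraph
    disease_graph: OntologyGraph
    translations: TranslationTable
    phenotype_leaves: list[TermId]
    grouping_ids: list[TermId]
    subtype_ids: list[TermId]
    distractor_ids: list[TermId]
    disease_pools: dict[TermId, list[TermId]]


def _gen_phenotype_graph(spec: CorpusSpec, rng: np.random.Generator):
    n_leaves = spec.n_phenotype_leaves
    if n_leaves is None:
        n_leaves = max(int(np.ceil(5 * spec.mean_features_per_case)), 20)
    n_branches = 10
    terms: dict[TermId, OntologyTerm] = {}
    root = TermId("HP:0000001")
    terms[root] = OntologyTerm(id=root, label="Phenotypic abnormality")
    leaves: list[TermId] = []
    counter = 2
    for b in range(n_branches):
        branch = TermId(f"HP:{counter:07d}")
        counter += 1
        terms[branch] = OntologyTerm(
            id=branch,
            label=f"Abnormality of the {_pseudo_word(rng)}",
            parents=[root],
        )
        per_branch = n_leaves // n_branches + (1 if b < n_leaves % n_branches else 0)
        for _ in range(per_branch):
            leaf = TermId(f"HP:{counter:07d}")
            counter += 1
            terms[leaf] = OntologyTerm(
                id=leaf,
                label=f"{_pseudo_word(rng).capitalize()} {_pseudo_word(rng, 2)}ia",
                parents=[branch],
            )
            leaves.append(leaf)
    return OntologyGraph(terms, version="mini-pheno-1"), leaves


def _gen_disease_graph(spec: CorpusSpec, rng: np.random.Generator):
    terms: dict[TermId, OntologyTerm] = {}
    root = TermId("MONDO:0000001")
    terms[root] = OntologyTerm(id=root, label="disease")
    groupings: list[TermId] = []
    subtypes: list[TermId] = []
    counter = 2
    lo, hi = spec.subtypes_per_disease
    for _ in range(spec.n_diseases):
        gid = TermId(f"MONDO:{counter:07d}")
        counter += 1
        gname = f"{_pseudo_word(rng).capitalize()} syndrome"
        terms[gid] = OntologyTerm(
            id=gid,
            label=gname,
            synonyms=[f"{_pseudo_word(rng).capitalize()} disease"],
            parents=[root],
        )
        groupings.append(gid)
        for k in range(int(rng.integers(lo, hi + 1))):
            sid = TermId(f"MONDO:{counter:07d}")
            counter += 1
            terms[sid] = OntologyTerm(
                id=sid,
                label=f"{gname} type {k + 1}",
                synonyms=[f"{gname.upper()[:4]}{k + 1}"],
                parents=[gid],
            )
            subtypes.append(sid)
    distractors: list[TermId] = []
    for _ in range(spec.n_distractor_diseases):
        did = TermId(f"MONDO:{counter:07d}")
        counter += 1
        n_syn = int(rng.integers(1, 4))
        terms[did] = OntologyTerm(
            id=did,
            label=f"{_pseudo_word(rng).capitalize()} {_pseudo_word(rng, 2)}osis",
            synonyms=[f"{_pseudo_word(rng).capitalize()} deficiency" for _ in range(n_syn)],
            parents=[root],
        )
        distractors.append(did)
    # one obsolete term: loaded but never indexed for grounding
    obsolete_id = TermId(f"MONDO:{counter:07d}")
    terms[obsolete_id] = OntologyTerm(
        id=obsolete_id, label="obsolete retired disease", parents=[root], obsolete=True
    )
    return OntologyGraph(terms, version="mini-disease-1"), groupings, subtypes, distractors


def _gen_translations(
    spec: CorpusSpec,
    pheno: OntologyGraph,
    disease: OntologyGraph,
    rng: np.random.Generator,
) -> TranslationTable:
    table = TranslationTable()
    pheno_terms = sorted(t.id for t in pheno)
    for term in pheno_terms:
        table.add(term, "en", pheno.label(term))
    for lang in STUDY_LANGUAGES:
        if lang == "en":
            continue
        dropout = spec.untranslated_term_fraction.get(lang, 0.0)
        for term in pheno_terms:
            if dropout > 0 and rng.random() < dropout:
                continue
            table.add(term, lang, f"{lang}:{pheno.label(term)}")
    for term in sorted(t.id for t in disease):
        if disease.terms[term].obsolete:
            continue
        table.add(term, "en", disease.label(term))
        for lang in STUDY_LANGUAGES:
            if lang != "en":
                table.add(term, lang, f"{lang}:{disease.label(term)}")
    return table


def gen_mini_ontologies(spec: CorpusSpec) -> MiniOntologies:
    """Generate the phenotype tree, the disease hierarchy, and translations.

    Deterministic in ``spec.seed``: the same spec yields byte-identical
    serialised files.
    """
    rng = np.random.default_rng(spec.seed)
    pheno_graph, leaves = _gen_phenotype_graph(spec, rng)
    if spec.mean_features_per_case > len(leaves):
        raise ValueError("more features requested per case than phenotype leaves exist")
    disease_graph, groupings, subtypes, distractors = _gen_disease_graph(spec, rng)
    translations = _gen_translations(spec, pheno_graph, disease_graph, rng)
    pools: dict[TermId, list[TermId]] = {}
    for sid in subtypes:
        picks = rng.choice(len(leaves), size=min(spec.pool_size, len(leaves)), replace=False)
        pools[sid] = [leaves[int(i)] for i in picks]
    return MiniOntologies(
        phenotype_graph=pheno_graph,
        disease_graph=disease_graph,
        translations=translations,
        phenotype_leaves=leaves,
        grouping_ids=groupings,
        subtype_ids=subtypes,
        distractor_ids=distractors,
        disease_pools=pools,
    )


def _sample_duration(rng: np.random.Generator, max_years: int = 60) -> str:
    years = int(rng.integers(0, max_years))
    if years >= 1:
        return f"P{years}Y"
    months = int(rng.integers(0, 12))
    if months >= 1:
        return f"P{months}M"
    return f"P{int(rng.integers(1, 28))}D"


def gen_cases(spec: CorpusSpec, onts: MiniOntologies) -> list[CaseRecord]:
    """Sample a corpus of case records against the mini ontologies.

    Each case draws a subtype-level diagnosis, a Poisson number of phenotype
    features biased toward the disease's own feature pool, marks a fraction
    excluded (always keeping at least one observed), and assigns onsets,
    sex and age per the spec.
    """
    rng = np.random.default_rng(spec.seed + 1)
    leaves = onts.phenotype_leaves
    records: list[CaseRecord] = []
    sex_values = (Sex.FEMALE, Sex.MALE, Sex.UNKNOWN)
    for i in range(spec.n_cases):
        diagnosis = onts.subtype_ids[int(rng.integers(len(onts.subtype_ids)))]
        pool = onts.disease_pools[diagnosis]
        n_features = min(max(1, int(rng.poisson(spec.mean_features_per_case))), len(leaves))
        n_from_pool = min(
            int(rng.binomial(n_features, spec.pool_draw_probability)), len(pool)
        )
        chosen = [pool[int(j)] for j in rng.choice(len(pool), size=n_from_pool, replace=False)]
        chosen_set = set(chosen)
        noise = [t for t in leaves if t not in chosen_set]
        n_noise = n_features - n_from_pool
        chosen += [noise[int(j)] for j in rng.choice(len(noise), size=n_noise, replace=False)]

        features = []
        for k, term in enumerate(chosen):
            excluded = bool(rng.random() < spec.excluded_feature_fraction) and k > 0
            onset = None
            if not excluded and rng.random() < spec.onset_fraction:
                onset = _sample_duration(rng)
            features.append(PhenotypeObservation(term=term, excluded=excluded, onset=onset))

        sex = sex_values[int(rng.choice(3, p=spec.sex_probabilities))]
        age = _sample_duration(rng) if rng.random() < spec.age_fraction else None
        records.append(
            CaseRecord(
                id=f"case-{i:05d}",
                subject=SubjectInfo(sex=sex, age=age),
                features=features,
                diagnosis=diagnosis,
                diagnosis_label=onts.disease_graph.label(diagnosis),
            )
        )
    return records


def write_corpus(spec: CorpusSpec, out_dir) -> Path:
    """Materialise every pipeline input under ``out_dir`` as text files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    onts = gen_mini_ontologies(spec)
    save_obograph(onts.phenotype_graph, out_dir / "phenotypes.obographs.json")
    save_obograph(onts.disease_graph, out_dir / "diseases.obographs.json")
    save_translation_tsv(onts.translations, out_dir / "translations.tsv")
    case_dir = out_dir / "phenopackets"
    case_dir.mkdir(exist_ok=True)
    for record in gen_cases(spec, onts):
        write_phenopacket(record, case_dir / f"{record.id}.json")
    return out_dir


def gen_regression_fixture() -> dict[str, list]:
    """The two published per-language count tables, as LanguageSummary rows.

    These are shipped verbatim as data for regression tests of the report
    layer; they are not recomputable offline because they summarise live
    model runs.
    """
    out = {}
    for name, fname in (("gpt4o", "gpt4o_counts.tsv"), ("meditron", "meditron_counts.tsv")):
        ref = resources.files("babeldx").joinpath(f"data/regression/{fname}")
        with resources.as_file(ref) as path:
            out[name] = read_counts_tsv(path)
    return out
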