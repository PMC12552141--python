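import itertools

import pytest
import yaml

from babeldx.ontology import STUDY_LANGUAGES, MissingTranslationError, TermId
from babeldx.phenopackets import CaseRecord, PhenotypeObservation, Sex, SubjectInfo
from babeldx.prompts import (
    TemplatePackError,
    get_template_pack,
    leaked_strings,
    load_template_pack,
    render_age_phrase,
    render_prompt,
    write_prompts,
)


@pytest.fixture(scope="module")
def en_pack():
    return get_template_pack("en")


@pytest.fixture
def case(mini_onts, mini_cases):
    return mini_cases[0]


class TestAgePhrase:
    @pytest.mark.parametrize(
        "duration,expected",
        [
            ("P4Y", "4-year-old"),
            ("P6M", "6-month-old"),
            ("P2Y3M", "2-year-old"),  # mixed units truncate to the largest
            ("P11D", "11-day-old"),
            ("P2W", "14-day-old"),
        ],
    )
    def test_english(self, en_pack, duration, expected):
        assert render_age_phrase(duration, en_pack) == expected

    def test_unparseable(self, en_pack):
        with pytest.raises(ValueError):
            render_age_phrase("4 years", en_pack)


class TestPackLoading:
    @pytest.mark.parametrize("lang", STUDY_LANGUAGES)
    def test_all_shipped_packs_load_and_audit(self, lang):
        pack = get_template_pack(lang)
        assert pack.language == lang
        if lang != "en":
            assert pack.english_reply_instruction

    def test_missing_frame_is_schema_error(self, tmp_path):
        doc = yaml.safe_load(
            __import__("importlib.resources", fromlist=["files"])
            .files("babeldx").joinpath("data/templates/en.yaml").read_text()
        )
        del doc["excluded_frame"]
        path = tmp_path / "broken.yaml"
        path.write_text(yaml.safe_dump(doc), encoding="utf-8")
        with pytest.raises(TemplatePackError, match="excluded_frame"):
            load_template_pack(path)

    def test_missing_placeholder_is_audit_error(self, tmp_path):
        doc = yaml.safe_load(
            __import__("importlib.resources", fromlist=["files"])
            .files("babeldx").joinpath("data/templates/en.yaml").read_text()
        )
        doc["observed_frame"] = "The patient presented with findings."
        path = tmp_path / "broken.yaml"
        path.write_text(yaml.safe_dump(doc), encoding="utf-8")
        with pytest.raises(TemplatePackError, match="observed_frame"):
            load_template_pack(path)

    def test_unknown_language(self):
        with pytest.raises(TemplatePackError):
            get_template_pack("xx")


class TestRenderPrompt:
    def test_manifest_labels_in_text(self, mini_onts, case, en_pack):
        prompt = render_prompt(case, en_pack, mini_onts.translations)
        assert prompt.text
        for term, label, status in prompt.term_manifest:
            assert label in prompt.text
            assert status in ("observed", "excluded")
        assert {t for t, _, _ in prompt.term_manifest} == {f.term for f in case.features}

    def test_excluded_terms_in_exclusion_frame_only(self, mini_onts, en_pack):
        record = CaseRecord(
            id="c1",
            subject=SubjectInfo(sex=Sex.FEMALE, age="P4Y"),
            features=[
                PhenotypeObservation(term=mini_onts.phenotype_leaves[0]),
                PhenotypeObservation(term=mini_onts.phenotype_leaves[1]),
                PhenotypeObservation(term=mini_onts.phenotype_leaves[2], excluded=True),
            ],
            diagnosis=mini_onts.subtype_ids[0],
            diagnosis_label=mini_onts.disease_graph.label(mini_onts.subtype_ids[0]),
        )
        prompt = render_prompt(record, en_pack, mini_onts.translations)
        excl_label = mini_onts.translations.translate(mini_onts.phenotype_leaves[2], "en")
        exclusion_sentence = next(
            ln for ln in prompt.text.splitlines() if "excluded" in ln
        )
        assert excl_label in exclusion_sentence
        before, _, after = prompt.text.partition("The following findings were excluded")
        assert excl_label not in before

    def test_german_same_structure_english_example(self, mini_onts, case):
        en = render_prompt(case, get_template_pack("en"), mini_onts.translations)
        de = render_prompt(case, get_template_pack("de"), mini_onts.translations)
        assert "The example output format is:" in de.text  # example stays English
        assert de.text.count("\n\n") == en.text.count("\n\n") + 1  # + reply instruction
        assert [(t, s) for t, _, s in de.term_manifest] == [
            (t, s) for t, _, s in en.term_manifest
        ]
        for _, label, _ in de.term_manifest:
            assert label.startswith("de:")

    def test_observed_before_example_block(self, mini_onts, case, en_pack):
        prompt = render_prompt(case, en_pack, mini_onts.translations)
        cut = prompt.text.index("The example output format is:")
        for _, label, status in prompt.term_manifest:
            if status == "observed":
                assert prompt.text.index(label) < cut

    def test_determinism(self, mini_onts, case, en_pack):
        a = render_prompt(case, en_pack, mini_onts.translations)
        b = render_prompt(case, en_pack, mini_onts.translations)
        assert a.text == b.text
        assert a.sha256 == b.sha256

    def test_missing_translation_lists_terms(self, mini_onts, case):
        pack = get_template_pack("tr")
        table = mini_onts.translations
        key = (case.features[0].term, "tr")
        removed = table.entries.pop(key)
        try:
            with pytest.raises(MissingTranslationError, match=str(case.features[0].term)):
                render_prompt(case, pack, table)
            # explicit fallback renders with the English label instead
            prompt = render_prompt(case, pack, table, fallback=True)
            assert mini_onts.phenotype_graph.label(case.features[0].term) in prompt.text
        finally:
            table.entries[key] = removed

    def test_onset_grouping(self, mini_onts, en_pack):
        leaves = mini_onts.phenotype_leaves
        record = CaseRecord(
            id="c2",
            subject=SubjectInfo(sex=Sex.MALE, age="P10Y"),
            features=[
                PhenotypeObservation(term=leaves[0], onset="P2Y"),
                PhenotypeObservation(term=leaves[1], onset="P2Y"),
                PhenotypeObservation(term=leaves[2], onset="P5Y"),
                PhenotypeObservation(term=leaves[3]),
            ],
            diagnosis=mini_onts.subtype_ids[0],
        )
        prompt = render_prompt(record, en_pack, mini_onts.translations)
        # one sentence for the shared P2Y onset, one for P5Y, one plain
        assert prompt.text.count("As a 2-year-old") == 1
        assert prompt.text.count("As a 5-year-old") == 1
        labels = [mini_onts.translations.translate(leaves[i], "en") for i in range(4)]
        p2 = prompt.text.index("As a 2-year-old")
        p5 = prompt.text.index("As a 5-year-old")
        assert p2 < p5 < prompt.text.index(labels[3])


def _grid_cases(mini_onts):
    """54 simulated permutation cases: 3 sexes x 3 ages x 3 observed x 2 excluded."""
    leaves = mini_onts.phenotype_leaves
    sexes = (Sex.FEMALE, Sex.MALE, Sex.UNKNOWN)
    ages = ("P4Y", "P6M", None)
    observed_sets = (leaves[:1], leaves[:3], leaves[3:8])
    excluded_sets = ([], leaves[10:12])
    cases = []
    for i, (sex, age, obs, excl) in enumerate(
        itertools.product(sexes, ages, observed_sets, excluded_sets)
    ):
        features = [PhenotypeObservation(term=t) for t in obs]
        features += [PhenotypeObservation(term=t, excluded=True) for t in excl]
        cases.append(
            CaseRecord(
                id=f"grid-{i:02d}",
                subject=SubjectInfo(sex=sex, age=age),
                features=features,
                diagnosis=mini_onts.subtype_ids[0],
                diagnosis_label=mini_onts.disease_graph.label(mini_onts.subtype_ids[0]),
            )
        )
    return cases


class TestSimulatedGrid:
    def test_54_cases_render_in_all_ten_packs(self, mini_onts):
        cases = _grid_cases(mini_onts)
        assert len(cases) == 54
        packs = [get_template_pack(lang) for lang in STUDY_LANGUAGES]
        for case in cases:
            manifests = []
            for pack in packs:
                prompt = render_prompt(case, pack, mini_onts.translations)
                assert prompt.text
                assert leaked_strings(prompt, case) == []
                manifests.append([(t, s) for t, _, s in prompt.term_manifest])
            # language parity: identical manifests (ids + status) everywhere
            assert all(m == manifests[0] for m in manifests[1:])


class TestWritePrompts:
    def test_files_and_manifest(self, tmp_path, mini_onts, mini_cases, en_pack):
        prompts = [
            render_prompt(c, en_pack, mini_onts.translations) for c in mini_cases[:5]
        ]
        manifest = write_prompts(prompts, tmp_path / "out")
        lines = manifest.read_text(encoding="utf-8").strip().splitlines()
        assert len(lines) == 6  # header + 5
        for prompt in prompts:
            path = tmp_path / "out" / f"{prompt.case_id}_en.txt"
            assert path.read_text(encoding="utf-8") == prompt.text
            assert prompt.sha256 in manifest.read_text(encoding="utf-8")
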