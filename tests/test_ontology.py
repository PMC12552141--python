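import json

import pytest

from babeldx.fixtures import CorpusSpec, gen_mini_ontologies
from babeldx.ontology import (
    MissingTranslationError,
    OntologyError,
    OntologyGraph,
    OntologyTerm,
    TermId,
    load_obograph,
    load_translation_tsv,
    save_obograph,
    save_translation_tsv,
)


class TestTermId:
    @pytest.mark.parametrize("curie", ["HP:0000118", "MONDO:0007947", "X:A"])
    def test_valid(self, curie):
        tid = TermId(curie)
        assert tid == curie
        assert tid.prefix == curie.split(":")[0]
        assert tid.local == curie.split(":", 1)[1]

    @pytest.mark.parametrize("bad", ["HP", "hp:0000118", ":123", "HP:", "HP:1:2", "HP 0001"])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            TermId(bad)

    def test_is_string(self):
        assert isinstance(TermId("HP:1"), str)
        assert {TermId("HP:1")} == {"HP:1"}


class TestGraphConstruction:
    def test_self_parent_rejected(self):
        with pytest.raises(OntologyError, match="parent"):
            OntologyTerm(id=TermId("X:A"), label="A", parents=[TermId("X:A")])

    def test_dangling_parent_rejected(self):
        a = TermId("X:A")
        with pytest.raises(OntologyError, match="unknown parent"):
            OntologyGraph({a: OntologyTerm(id=a, label="A", parents=[TermId("X:B")])})

    def test_cycle_rejected_names_member(self):
        a, b = TermId("X:A"), TermId("X:B")
        terms = {
            a: OntologyTerm(id=a, label="A", parents=[b]),
            b: OntologyTerm(id=b, label="B", parents=[a]),
        }
        with pytest.raises(OntologyError, match="cycle.*X:[AB]"):
            OntologyGraph(terms)

    def test_unlabelled_non_obsolete_rejected(self):
        with pytest.raises(OntologyError, match="label"):
            OntologyTerm(id=TermId("X:A"), label="")


class TestAncestors:
    def test_root_has_none(self, chain_graph):
        assert chain_graph.ancestors(TermId("X:A")) == set()

    def test_chain(self, chain_graph):
        assert chain_graph.ancestors(TermId("X:C")) == {"X:B", "X:A"}

    def test_diamond(self, diamond_graph):
        # brute-force DFS by hand: D -> {B, C}, B -> {A}, C -> {A}
        assert diamond_graph.ancestors(TermId("X:D")) == {"X:B", "X:C", "X:A"}

    def test_unknown_id_raises(self, chain_graph):
        with pytest.raises(KeyError):
            chain_graph.ancestors(TermId("X:Z"))

    def test_descendants_inverse(self, diamond_graph):
        assert diamond_graph.descendants(TermId("X:A")) == {"X:B", "X:C", "X:D"}

    def test_parent_closure_contained(self, mini_onts):
        # for every parent p of x: {p} | ancestors(p) <= ancestors(x)
        for graph in (mini_onts.phenotype_graph, mini_onts.disease_graph):
            for term in graph:
                anc = graph.ancestors(term.id)
                for p in term.parents:
                    assert {p} | graph.ancestors(p) <= anc


class TestObographIO:
    def test_chain_file_round(self, tmp_path, chain_graph):
        path = tmp_path / "chain.json"
        save_obograph(chain_graph, path)
        loaded = load_obograph(path)
        assert loaded.ancestors(TermId("X:C")) == {"X:B", "X:A"}

    def test_malformed_json(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json", encoding="utf-8")
        with pytest.raises(OntologyError, match="malformed"):
            load_obograph(path)

    def test_dangling_edge_reference(self, tmp_path):
        doc = {
            "graphs": [
                {
                    "nodes": [{"id": "X:A", "lbl": "A"}],
                    "edges": [{"sub": "X:A", "pred": "is_a", "obj": "X:GONE"}],
                }
            ]
        }
        path = tmp_path / "dangling.json"
        path.write_text(json.dumps(doc), encoding="utf-8")
        with pytest.raises(OntologyError, match="unknown parent"):
            load_obograph(path)

    def test_cyclic_file_rejected(self, tmp_path):
        doc = {
            "graphs": [
                {
                    "nodes": [{"id": "X:A", "lbl": "A"}, {"id": "X:B", "lbl": "B"}],
                    "edges": [
                        {"sub": "X:A", "pred": "is_a", "obj": "X:B"},
                        {"sub": "X:B", "pred": "is_a", "obj": "X:A"},
                    ],
                }
            ]
        }
        path = tmp_path / "cycle.json"
        path.write_text(json.dumps(doc), encoding="utf-8")
        with pytest.raises(OntologyError, match="cycle"):
            load_obograph(path)

    def test_obo_purl_ids_mapped(self, tmp_path):
        doc = {
            "graphs": [
                {
                    "nodes": [
                        {"id": "http://purl.obolibrary.org/obo/HP_0000118", "lbl": "root"},
                        {"id": "http://purl.obolibrary.org/obo/HP_0000003", "lbl": "kid"},
                    ],
                    "edges": [
                        {
                            "sub": "http://purl.obolibrary.org/obo/HP_0000003",
                            "pred": "is_a",
                            "obj": "http://purl.obolibrary.org/obo/HP_0000118",
                        }
                    ],
                }
            ]
        }
        path = tmp_path / "purl.json"
        path.write_text(json.dumps(doc), encoding="utf-8")
        graph = load_obograph(path)
        assert TermId("HP:0000003") in graph
        assert graph.ancestors(TermId("HP:0000003")) == {"HP:0000118"}

    def test_non_isa_edges_ignored(self, tmp_path):
        doc = {
            "graphs": [
                {
                    "nodes": [{"id": "X:A", "lbl": "A"}, {"id": "X:B", "lbl": "B"}],
                    "edges": [{"sub": "X:B", "pred": "part_of", "obj": "X:A"}],
                }
            ]
        }
        path = tmp_path / "po.json"
        path.write_text(json.dumps(doc), encoding="utf-8")
        graph = load_obograph(path)
        assert graph.ancestors(TermId("X:B")) == set()

    def test_mini_disease_counts(self, tmp_path):
        # 10 grouping diseases x exactly 3 subtypes -> 40 disease terms
        spec = CorpusSpec(n_diseases=10, subtypes_per_disease=(3, 3), seed=42)
        onts = gen_mini_ontologies(spec)
        path = tmp_path / "disease.json"
        save_obograph(onts.disease_graph, path)
        loaded = load_obograph(path)
        groupings = [
            t for t in loaded
            if t.parents == [TermId("MONDO:0000001")] and t.label.endswith("syndrome")
        ]
        subtypes = [t for t in loaded if "type" in t.label]
        assert len(groupings) == 10
        assert len(subtypes) == 30

    def test_round_trip_preserves_everything(self, tmp_path, mini_onts):
        graph = mini_onts.disease_graph
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_obograph(graph, p1)
        loaded = load_obograph(p1)
        save_obograph(loaded, p2)
        assert len(loaded) == len(graph)
        for term in graph:
            other = loaded.terms[term.id]
            assert other.label == term.label
            assert sorted(other.synonyms) == sorted(term.synonyms)
            assert sorted(other.parents) == sorted(term.parents)
            assert other.obsolete == term.obsolete
        assert p1.read_bytes() == p2.read_bytes()


class TestTranslations:
    def test_identity_language(self, mini_onts):
        term = mini_onts.phenotype_leaves[0]
        label = mini_onts.phenotype_graph.label(term)
        assert mini_onts.translations.translate(term, "en") == label

    def test_fallback_warns(self, mini_onts, caplog):
        term = mini_onts.phenotype_leaves[0]
        with caplog.at_level("WARNING"):
            result = mini_onts.translations.translate(term, "xx")
        assert result == mini_onts.phenotype_graph.label(term)
        assert "falling back" in caplog.text

    def test_fallback_never_fires_for_english(self, mini_onts, caplog):
        with caplog.at_level("WARNING"):
            for term in mini_onts.phenotype_leaves:
                mini_onts.translations.translate(term, "en")
        assert not caplog.records

    def test_no_fallback_raises(self, mini_onts):
        with pytest.raises(MissingTranslationError):
            mini_onts.translations.translate(
                mini_onts.phenotype_leaves[0], "xx", fallback=False
            )

    def test_unknown_term_raises(self, mini_onts):
        with pytest.raises(KeyError):
            mini_onts.translations.translate(TermId("HP:9999999"), "en")

    def test_tsv_round_trip_verbatim(self, tmp_path, mini_onts):
        path = tmp_path / "translations.tsv"
        save_translation_tsv(mini_onts.translations, path)
        loaded = load_translation_tsv(path)
        assert set(loaded.entries) == set(mini_onts.translations.entries)
        for key, entry in mini_onts.translations.entries.items():
            assert loaded.entries[key].label == entry.label
            assert loaded.entries[key].synonyms == entry.synonyms

    def test_coverage_counts(self, mini_onts):
        coverage = mini_onts.translations.coverage
        assert set(coverage) == {
            "en", "zh", "cs", "nl", "fr", "de", "it", "ja", "es", "tr"
        }
        n_pheno = len(mini_onts.phenotype_graph)
        assert coverage["en"] >= n_pheno
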