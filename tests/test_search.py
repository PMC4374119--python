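"""Index build / JSON round trip and the three search modes."""

import json
import random

import pytest

from conftest import mol
from wikichem.canonical import canonical_smiles
from wikichem.match import is_substructure
from wikichem.molgraph import molecular_weight
from wikichem.search import (
    build_index,
    load_index,
    save_index,
    search_exact,
    search_similarity,
    search_substructure,
)
from wikichem.synthgen import GenConfig, random_molecule


@pytest.fixture(scope="module")
def small_index(dictionary):
    entries = [
        ("c1ccccc1", "Benzene"),
        ("Cc1ccccc1", "Toluene"),
        ("CCO", "Ethanol"),
        ("N[C@@H](C)C(=O)O", "L-Alanine"),
        ("N[C@H](C)C(=O)O", "D-Alanine"),
        ("OCC", "Ethanol (synonym)"),  # cross-page duplicate of ethanol
    ]
    return build_index(entries, dictionary)


class TestBuildIndex:
    def test_invalid_entries_go_to_error_report(self, dictionary):
        index = build_index(
            [("CCO", "A"), ("CC", "B"), ("C1CC", "Bad"), ("c1ccccc1", "C")], dictionary
        )
        assert index.count == 3
        assert len(index.errors) == 1
        assert index.errors[0].page == "Bad"

    def test_same_page_stereo_pair_two_records(self, dictionary):
        index = build_index(
            [("N[C@@H](C)C(=O)O", "Ala"), ("N[C@H](C)C(=O)O", "Ala")], dictionary
        )
        assert index.count == 2
        assert {r.page for r in index.records} == {"Ala"}

    def test_duplicate_page_structure_collapses(self, dictionary):
        index = build_index([("CCO", "E"), ("OCC", "E")], dictionary)
        assert index.count == 1

    def test_empty_input(self, dictionary):
        index = build_index([], dictionary)
        assert index.count == 0
        assert index.dictionary_version == dictionary.version

    def test_record_fields(self, small_index, dictionary):
        rec = next(r for r in small_index.records if r.page == "Benzene")
        assert rec.mf == "C6H6"
        assert rec.mw == pytest.approx(78.11, abs=0.005)
        assert len(rec.words) == 16

    def test_tab_in_page_title_rejected(self, dictionary):
        with pytest.raises(ValueError):
            build_index([("C", "bad\ttitle")], dictionary)

    def test_json_round_trip(self, small_index, tmp_path):
        path = tmp_path / "index.json"
        save_index(small_index, path)
        payload = json.loads(path.read_text())
        assert payload["header"]["count"] == small_index.count
        assert payload["header"]["dictionary_version"] == small_index.dictionary_version
        loaded = load_index(path)
        assert loaded.records == small_index.records


class TestSubstructure:
    def test_self_query_first_with_zero_delta(self, small_index, dictionary):
        result = search_substructure(mol("c1ccccc1"), small_index, dictionary)
        assert result.hits[0].record.page == "Benzene"
        assert result.hits[0].mw_delta == 0.0

    def test_benzene_hits(self, small_index, dictionary):
        result = search_substructure(mol("c1ccccc1"), small_index, dictionary)
        assert [h.record.page for h in result.hits] == ["Benzene", "Toluene"]

    def test_zero_hits(self, small_index, dictionary):
        result = search_substructure(mol("c1ccsc1"), small_index, dictionary)
        assert result.hits == []

    def test_mw_delta_non_decreasing(self, small_index, dictionary):
        result = search_substructure(mol("C"), small_index, dictionary)
        deltas = [h.mw_delta for h in result.hits]
        assert deltas == sorted(deltas)

    def test_two_step_equals_brute_force(self, dictionary):
        rng = random.Random(11)
        config = GenConfig(seed=11, atom_budget=(2, 10), ring_probability=0.35)
        entries = [
            (random_molecule(config, rng), f"Page {i:03d}") for i in range(120)
        ]
        index = build_index(entries, dictionary)
        targets = {r.structure: mol(r.structure) for r in index.records}
        q_config = GenConfig(seed=11, atom_budget=(1, 6), ring_probability=0.3)
        for _ in range(15):
            query = mol(random_molecule(q_config, rng))
            result = search_substructure(query, index, dictionary)
            got = {(h.record.structure, h.record.page) for h in result.hits}
            expected = {
                (r.structure, r.page)
                for r in index.records
                if is_substructure(query, targets[r.structure])
            }
            assert got == expected


class TestSimilarity:
    def test_exact_match_forced_first(self, small_index, dictionary):
        result = search_similarity(mol("OCC"), small_index, dictionary)
        assert result.hits[0].score == 1.0
        assert canonical_smiles(mol("CCO")).canonical_smiles == result.hits[0].record.structure

    def test_scores_weakly_decrease_after_head(self, small_index, dictionary):
        result = search_similarity(mol("Cc1ccccc1"), small_index, dictionary)
        scores = [h.score for h in result.hits]
        assert scores == sorted(scores, reverse=True)

    def test_all_records_returned(self, small_index, dictionary):
        result = search_similarity(mol("C"), small_index, dictionary)
        assert len(result.hits) == small_index.count

    def test_single_record_index(self, dictionary):
        index = build_index([("CCO", "Only")], dictionary)
        result = search_similarity(mol("CC"), index, dictionary)
        assert len(result.hits) == 1
        assert 0.0 <= result.hits[0].score <= 1.0

    def test_top_limit(self, small_index, dictionary):
        result = search_similarity(mol("C"), small_index, dictionary).top(2)
        assert len(result.hits) == 2


class TestExact:
    def test_canonicalization_merges_writings(self, small_index):
        hits = search_exact(mol("OCC"), small_index).hits
        assert {h.record.page for h in hits} == {"Ethanol", "Ethanol (synonym)"}

    def test_stereo_mismatch_no_hit(self, small_index):
        hits = search_exact(mol("NC(C)C(=O)O"), small_index).hits
        assert hits == []  # achiral query matches neither enantiomer record

    def test_shared_structure_all_pages_returned(self, small_index):
        assert len(search_exact(mol("CCO"), small_index).hits) == 2


class TestRankingContract:
    def test_self_retrieval_all_modes(self, dictionary):
        rng = random.Random(3)
        config = GenConfig(seed=3, atom_budget=(3, 9), ring_probability=0.3)
        entries = [(random_molecule(config, rng), f"P{i:02d}") for i in range(30)]
        index = build_index(entries, dictionary)
        for rec in index.records[:10]:
            query = mol(rec.structure)
            sub = search_substructure(query, index, dictionary)
            sim = search_similarity(query, index, dictionary)
            exact = search_exact(query, index)
            assert sub.hits[0].record.structure == rec.structure
            assert sim.hits[0].record.structure == rec.structure
            assert exact.hits and exact.hits[0].record.structure == rec.structure

    def test_name_filter(self, small_index, dictionary):
        result = search_similarity(mol("CCO"), small_index, dictionary)
        filtered = result.filter_pages("ethanol")
        assert {h.record.page for h in filtered.hits} == {"Ethanol", "Ethanol (synonym)"}

    def test_screening_effectiveness_logged(self, dictionary, capsys):
        # soft property: screening discards a decent share of non-hits
        rng = random.Random(21)
        config = GenConfig(seed=21, atom_budget=(2, 10), ring_probability=0.35)
        entries = [(random_molecule(config, rng), f"Q{i:03d}") for i in range(100)]
        index = build_index(entries, dictionary)
        from wikichem.fingerprint import compute_descriptor, screen_pass

        query = mol("c1ccncc1")
        q = compute_descriptor(query, dictionary)
        passed = sum(
            1 for r in index.records if screen_pass(q, r.descriptor(dictionary.version))
        )
        print(f"screening kept {passed}/{index.count} candidates")
        assert passed <= index.count  # informational, never a hard failure
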