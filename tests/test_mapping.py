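from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_levenshtein
from phenosig.mapping import (
    DEFAULT_BLACKLIST,
    SynonymIndex,
    levenshtein,
    map_corpus,
    map_name,
    normalize_string,
)
from phenosig.model import CaseReport, DrugConcept
from phenosig.simulate import CorruptionSpec, GeneratorConfig, generate_cases, generate_world


def _dict(*entries) -> dict[str, DrugConcept]:
    out = {}
    for did, canonical, *syns in entries:
        out[did] = DrugConcept(did, canonical, frozenset([canonical, *syns]))
    return out


@pytest.fixture
def index() -> SynonymIndex:
    return SynonymIndex(
        _dict(
            ("D1", "aspirin", "acetylsalicylic acid"),
            ("D2", "tylenol", "paracetamol", "acetaminophen"),
            ("D3", "propranolol"),
            ("D4", "metoprolol"),
        )
    )


# --- normalize ---------------------------------------------------------------


def test_normalize_strips_case_punctuation_whitespace():
    assert normalize_string("  Aspirin®  ") == "aspirin"
    assert normalize_string("ACETYL-SALICYLIC   ACID!") == "acetyl salicylic acid"


def test_normalize_identity_on_canonical():
    assert normalize_string("aspirin") == "aspirin"


@settings(max_examples=200, deadline=None)
@given(st.text(max_size=30))
def test_normalize_is_idempotent(s):
    assert normalize_string(normalize_string(s)) == normalize_string(s)


# --- levenshtein vs oracle ---------------------------------------------------


@settings(max_examples=150, deadline=None)
@given(st.text(alphabet="abcde", max_size=10), st.text(alphabet="abcde", max_size=10))
def test_levenshtein_matches_recursive_oracle(s, t):
    assert levenshtein(s, t) == oracle_levenshtein(s, t)


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="abcdef", max_size=12), st.text(alphabet="abcdef", max_size=12),
       st.integers(0, 5))
def test_capped_levenshtein_agrees_below_cap(s, t, cap):
    true = oracle_levenshtein(s, t)
    capped = levenshtein(s, t, cap=cap)
    if true <= cap:
        assert capped == true
    else:
        assert capped > cap


# --- map_name ----------------------------------------------------------------


def test_blacklist_token_maps_to_blacklist_stage(index):
    for token in ("UNKNOWN", "unk", "  Unknown  "):
        res = map_name(token, index)
        assert res.stage == "blacklist"
        assert not res.matches


def test_exact_synonym_maps_exact(index):
    res = map_name("Acetaminophen", index)
    assert res.stage == "exact"
    assert res.matches == {"D2"}
    assert res.distance == 0


def test_distance_6_with_no_substring_is_unmapped(index):
    res = map_name("aspirinqqqqqq", index)  # 6 insertions from "aspirin"
    assert res.stage == "unmapped"
    assert not res.matches
    assert res.nearest_distance == 6


def test_two_edit_misspelling_maps_fuzzy_with_oracle_distance(index):
    verbatim = "propranalul"  # two substitutions of propranolol
    res = map_name(verbatim, index)
    assert res.stage == "fuzzy"
    assert res.matches == {"D3"}
    # oracle: brute-force distance over the whole dictionary
    best = min(
        (oracle_levenshtein(normalize_string(verbatim), normalize_string(s)), d)
        for d, c in index.concepts.items()
        for s in c.synonyms
    )
    assert res.distance == best[0] == 2


def test_part_match_on_dose_decorated_mention(index):
    res = map_name("TYLENOL 500MG TABLET", index)
    assert res.stage == "part"
    assert res.matches == {"D2"}


def test_multi_drug_phrase_union(index):
    res = map_name("aspirin + metoprolol", index)
    assert res.matches == {"D1", "D4"}
    assert res.stage == "exact"
    res2 = map_name("aspirin/tylenol and propranolol", index)
    assert res2.matches == {"D1", "D2", "D3"}


def test_fuzzy_never_exceeds_five_edits(index):
    rng = random.Random(0)
    letters = "abcdefghijklmnopqrstuvwxyz"
    for _ in range(300):
        s = "".join(rng.choice(letters) for _ in range(rng.randint(1, 14)))
        res = map_name(s, index)
        if res.stage == "fuzzy":
            assert 1 <= res.distance <= 5


def test_tied_minimum_distance_returns_all_and_marks_ambiguous():
    index = SynonymIndex(_dict(("DA", "abcdef"), ("DB", "abcdeg")))
    res = map_name("abcdez", index)
    assert res.stage == "fuzzy"
    assert res.distance == 1
    assert res.matches == {"DA", "DB"}
    assert res.ambiguous


# --- map_corpus --------------------------------------------------------------


def _case(cid, mentions):
    return CaseReport(cid, None, tuple(mentions), frozenset(), frozenset(), frozenset())


def test_exact_corpus_has_full_name_coverage(index):
    corpus = [_case("C1", ["aspirin", "UNKNOWN"]), _case("C2", ["tylenol"])]
    mapped, cov, unmapped = map_corpus(corpus, index.concepts)
    assert cov.frac_names_mapped == 1.0  # blacklist tokens excluded from denominator
    assert cov.frac_reports_mapped == 1.0
    assert unmapped == []


def test_all_blacklist_corpus_has_zero_report_coverage(index):
    corpus = [_case("C1", ["UNKNOWN"]), _case("C2", ["UNK", "unknown"])]
    _, cov, _ = map_corpus(corpus, index.concepts)
    assert cov.frac_reports_mapped == 0.0


def test_unmapped_report_carries_nearest_distance(index):
    corpus = [_case("C1", ["zzzzzzzzzzzzzzz"])]
    _, cov, unmapped = map_corpus(corpus, index.concepts)
    assert cov.frac_reports_mapped == 0.0
    assert len(unmapped) == 1
    assert unmapped[0].nearest_distance > 5


def test_mapping_is_order_independent(index):
    corpus = [_case(f"C{i}", [m]) for i, m in enumerate(
        ["aspirin", "propranalol", "UNKNOWN", "tylenol 500mg", "qqqq"])]
    mapped_fwd, _, _ = map_corpus(corpus, index.concepts)
    mapped_rev, _, _ = map_corpus(list(reversed(corpus)), index.concepts)
    by_verbatim_fwd = {r.verbatim: r for mc in mapped_fwd for r in mc.results}
    by_verbatim_rev = {r.verbatim: r for mc in mapped_rev for r in mc.results}
    assert by_verbatim_fwd == by_verbatim_rev


def test_corrupted_corpus_maps_to_intended_drug_per_ground_truth():
    cfg = GeneratorConfig(
        seed=11, n_cases=2000, n_drugs=25, n_proteins=15,
        corruption=CorruptionSpec(typo_prob=0.5, max_edits=2),
        blacklist_mention_prob=0.05,
    )
    world = generate_world(cfg)
    cases, truth = generate_cases(cfg, world)
    mapped, cov, _ = map_corpus(cases, world.concepts, world.blacklist)
    total = correct = 0
    for mc in mapped:
        for i, res in enumerate(mc.results):
            intended = truth.mention_map[(mc.case_id, i)]
            if intended is None:
                assert res.stage == "blacklist"
                continue
            total += 1
            if res.matches == {intended}:
                correct += 1
    assert total > 0
    assert correct / total >= 0.95


def test_precision_on_separated_dictionary_is_perfect():
    # synonyms pairwise >= 6 edits apart, corruption <= 2 edits: every fuzzy
    # match must recover exactly the intended drug
    cfg = GeneratorConfig(
        seed=5, n_cases=1500, n_drugs=20, n_proteins=10,
        corruption=CorruptionSpec(typo_prob=0.6, max_edits=2),
        min_synonym_separation=6,
    )
    world = generate_world(cfg)
    cases, truth = generate_cases(cfg, world)
    mapped, _, _ = map_corpus(cases, world.concepts, world.blacklist)
    for mc in mapped:
        for i, res in enumerate(mc.results):
            if res.stage == "fuzzy":
                assert not res.ambiguous
                assert res.matches == {truth.mention_map[(mc.case_id, i)]}
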