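from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_annotated
from phenosig.signals import (
    ContingencyTable,
    SignalFilter,
    build_contingency,
    fisher_exact,
    mechanism_profiles,
    prr,
    profile_entity,
    qvalues,
    screen_all,
)


# --- oracles -----------------------------------------------------------------


def oracle_fisher_two_sided(a, b, c, d) -> Fraction:
    """Brute-force: enumerate every table with the observed margins and sum
    the exact probabilities of those no more probable than the observed."""
    import math as m

    r1, r2, k, n = a + b, c + d, a + c, a + b + c + d

    def table_prob(x):
        if not (0 <= x <= r1 and 0 <= k - x <= r2):
            return None
        return Fraction(m.comb(r1, x) * m.comb(r2, k - x), m.comb(n, k))

    obs = table_prob(a)
    total = Fraction(0)
    for x in range(0, k + 1):
        p = table_prob(x)
        if p is not None and p <= obs:
            total += p
    return total


def oracle_bh(p):
    """Direct min-over-tail step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_i, idx in enumerate(order, start=1):
        tail = min(
            p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
        )
        q[idx] = min(1.0, tail)
    return q


# --- contingency -------------------------------------------------------------


def _six_case_corpus(toy_hierarchy):
    return [
        make_annotated("C1", targets={"P1"}, reactions={"L4_CAD_THR"}),
        make_annotated("C2", targets={"P1"}, reactions={"L4_SVT"}),
        make_annotated("C3", targets={"P1"}),
        make_annotated("C4", reactions={"L4_CAD_DIS"}),
        make_annotated("C5", reactions={"L4_SB"}),
        make_annotated("C6"),
    ]


def test_six_case_hand_fixture_counts(toy_hierarchy):
    corpus = _six_case_corpus(toy_hierarchy)
    # at level 2, both coronary leaves roll up to L2_CORO
    t = build_contingency(corpus, "target", "P1", "reaction", "L2_CORO", 2, toy_hierarchy)
    assert (t.a, t.b, t.c, t.d) == (1, 2, 1, 2)
    t4 = build_contingency(corpus, "target", "P1", "reaction", "L4_CAD_THR", 4, toy_hierarchy)
    assert (t4.a, t4.b, t4.c, t4.d) == (1, 2, 0, 3)


def test_entity_absent_gives_empty_top_row(toy_hierarchy):
    corpus = _six_case_corpus(toy_hierarchy)
    t = build_contingency(corpus, "target", "P99", "reaction", "L2_CORO", 2, toy_hierarchy)
    assert t.a == t.b == 0
    assert t.n == len(corpus)


def test_cells_partition_the_corpus(toy_hierarchy):
    corpus = _six_case_corpus(toy_hierarchy)
    for event in ("L2_CORO", "L2_ARRH"):
        t = build_contingency(corpus, "target", "P1", "reaction", event, 2, toy_hierarchy)
        assert t.n == len(corpus)


def test_event_at_wrong_level_is_an_error(toy_hierarchy):
    with pytest.raises(ValueError, match="level"):
        build_contingency([], "target", "P1", "reaction", "L2_CORO", 4, toy_hierarchy)


def test_unknown_event_is_an_error(toy_hierarchy):
    with pytest.raises(KeyError):
        build_contingency([], "target", "P1", "reaction", "NOPE", 4, toy_hierarchy)


def test_outcome_events_ignore_level(toy_hierarchy):
    corpus = [make_annotated("C1", targets={"P1"}, outcomes={"DE"}),
              make_annotated("C2", outcomes={"DE"})]
    t = build_contingency(corpus, "target", "P1", "outcome", "DE")
    assert (t.a, t.b, t.c, t.d) == (1, 0, 1, 0)


# --- prr ---------------------------------------------------------------------


def test_prr_on_printed_cohort_counts():
    # oracle: the ratio of the two reporting proportions
    t = ContingencyTable(241, 1067, 4059, 13118)
    expected = (241 / 1308) / (4059 / 17177)
    assert prr(t) == pytest.approx(expected, abs=1e-12)
    assert round(prr(t), 4) == 0.7797


def test_equal_proportions_give_unity():
    assert prr(ContingencyTable(5, 5, 50, 50)) == 1.0


def test_zero_a_with_nonzero_c_gives_zero():
    assert prr(ContingencyTable(0, 10, 5, 85)) == 0.0


def test_undefined_prr_raises_and_permissive_flags():
    with pytest.raises(ZeroDivisionError):
        prr(ContingencyTable(0, 0, 5, 5))
    with pytest.raises(ZeroDivisionError):
        prr(ContingencyTable(3, 7, 0, 10))
    assert math.isnan(prr(ContingencyTable(0, 0, 5, 5), permissive=True))
    assert prr(ContingencyTable(3, 7, 0, 10), permissive=True) == math.inf


@settings(max_examples=300, deadline=None)
@given(st.integers(0, 500), st.integers(0, 500), st.integers(1, 500), st.integers(0, 500))
def test_prr_identity_in_exact_arithmetic(a, b, c, d):
    if a + b == 0:
        return
    lhs = Fraction(a * (c + d), c * (a + b))
    rhs = Fraction(a, a + b) / Fraction(c, c + d)
    assert lhs == rhs
    assert prr(ContingencyTable(a, b, c, d)) == float(lhs)


# --- fisher ------------------------------------------------------------------


def test_fisher_on_printed_cohort_counts_matches_printed_precision():
    p = fisher_exact(ContingencyTable(241, 1067, 4059, 13118))
    assert float(f"{p:.2g}") == 0.000012


def test_symmetric_table_gives_p_one():
    assert fisher_exact(ContingencyTable(4, 6, 4, 6)) == pytest.approx(1.0, abs=1e-12)


def test_fisher_matches_enumeration_oracle_on_random_small_tables():
    rng = np.random.default_rng(42)
    for _ in range(300):
        cells = rng.multinomial(int(rng.integers(4, 41)), [0.25] * 4)
        a, b, c, d = (int(x) for x in cells)
        got = fisher_exact(ContingencyTable(a, b, c, d))
        want = float(oracle_fisher_two_sided(a, b, c, d))
        assert got == pytest.approx(want, abs=1e-12)


def test_fisher_one_sided_is_upper_tail():
    t = ContingencyTable(8, 2, 2, 8)
    from scipy.stats import hypergeom
    want = float(hypergeom.sf(7, 20, 10, 10))
    assert fisher_exact(t, sided="one") == pytest.approx(want, rel=1e-9)


def test_fisher_exact_and_scipy_paths_agree_on_medium_tables():
    from scipy.stats import fisher_exact as scipy_fisher
    rng = np.random.default_rng(3)
    for _ in range(20):
        cells = rng.multinomial(800, [0.1, 0.3, 0.2, 0.4])
        a, b, c, d = (int(x) for x in cells)
        got = fisher_exact(ContingencyTable(a, b, c, d))
        want = scipy_fisher([[a, b], [c, d]])[1]
        assert got == pytest.approx(want, rel=1e-6)


# --- qvalues -----------------------------------------------------------------


def test_single_p_is_its_own_q():
    assert qvalues([0.037]).tolist() == [0.037]


def test_textbook_step_up_example():
    assert qvalues([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)


def test_all_equal_p_stay_equal():
    q = qvalues([0.2, 0.2, 0.2])
    assert q.tolist() == pytest.approx([0.2, 0.2, 0.2])


def test_out_of_range_p_is_an_error():
    with pytest.raises(ValueError):
        qvalues([0.5, 1.2])
    with pytest.raises(ValueError):
        qvalues([-0.1])


def test_qvalues_match_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        m = int(rng.integers(1, 60))
        p = rng.random(m)
        assert qvalues(p).tolist() == pytest.approx(oracle_bh(p.tolist()), abs=1e-12)


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_qvalues_are_monotone_in_p(p):
    q = qvalues(p)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_storey_never_exceeds_bh():
    rng = np.random.default_rng(1)
    p = rng.random(200)
    assert np.all(qvalues(p, method="storey") <= qvalues(p, method="bh") + 1e-15)


# --- profiles and screens ----------------------------------------------------


def _profile_corpus(toy_hierarchy, rng, n=600):
    corpus = []
    for i in range(n):
        exposed = rng.random() < 0.4
        reactions = set()
        for leaf in ("L4_CAD_THR", "L4_SVT", "L4_SB"):
            base = 0.05
            pr = 0.35 if (leaf == "L4_CAD_THR" and exposed) else base
            if rng.random() < pr:
                reactions.add(leaf)
        corpus.append(
            make_annotated(f"C{i}", targets={"P1"} if exposed else set(), reactions=reactions)
        )
    return corpus


def test_planted_reaction_ranks_first_and_prrs_recompute(toy_hierarchy):
    rng = np.random.default_rng(8)
    corpus = _profile_corpus(toy_hierarchy, rng)
    filt = SignalFilter(min_entity_support=50, min_cooccurrence=5)
    records = profile_entity(corpus, "target", "P1", "reaction", 4, filt, toy_hierarchy)
    assert records[0].event_id == "L4_CAD_THR"
    assert records[0].supported and records[0].strong and records[0].significant
    # oracle: recompute each PRR from an independently built table
    for r in records:
        t = build_contingency(corpus, "target", "P1", "reaction", r.event_id, 4, toy_hierarchy)
        assert (t.a, t.b, t.c, t.d) == (r.table.a, r.table.b, r.table.c, r.table.d)
        assert prr(t, permissive=True) == pytest.approx(r.prr, nan_ok=True)


def test_single_event_profile_has_q_equal_p(toy_hierarchy):
    corpus = [
        make_annotated("C1", targets={"P1"}, reactions={"L4_SB"}),
        make_annotated("C2", targets={"P1"}),
        make_annotated("C3", reactions={"L4_SB"}),
        make_annotated("C4"),
    ]
    records = profile_entity(corpus, "target", "P1", "reaction", 4,
                             SignalFilter(min_entity_support=1, min_cooccurrence=1), toy_hierarchy)
    assert len(records) == 1
    assert records[0].q == records[0].p


def test_entity_below_support_raises_naming_the_support(toy_hierarchy):
    corpus = [make_annotated("C1", targets={"P1"})]
    with pytest.raises(ValueError, match="500"):
        profile_entity(corpus, "target", "P1", "reaction", 4, SignalFilter(), toy_hierarchy)


def test_empty_corpus_screen_is_empty(toy_hierarchy):
    res = screen_all([], "target", "reaction", 4, SignalFilter(), toy_hierarchy)
    assert res.records == []


def test_screen_restricted_to_one_entity_matches_profile_modulo_q(toy_hierarchy):
    rng = np.random.default_rng(12)
    corpus = _profile_corpus(toy_hierarchy, rng)
    filt = SignalFilter(min_entity_support=50, min_cooccurrence=5)
    prof = profile_entity(corpus, "target", "P1", "reaction", 4, filt, toy_hierarchy)
    scr = screen_all(corpus, "target", "reaction", 4, filt, toy_hierarchy, entities=["P1"])
    prof_map = {r.event_id: r for r in prof}
    scr_with_a = [r for r in scr.records if r.table.a > 0]
    assert set(prof_map) == {r.event_id for r in scr_with_a}
    for r in scr_with_a:
        pr = prof_map[r.event_id]
        assert r.table == pr.table
        assert r.p == pytest.approx(pr.p)
        assert r.prr == pytest.approx(pr.prr, nan_ok=True)


def test_null_screen_controls_false_positives(toy_hierarchy):
    # null world: no planted effects; at 10,000 pairs the q<0.05 fraction
    # must stay at or below 7%
    from phenosig.integrate import annotate_cases
    from phenosig.mapping import map_corpus
    from phenosig.simulate import GeneratorConfig, generate_cases, generate_world

    cfg = GeneratorConfig(seed=21, n_cases=4000, n_drugs=60, n_proteins=50,
                          n_reaction_leaves=200, background_reaction_prob=0.01,
                          targets_per_drug=(1, 1))
    world = generate_world(cfg)
    cases, _ = generate_cases(cfg, world)
    mapped, _, _ = map_corpus(cases, world.concepts, world.blacklist)
    annotated = annotate_cases(mapped, world.links, world.annotations, world.concepts)
    res = screen_all(annotated, "target", "reaction", 4,
                     SignalFilter(min_entity_support=50, min_cooccurrence=5),
                     world.hierarchy)
    assert res.summary["n_pairs"] >= 5000
    assert res.summary["frac_significant"] <= 0.07


# --- mechanism profiles ------------------------------------------------------


def _mechanism_corpus(rng, n=800):
    corpus = []
    for i in range(n):
        u = rng.random()
        if u < 0.25:
            actions = {"P1": {"agonist"}}
        elif u < 0.5:
            actions = {"P1": {"antagonist"}}
        else:
            actions = {}
        exposed_ant = actions.get("P1") == {"antagonist"}
        reactions = set()
        if rng.random() < (0.4 if exposed_ant else 0.05):
            reactions.add("L4_MI")
        if rng.random() < 0.05:
            reactions.add("L4_SB")
        corpus.append(
            make_annotated(f"C{i}", targets=set(actions), reactions=reactions,
                           target_actions=actions)
        )
    return corpus


def test_reaction_flagged_only_in_antagonist_profile(toy_hierarchy):
    rng = np.random.default_rng(5)
    corpus = _mechanism_corpus(rng)
    filt = SignalFilter(min_entity_support=50, min_cooccurrence=5)
    ag, an = mechanism_profiles(corpus, "P1", "reaction", 4, filt, toy_hierarchy)
    an_flagged = {r.event_id for r in an if r.supported and r.strong and r.significant}
    ag_flagged = {r.event_id for r in ag if r.supported and r.strong and r.significant}
    assert "L4_MI" in an_flagged
    assert "L4_MI" not in ag_flagged


def test_identical_action_sets_give_identical_profiles(toy_hierarchy):
    corpus = []
    rng = np.random.default_rng(6)
    for i in range(200):
        exposed = rng.random() < 0.5
        acts = {"P1": {"agonist"}} if (exposed and i % 2 == 0) else (
            {"P1": {"antagonist"}} if exposed else {})
        reactions = {"L4_SB"} if rng.random() < 0.1 else set()
        corpus.append(make_annotated(f"C{i}", targets=set(acts), reactions=reactions,
                                     target_actions=acts))
    filt = SignalFilter(min_entity_support=1, min_cooccurrence=1)
    ag, an = mechanism_profiles(corpus, "P1", "reaction", 4, filt, toy_hierarchy)
    # each side's table totals equal its partition size
    n_ag_only = sum(1 for c in corpus if c.target_actions.get("P1") == frozenset({"agonist"}))
    n_an_only = sum(1 for c in corpus if c.target_actions.get("P1") == frozenset({"antagonist"}))
    n_rest = len(corpus) - n_ag_only - n_an_only
    for r in ag:
        assert r.table.n == n_ag_only + n_rest
    for r in an:
        assert r.table.n == n_an_only + n_rest


def test_absent_action_side_is_empty_with_warning(toy_hierarchy):
    corpus = [
        make_annotated("C1", targets={"P1"}, target_actions={"P1": {"antagonist"}},
                       reactions={"L4_SB"}),
        make_annotated("C2"),
    ]
    with pytest.warns(UserWarning, match="agonist"):
        ag, an = mechanism_profiles(corpus, "P1", "reaction", 4,
                                    SignalFilter(min_entity_support=1, min_cooccurrence=1),
                                    toy_hierarchy)
    assert ag == []
    assert len(an) == 1
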