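"""The common-user merge: published rule table, worked dialogue, invariants."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ldd.consensus import (
    ConsensusConfig,
    harmonize_corpus,
    merge_discourse_votes,
    merge_emotion_votes,
)
from ldd.corpus import (
    ConfidenceRating,
    DiscourseVote,
    EmotionVote,
    RaterVotes,
    Sentence,
    ValidationError,
)

# The 29-rule consensus table, in placeholder form: three rater vote sets
# over abstract labels d1..d4 and the expected (label, level, weight) outcome.
RULES = [
    (["d1"], ["d1"], ["d1"], [("d1", "H", 1.0)]),
    (["d1", "d2"], ["d1", "d2"], ["d1", "d2"], [("d1", "H", 1.0), ("d2", "H", 1.0)]),
    (["d1", "d2"], ["d1", "d2"], ["d1"], [("d1", "H", 1.0), ("d2", "M", 1.0)]),
    (["d1", "d2"], ["d1"], ["d1"], [("d1", "H", 0.8)]),
    (["d1", "d2", "d3"], ["d1"], ["d1"], [("d1", "H", 0.6)]),
    (["d1", "d2"], ["d1", "d3"], ["d1"], [("d1", "H", 0.6)]),
    (["d1", "d2", "d3"], ["d1", "d2"], ["d1", "d2"], [("d1", "H", 0.8), ("d2", "H", 0.8)]),
    (["d1"], ["d1"], [], [("d1", "M", 1.0)]),
    (["d1"], ["d1"], ["d2"], [("d1", "M", 1.0)]),
    (["d1"], ["d1", "d3"], ["d2"], [("d1", "M", 0.8)]),
    (["d1", "d2"], ["d2", "d3"], ["d1", "d2"], [("d1", "M", 1.0), ("d2", "H", 0.8)]),
    (["d1", "d2"], ["d1"], ["d2"], [("d1", "M", 1.0), ("d2", "M", 1.0)]),
    (["d1", "d2"], ["d1", "d3"], [], [("d1", "M", 0.6)]),
    (["d1", "d2"], ["d1", "d2"], [], [("d1", "M", 1.0), ("d2", "M", 1.0)]),
    (["d1", "d2"], ["d1", "d2"], ["d3", "d4"], [("d1", "M", 1.0), ("d2", "M", 1.0)]),
    (["d1"], ["d1"], ["d3", "d4"], [("d1", "M", 1.0)]),
    (["d1"], ["d1", "d2"], ["d2"], [("d1", "M", 1.0), ("d2", "M", 1.0)]),
    (
        ["d1", "d4"], ["d2", "d3", "d4"], ["d1", "d2", "d3"],
        [("d1", "M", 1.0), ("d2", "M", 1.0), ("d3", "M", 1.0), ("d4", "M", 1.0)],
    ),
    (["d1"], ["d1", "d2"], ["d2", "d3"], [("d1", "M", 1.0), ("d2", "M", 0.8)]),
    (["d1"], ["d2", "d3", "d4"], ["d2"], [("d2", "M", 0.6)]),
    ([], ["d1", "d2"], [], []),
    (["d1", "d2"], ["d1", "d2"], ["d1", "d3"], [("d1", "H", 0.8), ("d2", "M", 1.0)]),
    (["d1"], [], [], []),
    (["d1", "d2"], ["d1"], ["d3"], [("d1", "M", 0.8)]),
    (["d1", "d2"], ["d1", "d2"], ["d3"], [("d1", "M", 1.0), ("d2", "M", 1.0)]),
    (["d1"], ["d1", "d2"], ["d1", "d2", "d3"], [("d1", "H", 0.8), ("d2", "M", 0.8)]),
    (["d1", "d2"], ["d1"], [], [("d1", "M", 0.8)]),
    (
        ["d1", "d2"], ["d1", "d3"], ["d2", "d3"],
        [("d1", "M", 1.0), ("d2", "M", 1.0), ("d3", "M", 1.0)],
    ),
    (["d1", "d2"], ["d1", "d3"], ["d2"], [("d1", "M", 0.8), ("d2", "M", 1.0)]),
]

# Two concrete bindings of the abstract placeholders to discourse codes.
BINDINGS = [
    {"d1": "M", "d2": "U", "d3": "A", "d4": "H"},
    {"d1": "C", "d2": "H", "d3": "M", "d4": "U"},
]


def _bind(labels, binding):
    return [binding[x] for x in labels]


@pytest.mark.parametrize("rule_idx", range(len(RULES)))
@pytest.mark.parametrize("binding", BINDINGS, ids=["MUAH", "CHMU"])
def test_rule_table_under_label_bindings_and_rater_permutations(rule_idx, binding):
    """Every printed rule is reproduced for concrete labels and any rater order."""
    v1, v2, v3, expected = RULES[rule_idx]
    want = {
        (binding[lab], level, round(weight, 6))
        for lab, level, weight in expected
    }
    for perm in itertools.permutations([v1, v2, v3]):
        got = merge_discourse_votes([_bind(v, binding) for v in perm])
        assert {(d.discourse, d.level, round(d.weight, 6)) for d in got} == want


def test_none_outcome_for_empty_slots():
    assert merge_discourse_votes([[], [], []]) == ()


def test_rejects_wrong_slot_count_and_duplicates():
    with pytest.raises(ValidationError):
        merge_discourse_votes([["M"], ["M"], ["M"], ["M"]])
    with pytest.raises(ValidationError):
        merge_discourse_votes([["M", "M"], [], []])


def test_emotion_merge_support_rule():
    """Unanimity gives H; 2-of-3 gives M; singletons drop; no weights."""
    assert [(e.emotion, e.level) for e in
            merge_emotion_votes([["joy"], ["joy"], ["joy"]])] == [("joy", "H")]
    got = merge_emotion_votes([["joy", "pride"], ["joy"], ["sadness"]])
    assert [(e.emotion, e.level) for e in got] == [("joy", "M")]
    assert merge_emotion_votes([["joy"], ["sadness"], ["fear"]]) == ()


DIALOGUE_VOTES = [
    # (per-rater discourse label lists, expected consensus {(code, level, weight)})
    ([["H"], ["H"], ["H"]], {("H", "H", 1.0)}),
    ([["U", "H"], ["M", "H"], ["H"]], {("H", "H", 0.6)}),
    ([["H"], ["H", "C"], ["H"]], {("H", "H", 0.8)}),
    ([["A"], ["A"], ["A", "H"]], {("A", "H", 0.8)}),
    ([["M", "H"], ["M", "H"], ["M", "H"]], {("M", "H", 1.0), ("H", "H", 1.0)}),
    ([["M"], ["M", "H"], ["M"]], {("M", "H", 0.8)}),
]


def test_worked_dialogue_consensus_outcomes():
    """The six common-user outcomes of the worked coffee-shop dialogue."""
    raw = []
    for i, (vote_sets, _) in enumerate(DIALOGUE_VOTES, start=1):
        sent = Sentence(f"s{i}", "FroLatteAd_10", i, "speaker1", f"turn {i}")
        per_rater = [
            RaterVotes(
                sentence_id=sent.sentence_id,
                rater_id=f"rater{r + 1}",
                discourse_votes=tuple(DiscourseVote(d) for d in labels),
            )
            for r, labels in enumerate(vote_sets)
        ]
        raw.append((sent, per_rater))
    corpus = harmonize_corpus(raw)
    for s, (_, expected) in zip(corpus.sentences, DIALOGUE_VOTES):
        got = {(d.discourse, d.level, d.weight) for d in s.discourse_set}
        assert got == expected, s.sentence_id
        assert not s.excluded


def test_none_outcome_sentences_are_excluded():
    sent = Sentence("s1", "d", 1, "a", "hello")
    per_rater = [
        RaterVotes("s1", "r1", (DiscourseVote("M"),)),
        RaterVotes("s1", "r2"),
        RaterVotes("s1", "r3"),
    ]
    corpus = harmonize_corpus([(sent, per_rater)])
    assert corpus.sentences[0].excluded
    assert corpus.sentences[0].discourse_set == ()
    assert corpus.included() == []


labels_st = st.sets(st.sampled_from(["M", "U", "A", "H", "C"]), max_size=4)
votes_st = st.tuples(labels_st, labels_st, labels_st)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(votes_st)
def test_rater_permutation_invariance(votes):
    """The merge depends only on the multiset of vote sets."""
    base = merge_discourse_votes([sorted(v) for v in votes])
    for perm in itertools.permutations(votes):
        assert merge_discourse_votes([sorted(v) for v in perm]) == base


@settings(max_examples=200, deadline=None, derandomize=True)
@given(votes_st)
def test_weight_quantization_and_level_law(votes):
    """Weights are multiples of 0.2 in [0,1]; H iff all three raters agree."""
    got = merge_discourse_votes([sorted(v) for v in votes])
    for d in got:
        assert round(d.weight / 0.2, 6) == pytest.approx(round(d.weight / 0.2))
        assert 0.0 <= d.weight <= 1.0
        support = sum(d.discourse in v for v in votes)
        assert support >= 2
        assert d.level == ("H" if support == 3 else "M")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(votes_st, st.integers(0, 2), st.sampled_from(["M", "U", "A", "H", "C"]))
def test_adding_a_vote_never_removes_a_label(votes, slot, extra):
    """Monotonicity: an extra vote for x cannot push x out of the output."""
    before = {d.discourse for d in merge_discourse_votes([sorted(v) for v in votes])}
    grown = [set(v) for v in votes]
    if len(grown[slot]) >= 4 and extra not in grown[slot]:
        return
    grown[slot].add(extra)
    after = {d.discourse for d in merge_discourse_votes([sorted(v) for v in grown])}
    assert before <= after


def test_individual_confidences_and_weights_are_ignored():
    """Metamorphic: perturbing rater confidences/weights leaves output fixed."""
    sent = Sentence("s1", "d", 1, "a", "hello")

    def build(conf_level, weight):
        per_rater = [
            RaterVotes(
                "s1", f"r{r}",
                discourse_votes=(
                    DiscourseVote(
                        "M",
                        ConfidenceRating("three_level", conf_level),
                        weight,
                    ),
                    DiscourseVote("H") if r < 2 else DiscourseVote("U"),
                ),
                emotion_votes=(
                    EmotionVote("joy", ConfidenceRating("three_level", conf_level)),
                ),
            )
            for r in range(3)
        ]
        return harmonize_corpus([(sent, per_rater)]).sentences[0]

    assert build("low", 0.1) == build("high", 1.0)


def test_min_support_config_is_honoured():
    config = ConsensusConfig(min_support=3)
    got = merge_discourse_votes([["M", "U"], ["M"], ["M"]], config)
    assert [(d.discourse, d.level) for d in got] == [("M", "H")]
    assert merge_discourse_votes([["M"], ["M"], []], config) == ()
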