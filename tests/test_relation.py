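"""Association statistics: worked example, brute-force oracle, invariants."""

import math

import numpy as np
import pytest

from ldd.corpus import AnnotatedCorpus, ValidationError
from ldd.relation import (
    LabelSetPair,
    UndefinedConditionalError,
    conditional_probability,
    pair_contributions,
    relation,
    relation_table,
    top_k_filter,
    weight_level,
)
from ldd.synthetic import SyntheticConfig, generate_annotated_corpus

from conftest import numeric_sentence


def oracle_prob(corpus, discourses, emotions):
    """Literal nested-loop transcription of the estimator definition."""
    num = den = 0.0
    for s in corpus.included():
        if {e.emotion for e in s.emotion_set} == set(emotions):
            term = 1.0
            for d in s.discourse_set:
                term *= d.confidence if d.confidence is not None else 1.0
            for e in s.emotion_set:
                term *= e.confidence if e.confidence is not None else 1.0
            den += term
            if {d.discourse for d in s.discourse_set} == set(discourses):
                num += term
    return num / den


def oracle_weight(corpus, discourses, emotions, mode):
    values = []
    for s in corpus.included():
        if (
            {d.discourse for d in s.discourse_set} == set(discourses)
            and {e.emotion for e in s.emotion_set} == set(emotions)
        ):
            values.append(math.prod(d.weight for d in s.discourse_set))
    if not values:
        return 0.0
    return math.prod(values) if mode == "product" else sum(values)


class TestWorkedExample:
    """The four-sentence numeric dataset with exclusive co-occurrence."""

    PAIR = LabelSetPair(frozenset({"M"}), frozenset({"joy"}))

    def test_probability_is_one(self, worked_example_corpus):
        assert conditional_probability(worked_example_corpus, self.PAIR) == pytest.approx(1.0)

    def test_weight_level_product(self, worked_example_corpus):
        got = weight_level(worked_example_corpus, self.PAIR, "product")
        assert got == pytest.approx(1 * 0.8 * 0.7 * 0.4)

    def test_weight_level_sum(self, worked_example_corpus):
        assert weight_level(worked_example_corpus, self.PAIR, "sum") == pytest.approx(2.9)

    def test_relation(self, worked_example_corpus):
        assert relation(worked_example_corpus, self.PAIR) == pytest.approx(0.224)


def test_probability_zero_when_combo_absent(mixed_corpus):
    pair = LabelSetPair(frozenset({"A"}), frozenset({"joy"}))
    assert conditional_probability(mixed_corpus, pair) == 0.0
    assert relation(mixed_corpus, pair) == 0.0


def test_undefined_conditional_raises(mixed_corpus):
    pair = LabelSetPair(frozenset({"M"}), frozenset({"anguish"}))
    with pytest.raises(UndefinedConditionalError):
        conditional_probability(mixed_corpus, pair)


def test_unknown_weight_mode_rejected(mixed_corpus):
    with pytest.raises(ValidationError):
        weight_level(mixed_corpus, LabelSetPair(frozenset("M"), frozenset({"joy"})), "mean")


@pytest.mark.parametrize(
    "discourses,emotions",
    [({"M"}, {"joy"}), ({"M", "H"}, {"joy"}), ({"U"}, {"joy"}),
     ({"U"}, {"sadness", "fear"}), ({"H"}, {"sadness", "fear"})],
)
@pytest.mark.parametrize("mode", ["product", "sum"])
def test_statistics_match_bruteforce_oracle(mixed_corpus, discourses, emotions, mode):
    pair = LabelSetPair(frozenset(discourses), frozenset(emotions))
    assert conditional_probability(mixed_corpus, pair) == pytest.approx(
        oracle_prob(mixed_corpus, discourses, emotions)
    )
    assert weight_level(mixed_corpus, pair, mode) == pytest.approx(
        oracle_weight(mixed_corpus, discourses, emotions, mode)
    )
    assert relation(mixed_corpus, pair, mode=mode) == pytest.approx(
        oracle_prob(mixed_corpus, discourses, emotions)
        * oracle_weight(mixed_corpus, discourses, emotions, mode)
    )


def test_oracle_equivalence_on_random_small_corpora():
    """On generated corpora every table cell equals the nested-loop oracle."""
    for seed in (1, 2, 3):
        corpus, _ = generate_annotated_corpus(n_sentences=10, seed=seed)
        table = relation_table(corpus)
        for rec in table.records:
            d = set(rec.pair.discourses)
            e = set(rec.pair.emotions)
            assert rec.prob == pytest.approx(oracle_prob(corpus, d, e))
            assert rec.weight_level == pytest.approx(
                oracle_weight(corpus, d, e, "product")
            )
            assert rec.relation == pytest.approx(rec.prob * rec.weight_level)


def test_row_sums_and_intensity_bounds_on_synthetic_corpora():
    """Per emotion set the probabilities over observed combos sum to 1;
    RI lies in [0, 1] and attains 1 in every stratum."""
    for seed in (11, 12):
        corpus, _ = generate_annotated_corpus(n_sentences=120, seed=seed)
        table = relation_table(corpus)
        frame = table.to_frame()
        for _, row_sum in frame.groupby("emotion_set")["prob"].sum().items():
            assert row_sum == pytest.approx(1.0, abs=1e-9)
        assert ((frame["intensity"] >= 0) & (frame["intensity"] <= 1 + 1e-12)).all()
        for (n, l), group in frame.groupby(["n", "l"]):
            if group["relation"].max() > 0:
                assert group["intensity"].max() == pytest.approx(1.0)


def test_scale_invariance_with_equal_combo_sizes():
    """Scaling all confidences by gamma cancels when every sentence has the
    same number of discourse and emotion labels."""
    base = AnnotatedCorpus(
        sentences=[
            numeric_sentence("s1", [("M", 0.8, 1.0)], [("joy", 0.6)]),
            numeric_sentence("s2", [("U", 0.5, 0.9)], [("joy", 0.7)]),
            numeric_sentence("s3", [("M", 0.3, 0.5)], [("joy", 0.2)]),
        ]
    )
    gamma = 0.5
    scaled = AnnotatedCorpus(
        sentences=[
            numeric_sentence(
                s.sentence_id,
                [(d.discourse, d.confidence * gamma, d.weight) for d in s.discourse_set],
                [(e.emotion, e.confidence * gamma) for e in s.emotion_set],
            )
            for s in base.sentences
        ]
    )
    pair = LabelSetPair(frozenset({"M"}), frozenset({"joy"}))
    assert conditional_probability(scaled, pair) == pytest.approx(
        conditional_probability(base, pair)
    )


def test_relation_table_intensity_stratum_division():
    """R values (0.2, 0.1, 0.4) in one stratum normalize to (0.5, 0.25, 1)."""
    corpus = AnnotatedCorpus(
        sentences=[
            numeric_sentence("s1", [("M", 1.0, 0.4)], [("joy", 1.0)]),
            numeric_sentence("s2", [("U", 1.0, 0.2)], [("sadness", 1.0)]),
            numeric_sentence("s3", [("H", 1.0, 0.1)], [("fear", 1.0)]),
        ]
    )
    # each pair is alone with its emotion set: prob = 1, R = weight
    table = relation_table(corpus)
    by_combo = {r.pair.discourse_key: r for r in table.records}
    assert by_combo["M"].intensity == pytest.approx(1.0)
    assert by_combo["U"].intensity == pytest.approx(0.5)
    assert by_combo["H"].intensity == pytest.approx(0.25)


def test_single_record_stratum_self_normalizes():
    corpus = AnnotatedCorpus(
        sentences=[numeric_sentence("s1", [("M", 0.4, 0.3)], [("joy", 0.9)])]
    )
    table = relation_table(corpus)
    assert len(table.records) == 1
    assert table.records[0].intensity == pytest.approx(1.0)


def test_empty_corpus_rejected():
    with pytest.raises(ValidationError):
        relation_table(AnnotatedCorpus(sentences=[]))


class TestTopK:
    def _table(self, ris):
        # one emotion set, singleton combos with prob 1 and distinct weights
        codes = ["M", "U", "A", "H", "C"]
        sentences = [
            numeric_sentence(f"s{i}", [(codes[i], 1.0, w)], [("joy", 1.0)])
            for i, w in enumerate(ris)
        ]
        return relation_table(AnnotatedCorpus(sentences=sentences))

    def test_k_exceeding_count_keeps_all(self):
        table = self._table([0.9, 0.5, 0.4])
        assert len(top_k_filter(table, 5).records) == 3

    def test_smallest_dropped(self):
        table = self._table([0.9, 0.5, 0.4, 0.3, 0.2])
        kept = top_k_filter(table, 4)
        dropped = {r.pair.discourse_key for r in table.records} - {
            r.pair.discourse_key for r in kept.records
        }
        low = min(table.records, key=lambda r: r.intensity)
        assert dropped == {low.pair.discourse_key}

    def test_tie_break_is_deterministic_lexicographic(self):
        # two records tied at the cutoff with equal support: smaller code wins
        table = self._table([1.0, 0.5, 0.5])
        kept = top_k_filter(table, 2)
        keys = {r.pair.discourse_key for r in kept.records}
        tied = sorted(
            r.pair.discourse_key for r in table.records
            if r.intensity == pytest.approx(0.5)
        )
        assert tied[0] in keys and tied[1] not in keys

    def test_k_must_be_positive(self):
        with pytest.raises(ValidationError):
            top_k_filter(self._table([0.5]), 0)


def test_pair_contributions_consistent_with_estimator(mixed_corpus):
    pair = LabelSetPair(frozenset({"M"}), frozenset({"joy"}))
    num, den = pair_contributions(mixed_corpus, pair)
    assert num.sum() / den.sum() == pytest.approx(
        conditional_probability(mixed_corpus, pair)
    )
    assert (num <= den + 1e-12).all()


def test_unbiasedness_smoke():
    """Estimator mean over repeated synthetic corpora stays within three
    Monte-Carlo standard errors of the planted conditional (small version
    of the full recovery experiment)."""
    p = 0.3
    config = SyntheticConfig(
        combo_distribution={("M",): p, ("U",): 1 - p},
        emotion_conditionals={("M",): {("joy",): 1.0}, ("U",): {("joy",): 1.0}},
    )
    pair = LabelSetPair(frozenset({"M"}), frozenset({"joy"}))
    estimates = []
    for seed in range(120):
        corpus, _ = generate_annotated_corpus(config, n_sentences=150, seed=seed)
        estimates.append(conditional_probability(corpus, pair))
    estimates = np.asarray(estimates)
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - p) < 3 * se + 1e-12
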