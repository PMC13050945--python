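import pytest

from ldd.corpus import (
    AnnotatedCorpus,
    AnnotatedSentence,
    ConsensusDiscourse,
    ConsensusEmotion,
)


def numeric_sentence(sid, discourses, emotions):
    """Build an AnnotatedSentence from numeric-confidence tuples.

    ``discourses``: iterable of (code, confidence, weight);
    ``emotions``: iterable of (label, confidence).
    """
    return AnnotatedSentence(
        sentence_id=sid,
        discourse_set=tuple(
            ConsensusDiscourse(discourse=d, weight=w, confidence=c)
            for d, c, w in discourses
        ),
        emotion_set=tuple(
            ConsensusEmotion(emotion=e, confidence=c) for e, c in emotions
        ),
    )


@pytest.fixture
def worked_example_corpus():
    """The four-sentence numeric dataset of the worked example.

    One discourse co-occurring exclusively with one emotion, with printed
    confidence scores (0.2/0.3/0.3/0.2 for the discourse, 0.4/0.2/0.3/0.2
    for the emotion) and discourse weights 1/0.8/0.7/0.4.
    """
    rows = [(0.2, 0.4, 1.0), (0.3, 0.2, 0.8), (0.3, 0.3, 0.7), (0.2, 0.2, 0.4)]
    sentences = [
        numeric_sentence(f"s{i}", [("M", cd, w)], [("joy", ce)])
        for i, (cd, ce, w) in enumerate(rows, start=1)
    ]
    return AnnotatedCorpus(sentences=sentences)


@pytest.fixture
def mixed_corpus():
    """Six sentences with mixed combinations for oracle cross-checks."""
    return AnnotatedCorpus(
        sentences=[
            numeric_sentence("s1", [("M", 0.9, 1.0)], [("joy", 0.8)]),
            numeric_sentence("s2", [("M", 0.5, 0.6)], [("joy", 0.4)]),
            numeric_sentence(
                "s3", [("M", 0.7, 0.8), ("H", 0.6, 0.5)], [("joy", 0.9)]
            ),
            numeric_sentence("s4", [("U", 0.8, 0.9)], [("joy", 0.7)]),
            numeric_sentence(
                "s5", [("U", 0.6, 0.7)], [("sadness", 0.9), ("fear", 0.5)]
            ),
            numeric_sentence(
                "s6", [("H", 0.4, 0.3)], [("sadness", 0.6), ("fear", 0.8)]
            ),
        ]
    )
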