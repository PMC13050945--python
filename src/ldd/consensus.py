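"""Harmonization of three raters' votes into the "common user" annotation.

The merge is governed by a small general law rather than a rule table:

* a label is **kept** iff at least ``min_support`` raters (default 2 of 3)
  voted for it; labels with a single supporter are discarded;
* a kept label's confidence is **H** if all three raters voted for it,
  otherwise **M**;
* a kept label's weight starts at 1 and loses ``penalty`` (default 0.2) for
  every *discarded companion incidence* — each time a rater's vote set
  contains the kept label alongside a label that was discarded, each such
  discarded label in that set counts once;
* if nothing is kept the sentence gets the *none-outcome* ``(none, L, 0)``
  and is excluded from all downstream estimation.

The individual raters' confidence scores and weights play no role in the
merge; only the label sets do.  Emotions are merged under the same
support/confidence law but carry no weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import (
    AnnotatedCorpus,
    AnnotatedSentence,
    ConsensusDiscourse,
    ConsensusEmotion,
    RaterVotes,
    Sentence,
    ValidationError,
)

__all__ = ["ConsensusConfig", "merge_discourse_votes", "merge_emotion_votes",
           "harmonize_corpus"]

N_RATERS = 3


@dataclass(frozen=True)
class ConsensusConfig:
    """Tunable parameters of the common-user merge.

    Defaults reproduce the published 29-rule table exactly.  ``min_support``
    other than 2 and rater counts other than 3 are configuration hooks with
    untested semantics.
    """

    min_support: int = 2
    unanimity_level: str = "H"
    majority_level: str = "M"
    penalty_per_discarded_companion: float = 0.2
    weight_floor: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.min_support <= N_RATERS):
            raise ValidationError("min_support must be in 1..3")
        if not (0.0 <= self.penalty_per_discarded_companion <= 1.0):
            raise ValidationError("penalty must be in [0, 1]")


def _check_slots(vote_sets: Sequence[Iterable[str]]) -> list[list[str]]:
    if len(vote_sets) != N_RATERS:
        raise ValidationError(f"expected {N_RATERS} rater slots, got {len(vote_sets)}")
    out = []
    for i, labels in enumerate(vote_sets):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate labels in rater slot {i + 1}")
        out.append(labels)
    return out


def _merge_labels(
    vote_sets: Sequence[Iterable[str]], config: ConsensusConfig
) -> dict[str, tuple[str, float]]:
    """Core law: map kept label -> (confidence level, weight)."""
    sets = _check_slots(vote_sets)
    support: dict[str, int] = {}
    for labels in sets:
        for lab in labels:
            support[lab] = support.get(lab, 0) + 1
    kept = {lab for lab, n in support.items() if n >= config.min_support}
    result: dict[str, tuple[str, float]] = {}
    for lab in kept:
        level = (
            config.unanimity_level if support[lab] == N_RATERS
            else config.majority_level
        )
        # one penalty per discarded companion per rater set containing lab
        n_dc = sum(
            sum(1 for other in labels if other not in kept)
            for labels in sets
            if lab in labels
        )
        weight = max(
            config.weight_floor,
            1.0 - config.penalty_per_discarded_companion * n_dc,
        )
        result[lab] = (level, round(weight, 10))
    return result


def merge_discourse_votes(
    vote_sets: Sequence[Iterable[str]],
    config: ConsensusConfig | None = None,
) -> tuple[ConsensusDiscourse, ...]:
    """Merge three raters' discourse label sets into the common-user set.

    Parameters
    ----------
    vote_sets : sequence of 3 label iterables
        One entry per rater; an empty iterable is the "(none)" slot.
    config : ConsensusConfig, optional

    Returns
    -------
    tuple of ConsensusDiscourse
        Sorted by discourse code.  Empty tuple is the none-outcome
        ``(none, L, 0)``: no label reached the support threshold.
    """
    config = config or ConsensusConfig()
    merged = _merge_labels(vote_sets, config)
    return tuple(
        ConsensusDiscourse(discourse=lab, level=level, weight=weight)
        for lab, (level, weight) in sorted(merged.items())
    )


def merge_emotion_votes(
    vote_sets: Sequence[Iterable[str]],
    config: ConsensusConfig | None = None,
) -> tuple[ConsensusEmotion, ...]:
    """Merge three raters' emotion label sets (same support law, no weights)."""
    config = config or ConsensusConfig()
    merged = _merge_labels(vote_sets, config)
    return tuple(
        ConsensusEmotion(emotion=lab, level=level)
        for lab, (level, _) in sorted(merged.items())
    )


def harmonize_corpus(
    raw_votes: Sequence[tuple[Sentence, Sequence[RaterVotes]]],
    config: ConsensusConfig | None = None,
) -> AnnotatedCorpus:
    """Apply both merges to every sentence of a raw-vote collection.

    Sentences whose discourse merge yields the none-outcome are marked
    ``excluded`` and discarded from all downstream analysis (they stay in
    the corpus file for auditability).
    """
    config = config or ConsensusConfig()
    sentences: list[AnnotatedSentence] = []
    for sentence, per_rater in raw_votes:
        if len(per_rater) != N_RATERS:
            raise ValidationError(
                f"sentence {sentence.sentence_id}: expected {N_RATERS} rater "
                f"slots, got {len(per_rater)}"
            )
        d_sets = [sorted(rv.discourse_labels) for rv in per_rater]
        e_sets = [sorted(rv.emotion_labels) for rv in per_rater]
        discourses = merge_discourse_votes(d_sets, config)
        emotions = merge_emotion_votes(e_sets, config)
        if discourses:
            sentences.append(
                AnnotatedSentence(
                    sentence_id=sentence.sentence_id,
                    discourse_set=discourses,
                    emotion_set=emotions,
                )
            )
        else:
            sentences.append(
                AnnotatedSentence(
                    sentence_id=sentence.sentence_id,
                    emotion_set=emotions,
                    excluded=True,
                )
            )
    provenance = {
        "consensus_config": {
            "min_support": config.min_support,
            "unanimity_level": config.unanimity_level,
            "majority_level": config.majority_level,
            "penalty_per_discarded_companion": config.penalty_per_discarded_companion,
            "weight_floor": config.weight_floor,
        }
    }
    return AnnotatedCorpus(sentences=sentences, provenance=provenance)
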