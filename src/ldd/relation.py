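"""Discourse–emotion association statistics.

Four quantities are computed for a pair (discourse combination D, emotion
set E) over a corpus of consensus-annotated sentences:

* **conditional probability**  Prob(D | E) — a confidence-weighted
  estimator: the numerator sums, over sentences whose discourse set equals
  D *exactly* and emotion set equals E exactly, the product of the
  discourse and emotion confidence scores; the denominator sums the same
  product over all sentences whose emotion set equals E, using each
  sentence's own discourse set.  Exact-match (partition) semantics make the
  probabilities over observed discourse combinations sum to 1 for each
  emotion set, and make the estimator unbiased for the generative
  conditional.
* **weight level**  W(D | E) — the per-sentence product of the involved
  discourse weights, aggregated across matching sentences either by product
  (default; matches the worked convention) or by sum.
* **relation**  R = Prob × W.
* **relation intensity**  RI = R / max R over the stratum of pairs with the
  same number of discourses n and emotions l; RI lies in [0, 1] and attains
  1 in every non-empty stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .corpus import (
    AnnotatedCorpus,
    AnnotatedSentence,
    ValidationError,
    normalize_discourse,
    normalize_emotion,
)

__all__ = [
    "LabelSetPair",
    "RelationRecord",
    "RelationTable",
    "UndefinedConditionalError",
    "conditional_probability",
    "weight_level",
    "relation",
    "relation_table",
    "top_k_filter",
    "pair_contributions",
]


class UndefinedConditionalError(ValueError):
    """The conditioning emotion set never occurs: the estimator is undefined.

    Raised instead of returning 0 so that "emotion set absent" stays
    distinguishable from "zero association".
    """


@dataclass(frozen=True)
class LabelSetPair:
    """A (discourse combination, emotion set) pair, both non-empty."""

    discourses: frozenset[str]
    emotions: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "discourses",
            frozenset(normalize_discourse(d) for d in self.discourses),
        )
        object.__setattr__(
            self, "emotions",
            frozenset(normalize_emotion(e) for e in self.emotions),
        )
        if not self.discourses or not self.emotions:
            raise ValidationError("both label sets must be non-empty")
        if len(self.discourses) > 5:
            raise ValidationError("at most 5 discourses")

    @property
    def n(self) -> int:
        return len(self.discourses)

    @property
    def l(self) -> int:
        return len(self.emotions)

    @property
    def discourse_key(self) -> str:
        return ",".join(sorted(self.discourses))

    @property
    def emotion_key(self) -> str:
        return ";".join(sorted(self.emotions))


@dataclass(frozen=True)
class RelationRecord:
    """One cell of the relation table."""

    pair: LabelSetPair
    prob: float
    weight_level: float
    relation: float
    intensity: float
    support: int


def _sentence_confidence_product(
    s: AnnotatedSentence, mapping: Mapping[str, float] | None
) -> float:
    """Product of all discourse and emotion confidences of sentence ``s``."""
    return prod(d.numeric_confidence(mapping) for d in s.discourse_set) * prod(
        e.numeric_confidence(mapping) for e in s.emotion_set
    )


def pair_contributions(
    corpus: AnnotatedCorpus,
    pair: LabelSetPair,
    mapping: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-included-sentence numerator and denominator terms for ``pair``.

    The estimator on any sentence subset is ``num[idx].sum() / den[idx].sum()``;
    this is what the subsampling study vectorizes over.
    """
    included = corpus.included()
    num = np.zeros(len(included))
    den = np.zeros(len(included))
    for i, s in enumerate(included):
        if s.emotion_labels == pair.emotions:
            c = _sentence_confidence_product(s, mapping)
            den[i] = c
            if s.discourse_labels == pair.discourses:
                # exact match: the numerator product over the pair's
                # discourses coincides with the sentence's own product
                num[i] = c
    return num, den


def conditional_probability(
    corpus: AnnotatedCorpus,
    pair: LabelSetPair,
    mapping: Mapping[str, float] | None = None,
) -> float:
    """Confidence-weighted Prob(D | E) under exact-match semantics.

    Raises
    ------
    UndefinedConditionalError
        If no included sentence carries the pair's emotion set.
    """
    num, den = pair_contributions(corpus, pair, mapping)
    total = den.sum()
    if total <= 0.0:
        raise UndefinedConditionalError(
            f"emotion set {{{pair.emotion_key}}} never occurs (or only with "
            "zero confidence); the conditional is undefined"
        )
    return float(num.sum() / total)


def weight_level(
    corpus: AnnotatedCorpus,
    pair: LabelSetPair,
    mode: str = "product",
) -> float:
    """Aggregate the matching sentences' discourse-weight products.

    Per matching sentence (discourse set == D and emotion set == E, exactly)
    the product of the weights of the pair's discourses is taken; across
    sentences the values are combined by ``mode``:

    * ``"product"`` (default) — the worked-example convention;
    * ``"sum"`` — the definitional wording.

    Zero matching sentences yield 0 in both modes.
    """
    if mode not in ("product", "sum"):
        raise ValidationError(f"unknown weight aggregation mode {mode!r}")
    per_sentence = [
        prod(d.weight for d in s.discourse_set)
        for s in corpus.included()
        if s.discourse_labels == pair.discourses
        and s.emotion_labels == pair.emotions
    ]
    if not per_sentence:
        return 0.0
    return float(prod(per_sentence) if mode == "product" else sum(per_sentence))


def relation(
    corpus: AnnotatedCorpus,
    pair: LabelSetPair,
    mapping: Mapping[str, float] | None = None,
    mode: str = "product",
) -> float:
    """R(D | E) = Prob(D | E) × W(D | E)."""
    return conditional_probability(corpus, pair, mapping) * weight_level(
        corpus, pair, mode
    )


@dataclass
class RelationTable:
    """All relation records for the pairs observed in a corpus."""

    records: list[RelationRecord] = field(default_factory=list)
    weight_aggregation: str = "product"
    normalization_strata: dict[tuple[int, int], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Deterministically ordered DataFrame (emotion set, then discourse set)."""
        rows = [
            {
                "emotion_set": r.pair.emotion_key,
                "discourse_set": r.pair.discourse_key,
                "n": r.pair.n,
                "l": r.pair.l,
                "prob": r.prob,
                "weight_level": r.weight_level,
                "relation": r.relation,
                "intensity": r.intensity,
                "support": r.support,
            }
            for r in self.records
        ]
        frame = pd.DataFrame(
            rows,
            columns=[
                "emotion_set", "discourse_set", "n", "l", "prob",
                "weight_level", "relation", "intensity", "support",
            ],
        )
        return frame.sort_values(
            ["emotion_set", "discourse_set"], kind="mergesort"
        ).reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False)

    def emotion_sets(self) -> list[str]:
        return sorted({r.pair.emotion_key for r in self.records})


def relation_table(
    corpus: AnnotatedCorpus,
    mapping: Mapping[str, float] | None = None,
    mode: str = "product",
) -> RelationTable:
    """Compute Prob, W, R and RI for every observed (emotion set, combo) pair.

    Only pairs observed as exact combinations in the corpus are enumerated
    (unobserved cells are implicitly zero).  RI normalizes R within each
    (n, l) stratum; a stratum whose maximal R is 0 gets RI = 0 throughout.
    """
    included = corpus.included()
    if not included:
        raise ValidationError("corpus has no included sentences")
    pairs: dict[LabelSetPair, int] = {}
    for s in included:
        pair = LabelSetPair(s.discourse_labels, s.emotion_labels)
        pairs[pair] = pairs.get(pair, 0) + 1
    prelim: list[tuple[LabelSetPair, float, float, float, int]] = []
    for pair, support in pairs.items():
        p = conditional_probability(corpus, pair, mapping)
        w = weight_level(corpus, pair, mode)
        prelim.append((pair, p, w, p * w, support))
    strata: dict[tuple[int, int], float] = {}
    for pair, _, _, r, _ in prelim:
        key = (pair.n, pair.l)
        strata[key] = max(strata.get(key, 0.0), r)
    records = [
        RelationRecord(
            pair=pair,
            prob=p,
            weight_level=w,
            relation=r,
            intensity=(r / strata[(pair.n, pair.l)]) if strata[(pair.n, pair.l)] > 0 else 0.0,
            support=support,
        )
        for pair, p, w, r, support in prelim
    ]
    records.sort(key=lambda r: (r.pair.emotion_key, r.pair.discourse_key))
    return RelationTable(
        records=records,
        weight_aggregation=mode,
        normalization_strata=strata,
    )


def top_k_filter(table: RelationTable, k: int = 5) -> RelationTable:
    """Keep, per emotion set, the k records with largest relation intensity.

    Ties at the cutoff break deterministically by (larger support, then
    lexicographically smaller discourse-set code).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    by_emotion: dict[str, list[RelationRecord]] = {}
    for r in table.records:
        by_emotion.setdefault(r.pair.emotion_key, []).append(r)
    kept: list[RelationRecord] = []
    for key in sorted(by_emotion):
        ranked = sorted(
            by_emotion[key],
            key=lambda r: (-r.intensity, -r.support, r.pair.discourse_key),
        )
        kept.extend(ranked[:k])
    kept.sort(key=lambda r: (r.pair.emotion_key, r.pair.discourse_key))
    return RelationTable(
        records=kept,
        weight_aggregation=table.weight_aggregation,
        normalization_strata=dict(table.normalization_strata),
    )
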