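"""Synthetic three-rater annotated corpora with planted structure.

The generator emulates the shape of the study data — two-speaker dialogues
whose sentences carry a latent discourse combination, emotion sets drawn
from per-combination conditional distributions, and three noisy raters —
so that every pipeline stage (consensus merge, association statistics,
agreement, stability) is testable without any download.  Because the
generative law is explicit, the true conditional Pr(combination | emotion
set) is available in closed form for parameter-recovery tests.

Defaults are sized to the study regime: 40 dialogues of 6–7 sentences
(≈264 sentences), 13 discourse combinations with mass skewed toward
Hysteric-containing combinations, and moderate rater disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import (
    AnnotatedCorpus,
    AnnotatedSentence,
    ConfidenceRating,
    ConsensusDiscourse,
    ConsensusEmotion,
    DISCOURSE_CODES,
    DiscourseVote,
    EmotionVote,
    MAX_DISCOURSES_PER_RATER,
    MAX_EMOTIONS_PER_RATER,
    RaterVotes,
    Sentence,
    ValidationError,
    emotion_vocabulary,
    normalize_discourse,
    normalize_emotion,
)
from .relation import LabelSetPair

__all__ = [
    "RaterNoise",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_corpus",
    "generate_annotated_corpus",
    "planted_conditional",
    "DEFAULT_COMBO_DISTRIBUTION",
    "DEFAULT_EMOTION_CONDITIONALS",
]

Combo = tuple[str, ...]
EmotionSet = tuple[str, ...]

#: 13 discourse combinations (the column layout of the study's tables),
#: with mass skewed toward Hysteric-containing combinations as observed.
DEFAULT_COMBO_DISTRIBUTION: dict[Combo, float] = {
    ("H",): 0.30,
    ("M",): 0.12,
    ("U",): 0.10,
    ("A",): 0.05,
    ("C",): 0.03,
    ("H", "M"): 0.10,
    ("M", "U"): 0.06,
    ("A", "H"): 0.06,
    ("A", "M"): 0.04,
    ("C", "H"): 0.04,
    ("A", "C"): 0.03,
    ("A", "H", "M"): 0.04,
    ("H", "M", "U"): 0.03,
}

#: Per-combination emotion-set conditionals.  Sets are shared across
#: combinations so the implied Pr(combo | emotion set) are non-degenerate.
DEFAULT_EMOTION_CONDITIONALS: dict[Combo, dict[EmotionSet, float]] = {
    ("H",): {
        ("admiration", "approval", "excitement"): 0.4,
        ("approval", "curiosity"): 0.3,
        ("disappointment", "sadness"): 0.3,
    },
    ("M",): {
        ("approval", "neutral"): 0.4,
        ("neutral", "pride"): 0.3,
        ("anxiety", "nervousness"): 0.3,
    },
    ("U",): {
        ("neutral",): 0.5,
        ("approval", "realization"): 0.3,
        ("annoyance", "neutral"): 0.2,
    },
    ("A",): {
        ("approval", "caring", "curiosity"): 0.4,
        ("caring", "curiosity"): 0.35,
        ("caring", "neutral", "realization"): 0.25,
    },
    ("C",): {("approval", "desire", "joy"): 1.0},
    ("H", "M"): {
        ("annoyance", "disappointment", "disapproval"): 0.5,
        ("anxiety", "realization"): 0.3,
        ("caring", "curiosity"): 0.2,
    },
    ("M", "U"): {
        ("approval", "excitement", "pride"): 0.5,
        ("approval", "realization"): 0.5,
    },
    ("A", "H"): {
        ("caring", "curiosity", "neutral"): 0.6,
        ("annoyance", "disappointment", "disapproval"): 0.4,
    },
    ("A", "M"): {("approval", "caring", "optimism"): 1.0},
    ("C", "H"): {("admiration", "approval", "desire"): 0.6, ("neutral",): 0.4},
    ("A", "C"): {("admiration", "approval", "desire"): 1.0},
    ("A", "H", "M"): {("annoyance", "disappointment", "disapproval"): 1.0},
    ("H", "M", "U"): {
        ("admiration", "approval", "excitement"): 0.5,
        ("annoyance", "disapproval", "realization"): 0.5,
    },
}

_LEVELS = ("low", "mid", "high")


@dataclass(frozen=True)
class RaterNoise:
    """Label-set perturbation probabilities for one rater.

    ``p_drop`` applies independently to each true label; ``p_swap`` replaces
    one surviving label with a random absent one; ``p_add`` appends one
    random absent label.  Noise acts on label sets only — the consensus
    merge provably ignores individual confidences and weights.
    """

    p_drop: float = 0.15
    p_add: float = 0.10
    p_swap: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_drop", "p_add", "p_swap"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")


def _normalize_dist(dist: Mapping, what: str) -> dict:
    total = float(sum(dist.values()))
    if not dist or total <= 0:
        raise ValidationError(f"{what}: empty or non-positive distribution")
    if any(v < 0 for v in dist.values()):
        raise ValidationError(f"{what}: negative probability")
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{what}: probabilities sum to {total}, not 1")
    return dict(dist)


def _canon_combo(combo: Sequence[str]) -> Combo:
    labels = tuple(sorted(normalize_discourse(d) for d in combo))
    if not (1 <= len(labels) <= MAX_DISCOURSES_PER_RATER):
        raise ValidationError(f"combo size {len(labels)} outside 1..4")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate labels in combo")
    return labels


def _canon_eset(eset: Sequence[str]) -> EmotionSet:
    labels = tuple(sorted(normalize_emotion(e) for e in eset))
    if not (1 <= len(labels) <= MAX_EMOTIONS_PER_RATER):
        raise ValidationError(f"emotion set size {len(labels)} outside 1..3")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate labels in emotion set")
    return labels


@dataclass
class SyntheticConfig:
    """Generative law and annotation-process parameters."""

    n_dialogues: int = 40
    sentences_per_dialogue: int | tuple[int, int] = (6, 7)
    combo_distribution: dict[Combo, float] = field(
        default_factory=lambda: dict(DEFAULT_COMBO_DISTRIBUTION)
    )
    emotion_conditionals: dict[Combo, dict[EmotionSet, float]] = field(
        default_factory=lambda: {
            c: dict(d) for c, d in DEFAULT_EMOTION_CONDITIONALS.items()
        }
    )
    rater_noise: tuple[RaterNoise, ...] = (
        RaterNoise(), RaterNoise(), RaterNoise(),
    )
    confidence_level_probs: dict[str, float] = field(
        default_factory=lambda: {"high": 0.5, "mid": 0.35, "low": 0.15}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_dialogues < 1:
            raise ValidationError("n_dialogues must be >= 1")
        self.combo_distribution = _normalize_dist(
            {_canon_combo(c): p for c, p in self.combo_distribution.items()},
            "combo_distribution",
        )
        conds = {}
        for combo, dist in self.emotion_conditionals.items():
            combo = _canon_combo(combo)
            conds[combo] = _normalize_dist(
                {_canon_eset(e): p for e, p in dist.items()},
                f"emotion_conditionals[{combo}]",
            )
        self.emotion_conditionals = conds
        for combo in self.combo_distribution:
            if combo not in self.emotion_conditionals:
                raise ValidationError(f"no emotion conditional for combo {combo}")
        if len(self.rater_noise) != 3:
            raise ValidationError("exactly 3 rater noise entries required")
        self.confidence_level_probs = _normalize_dist(
            {k.lower(): v for k, v in self.confidence_level_probs.items()},
            "confidence_level_probs",
        )
        if set(self.confidence_level_probs) - set(_LEVELS):
            raise ValidationError("confidence levels must be low/mid/high")


@dataclass
class SyntheticTruth:
    """Per-sentence ground truth plus the generative law itself."""

    config: SyntheticConfig
    assignments: dict[str, tuple[Combo, EmotionSet]]


def planted_conditional(
    truth: SyntheticTruth | SyntheticConfig, pair: LabelSetPair
) -> float:
    """Exact Pr(discourse combo | emotion set) implied by the generative law.

    Bayes arithmetic on the config, not on samples:
    Pr(D | E) = Pr(D) Pr(E | D) / sum_D' Pr(D') Pr(E | D').
    """
    config = truth.config if isinstance(truth, SyntheticTruth) else truth
    eset = tuple(sorted(pair.emotions))
    combo = tuple(sorted(pair.discourses))
    denom = sum(
        p * config.emotion_conditionals[c].get(eset, 0.0)
        for c, p in config.combo_distribution.items()
    )
    if denom <= 0:
        raise ValidationError(
            f"emotion set {eset} has zero probability under the generative law"
        )
    numer = config.combo_distribution.get(combo, 0.0) * config.emotion_conditionals.get(
        combo, {}
    ).get(eset, 0.0)
    return numer / denom


def _sample_dist(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _perturb(
    rng: np.random.Generator,
    labels: Combo | EmotionSet,
    noise: RaterNoise,
    universe: Sequence[str],
    cap: int,
) -> list[str]:
    kept = [lab for lab in labels if rng.random() >= noise.p_drop]
    absent = [u for u in universe if u not in labels]
    if kept and absent and rng.random() < noise.p_swap:
        i = rng.integers(len(kept))
        repl = absent[rng.integers(len(absent))]
        if repl not in kept:
            kept[i] = repl
    pool = [u for u in universe if u not in kept]
    if pool and len(kept) < cap and rng.random() < noise.p_add:
        kept.append(pool[rng.integers(len(pool))])
    return sorted(set(kept))


def _sample_confidence(rng: np.random.Generator, config: SyntheticConfig) -> ConfidenceRating:
    level = _sample_dist(rng, config.confidence_level_probs)
    return ConfidenceRating("three_level", str(level))


def generate_corpus(
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> tuple[list[tuple[Sentence, list[RaterVotes]]], SyntheticTruth]:
    """Draw a raw three-rater vote collection from the generative law.

    ``seed`` overrides ``config.seed``; the output is fully reproducible
    under a fixed seed.  Returns the raw votes (ready for
    :func:`ldd.consensus.harmonize_corpus`) and the ground truth.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    vocab = emotion_vocabulary()
    records: list[tuple[Sentence, list[RaterVotes]]] = []
    assignments: dict[str, tuple[Combo, EmotionSet]] = {}
    spd = config.sentences_per_dialogue
    counter = 0
    for d in range(config.n_dialogues):
        dialogue_id = f"dlg{d + 1:04d}"
        n_sent = (
            spd if isinstance(spd, int)
            else int(rng.integers(spd[0], spd[1] + 1))
        )
        for pos in range(1, n_sent + 1):
            counter += 1
            sid = f"s{counter:05d}"
            combo = _sample_dist(rng, config.combo_distribution)
            eset = _sample_dist(rng, config.emotion_conditionals[combo])
            assignments[sid] = (combo, eset)
            sentence = Sentence(
                sentence_id=sid,
                dialogue_id=dialogue_id,
                position=pos,
                speaker=f"speaker{(pos - 1) % 2 + 1}",
                text=f"(synthetic sentence {sid})",
            )
            per_rater = []
            for r, noise in enumerate(config.rater_noise, start=1):
                d_labels = _perturb(
                    rng, combo, noise, DISCOURSE_CODES, MAX_DISCOURSES_PER_RATER
                )
                e_labels = _perturb(
                    rng, eset, noise, vocab, MAX_EMOTIONS_PER_RATER
                )
                per_rater.append(
                    RaterVotes(
                        sentence_id=sid,
                        rater_id=f"rater{r}",
                        discourse_votes=tuple(
                            DiscourseVote(
                                discourse=lab,
                                confidence=_sample_confidence(rng, config),
                                weight=round(float(rng.integers(1, 11)) / 10, 1),
                            )
                            for lab in d_labels
                        ),
                        emotion_votes=tuple(
                            EmotionVote(
                                emotion=lab,
                                confidence=_sample_confidence(rng, config),
                            )
                            for lab in e_labels
                        ),
                    )
                )
            records.append((sentence, per_rater))
    return records, SyntheticTruth(config=config, assignments=assignments)


def generate_annotated_corpus(
    config: SyntheticConfig | None = None,
    n_sentences: int = 264,
    seed: int | None = None,
    confidence_range: tuple[float, float] = (0.2, 1.0),
) -> tuple[AnnotatedCorpus, SyntheticTruth]:
    """Draw a consensus-level corpus directly from the generative law.

    Skips the rater layer: each sentence carries its true combination and
    emotion set with independent uniform numeric confidences in
    ``confidence_range`` and uniform weights on {0.1, ..., 1.0}.  This is
    the input shape for estimator-recovery and subsampling studies, where
    the quantity of interest is the Eq.-level estimator itself rather than
    the consensus merge.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    lo, hi = confidence_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValidationError("confidence_range must satisfy 0 <= lo <= hi <= 1")
    sentences = []
    assignments: dict[str, tuple[Combo, EmotionSet]] = {}
    for i in range(1, n_sentences + 1):
        sid = f"s{i:05d}"
        combo = _sample_dist(rng, config.combo_distribution)
        eset = _sample_dist(rng, config.emotion_conditionals[combo])
        assignments[sid] = (combo, eset)
        sentences.append(
            AnnotatedSentence(
                sentence_id=sid,
                discourse_set=tuple(
                    ConsensusDiscourse(
                        discourse=lab,
                        level="H",
                        weight=round(float(rng.integers(1, 11)) / 10, 1),
                        confidence=float(rng.uniform(lo, hi)),
                    )
                    for lab in combo
                ),
                emotion_set=tuple(
                    ConsensusEmotion(
                        emotion=lab,
                        level="H",
                        confidence=float(rng.uniform(lo, hi)),
                    )
                    for lab in eset
                ),
            )
        )
    corpus = AnnotatedCorpus(
        sentences=sentences, provenance={"source": "synthetic", "seed": seed}
    )
    return corpus, SyntheticTruth(config=config, assignments=assignments)
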