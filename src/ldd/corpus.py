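"""Domain model and file formats for discourse/emotion-annotated dialogue corpora.

The unit of annotation is the *sentence* — one complete enunciation by a
speaker in a two-party dialogue.  Each of three raters assigns a sentence up
to four Lacanian discourse labels (Master, University, Analyst, Hysteric,
Capitalist), each with an ordinal confidence rating and a strength-of-presence
weight in [0, 1], and up to three emotion labels from a 30-label vocabulary
(the 27 GoEmotions categories plus ``neutral``, ``anguish`` and ``anxiety``),
each with a confidence rating.

Two on-disk formats are supported, both JSON Lines:

* **raw votes** — one record per (sentence, rater), carrying that rater's
  discourse and emotion votes;
* **consensus corpus** — one record per sentence after harmonization into the
  "common user", with a header record carrying schema/provenance metadata.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DISCOURSE_CODES",
    "DISCOURSE_NAMES",
    "MAX_DISCOURSES_PER_RATER",
    "MAX_EMOTIONS_PER_RATER",
    "emotion_vocabulary",
    "ConfidenceRating",
    "DEFAULT_CONFIDENCE_MAPPINGS",
    "confidence_to_numeric",
    "Sentence",
    "DiscourseVote",
    "EmotionVote",
    "RaterVotes",
    "ConsensusDiscourse",
    "ConsensusEmotion",
    "AnnotatedSentence",
    "AnnotatedCorpus",
    "VocabularyError",
    "ValidationError",
    "ParseError",
    "load_raw_votes",
    "save_raw_votes",
    "load_annotated_corpus",
    "save_annotated_corpus",
    "export_corpus_csv",
    "convert_deposited_votes",
]

SCHEMA_VERSION = "1"

# Five discourse positions, keyed by their single-letter codes.
DISCOURSE_NAMES: dict[str, str] = {
    "M": "Master",
    "U": "University",
    "A": "Analyst",
    "H": "Hysteric",
    "C": "Capitalist",
}
DISCOURSE_CODES: tuple[str, ...] = tuple(DISCOURSE_NAMES)
_NAME_TO_CODE = {name.lower(): code for code, name in DISCOURSE_NAMES.items()}

MAX_DISCOURSES_PER_RATER = 4
MAX_EMOTIONS_PER_RATER = 3

# 27 GoEmotions categories; the study's vocabulary appends neutral, anguish, anxiety.
_GOEMOTIONS = (
    "admiration", "amusement", "anger", "annoyance", "approval", "caring",
    "confusion", "curiosity", "desire", "disappointment", "disapproval",
    "disgust", "embarrassment", "excitement", "fear", "gratitude", "grief",
    "joy", "love", "nervousness", "optimism", "pride", "realization",
    "relief", "remorse", "sadness", "surprise",
)
_EMOTIONS = _GOEMOTIONS + ("neutral", "anguish", "anxiety")


class VocabularyError(ValueError):
    """An emotion or discourse label outside the closed vocabularies."""


class ValidationError(ValueError):
    """A record violating a structural invariant (caps, ranges, duplicates)."""


class ParseError(ValueError):
    """A malformed file record; message names the offending line."""


def emotion_vocabulary() -> list[str]:
    """Return the 30-label emotion vocabulary in stable order.

    The order is: the 27 GoEmotions labels alphabetically, then ``neutral``,
    ``anguish``, ``anxiety``.  All labels are lowercase.
    """
    return list(_EMOTIONS)


def normalize_emotion(label: str) -> str:
    """Lowercase/trim ``label`` and check it against the vocabulary."""
    name = label.strip().lower()
    if name not in _EMOTIONS:
        raise VocabularyError(f"unknown emotion label: {label!r}")
    return name


def normalize_discourse(label: str) -> str:
    """Map a discourse code or full name (any case) to its one-letter code."""
    token = label.strip()
    if token.upper() in DISCOURSE_NAMES:
        return token.upper()
    code = _NAME_TO_CODE.get(token.lower())
    if code is None:
        raise VocabularyError(f"unknown discourse label: {label!r}")
    return code


# ---------------------------------------------------------------------------
# Confidence ratings

#: Default numeric mappings per scale.  Scales are ordered worst-to-best; the
#: top of each scale maps to 1.  The ``consensus`` scale is the H/M/L triple
#: produced by the common-user merge.
DEFAULT_CONFIDENCE_MAPPINGS: dict[str, dict[str, float]] = {
    "four_level": {
        "definitely not": 0.0,
        "probably not": 1 / 3,
        "probably yes": 2 / 3,
        "definitely yes": 1.0,
    },
    "three_level": {"low": 1 / 3, "mid": 2 / 3, "high": 1.0},
    "consensus": {"l": 0.0, "m": 0.5, "h": 1.0},
}


@dataclass(frozen=True)
class ConfidenceRating:
    """An ordinal confidence level, optionally overridden by a raw number.

    Parameters
    ----------
    scale : str
        ``"four_level"`` (Definitely Not … Definitely Yes), ``"three_level"``
        (Low/Mid/High) or ``"consensus"`` (L/M/H).
    level : str
        A level belonging to the declared scale (case-insensitive).
    numeric_override : float, optional
        When given, used verbatim by :func:`confidence_to_numeric`; must lie
        in [0, 1].  Corpora built directly from numeric confidence tables use
        this field and leave the ordinal machinery aside.
    """

    scale: str = "three_level"
    level: str = "high"
    numeric_override: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in DEFAULT_CONFIDENCE_MAPPINGS:
            raise ValidationError(f"unknown confidence scale {self.scale!r}")
        object.__setattr__(self, "level", self.level.strip().lower())
        if self.level not in DEFAULT_CONFIDENCE_MAPPINGS[self.scale]:
            raise ValidationError(
                f"level {self.level!r} not on scale {self.scale!r}"
            )
        if self.numeric_override is not None and not (
            0.0 <= self.numeric_override <= 1.0
        ):
            raise ValidationError(
                f"numeric_override {self.numeric_override} outside [0, 1]"
            )


def confidence_to_numeric(
    rating: ConfidenceRating,
    mapping: Mapping[str, float] | None = None,
) -> float:
    """Convert an ordinal confidence rating to the number used by the estimator.

    A ``numeric_override`` is returned as-is.  Otherwise the level is looked
    up in ``mapping`` (default: the scale's entry in
    :data:`DEFAULT_CONFIDENCE_MAPPINGS`).  Any admissible mapping must be
    order-preserving in the ordinal level.
    """
    if rating.numeric_override is not None:
        return rating.numeric_override
    table = mapping if mapping is not None else DEFAULT_CONFIDENCE_MAPPINGS[rating.scale]
    normalized = {k.strip().lower(): v for k, v in table.items()}
    try:
        return float(normalized[rating.level])
    except KeyError:
        raise ValidationError(
            f"confidence level {rating.level!r} absent from mapping"
        ) from None


# ---------------------------------------------------------------------------
# Sentences and raw votes


@dataclass(frozen=True)
class Sentence:
    """One speaker turn (complete enunciation) within a dialogue."""

    sentence_id: str
    dialogue_id: str
    position: int
    speaker: str = ""
    text: str = "(no text)"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("position is 1-based")
        if not self.text:
            raise ValidationError("sentence text must be non-empty")


@dataclass(frozen=True)
class DiscourseVote:
    """One rater's vote for one discourse: label + confidence + weight."""

    discourse: str
    confidence: ConfidenceRating = ConfidenceRating()
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "discourse", normalize_discourse(self.discourse))
        if not (0.0 <= self.weight <= 1.0):
            raise ValidationError(f"weight {self.weight} outside [0, 1]")


@dataclass(frozen=True)
class EmotionVote:
    """One rater's vote for one emotion: label + confidence."""

    emotion: str
    confidence: ConfidenceRating = ConfidenceRating()

    def __post_init__(self) -> None:
        object.__setattr__(self, "emotion", normalize_emotion(self.emotion))


@dataclass(frozen=True)
class RaterVotes:
    """All votes one rater cast on one sentence (either set may be empty)."""

    sentence_id: str
    rater_id: str
    discourse_votes: tuple[DiscourseVote, ...] = ()
    emotion_votes: tuple[EmotionVote, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "discourse_votes", tuple(self.discourse_votes))
        object.__setattr__(self, "emotion_votes", tuple(self.emotion_votes))
        d_labels = [v.discourse for v in self.discourse_votes]
        if len(d_labels) > MAX_DISCOURSES_PER_RATER:
            raise ValidationError(
                f"{len(d_labels)} discourse votes exceed the cap of "
                f"{MAX_DISCOURSES_PER_RATER} (sentence {self.sentence_id}, "
                f"rater {self.rater_id})"
            )
        if len(set(d_labels)) != len(d_labels):
            raise ValidationError(
                f"duplicate discourse labels in one vote set "
                f"(sentence {self.sentence_id}, rater {self.rater_id})"
            )
        e_labels = [v.emotion for v in self.emotion_votes]
        if len(e_labels) > MAX_EMOTIONS_PER_RATER:
            raise ValidationError(
                f"{len(e_labels)} emotion votes exceed the cap of "
                f"{MAX_EMOTIONS_PER_RATER} (sentence {self.sentence_id}, "
                f"rater {self.rater_id})"
            )
        if len(set(e_labels)) != len(e_labels):
            raise ValidationError(
                f"duplicate emotion labels in one vote set "
                f"(sentence {self.sentence_id}, rater {self.rater_id})"
            )

    @property
    def discourse_labels(self) -> frozenset[str]:
        return frozenset(v.discourse for v in self.discourse_votes)

    @property
    def emotion_labels(self) -> frozenset[str]:
        return frozenset(v.emotion for v in self.emotion_votes)


# ---------------------------------------------------------------------------
# Consensus ("common user") annotations


@dataclass(frozen=True)
class ConsensusDiscourse:
    """A kept discourse in the common-user annotation.

    ``level`` is H (unanimous), M (majority) or L (only in the none-outcome);
    ``weight`` is the penalized strength, a multiple of 0.2 under the default
    consensus configuration.  ``confidence`` optionally carries a raw numeric
    confidence for corpora built from numeric tables.
    """

    discourse: str
    level: str = "H"
    weight: float = 1.0
    confidence: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "discourse", normalize_discourse(self.discourse))
        if self.level.upper() not in {"H", "M", "L"}:
            raise ValidationError(f"consensus level {self.level!r} not in H/M/L")
        object.__setattr__(self, "level", self.level.upper())
        if not (0.0 <= self.weight <= 1.0):
            raise ValidationError(f"weight {self.weight} outside [0, 1]")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValidationError("numeric confidence outside [0, 1]")

    def numeric_confidence(self, mapping: Mapping[str, float] | None = None) -> float:
        rating = ConfidenceRating("consensus", self.level, self.confidence)
        return confidence_to_numeric(rating, mapping)


@dataclass(frozen=True)
class ConsensusEmotion:
    """A kept emotion in the common-user annotation (no weight)."""

    emotion: str
    level: str = "H"
    confidence: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "emotion", normalize_emotion(self.emotion))
        if self.level.upper() not in {"H", "M", "L"}:
            raise ValidationError(f"consensus level {self.level!r} not in H/M/L")
        object.__setattr__(self, "level", self.level.upper())
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValidationError("numeric confidence outside [0, 1]")

    def numeric_confidence(self, mapping: Mapping[str, float] | None = None) -> float:
        rating = ConfidenceRating("consensus", self.level, self.confidence)
        return confidence_to_numeric(rating, mapping)


@dataclass(frozen=True)
class AnnotatedSentence:
    """A sentence with its consensus discourse combination and emotion set.

    ``excluded`` marks sentences whose discourse merge yielded the
    none-outcome; they are kept for bookkeeping but never enter any
    estimator.
    """

    sentence_id: str
    discourse_set: tuple[ConsensusDiscourse, ...] = ()
    emotion_set: tuple[ConsensusEmotion, ...] = ()
    excluded: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "discourse_set",
            tuple(sorted(self.discourse_set, key=lambda d: d.discourse)),
        )
        object.__setattr__(
            self,
            "emotion_set",
            tuple(sorted(self.emotion_set, key=lambda e: e.emotion)),
        )
        if self.excluded and self.discourse_set:
            raise ValidationError("excluded sentences carry no discourse set")
        labels = [d.discourse for d in self.discourse_set]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate discourses in consensus set")
        if len(labels) > MAX_DISCOURSES_PER_RATER:
            raise ValidationError("consensus discourse set exceeds cap of 4")
        emolabels = [e.emotion for e in self.emotion_set]
        if len(set(emolabels)) != len(emolabels):
            raise ValidationError("duplicate emotions in consensus set")
        if len(emolabels) > MAX_EMOTIONS_PER_RATER:
            raise ValidationError("consensus emotion set exceeds cap of 3")

    @property
    def discourse_labels(self) -> frozenset[str]:
        return frozenset(d.discourse for d in self.discourse_set)

    @property
    def emotion_labels(self) -> frozenset[str]:
        return frozenset(e.emotion for e in self.emotion_set)


@dataclass
class AnnotatedCorpus:
    """The set S of annotated sentences, plus provenance metadata."""

    sentences: list[AnnotatedSentence] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sentence_id for s in self.sentences]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sentence_ids in corpus")

    def included(self) -> list[AnnotatedSentence]:
        """Sentences that enter the estimators (non-excluded, non-empty)."""
        return [
            s for s in self.sentences
            if not s.excluded and s.discourse_set and s.emotion_set
        ]

    def __len__(self) -> int:
        return len(self.sentences)


# ---------------------------------------------------------------------------
# Raw-vote JSON Lines I/O


def _rating_to_json(r: ConfidenceRating) -> dict:
    out: dict = {"scale": r.scale, "level": r.level}
    if r.numeric_override is not None:
        out["numeric"] = r.numeric_override
    return out


def _rating_from_json(obj: dict | None) -> ConfidenceRating:
    if obj is None:
        return ConfidenceRating()
    return ConfidenceRating(
        scale=obj.get("scale", "three_level"),
        level=obj.get("level", "high"),
        numeric_override=obj.get("numeric"),
    )


def save_raw_votes(
    records: Iterable[tuple[Sentence, Sequence[RaterVotes]]],
    path: str | Path,
) -> None:
    """Write raw three-rater votes as JSON Lines, one record per (sentence, rater)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sentence, votes in records:
            for rv in votes:
                obj = {
                    "sentence_id": sentence.sentence_id,
                    "dialogue_id": sentence.dialogue_id,
                    "position": sentence.position,
                    "speaker": sentence.speaker,
                    "text": sentence.text,
                    "rater_id": rv.rater_id,
                    "discourses": [
                        {
                            "label": v.discourse,
                            "confidence": _rating_to_json(v.confidence),
                            "weight": v.weight,
                        }
                        for v in rv.discourse_votes
                    ],
                    "emotions": [
                        {
                            "label": v.emotion,
                            "confidence": _rating_to_json(v.confidence),
                        }
                        for v in rv.emotion_votes
                    ],
                }
                fh.write(json.dumps(obj, sort_keys=True) + "\n")


def load_raw_votes(
    path: str | Path,
    rater_ids: Sequence[str] | None = None,
) -> list[tuple[Sentence, list[RaterVotes]]]:
    """Read a raw-vote JSON Lines file.

    Returns one entry per sentence, in file order, each with one
    :class:`RaterVotes` per declared rater.  ``rater_ids`` defaults to the
    raters present in the file (sorted); a rater with no record for a
    sentence gets an empty vote set — the "(none)" slot of the merge rules.
    """
    path = Path(path)
    sentences: dict[str, Sentence] = {}
    votes: dict[str, dict[str, RaterVotes]] = {}
    seen_raters: set[str] = set()
    positions: set[tuple[str, int]] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path.name}:{lineno}: invalid JSON: {exc}") from exc
            try:
                sid = obj["sentence_id"]
                sent = Sentence(
                    sentence_id=sid,
                    dialogue_id=obj.get("dialogue_id", sid),
                    position=int(obj.get("position", 1)),
                    speaker=obj.get("speaker", ""),
                    text=obj.get("text") or "(no text)",
                )
                rv = RaterVotes(
                    sentence_id=sid,
                    rater_id=str(obj["rater_id"]),
                    discourse_votes=tuple(
                        DiscourseVote(
                            discourse=d["label"],
                            confidence=_rating_from_json(d.get("confidence")),
                            weight=float(d.get("weight", 1.0)),
                        )
                        for d in obj.get("discourses", [])
                    ),
                    emotion_votes=tuple(
                        EmotionVote(
                            emotion=e["label"],
                            confidence=_rating_from_json(e.get("confidence")),
                        )
                        for e in obj.get("emotions", [])
                    ),
                )
            except KeyError as exc:
                raise ParseError(f"{path.name}:{lineno}: missing field {exc}") from exc
            except (VocabularyError, ValidationError) as exc:
                raise type(exc)(f"{path.name}:{lineno}: {exc}") from exc
            if sid not in sentences:
                key = (sent.dialogue_id, sent.position)
                if key in positions:
                    raise ValidationError(
                        f"{path.name}:{lineno}: duplicate (dialogue, position) {key}"
                    )
                positions.add(key)
                sentences[sid] = sent
                votes[sid] = {}
            if rv.rater_id in votes[sid]:
                raise ValidationError(
                    f"{path.name}:{lineno}: duplicate record for sentence {sid}, "
                    f"rater {rv.rater_id}"
                )
            votes[sid][rv.rater_id] = rv
            seen_raters.add(rv.rater_id)
    raters = list(rater_ids) if rater_ids is not None else sorted(seen_raters)
    out = []
    for sid, sent in sentences.items():
        per_rater = [
            votes[sid].get(r, RaterVotes(sentence_id=sid, rater_id=r))
            for r in raters
        ]
        out.append((sent, per_rater))
    return out


# ---------------------------------------------------------------------------
# Consensus-corpus JSON Lines I/O


def save_annotated_corpus(corpus: AnnotatedCorpus, path: str | Path) -> None:
    """Write a consensus corpus: a header record then one record per sentence."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        header = {
            "schema_version": SCHEMA_VERSION,
            **{k: v for k, v in corpus.provenance.items()},
        }
        fh.write(json.dumps({"header": header}, sort_keys=True) + "\n")
        for s in corpus.sentences:
            obj = {
                "sentence_id": s.sentence_id,
                "excluded": s.excluded,
                "discourses": [
                    {
                        "label": d.discourse,
                        "level": d.level,
                        "weight": d.weight,
                        **({"confidence": d.confidence} if d.confidence is not None else {}),
                    }
                    for d in s.discourse_set
                ],
                "emotions": [
                    {
                        "label": e.emotion,
                        "level": e.level,
                        **({"confidence": e.confidence} if e.confidence is not None else {}),
                    }
                    for e in s.emotion_set
                ],
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def load_annotated_corpus(path: str | Path) -> AnnotatedCorpus:
    """Read a consensus corpus written by :func:`save_annotated_corpus`."""
    path = Path(path)
    sentences: list[AnnotatedSentence] = []
    provenance: dict = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path.name}:{lineno}: invalid JSON: {exc}") from exc
            if "header" in obj:
                header = obj["header"]
                version = str(header.get("schema_version", ""))
                if version != SCHEMA_VERSION:
                    raise ParseError(
                        f"{path.name}: schema version {version!r} != {SCHEMA_VERSION!r}"
                    )
                provenance = {
                    k: v for k, v in header.items() if k != "schema_version"
                }
                continue
            try:
                sentences.append(
                    AnnotatedSentence(
                        sentence_id=obj["sentence_id"],
                        excluded=bool(obj.get("excluded", False)),
                        discourse_set=tuple(
                            ConsensusDiscourse(
                                discourse=d["label"],
                                level=d.get("level", "H"),
                                weight=float(d.get("weight", 1.0)),
                                confidence=d.get("confidence"),
                            )
                            for d in obj.get("discourses", [])
                        ),
                        emotion_set=tuple(
                            ConsensusEmotion(
                                emotion=e["label"],
                                level=e.get("level", "H"),
                                confidence=e.get("confidence"),
                            )
                            for e in obj.get("emotions", [])
                        ),
                    )
                )
            except KeyError as exc:
                raise ParseError(f"{path.name}:{lineno}: missing field {exc}") from exc
            except (VocabularyError, ValidationError) as exc:
                raise type(exc)(f"{path.name}:{lineno}: {exc}") from exc
    return AnnotatedCorpus(sentences=sentences, provenance=provenance)


_CSV_COLUMNS = (
    "sentence_id", "excluded", "discourses", "discourse_levels",
    "discourse_weights", "emotions", "emotion_levels",
)


def export_corpus_csv(corpus: AnnotatedCorpus, path: str | Path) -> None:
    """Export a consensus corpus as CSV (sets joined with ``;``, sorted)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for s in corpus.sentences:
            writer.writerow(
                [
                    s.sentence_id,
                    int(s.excluded),
                    ";".join(d.discourse for d in s.discourse_set),
                    ";".join(d.level for d in s.discourse_set),
                    ";".join(f"{d.weight:g}" for d in s.discourse_set),
                    ";".join(e.emotion for e in s.emotion_set),
                    ";".join(e.level for e in s.emotion_set),
                ]
            )


def convert_deposited_votes(path: str | Path) -> list[tuple[Sentence, list[RaterVotes]]]:
    """Converter stub for the study's deposited annotation files.

    Users who fetch the deposited DailyDialog-derived annotations can complete
    this function to map their layout onto :func:`load_raw_votes` records and
    re-run the full analysis on the original data.  The mapping depends on the
    deposited layout and is intentionally left to the user.
    """
    raise NotImplementedError(
        "complete this converter against the deposited annotation layout, "
        "then feed its output to ldd.consensus.harmonize_corpus"
    )
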