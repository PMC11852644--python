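"""Syllabaries and triplet nonsense words for artificial-speech-stream experiments.

The stimulus inventory follows the triplet-embedded segmentation paradigm:
16 consonant-vowel syllables per syllabary, split into a pool of 12 used to
build four *high-TP* words (every within-word syllable transition has
probability 1, because each syllable occurs in exactly one word at exactly one
position) and a pool of 4 used to build four *low-TP* words (each syllable
occurs in three words, once at each of the three positions, so within-word
transitions have probability 1/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

SYLLABLE_MS = 300.0
ISI_MS = 50.0

Condition = Literal["unmixed_high", "unmixed_low", "mixed"]
CONDITIONS: tuple[Condition, ...] = ("unmixed_high", "unmixed_low", "mixed")


class DesignError(ValueError):
    """A stimulus-design constraint cannot be satisfied."""


@dataclass(frozen=True)
class Syllable:
    """A spoken CV syllable; all syllables share a fixed 300 ms duration."""

    label: str
    duration_ms: float = SYLLABLE_MS

    def __post_init__(self) -> None:
        if not self.label:
            raise DesignError("syllable label must be non-empty")


@dataclass(frozen=True)
class Syllabary:
    """A 16-syllable inventory: 12 high-pool + 4 low-pool labels, disjoint."""

    name: str
    high_pool: tuple[str, ...]
    low_pool: tuple[str, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return self.high_pool + self.low_pool


@dataclass(frozen=True)
class TripletWord:
    """A three-syllable nonsense word with a transitional-probability class."""

    syllables: tuple[str, str, str]
    tp_class: Literal["high", "low"]

    def __post_init__(self) -> None:
        if len(set(self.syllables)) != 3:
            raise DesignError(f"word {self.syllables} repeats a syllable")

    @property
    def label(self) -> str:
        return "".join(self.syllables)

    @property
    def initial(self) -> str:
        return self.syllables[0]

    @property
    def final(self) -> str:
        return self.syllables[2]


def validate_syllabary(
    name: str, high_pool: Sequence[str], low_pool: Sequence[str]
) -> Syllabary:
    """Validate pool sizes and label uniqueness, returning a `Syllabary`.

    Raises `DesignError` naming the offending label on duplicates, or
    describing the cardinality violation for wrongly sized pools.
    """
    if len(high_pool) != 12 or len(low_pool) != 4:
        raise DesignError(
            f"pools must have sizes 12 and 4, got {len(high_pool)} and {len(low_pool)}"
        )
    seen: set[str] = set()
    for label in (*high_pool, *low_pool):
        Syllable(label)  # label validity
        if label in seen:
            raise DesignError(f"duplicate syllable label: {label!r}")
        seen.add(label)
    return Syllabary(name, tuple(high_pool), tuple(low_pool))


# Printed stimulus inventory (words and foils per syllabary and stream type).
# High pools are ordered word-wise so that consecutive groups of three form
# the printed high-TP words.
SYLLABARY_A = validate_syllabary(
    "A",
    high_pool=("tu", "ci", "da", "bu", "pe", "po", "mo", "de", "go", "bi", "ba", "ca"),
    low_pool=("do", "ti", "ge", "mi"),
)
SYLLABARY_B = validate_syllabary(
    "B",
    high_pool=("to", "di", "du", "ce", "gi", "ta", "ga", "pa", "be", "bo", "ma", "co"),
    low_pool=("pi", "te", "gu", "me"),
)
SYLLABARIES = {"A": SYLLABARY_A, "B": SYLLABARY_B}

# Published foil sets (one counterbalancing list per stream type).
TABLE_FOILS = {
    ("A", "unmixed_high"): ("tubago", "bucica", "mopeda", "bidepo"),
    ("A", "unmixed_low"): ("dogeti", "timido", "midoge", "getimi"),
    ("A", "mixed"): ("gebado", "mogeti", "bimigo", "mideca"),
    ("B", "unmixed_high"): ("tomabe", "cedico", "gagidu", "bopata"),
    ("B", "unmixed_low"): ("pigute", "temepi", "mepigu", "guteme"),
    ("B", "mixed"): ("gumapi", "gagute", "bomebe", "mepaco"),
}

# Low-TP design pattern over an ordered pool (a, b, c, d): each syllable
# appears in three of the four words, once at each position, and each word
# omits exactly one distinct syllable. With pool (do, ti, ge, mi) this yields
# the printed words dotige / tidomi / migedo / gemiti.
_LOW_PATTERN = ((0, 1, 2), (1, 0, 3), (3, 2, 0), (2, 3, 1))


def build_words(
    syllabary: Syllabary, condition: Condition, mixed_variant: str = "A"
) -> list[TripletWord]:
    """Build the four words of a stream condition from a syllabary.

    unmixed_high: four disjoint triplets over the 12-syllable high pool.
    unmixed_low: the four-syllable shared design over the low pool.
    mixed: two high-TP + two low-TP words; variant "A" takes the last two of
    each unmixed set, variant "B" the first two (mirroring the two published
    mixed lists).
    """
    high = [
        TripletWord(tuple(syllabary.high_pool[3 * i : 3 * i + 3]), "high")
        for i in range(4)
    ]
    low = [
        TripletWord(tuple(syllabary.low_pool[j] for j in pattern), "low")
        for pattern in _LOW_PATTERN
    ]
    if condition == "unmixed_high":
        return high
    if condition == "unmixed_low":
        return low
    if condition == "mixed":
        if mixed_variant == "A":
            return low[2:] + high[2:]
        if mixed_variant == "B":
            return low[:2] + high[:2]
        raise DesignError(f"unknown mixed variant {mixed_variant!r}")
    raise DesignError(f"unknown condition {condition!r}")


def _rotate_word(word: TripletWord, shift: int) -> TripletWord:
    s = word.syllables
    return TripletWord(tuple(s[(i + shift) % 3] for i in range(3)), word.tp_class)


def _reverse_word(word: TripletWord) -> TripletWord:
    return TripletWord(word.syllables[::-1], word.tp_class)


def rotate_lists(
    syllabary: Syllabary,
    condition: Condition,
    n_lists: int = 4,
    mixed_variant: str = "A",
) -> list[list[TripletWord]]:
    """Counterbalancing lists rotating syllables across word positions.

    List 1 is the `build_words` output; lists 2-3 are cyclic position
    rotations and list 4 is the position reversal. Every transform preserves
    the condition's structural design, so across lists each syllable occupies
    every position it can occupy.
    """
    if n_lists < 1:
        raise DesignError("at least one list required")
    base = build_words(syllabary, condition, mixed_variant)
    transforms = [
        lambda w: w,
        lambda w: _rotate_word(w, 1),
        lambda w: _rotate_word(w, 2),
        _reverse_word,
    ]
    if n_lists > len(transforms):
        raise DesignError(f"at most {len(transforms)} lists supported")
    return [[t(w) for w in base] for t in transforms[:n_lists]]


def position_census(words: Iterable[TripletWord]) -> dict[str, list[int]]:
    """Per-syllable counts of occupancy at positions 1-3 across words."""
    census: dict[str, list[int]] = {}
    for word in words:
        for pos, label in enumerate(word.syllables):
            census.setdefault(label, [0, 0, 0])[pos] += 1
    return census


def words_from_labels(
    labels: Sequence[str], syllabary: Syllabary
) -> list[TripletWord]:
    """Parse concatenated 6-char word labels (e.g. "dotige") into words."""
    out = []
    for label in labels:
        sylls = tuple(label[i : i + 2] for i in range(0, 6, 2))
        cls = "low" if all(s in syllabary.low_pool for s in sylls) else "high"
        out.append(TripletWord(sylls, cls))
    return out
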