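"""Two-alternative forced-choice test design: foils, trial lists, scoring.

Foils reuse the familiarization syllables with matched positional frequency
but in orders never attested as within-word sequences, so that preferring a
word over its paired foil indexes sensitivity to the stream's statistics.
The 16-trial test pairs each of the four words with each of the four foils
exactly once, in four blocks of four trials with presentation order
counterbalanced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .lexicon import DesignError, Syllabary, TripletWord, position_census
from .stream_stats import TransitionModel

FIXATION_MS = 1000.0
AFC_ISI_MS = 500.0
TIMEOUT_S = 10.0
CHIRP_DETECTION_CUTOFF = 0.90  # participants at or below are excluded


@dataclass(frozen=True)
class Foil:
    syllables: tuple[str, str, str]
    source_condition: str

    @property
    def label(self) -> str:
        return "".join(self.syllables)


@dataclass(frozen=True)
class AFCTrial:
    word: TripletWord
    foil: Foil
    order: Literal["word_first", "foil_first"]
    block: int  # 1-4
    fixation_ms: float = FIXATION_MS
    isi_ms: float = AFC_ISI_MS
    timeout_s: float = TIMEOUT_S


@dataclass(frozen=True)
class AFCTrialList:
    trials: tuple[AFCTrial, ...]
    seed: int


def _within_word_pairs(words: Sequence[TripletWord]) -> set[tuple[str, str]]:
    pairs = set()
    for w in words:
        a, b, c = w.syllables
        pairs.add((a, b))
        pairs.add((b, c))
    return pairs


def make_foils(
    words: Sequence[TripletWord],
    syllabary: Syllabary,
    condition: str,
    seed: int = 0,
) -> list[Foil]:
    """Construct 4 foils matched to `words` in per-syllable positional frequency.

    Constraints: three distinct syllables per foil; the triplet differs from
    every word; no adjacent foil pair is a within-word pair of any word; and,
    except in the unmixed low-TP condition (where it is unavoidable), no
    adjacent foil pair can be realized across a word boundary either — which
    makes the empirical stream TP of every foil pair exactly 0.
    """
    if len(words) != 4:
        raise DesignError("foil construction expects 4 words")
    rng = np.random.default_rng(seed)
    pools = [[w.syllables[pos] for w in words] for pos in range(3)]
    banned = _within_word_pairs(words)
    word_labels = {w.label for w in words}
    finals = {w.final for w in words}
    initials = {w.initial for w in words}
    forbid_boundary = condition != "unmixed_low"

    def pair_ok(a: str, b: str) -> bool:
        if (a, b) in banned:
            return False
        if forbid_boundary and a in finals and b in initials:
            return False
        return True

    orders = [list(rng.permutation(4)) for _ in range(3)]

    def backtrack(row: int, used: list[set[int]], acc: list[tuple[str, ...]]):
        if row == 4:
            return acc
        for i in orders[0]:
            if i in used[0]:
                continue
            s1 = pools[0][i]
            for j in orders[1]:
                if j in used[1]:
                    continue
                s2 = pools[1][j]
                if s2 == s1 or not pair_ok(s1, s2):
                    continue
                for k in orders[2]:
                    if k in used[2]:
                        continue
                    s3 = pools[2][k]
                    if s3 in (s1, s2) or not pair_ok(s2, s3):
                        continue
                    if s1 + s2 + s3 in word_labels:
                        continue
                    used2 = [used[0] | {i}, used[1] | {j}, used[2] | {k}]
                    result = backtrack(row + 1, used2, acc + [(s1, s2, s3)])
                    if result is not None:
                        return result
        return None

    result = backtrack(0, [set(), set(), set()], [])
    if result is None:
        raise DesignError(
            "no admissible foil set: positional matching with the "
            "unattested-order constraints is infeasible for this word set"
        )
    return [Foil(tuple(s), condition) for s in result]


def foil_tp(foil: Foil, model: TransitionModel) -> dict[tuple[str, str], float]:
    """Empirical TP of each of the foil's two adjacent syllable pairs."""
    a, b, c = foil.syllables
    return {
        (a, b): model.tp_of(a, b),
        (b, c): model.tp_of(b, c),
    }


def make_trials(
    words: Sequence[TripletWord], foils: Sequence[Foil], seed: int = 0
) -> AFCTrialList:
    """Build the 16-trial list: complete word x foil pairing in 4 blocks of 4.

    Block b pairs word i with foil (i + b) mod 4; within each block two
    trials are word-first and two foil-first, arranged so that every word is
    presented first in exactly half of its trials. Trial order within block
    and block order are then shuffled by `seed`.
    """
    if len(words) != 4 or len(foils) != 4:
        raise DesignError("need exactly 4 words and 4 foils")
    rng = np.random.default_rng(seed)
    # word-first indicator: circulant with two ones per row and column
    word_first = [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1], [1, 0, 0, 1]]
    blocks: list[list[AFCTrial]] = []
    for b in range(4):
        block_trials = [
            AFCTrial(
                word=words[i],
                foil=foils[(i + b) % 4],
                order="word_first" if word_first[b][i] else "foil_first",
                block=b + 1,
            )
            for i in range(4)
        ]
        rng.shuffle(block_trials)
        blocks.append(block_trials)
    rng.shuffle(blocks)
    trials = tuple(
        AFCTrial(t.word, t.foil, t.order, block=bi + 1)
        for bi, block in enumerate(blocks)
        for t in block
    )
    return AFCTrialList(trials, seed)


@dataclass(frozen=True)
class AFCScore:
    n_trials: int
    n_correct: int
    percent_correct: float
    percent_by_class: dict[str, float]
    chirp_detection_rate: float | None
    excluded: bool


def score(
    trial_list: AFCTrialList,
    responses: Sequence[str | None],
    chirp_detection_rate: float | None = None,
) -> AFCScore:
    """Score 2-AFC responses ("word" / "foil" / None for timeout).

    Timeouts count as errors. Percent correct is reported overall and split
    by the word's TP class. If a chirp-detection rate is supplied, the
    participant is flagged excluded when it does not exceed 90%.
    """
    trials = trial_list.trials
    if len(responses) != len(trials):
        raise DesignError(
            f"got {len(responses)} responses for {len(trials)} trials"
        )
    correct = [r == "word" for r in responses]
    by_class: dict[str, list[bool]] = {}
    for t, c in zip(trials, correct):
        by_class.setdefault(t.word.tp_class, []).append(c)
    excluded = (
        chirp_detection_rate is not None
        and chirp_detection_rate <= CHIRP_DETECTION_CUTOFF
    )
    return AFCScore(
        n_trials=len(trials),
        n_correct=sum(correct),
        percent_correct=100.0 * sum(correct) / len(trials),
        percent_by_class={
            k: 100.0 * sum(v) / len(v) for k, v in by_class.items()
        },
        chirp_detection_rate=chirp_detection_rate,
        excluded=excluded,
    )


def trial_table(trial_list: AFCTrialList) -> pd.DataFrame:
    rows = [
        {
            "trial": i + 1,
            "block": t.block,
            "word": t.word.label,
            "tp_class": t.word.tp_class,
            "foil": t.foil.label,
            "order": t.order,
        }
        for i, t in enumerate(trial_list.trials)
    ]
    return pd.DataFrame(rows)
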