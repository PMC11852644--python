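"""Constrained pseudo-random familiarization streams with a chirp cover task.

A stream concatenates the four words of a condition, each repeated a fixed
number of times per block, under two adjacency constraints enforced across
block joins: the same word never occurs twice in a row, and the same syllable
never occurs on adjacent tokens (relevant when a word's final syllable equals
another word's initial syllable). Timing is strict: 300 ms per syllable plus
a 50 ms inter-syllable interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lexicon import ISI_MS, SYLLABLE_MS, DesignError, TripletWord

TOKEN_MS = SYLLABLE_MS + ISI_MS  # onset-to-onset spacing


@dataclass(frozen=True)
class StreamSpec:
    """Stream-level design parameters.

    Defaults are the study conditions: 60 repetitions of each word in six
    blocks of 10, 50 ms ISI, chirps on 10% of syllables (0.1 s sawtooth sweep
    450-1450 Hz superimposed on the syllable).
    """

    condition: str = "mixed"
    repetitions_per_word: int = 60
    blocks: int = 6
    reps_per_block: int = 10
    isi_ms: float = ISI_MS
    chirp_rate: float = 0.10
    chirp_duration_s: float = 0.1
    chirp_sweep_hz: tuple[float, float] = (450.0, 1450.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions_per_word != self.blocks * self.reps_per_block:
            raise DesignError("repetitions_per_word must equal blocks * reps_per_block")
        if not 0.0 <= self.chirp_rate <= 1.0:
            raise DesignError(f"chirp_rate must lie in [0, 1], got {self.chirp_rate}")


@dataclass(frozen=True)
class SyllableToken:
    label: str
    onset_ms: float
    word_index: int  # index into the stream's word list
    word_token: int  # ordinal of the word token this syllable belongs to
    position: int  # 1-3 within the word
    chirp: bool = False


@dataclass(frozen=True)
class StreamSequence:
    """The ordered, timed token stream — the experiment's stimulus object."""

    words: tuple[TripletWord, ...]
    word_tokens: tuple[tuple[int, int], ...]  # (word index, block index)
    syllable_tokens: tuple[SyllableToken, ...]
    spec: StreamSpec

    @property
    def total_duration_ms(self) -> float:
        return len(self.syllable_tokens) * TOKEN_MS

    def labels(self) -> list[str]:
        return [t.label for t in self.syllable_tokens]

    def word_onsets_ms(self) -> np.ndarray:
        return np.array(
            [t.onset_ms for t in self.syllable_tokens if t.position == 1]
        )


def _legal_after(prev: TripletWord | None, nxt: TripletWord) -> bool:
    if prev is None:
        return True
    return prev is not nxt and prev.final != nxt.initial


def _order_block(
    words: list[TripletWord],
    reps: int,
    prev_word: TripletWord | None,
    rng: np.random.Generator,
    max_retries: int,
) -> list[int]:
    """Shuffle a block's word multiset, repairing adjacency violations.

    A violating position is swapped forward to the first legal later
    position; if no repair exists the shuffle is rejected and retried.
    """
    indices = np.repeat(np.arange(len(words)), reps)
    for _ in range(max_retries):
        order = list(rng.permutation(indices))
        ok = True
        for i in range(len(order)):
            prev = words[order[i - 1]] if i > 0 else prev_word
            if _legal_after(prev, words[order[i]]):
                continue
            for j in range(i + 1, len(order)):
                if _legal_after(prev, words[order[j]]):
                    order[i], order[j] = order[j], order[i]
                    break
            else:
                ok = False  # no forward repair available
                break
        if not ok:
            continue
        # repair swaps can break already-visited pairs; validate the candidate
        prev = prev_word
        valid = True
        for idx in order:
            if not _legal_after(prev, words[idx]):
                valid = False
                break
            prev = words[idx]
        if valid:
            return order
    raise DesignError("no legal ordering found within retry budget")


def generate_sequence(
    words: list[TripletWord], spec: StreamSpec, seed: int | None = None
) -> StreamSequence:
    """Generate the full familiarization stream for `words` under `spec`.

    Per-block multiset shuffle with rejection and local repair, bounded at
    10,000 retries per block; adjacency constraints hold across block joins.
    Reproducible for a given seed.
    """
    if len(set(w.label for w in words)) != len(words):
        raise DesignError("words must be mutually distinct")
    if len(words) < 2:
        raise DesignError("at least two distinct words are required")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    word_tokens: list[tuple[int, int]] = []
    prev: TripletWord | None = None
    for block in range(spec.blocks):
        try:
            order = _order_block(list(words), spec.reps_per_block, prev, rng, 10_000)
        except DesignError as exc:
            raise DesignError(f"block {block}: {exc}") from exc
        word_tokens.extend((idx, block) for idx in order)
        prev = words[order[-1]]

    syllable_tokens: list[SyllableToken] = []
    for k, (widx, _block) in enumerate(word_tokens):
        for pos in range(3):
            t = len(syllable_tokens)
            syllable_tokens.append(
                SyllableToken(
                    label=words[widx].syllables[pos],
                    onset_ms=t * TOKEN_MS,
                    word_index=widx,
                    word_token=k,
                    position=pos + 1,
                )
            )
    return StreamSequence(tuple(words), tuple(word_tokens), tuple(syllable_tokens), spec)


def place_chirps(
    seq: StreamSequence, spec: StreamSpec | None = None, seed: int | None = None
) -> StreamSequence:
    """Flag chirp-carrying syllable tokens, stratified over word x position.

    Exactly round(rate * n_tokens) tokens are flagged; quotas of
    floor(n_chirps / (n_words * 3)) per (word, position) cell with the
    remainder assigned randomly, and no two chirps on adjacent tokens.
    """
    spec = spec or seq.spec
    if not 0.0 <= spec.chirp_rate <= 1.0:
        raise DesignError(f"chirp_rate must lie in [0, 1], got {spec.chirp_rate}")
    n_tokens = len(seq.syllable_tokens)
    n_chirps = round(spec.chirp_rate * n_tokens)
    if n_chirps == 0:
        return seq
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    n_cells = len(seq.words) * 3
    base, rem = divmod(n_chirps, n_cells)
    cells = [
        (w, p) for w in range(len(seq.words)) for p in range(1, 4)
    ]
    quotas = {cell: base for cell in cells}
    for cell_idx in rng.choice(len(cells), size=rem, replace=False):
        quotas[cells[cell_idx]] += 1

    cell_tokens: dict[tuple[int, int], list[int]] = {cell: [] for cell in cells}
    for i, tok in enumerate(seq.syllable_tokens):
        cell_tokens[(tok.word_index, tok.position)].append(i)

    for _ in range(10_000):
        chosen: set[int] = set()
        ok = True
        for cell in rng.permutation(len(cells)):
            cell = cells[cell]
            candidates = [
                i
                for i in cell_tokens[cell]
                if i - 1 not in chosen and i + 1 not in chosen
            ]
            if len(candidates) < quotas[cell]:
                ok = False
                break
            picked = rng.choice(candidates, size=quotas[cell], replace=False)
            # re-check adjacency within the picked set itself
            picked = sorted(int(i) for i in picked)
            if any(b - a == 1 for a, b in zip(picked, picked[1:])):
                ok = False
                break
            chosen.update(picked)
        if ok:
            break
    else:
        raise DesignError("no admissible chirp placement found within retry budget")

    tokens = tuple(
        replace(tok, chirp=(i in chosen)) for i, tok in enumerate(seq.syllable_tokens)
    )
    return StreamSequence(seq.words, seq.word_tokens, tokens, spec)


def validate_stream(seq: StreamSequence) -> list[str]:
    """Brute-force validator; returns a list of violation descriptions."""
    problems: list[str] = []
    spec = seq.spec
    for k in range(1, len(seq.word_tokens)):
        if seq.word_tokens[k][0] == seq.word_tokens[k - 1][0]:
            problems.append(f"word repeat at word token {k}")
    labels = seq.labels()
    for i in range(1, len(labels)):
        if labels[i] == labels[i - 1]:
            problems.append(f"identical adjacent syllables at token {i}")
    for block in range(spec.blocks):
        counts = np.zeros(len(seq.words), dtype=int)
        for widx, b in seq.word_tokens:
            if b == block:
                counts[widx] += 1
        if not np.all(counts == spec.reps_per_block):
            problems.append(f"block {block} quota violated: {counts.tolist()}")
    for i, tok in enumerate(seq.syllable_tokens):
        if tok.onset_ms != i * TOKEN_MS:
            problems.append(f"onset grid violated at token {i}")
    flags = [t.chirp for t in seq.syllable_tokens]
    for i in range(1, len(flags)):
        if flags[i] and flags[i - 1]:
            problems.append(f"adjacent chirps at token {i}")
    return problems
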