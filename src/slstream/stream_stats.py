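"""Transitional probabilities and entropy summaries of syllable streams.

Transitional probability (TP) is the local statistic of the paradigm:
TP(j | i) = count(i -> j) / count(i with a successor). Entropy is the global
statistic: the uncertainty of the next syllable under the stream's transition
structure. Because "the" entropy of a stream admits several defensible
formulas, every report carries all implemented variants; the scientific
contract is the ordering across conditions (low-TP > mixed > high-TP), not a
particular value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .lexicon import DesignError, TripletWord
from .sequence import StreamSequence

EntropyMethod = Literal["markov_stationary", "markov_row_mean", "joint_shannon"]
Normalization = Literal["none", "by_log_states", "by_log_16"]

ENTROPY_METHODS: tuple[EntropyMethod, ...] = (
    "markov_stationary",
    "markov_row_mean",
    "joint_shannon",
)
NORMALIZATIONS: tuple[Normalization, ...] = ("none", "by_log_states", "by_log_16")


@dataclass(frozen=True)
class TransitionModel:
    """Syllable-level transition structure plus word-boundary successor sets.

    `counts` may hold empirical tallies (integers) or expected counts from a
    closed-form design model; `tp[i, j] = P(state j | state i)` with the
    stream-final token excluded from denominators; `pi` is the state
    frequency distribution. `boundary_successors[w]` maps each word label to
    the probability of each legal successor word.
    """

    states: tuple[str, ...]
    counts: np.ndarray
    tp: np.ndarray
    pi: np.ndarray
    boundary_successors: dict[str, dict[str, float]]

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise DesignError(f"syllable {label!r} not in model") from None

    def tp_of(self, first: str, second: str) -> float:
        return float(self.tp[self.index(first), self.index(second)])


@dataclass(frozen=True)
class EntropyReport:
    method: EntropyMethod
    log_base: float
    normalization: Normalization
    value: float


def _finalize(
    states: tuple[str, ...],
    counts: np.ndarray,
    boundary: dict[str, dict[str, float]],
    pi: np.ndarray | None = None,
) -> TransitionModel:
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = np.where(row_sums > 0, counts / np.where(row_sums == 0, 1, row_sums), 0.0)
    if pi is None:
        total = counts.sum()
        pi = counts.sum(axis=1) / total if total else np.zeros(len(states))
    return TransitionModel(states, counts, tp, np.asarray(pi, dtype=float), boundary)


def empirical_tp(seq: StreamSequence) -> TransitionModel:
    """Tally adjacent syllable pairs and word-boundary successions of a stream."""
    labels = seq.labels()
    if len(labels) < 2:
        raise DesignError("sequence must contain at least two syllable tokens")
    states = tuple(sorted(set(labels)))
    idx = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)))
    for a, b in zip(labels, labels[1:]):
        counts[idx[a], idx[b]] += 1
    # state frequencies over all tokens (not just those with successors)
    pi = np.zeros(len(states))
    for lab in labels:
        pi[idx[lab]] += 1
    pi /= pi.sum()

    word_labels = [seq.words[w].label for w, _ in seq.word_tokens]
    boundary: dict[str, dict[str, float]] = {}
    tallies: dict[str, dict[str, int]] = {}
    for a, b in zip(word_labels, word_labels[1:]):
        tallies.setdefault(a, {}).setdefault(b, 0)
        tallies[a][b] += 1
    for a, succ in tallies.items():
        total = sum(succ.values())
        boundary[a] = {b: n / total for b, n in succ.items()}
    return _finalize(states, counts, boundary, pi)


def word_successor_graph(words: list[TripletWord]) -> dict[str, list[str]]:
    """Words legal as successors of each word under the sequencing constraints
    (no immediate word repeat; no identical adjacent syllables)."""
    graph: dict[str, list[str]] = {}
    for w in words:
        graph[w.label] = [
            v.label for v in words if v.label != w.label and v.initial != w.final
        ]
    return graph


def theoretical_tp(words: list[TripletWord], condition: str | None = None) -> TransitionModel:
    """Closed-form transition model assuming equal word frequencies and a
    uniform choice among legal successor words.

    Expected counts per word token: each word contributes its two within-word
    transitions plus one boundary transition to the initial syllable of each
    legal successor, weighted by the uniform successor probability.
    """
    if len(set(w.label for w in words)) != len(words):
        raise DesignError("duplicate words in design")
    graph = word_successor_graph(words)
    if any(len(succ) == 0 for succ in graph.values()):
        raise DesignError("a word has no legal successor; design infeasible")
    states = tuple(sorted({s for w in words for s in w.syllables}))
    idx = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)))
    w_by_label = {w.label: w for w in words}
    p_word = 1.0 / len(words)
    for w in words:
        a, b, c = w.syllables
        counts[idx[a], idx[b]] += p_word
        counts[idx[b], idx[c]] += p_word
        for succ in graph[w.label]:
            counts[idx[c], idx[w_by_label[succ].initial]] += p_word / len(
                graph[w.label]
            )
    pi = np.zeros(len(states))
    for w in words:
        for s in w.syllables:
            pi[idx[s]] += p_word / 3.0
    boundary = {
        w: {v: 1.0 / len(succ) for v in succ} for w, succ in graph.items()
    }
    return _finalize(states, counts, boundary, pi)


def empirical_within_tp(seq: StreamSequence) -> dict[tuple[str, str], float]:
    """Within-word transitional probabilities tallied from a stream.

    Numerator: occurrences of the pair inside a single word token (positions
    1-2 or 2-3). Denominator: all occurrences of the first syllable that have
    a successor. This is the design statistic usually quoted for the paradigm
    (1 for high-TP words, 1/3 for low-TP words in the four-word shared
    design); the full bigram tally of `empirical_tp` additionally picks up
    word-boundary echoes of the same pair.
    """
    toks = seq.syllable_tokens
    if len(toks) < 2:
        raise DesignError("sequence must contain at least two syllable tokens")
    first_counts: dict[str, int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for a, b in zip(toks, toks[1:]):
        first_counts[a.label] = first_counts.get(a.label, 0) + 1
        if a.word_token == b.word_token:
            key = (a.label, b.label)
            pair_counts[key] = pair_counts.get(key, 0) + 1
    return {
        pair: n / first_counts[pair[0]] for pair, n in pair_counts.items()
    }


def theoretical_within_tp(words: list[TripletWord]) -> dict[tuple[str, str], float]:
    """Closed-form within-word TPs under equal word frequencies."""
    occ: dict[str, float] = {}
    pair: dict[tuple[str, str], float] = {}
    p_word = 1.0 / len(words)
    for w in words:
        a, b, c = w.syllables
        for s in (a, b, c):
            occ[s] = occ.get(s, 0.0) + p_word
        pair[(a, b)] = pair.get((a, b), 0.0) + p_word
        pair[(b, c)] = pair.get((b, c), 0.0) + p_word
    return {k: v / occ[k[0]] for k, v in pair.items()}


def entropy(
    model: TransitionModel,
    method: EntropyMethod = "markov_stationary",
    log_base: float = 2.0,
    normalization: Normalization = "none",
) -> EntropyReport:
    """Entropy of the syllable transition structure.

    markov_stationary: -sum_i pi_i sum_j P(j|i) log P(j|i) (entropy rate
    under the state frequencies); markov_row_mean: unweighted mean of row
    entropies; joint_shannon: Shannon entropy of the bigram distribution
    pi_i * P(j|i).
    """
    if len(model.states) == 0:
        raise DesignError("empty model")
    if log_base <= 0 or log_base == 1:
        raise DesignError(f"invalid log base {log_base}")

    def h(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum() / np.log(log_base))

    rows_with_mass = model.tp.sum(axis=1) > 0
    row_h = np.array([h(model.tp[i]) for i in range(len(model.states))])
    if method == "markov_stationary":
        value = float((model.pi * row_h).sum())
    elif method == "markov_row_mean":
        value = float(row_h[rows_with_mass].mean())
    elif method == "joint_shannon":
        # conditional Shannon entropy of the bigram distribution:
        # H(pair) - H(first element). The unconditional pair entropy would
        # scale with the syllabary size and be nonzero even for a fully
        # deterministic chain, which would not measure predictability.
        joint = model.pi[:, None] * model.tp
        joint = joint / joint.sum()
        value = h(joint.ravel()) - h(joint.sum(axis=1))
    else:
        raise DesignError(f"unknown entropy method {method!r}")

    if normalization == "by_log_states":
        value /= np.log(len(model.states)) / np.log(log_base)
    elif normalization == "by_log_16":
        value /= np.log(16) / np.log(log_base)
    elif normalization != "none":
        raise DesignError(f"unknown normalization {normalization!r}")
    return EntropyReport(method, log_base, normalization, value)


def entropy_table(model: TransitionModel, log_base: float = 2.0) -> pd.DataFrame:
    """All entropy variants of a model, long format."""
    rows = []
    for method in ENTROPY_METHODS:
        for norm in NORMALIZATIONS:
            rep = entropy(model, method, log_base, norm)
            rows.append(
                {
                    "method": method,
                    "normalization": norm,
                    "log_base": log_base,
                    "entropy": rep.value,
                }
            )
    return pd.DataFrame(rows)


def stream_report(
    seq: StreamSequence, words: list[TripletWord], condition: str
) -> pd.DataFrame:
    """Design-statistics report for a generated stream, long format
    (condition, statistic, value), with deviation flags.

    Covers within-word and boundary TPs (empirical vs theoretical), all
    entropy variants, the chirp census, and total duration.
    """
    emp = empirical_tp(seq)
    theo = theoretical_tp(words, condition)
    emp_within = empirical_within_tp(seq)
    theo_within = theoretical_within_tp(words)
    rows: list[dict] = []

    def add(stat: str, value: float, flag: str = "") -> None:
        rows.append(
            {"condition": condition, "statistic": stat, "value": value, "flag": flag}
        )

    for w in words:
        a, b, c = w.syllables
        for first, second in ((a, b), (b, c)):
            t_emp = emp_within.get((first, second), 0.0)
            t_theo = theo_within[(first, second)]
            flag = "" if abs(t_emp - t_theo) <= 0.02 else "deviates"
            add(f"tp_within[{w.label}:{first}->{second}]", t_emp, flag)
            add(f"tp_within_theoretical[{w.label}:{first}->{second}]", t_theo)
    n_boundaries = len(seq.word_tokens) - 1
    for w_label, succ in theo.boundary_successors.items():
        # each word precedes ~1/n_words of the boundaries
        n_draws = max(n_boundaries / len(words), 1.0)
        for v_label, p in succ.items():
            p_emp = emp.boundary_successors.get(w_label, {}).get(v_label, 0.0)
            se = (p * (1 - p) / n_draws) ** 0.5
            flag = "" if abs(p_emp - p) <= max(0.02, 3 * se) else "deviates"
            add(f"p_boundary[{w_label}->{v_label}]", p_emp, flag)
            add(f"p_boundary_theoretical[{w_label}->{v_label}]", p)
    for _, erow in entropy_table(theo).iterrows():
        add(
            f"entropy[{erow['method']},{erow['normalization']}]",
            erow["entropy"],
        )
    n_chirps = sum(t.chirp for t in seq.syllable_tokens)
    add("n_syllable_tokens", len(seq.syllable_tokens))
    add("n_word_tokens", len(seq.word_tokens))
    add("n_chirps", n_chirps)
    for pos in (1, 2, 3):
        add(
            f"chirps_at_position_{pos}",
            sum(t.chirp for t in seq.syllable_tokens if t.position == pos),
        )
    add("duration_min", seq.total_duration_ms / 60_000.0)
    return pd.DataFrame(rows)
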