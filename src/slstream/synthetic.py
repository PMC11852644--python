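"""Synthetic cohorts: 2-AFC responders and word-onset-locked EEG.

Stands in for human participants so the full analysis chain is testable
end-to-end. Responder accuracies default to the study-condition means
(implicit/explicit x stream x word type); EEG is built from analytic
Gaussian-windowed component kernels (N100/P200/N400) over 1/f-plus-white
noise, with occasional high-amplitude square-pulse artifacts, so that the
processing chain's output can be checked against known injected truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .afc import AFCTrialList
from .lexicon import DesignError
from .montage import CHANNELS_66, MASTOIDS, channel_gains
from .erp import EEGRecording
from .sequence import StreamSequence

# Cohort sizes after the cover-task exclusion (16 / 16 / 23).
DEFAULT_GROUP_SIZES = {"unmixed_high": 16, "unmixed_low": 16, "mixed": 23}

# Published group-mean accuracies, rescaled to probabilities.
# Keys: (condition, task, tp_class).
_DEFAULT_P_CORRECT = {
    ("unmixed_high", "implicit", "high"): 0.613,
    ("unmixed_high", "explicit", "high"): 0.715,
    ("unmixed_low", "implicit", "low"): 0.559,
    ("unmixed_low", "explicit", "low"): 0.641,
    ("mixed", "implicit", "high"): 0.658,
    ("mixed", "explicit", "high"): 0.750,
    ("mixed", "implicit", "low"): 0.587,
    ("mixed", "explicit", "low"): 0.641,
}

TASKS = ("implicit", "explicit")


@dataclass(frozen=True)
class ResponderParams:
    """Bernoulli response model for the 2-AFC tasks plus the cover task."""

    p_correct: dict[tuple[str, str, str], float]
    chirp_hit_rate: float = 0.98
    n_participants: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for key, p in self.p_correct.items():
            if not 0.0 <= p <= 1.0:
                raise DesignError(f"p_correct[{key}] = {p} outside [0, 1]")
        if not 0.0 <= self.chirp_hit_rate <= 1.0:
            raise DesignError("chirp_hit_rate outside [0, 1]")

    def p_for(self, condition: str, task: str, tp_class: str) -> float:
        try:
            return self.p_correct[(condition, task, tp_class)]
        except KeyError:
            raise DesignError(
                f"no accuracy parameter for ({condition}, {task}, {tp_class})"
            ) from None


def default_responder_params(seed: int = 0) -> ResponderParams:
    """Responder parameters at the study-condition group means."""
    return ResponderParams(p_correct=dict(_DEFAULT_P_CORRECT), seed=seed)


def simulate_responses(
    params: ResponderParams,
    trial_lists: dict[tuple[int, str, str], AFCTrialList],
    n_chirps: int = 72,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per-trial 2-AFC choices and cover-task detections for a cohort.

    `trial_lists` maps (participant, condition, task) to the participant's
    16-trial list. Each trial is an independent Bernoulli draw at the
    (condition, task, tp_class) accuracy; chirp detections are binomial at
    the chirp hit rate. Returns a tidy per-trial table.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rows = []
    chirp_rates: dict[tuple[int, str], float] = {}
    for (pid, condition, task), tl in sorted(
        trial_lists.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        key = (pid, condition)
        if key not in chirp_rates:
            chirp_rates[key] = rng.binomial(n_chirps, params.chirp_hit_rate) / n_chirps
        for i, trial in enumerate(tl.trials):
            p = params.p_for(condition, task, trial.word.tp_class)
            correct = bool(rng.random() < p)
            rows.append(
                {
                    "participant": pid,
                    "condition": condition,
                    "task": task,
                    "trial": i + 1,
                    "tp_class": trial.word.tp_class,
                    "response": "word" if correct else "foil",
                    "correct": int(correct),
                    "chirp_detection_rate": chirp_rates[key],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComponentEffect:
    """One ERP component kernel: a Gaussian-windowed deflection."""

    name: str
    base_uv: float  # signed; negative for N100/N400, positive for P200
    latency_ms: float
    width_ms: float  # Gaussian sigma
    condition_offsets_uv: dict[str, float] = field(default_factory=dict)
    half_offsets_uv: dict[int, float] = field(default_factory=dict)
    tp_class_offsets_uv: dict[str, float] = field(default_factory=dict)

    def amplitude(self, condition: str, half: int, tp_class: str) -> float:
        return (
            self.base_uv
            + self.condition_offsets_uv.get(condition, 0.0)
            + self.half_offsets_uv.get(half, 0.0)
            + self.tp_class_offsets_uv.get(tp_class, 0.0)
        )


@dataclass(frozen=True)
class ErpEffectParams:
    """Simulation parameters for the EEG generator."""

    components: tuple[ComponentEffect, ...]
    noise_rms_uv: float = 10.0
    noise_exponent: float = 1.0  # 1/f^a power
    noise_white_fraction: float = 0.3  # share of noise variance that is white
    artifact_rate: float = 0.0  # per word-token probability
    artifact_amplitude_uv: float = 300.0
    artifact_duration_ms: float = 200.0
    off_roi_gain: float = 0.3
    pad_s: float = 2.0

    def __post_init__(self) -> None:
        for c in self.components:
            if c.width_ms <= 0:
                raise DesignError(f"component {c.name} width must be positive")
        if self.noise_rms_uv < 0 or not 0 <= self.artifact_rate <= 1:
            raise DesignError("invalid noise or artifact parameters")


def default_erp_effects(
    noise_rms_uv: float = 10.0, artifact_rate: float = 0.05
) -> ErpEffectParams:
    """Plausible defaults: N100/N400 negative, P200 positive, with the
    study's qualitative contrasts encoded as amplitude offsets (facilitated
    mixed-stream processing in P200/N400, larger second-half N100, larger
    N100/N400 for high-TP words)."""
    return ErpEffectParams(
        components=(
            ComponentEffect(
                "N100", -3.0, 90.0, 15.0,
                half_offsets_uv={1: 0.0, 2: -0.8},
                tp_class_offsets_uv={"high": -0.4, "low": 0.0},
            ),
            ComponentEffect(
                "P200", 4.0, 170.0, 20.0,
                condition_offsets_uv={"mixed": 1.0, "unmixed_low": -0.5},
            ),
            ComponentEffect(
                "N400", -5.0, 400.0, 30.0,
                condition_offsets_uv={"mixed": -1.5},
                tp_class_offsets_uv={"high": -0.5, "low": 0.0},
            ),
        ),
        noise_rms_uv=noise_rms_uv,
        artifact_rate=artifact_rate,
    )


def _one_over_f_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sfreq: float,
    rms_uv: float,
    exponent: float,
    white_fraction: float,
) -> np.ndarray:
    if rms_uv == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[freqs < 0.1] = shape[freqs >= 0.1][0] if np.any(freqs >= 0.1) else 0.0
    spectrum = (
        rng.standard_normal((n_channels, len(freqs)))
        + 1j * rng.standard_normal((n_channels, len(freqs)))
    ) * shape[None, :]
    pink = np.fft.irfft(spectrum, n=n_samples, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    white = rng.standard_normal((n_channels, n_samples))
    noise = (
        np.sqrt(1.0 - white_fraction) * pink + np.sqrt(white_fraction) * white
    )
    return rms_uv * noise


def simulate_eeg(
    seq: StreamSequence,
    effects: ErpEffectParams,
    seed: int = 0,
    condition: str | None = None,
    sfreq: float = 512.0,
    ch_names: tuple[str, ...] = CHANNELS_66,
) -> EEGRecording:
    """Synthesize a continuous EEG recording for one familiarization stream.

    Each word token contributes the three component kernels at its onset,
    with amplitude = base + condition/half/tp-class offsets, projected onto
    the scalp through fixed per-channel gains (maximal over the
    frontocentral ROI, zero at the mastoids). 1/f-plus-white noise is added
    on every channel including mastoids; artifacts are square pulses well
    above the rejection threshold on a random scalp channel, placed inside
    the epoch's own post-onset span. Bit-identical for identical seeds.
    """
    rng = np.random.default_rng(seed)
    condition = condition or seq.spec.condition
    half_blocks = seq.spec.blocks // 2
    epoch_span_ms = 1200.0
    for c in effects.components:
        if c.latency_ms >= epoch_span_ms:
            raise DesignError(
                f"component {c.name} latency {c.latency_ms} ms beyond epoch span"
            )

    n_samples = int(round((seq.total_duration_ms / 1000.0 + 2 * effects.pad_s) * sfreq))
    gains = channel_gains(ch_names, effects.off_roi_gain)
    signal_trace = np.zeros(n_samples)
    t = np.arange(n_samples) / sfreq

    events = []
    word_onset_tokens = [tok for tok in seq.syllable_tokens if tok.position == 1]
    for tok in word_onset_tokens:
        word = seq.words[tok.word_index]
        block = seq.word_tokens[tok.word_token][1]
        half = 1 if block < half_blocks else 2
        onset_s = tok.onset_ms / 1000.0 + effects.pad_s
        events.append(
            {
                "onset_s": onset_s,
                "condition": condition,
                "half": half,
                "tp_class": word.tp_class,
                "word": word.label,
                "block": block + 1,
            }
        )
        for comp in effects.components:
            amp = comp.amplitude(condition, half, word.tp_class)
            if amp == 0.0:
                continue
            center = onset_s + comp.latency_ms / 1000.0
            sigma = comp.width_ms / 1000.0
            lo = max(0, int((center - 5 * sigma) * sfreq))
            hi = min(n_samples, int((center + 5 * sigma) * sfreq) + 1)
            signal_trace[lo:hi] += amp * np.exp(
                -0.5 * ((t[lo:hi] - center) / sigma) ** 2
            )

    data = gains[:, None] * signal_trace[None, :]
    data += _one_over_f_noise(
        rng,
        len(ch_names),
        n_samples,
        sfreq,
        effects.noise_rms_uv,
        effects.noise_exponent,
        effects.noise_white_fraction,
    )

    if effects.artifact_rate > 0:
        scalp_idx = [i for i, ch in enumerate(ch_names) if ch not in MASTOIDS]
        n_art = int(round(effects.artifact_duration_ms / 1000.0 * sfreq))
        artifact_flags = []
        for ev in events:
            hit = rng.random() < effects.artifact_rate
            artifact_flags.append(hit)
            if not hit:
                continue
            ch = scalp_idx[rng.integers(len(scalp_idx))]
            # inside [250, 650] ms post-onset: affects only this epoch
            start_s = ev["onset_s"] + 0.25 + rng.random() * 0.2
            lo = int(start_s * sfreq)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[ch, lo : lo + n_art] += sign * effects.artifact_amplitude_uv
        for ev, flag in zip(events, artifact_flags):
            ev["artifact"] = int(flag)
    else:
        for ev in events:
            ev["artifact"] = 0

    return EEGRecording(data, sfreq, tuple(ch_names), pd.DataFrame(events))
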