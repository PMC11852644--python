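"""Tone-proxy audio rendering and event annotation for streams.

The original syllable recordings are not part of the package; syllables are
rendered as fixed-duration tones with one fundamental per syllable label so
that streams remain audible and timing-exact. The event annotation, not the
audio, is the contract consumed by downstream modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .lexicon import SYLLABLE_MS, DesignError
from .sequence import StreamSequence


def events_table(seq: StreamSequence) -> pd.DataFrame:
    """BIDS-style events: onset (s), duration (s), trial_type, word, position, chirp."""
    rows = []
    for tok in seq.syllable_tokens:
        rows.append(
            {
                "onset": tok.onset_ms / 1000.0,
                "duration": SYLLABLE_MS / 1000.0,
                "trial_type": "syllable",
                "word": seq.words[tok.word_index].label,
                "syllable": tok.label,
                "position": tok.position,
                "chirp": int(tok.chirp),
            }
        )
    return pd.DataFrame(rows)


def write_events_tsv(seq: StreamSequence, path: str) -> None:
    events_table(seq).to_csv(path, sep="\t", index=False)


def _syllable_tone(label: str, n: int, sr: int) -> np.ndarray:
    # distinct fundamental per label, deterministic in the label itself
    f0 = 220.0 * 2 ** ((hash_label(label) % 16) / 12.0)
    t = np.arange(n) / sr
    tone = np.sin(2 * np.pi * f0 * t)
    ramp = min(int(0.01 * sr), n // 2)
    env = np.ones(n)
    env[:ramp] = np.linspace(0, 1, ramp)
    env[-ramp:] = np.linspace(1, 0, ramp)
    return 0.4 * tone * env


def hash_label(label: str) -> int:
    """Stable (process-independent) small hash of a syllable label."""
    h = 0
    for ch in label:
        h = (h * 31 + ord(ch)) % 997
    return h


def _chirp(n: int, sr: int, f_lo: float, f_hi: float) -> np.ndarray:
    t = np.arange(n) / sr
    freq = f_lo + (f_hi - f_lo) * t / t[-1] if n > 1 else np.array([f_lo])
    phase = 2 * np.pi * np.cumsum(freq) / sr
    # sawtooth of the swept phase
    return 0.3 * (2 * ((phase / (2 * np.pi)) % 1.0) - 1.0)


def render_audio(
    seq: StreamSequence, mode: str = "tone_proxy", sample_rate: int = 16_000
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a stream to a waveform plus its lossless event annotation.

    The waveform spans exactly `seq.total_duration_ms`; each chirp-flagged
    syllable carries a superimposed sawtooth sweep (by default 0.1 s,
    450-1450 Hz) starting at the syllable onset.
    """
    if mode != "tone_proxy":
        raise DesignError(f"unsupported render mode {mode!r}")
    n_total = int(round(seq.total_duration_ms / 1000.0 * sample_rate))
    wave = np.zeros(n_total)
    n_syll = int(round(SYLLABLE_MS / 1000.0 * sample_rate))
    spec = seq.spec
    n_chirp = int(round(spec.chirp_duration_s * sample_rate))
    f_lo, f_hi = spec.chirp_sweep_hz
    for tok in seq.syllable_tokens:
        start = int(round(tok.onset_ms / 1000.0 * sample_rate))
        seg = _syllable_tone(tok.label, n_syll, sample_rate)
        wave[start : start + n_syll] += seg[: max(0, n_total - start)]
        if tok.chirp:
            ch = _chirp(n_chirp, sample_rate, f_lo, f_hi)
            end = min(start + n_chirp, n_total)
            wave[start:end] += ch[: end - start]
    return wave, events_table(seq)


def write_wav(wave: np.ndarray, path: str, sample_rate: int = 16_000) -> None:
    peak = np.max(np.abs(wave)) if wave.size else 0.0
    scaled = wave / peak * 0.9 if peak > 0 else wave
    wavfile.write(path, sample_rate, (scaled * 32767).astype(np.int16))
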