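"""ERP chain: filtering, epoching, rejection, averaging, peak measurement."""

import numpy as np
import pandas as pd
import pytest

from slstream.erp import (
    EEGRecording,
    EpochSet,
    ErpComponentSpec,
    EvokedAverage,
    N100,
    N400,
    P200,
    epoch,
    evoked,
    peak,
    preprocess,
    reject,
)
from slstream.lexicon import DesignError
from slstream.montage import REDUCED_MONTAGE, ROI_FRONTOCENTRAL
from slstream.sequence import StreamSpec, generate_sequence
from slstream.synthetic import (
    ComponentEffect,
    ErpEffectParams,
    default_erp_effects,
    simulate_eeg,
)


def _recording(data: np.ndarray, sfreq=512.0, onsets=(2.0,)) -> EEGRecording:
    events = pd.DataFrame(
        {"onset_s": list(onsets), "condition": "mixed", "half": 1, "tp_class": "high"}
    )
    return EEGRecording(data, sfreq, REDUCED_MONTAGE, events)


def test_notch_attenuates_50hz_by_30db():
    t = np.arange(0, 20.0, 1 / 512.0)
    sine = 100.0 * np.sin(2 * np.pi * 50.0 * t)
    rec = _recording(np.tile(sine, (11, 1)))
    out = preprocess(rec)
    mid = slice(out.data.shape[1] // 4, 3 * out.data.shape[1] // 4)
    rms_in = np.sqrt(np.mean(sine**2))
    rms_out = max(np.sqrt(np.mean(out.data[0, mid] ** 2)), 1e-12)
    assert 20 * np.log10(rms_in / rms_out) >= 30.0


def test_highpass_removes_dc():
    rec = _recording(np.full((11, 512 * 20), 50.0))
    out = preprocess(rec)
    assert np.abs(out.data).max() < 1.0


def test_zero_phase_no_latency_shift():
    """An in-band 10 Hz Gaussian burst keeps its peak within one sample."""
    t = np.arange(0, 20.0, 1 / 512.0)
    burst = np.sin(2 * np.pi * 10 * t) * np.exp(-0.5 * ((t - 10.0) / 0.2) ** 2)
    data = np.tile(burst, (11, 1))
    data[-2:] = 0.0  # quiet mastoids
    out = preprocess(_recording(data))
    # cross-correlate input (decimated) with output to estimate the lag
    x = burst[::2]
    y = out.data[0]
    lags = np.arange(-5, 6)
    corrs = [np.dot(x, np.roll(y, lag)) for lag in lags]
    assert abs(lags[int(np.argmax(corrs))]) <= 1


def test_preprocess_requires_mastoids():
    events = pd.DataFrame({"onset_s": [1.0]})
    rec = EEGRecording(
        np.zeros((9, 512 * 4)), 512.0, ROI_FRONTOCENTRAL, events
    )
    with pytest.raises(DesignError, match="mastoid"):
        preprocess(rec)


def test_downsampling_halves_rate():
    rec = _recording(np.zeros((11, 512 * 10)))
    out = preprocess(rec)
    assert out.sfreq == 256.0
    assert out.data.shape[1] == 512 * 10 // 2


@pytest.fixture(scope="module")
def clean_epochs(words_by_condition):
    seq = generate_sequence(
        words_by_condition["mixed"], StreamSpec(condition="mixed", seed=1)
    )
    eff = default_erp_effects(noise_rms_uv=2.0, artifact_rate=0.0)
    rec = simulate_eeg(seq, eff, seed=5, ch_names=REDUCED_MONTAGE)
    return epoch(preprocess(rec))


def test_epoch_counts_and_shape(clean_epochs):
    assert clean_epochs.epochs.shape[0] == 240
    assert clean_epochs.epochs.shape[2] == 384  # 1.5 s at 256 Hz
    # window edges on the 256 Hz grid, within two sample periods
    assert clean_epochs.times_ms[0] == pytest.approx(-300.0, abs=2 * 1000 / 256)
    assert clean_epochs.times_ms[-1] == pytest.approx(1200.0, abs=2 * 1000 / 256)


def test_baseline_mean_is_zero(clean_epochs):
    mask = (clean_epochs.times_ms >= -300.0) & (clean_epochs.times_ms < 0)
    base = clean_epochs.epochs[:, :, mask].mean(axis=2)
    assert np.abs(base).max() < 1e-9


def test_event_too_close_to_edge_skipped():
    data = np.zeros((11, 512 * 4))
    rec = _recording(data, onsets=(0.05, 2.0))
    out = epoch(preprocess(rec))
    assert out.epochs.shape[0] == 1
    assert out.labels.onset_s.iloc[0] == pytest.approx(2.0)


def test_reject_threshold_adjacency():
    base = np.zeros((2, 11, 384))
    base[0, 3, 100] = 101.0
    base[1, 3, 100] = 99.0
    eps = EpochSet(
        base, 256.0, REDUCED_MONTAGE, np.linspace(-300, 1200, 384),
        pd.DataFrame({"condition": ["mixed"] * 2}),
    )
    out, excluded = reject(eps)
    assert out.rejected.tolist() == [True, False]
    assert out.reject_channel[0] == REDUCED_MONTAGE[3]
    assert not excluded  # exactly half rejected is not > 0.5


def test_reject_ignores_mastoid_channels():
    base = np.zeros((1, 11, 384))
    base[0, REDUCED_MONTAGE.index("M1"), 10] = 500.0
    eps = EpochSet(
        base, 256.0, REDUCED_MONTAGE, np.linspace(-300, 1200, 384),
        pd.DataFrame({"condition": ["mixed"]}),
    )
    out, excluded = reject(eps)
    assert not out.rejected.any() and not excluded


def test_reject_is_idempotent_and_flags_high_rate(words_by_condition):
    seq = generate_sequence(
        words_by_condition["mixed"], StreamSpec(condition="mixed", seed=2)
    )
    eff = default_erp_effects(noise_rms_uv=2.0, artifact_rate=0.6)
    rec = simulate_eeg(seq, eff, seed=6, ch_names=REDUCED_MONTAGE)
    eps = epoch(preprocess(rec))
    once, excluded = reject(eps)
    twice, excluded2 = reject(once)
    assert np.array_equal(once.rejected, twice.rejected)
    assert excluded and excluded2  # 60% artifact rate exceeds the 50% rule


def test_rejection_matches_injected_artifacts_exactly(words_by_condition):
    """Thresholding removes exactly the epochs that carry injected artifacts."""
    seq = generate_sequence(
        words_by_condition["mixed"], StreamSpec(condition="mixed", seed=3)
    )
    eff = default_erp_effects(noise_rms_uv=10.0, artifact_rate=0.2)
    rec = simulate_eeg(seq, eff, seed=8, ch_names=REDUCED_MONTAGE)
    eps = epoch(preprocess(rec))
    out, _ = reject(eps)
    assert out.rejected.tolist() == eps.labels.artifact.astype(bool).tolist()


def test_evoked_grouping_and_linearity(clean_epochs):
    groups = evoked(clean_epochs, ("half",))
    assert {g.group["half"] for g in groups} == {1, 2}
    assert all(g.n_epochs == 120 for g in groups)
    total = evoked(clean_epochs, ())[0]
    weighted = sum(g.data * g.n_epochs for g in groups) / 240
    assert np.allclose(total.data, weighted)
    with pytest.raises(DesignError):
        evoked(clean_epochs, ("nonexistent",))


def test_evoked_idempotent_on_identical_epochs():
    ep = np.random.default_rng(0).normal(size=(1, 11, 384))
    two = np.concatenate([ep, ep])
    eps = EpochSet(
        two, 256.0, REDUCED_MONTAGE, np.linspace(-300, 1200, 384),
        pd.DataFrame({"condition": ["mixed"] * 2}),
    )
    av = evoked(eps, ())[0]
    assert np.allclose(av.data, ep[0])


def test_peak_equals_exhaustive_scan(rng):
    """Vectorized check on 1,000 random traces against a brute-force oracle."""
    times = np.linspace(-300, 1200, 384)
    mask = (times >= 350) & (times <= 450)
    for _ in range(2):
        traces = rng.normal(size=(500, len(ROI_FRONTOCENTRAL) + 2, 384))
        for tr in traces[:25]:  # object construction is the slow part
            ev = EvokedAverage(tr, 256.0, REDUCED_MONTAGE, times, {}, 1)
            pk = peak(ev, N400)
            roi = tr[: len(ROI_FRONTOCENTRAL)].mean(axis=0)
            best = min(
                ((v, t) for v, t in zip(roi[mask], times[mask])),
                key=lambda vt: (vt[0], vt[1]),
            )
            assert pk.amplitude_uv == pytest.approx(best[0])
            assert pk.latency_ms == pytest.approx(best[1])
        # vectorized oracle over the full batch
        roi_all = traces[:, : len(ROI_FRONTOCENTRAL)].mean(axis=1)[:, mask]
        amps = [
            peak(EvokedAverage(tr, 256.0, REDUCED_MONTAGE, times, {}, 1), N400).amplitude_uv
            for tr in traces
        ]
        assert np.allclose(amps, roi_all.min(axis=1))


def test_peak_positive_polarity_and_tie_rule():
    times = np.linspace(-300, 1200, 384)
    flat = np.zeros((11, 384))
    ev = EvokedAverage(flat, 256.0, REDUCED_MONTAGE, times, {}, 1)
    pk = peak(ev, N400)
    assert pk.amplitude_uv == 0.0
    assert pk.latency_ms == times[(times >= 350)][0]  # earliest sample wins
    pk_pos = peak(ev, P200)
    assert pk_pos.latency_ms == times[(times >= 120)][0]
    with pytest.raises(DesignError):
        peak(ev, ErpComponentSpec("X", (2000.0, 2100.0), "negative"))
    with pytest.raises(DesignError):
        peak(
            EvokedAverage(flat[:2], 256.0, ("A", "B"), times, {}, 1), N400
        )


def test_injected_n400_recovered_via_full_chain(words_by_condition):
    seq = generate_sequence(
        words_by_condition["mixed"], StreamSpec(condition="mixed", seed=4)
    )
    eff = ErpEffectParams(
        components=(ComponentEffect("N400", -5.0, 400.0, 30.0),),
        noise_rms_uv=0.0,
        artifact_rate=0.0,
    )
    rec = simulate_eeg(seq, eff, seed=9, ch_names=REDUCED_MONTAGE)
    eps, _ = reject(epoch(preprocess(rec)))
    pk = peak(evoked(eps, ())[0], N400)
    assert pk.amplitude_uv == pytest.approx(-5.0, abs=0.1)
    assert pk.latency_ms == pytest.approx(400.0, abs=1000 / 256 + 1e-9)
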