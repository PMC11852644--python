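"""Electrode montage: 64 scalp channels (10-10 names) plus two mastoids."""

from __future__ import annotations

import numpy as np

CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)
MASTOIDS: tuple[str, str] = ("M1", "M2")
CHANNELS_66: tuple[str, ...] = CHANNELS_64 + MASTOIDS

# frontocentral region of interest where the targeted components are maximal
ROI_FRONTOCENTRAL: tuple[str, ...] = (
    "F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2"
)

REDUCED_MONTAGE: tuple[str, ...] = ROI_FRONTOCENTRAL + MASTOIDS

assert len(CHANNELS_64) == 64


def channel_gains(ch_names: tuple[str, ...], off_roi_gain: float = 0.3) -> np.ndarray:
    """Fixed scalar forward gain per channel: 1 over the frontocentral ROI,
    `off_roi_gain` elsewhere on the scalp, 0 at the mastoids."""
    gains = np.full(len(ch_names), off_roi_gain)
    for i, ch in enumerate(ch_names):
        if ch in ROI_FRONTOCENTRAL:
            gains[i] = 1.0
        elif ch in MASTOIDS:
            gains[i] = 0.0
    return gains
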