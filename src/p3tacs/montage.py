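"""Channel montage helpers.

A 32-channel 10-10 cap (BrainAmp-style layout including Pz) plus one EOG
channel.  Scalp positions come from the standard 10-05 montage shipped
with MNE and are used only to build smooth spatial profiles (parietal
P300 topography, frontal blink gradient); no head model is involved.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

#: default EEG channel labels (10-10 names, 32 channels, Pz included)
EEG_CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT9", "FC5", "FC1",
    "FC2", "FC6", "FT10", "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5",
    "CP1", "CP2", "CP6", "TP10", "P7", "P3", "Pz", "P4", "P8", "O1",
    "Oz", "O2",
]

EOG_CHANNEL = "EOG"


def channel_labels(n_channels: int = 32, include_eog: bool = True) -> list[str]:
    """First ``n_channels`` EEG labels of the 10-10 cap, optionally + EOG."""
    if not 1 <= n_channels <= len(EEG_CHANNELS_32):
        raise ValueError(f"n_channels must be in [1, {len(EEG_CHANNELS_32)}]")
    labels = list(EEG_CHANNELS_32[:n_channels])
    if include_eog:
        labels.append(EOG_CHANNEL)
    return labels


@lru_cache(maxsize=1)
def _positions() -> dict[str, np.ndarray]:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    return {k: np.asarray(v) for k, v in montage.get_positions()["ch_pos"].items()}


def great_circle_weights(labels: list[str], origin: str, floor: float = 0.0) -> np.ndarray:
    """Cosine falloff with great-circle angle from ``origin``, clipped at 0
    and raised to ``floor`` as a minimum.

    The EOG channel (not on the scalp) gets weight ``floor``.
    """
    pos = _positions()
    if origin not in pos:
        raise ValueError(f"unknown origin electrode {origin!r}")
    o = pos[origin] / np.linalg.norm(pos[origin])
    w = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab not in pos:
            w[i] = floor
            continue
        v = pos[lab] / np.linalg.norm(pos[lab])
        w[i] = max(float(np.dot(o, v)), floor)
    return w
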