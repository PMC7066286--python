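"""Online and offline preprocessing chains.

The online chain (run between the pre and during blocks to extract the
stimulation parameters) is a 0.5-20 Hz zero-phase band-pass, -3 to +4 s
epochs around stimulus onset, -50-0 ms baseline removal and blink-trial
rejection.  The offline chain additionally low-passes at 8 Hz,
re-references to the channel average and removes EOG-correlated
independent components, protecting any component whose trial-averaged
time course peaks inside the P300 window.

Filtering is forward-backward (zero phase) throughout: a causal filter
would delay the P300 peak and corrupt the latency that drives the
stimulation timing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .config import PreprocessConfig
from .io import Recording
from .montage import EOG_CHANNEL

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Stimulus-locked trials x channels x time (µV).

    ``times_ms`` is relative to stimulus onset.  Rejected trials stay in
    ``data`` but are excluded from every average via ``metadata.rejected``.
    """

    data: np.ndarray
    times_ms: np.ndarray
    channel_labels: list
    metadata: pd.DataFrame  # columns: stimulus_type, rejected, rejection_reason
    sampling_rate_hz: float
    baseline_ms: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("time axis length mismatch")
        if self.data.shape[0] != len(self.metadata):
            raise ValueError("metadata length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def retained_mask(self, stimulus_type: Optional[str] = None) -> np.ndarray:
        mask = ~self.metadata["rejected"].to_numpy()
        if stimulus_type is not None:
            mask &= (self.metadata["stimulus_type"] == stimulus_type).to_numpy()
        return mask

    def erp(self, channel: str, stimulus_type: Optional[str] = "target") -> np.ndarray:
        """Average over retained trials of one condition at one channel."""
        mask = self.retained_mask(stimulus_type)
        if not mask.any():
            raise ValueError(f"no retained {stimulus_type!r} epochs")
        return self.data[mask, self.channel_index(channel), :].mean(axis=0)

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), metadata=self.metadata.copy())


def filter_signal(
    rec: Recording,
    high_pass_hz: Optional[float] = None,
    low_pass_hz: Optional[float] = None,
    hp_order: int = 2,
    lp_order: int = 4,
) -> Recording:
    """Zero-phase Butterworth filtering of a continuous recording.

    ``sosfiltfilt`` squares the magnitude response, so the effective
    attenuation at twice a low-pass cutoff exceeds 40 dB at the default
    order while the passband stays flat to well under 1%.
    """
    nyq = rec.sampling_rate_hz / 2.0
    for cut in (high_pass_hz, low_pass_hz):
        if cut is not None and not 0 < cut < nyq:
            raise ValueError(f"cutoff {cut} Hz outside (0, Nyquist={nyq} Hz)")
    if high_pass_hz is not None and low_pass_hz is not None and high_pass_hz >= low_pass_hz:
        raise ValueError("high_pass_hz must be below low_pass_hz")
    sections = []
    if high_pass_hz is not None:
        sections.append(
            signal.butter(hp_order, high_pass_hz, btype="highpass", fs=rec.sampling_rate_hz, output="sos")
        )
    if low_pass_hz is not None:
        sections.append(
            signal.butter(lp_order, low_pass_hz, btype="lowpass", fs=rec.sampling_rate_hz, output="sos")
        )
    data = rec.data
    if sections:
        data = signal.sosfiltfilt(np.vstack(sections), data, axis=-1)
    return replace(rec, data=np.ascontiguousarray(data), events=list(rec.events))


def epoch(
    rec: Recording,
    window_ms: Tuple[float, float] = (-3000.0, 4000.0),
    baseline_ms: Optional[Tuple[float, float]] = (-50.0, 0.0),
    codes: Sequence[str] = ("standard", "target"),
) -> EpochSet:
    """Cut epochs around events of the requested codes.

    The window is closed on both ends (a (-3000, 4000) ms window at
    1000 Hz yields 7001 samples).  The per-channel mean over the
    baseline window is subtracted.  Events whose window would cross a
    record edge are dropped with a logged count.
    """
    w0, w1 = window_ms
    if w1 <= w0:
        raise ValueError("window_ms must be increasing")
    if baseline_ms is not None and not (w0 <= baseline_ms[0] <= baseline_ms[1] <= w1):
        raise ValueError("baseline window must lie within the epoch window")
    fs = rec.sampling_rate_hz
    i0 = int(round(w0 * fs / 1000.0))
    i1 = int(round(w1 * fs / 1000.0))
    times_ms = np.arange(i0, i1 + 1) * 1000.0 / fs

    matching = [(s, c) for s, c in sorted(rec.events) if c in codes]
    if not matching:
        raise ValueError(f"no events with codes {tuple(codes)} in recording")
    keep, dropped = [], 0
    for s, c in matching:
        if s + i0 < 0 or s + i1 >= rec.n_samples:
            dropped += 1
        else:
            keep.append((s, c))
    if dropped:
        logger.info("epoch: dropped %d events too close to record edges", dropped)
    if not keep:
        raise ValueError("all matching events fall outside the record")

    data = np.stack([rec.data[:, s + i0 : s + i1 + 1] for s, _ in keep])
    if baseline_ms is not None:
        bmask = (times_ms >= baseline_ms[0]) & (times_ms <= baseline_ms[1])
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    metadata = pd.DataFrame(
        {
            "event_sample": [s for s, _ in keep],
            "stimulus_type": [c for _, c in keep],
            "rejected": False,
            "rejection_reason": "",
        }
    )
    return EpochSet(
        data=data,
        times_ms=times_ms,
        channel_labels=list(rec.channel_labels),
        metadata=metadata,
        sampling_rate_hz=fs,
        baseline_ms=baseline_ms,
    )


def reject_blink_trials(
    ep: EpochSet,
    amp_threshold_uv: float = 100.0,
    uniformity_r: float = 0.8,
    window_ms: Tuple[float, float] = (0.0, 1000.0),
    exclude_channels: Sequence[str] = (EOG_CHANNEL,),
) -> EpochSet:
    """Flag trials with a blink inside the post-onset window.

    A trial is rejected iff the peak absolute amplitude in the window
    exceeds the threshold on at least one channel AND the median
    pairwise inter-channel correlation of the windowed signal exceeds
    ``uniformity_r`` — the operational reading of a "large deflection,
    uniform on all channels".  Retained trials are untouched.
    """
    tmask = (ep.times_ms >= window_ms[0]) & (ep.times_ms <= window_ms[1])
    if not tmask.any():
        raise ValueError("rejection window outside epoch")
    ch_idx = [i for i, lab in enumerate(ep.channel_labels) if lab not in exclude_channels]
    out = ep.copy()
    rejected = out.metadata["rejected"].to_numpy().copy()
    reasons = out.metadata["rejection_reason"].to_numpy(dtype=object).copy()
    for t in range(ep.n_trials):
        if rejected[t]:
            continue
        seg = ep.data[t][ch_idx][:, tmask]
        if np.abs(seg).max() <= amp_threshold_uv:
            continue
        r = np.corrcoef(seg)
        med = float(np.median(r[np.triu_indices_from(r, k=1)]))
        if med > uniformity_r:
            rejected[t] = True
            reasons[t] = "blink"
    out.metadata["rejected"] = rejected
    out.metadata["rejection_reason"] = reasons
    n = int(rejected.sum())
    if n:
        logger.info("reject_blink_trials: rejected %d/%d trials", n, ep.n_trials)
    return out


def average_reference(
    ep: EpochSet, exclude_channels: Sequence[str] = (EOG_CHANNEL,)
) -> EpochSet:
    """Subtract the instantaneous mean over scalp channels.

    Idempotent; preserves all inter-channel differences exactly.  The
    EOG channel is excluded from, and untouched by, the reference.
    """
    ch_idx = [i for i, lab in enumerate(ep.channel_labels) if lab not in exclude_channels]
    if len(ch_idx) < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = ep.copy()
    mean = out.data[:, ch_idx, :].mean(axis=1, keepdims=True)
    out.data[:, ch_idx, :] -= mean
    return out


def clean_components(
    ep: EpochSet,
    eog_label: str = EOG_CHANNEL,
    corr_threshold: float = 0.7,
    p300_window_ms: Tuple[float, float] = (300.0, 600.0),
    n_components: int = 20,
    seed: int = 0,
) -> EpochSet:
    """Remove EOG-correlated independent components from the scalp data.

    Components whose concatenated time course correlates with the EOG
    channel above ``corr_threshold`` are subtracted — unless their
    trial-averaged time course peaks inside the P300 window, which
    protects stimulus-locked P300 activity from removal.  Operates on
    retained trials only (the decomposition should not fit artifacts the
    rejection already flagged).
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning
    import warnings

    eog_idx = ep.channel_index(eog_label)
    ch_idx = [i for i in range(len(ep.channel_labels)) if i != eog_idx]
    retained = np.flatnonzero(ep.retained_mask())
    if len(retained) < 2:
        raise ValueError("too few retained trials for a decomposition")
    n_comp = min(n_components, len(ch_idx))

    X = ep.data[retained][:, ch_idx, :]  # trials x ch x time
    n_tr, n_ch, n_t = X.shape
    Xc = X.transpose(1, 0, 2).reshape(n_ch, n_tr * n_t)
    eog = ep.data[retained, eog_idx, :].reshape(-1)

    ica = FastICA(n_components=n_comp, random_state=seed, max_iter=1000, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        S = ica.fit_transform(Xc.T).T  # comps x samples
    if not np.all(np.isfinite(S)):
        raise RuntimeError("ICA decomposition failed: non-finite sources")

    eog_z = eog - eog.mean()
    remove = []
    for k in range(n_comp):
        s = S[k] - S[k].mean()
        denom = np.linalg.norm(s) * np.linalg.norm(eog_z)
        r = float(s @ eog_z / denom) if denom > 0 else 0.0
        if abs(r) <= corr_threshold:
            continue
        # P300 guard: stimulus-locked average peaking at 300-600 ms
        avg = np.abs(S[k].reshape(n_tr, n_t).mean(axis=0))
        peak_ms = float(ep.times_ms[int(np.argmax(avg))])
        if p300_window_ms[0] <= peak_ms <= p300_window_ms[1]:
            logger.info("clean_components: component %d protected (peak %.0f ms)", k, peak_ms)
            continue
        remove.append(k)

    out = ep.copy()
    if remove:
        A = ica.mixing_  # n_ch x n_comp
        artifact = (A[:, remove] @ S[remove]).reshape(n_ch, n_tr, n_t).transpose(1, 0, 2)
        cleaned = X - artifact
        for j, tr in enumerate(retained):
            out.data[tr, ch_idx, :] = cleaned[j]
    logger.info("clean_components: removed %d/%d components", len(remove), n_comp)
    return out


def run_chain(rec: Recording, cfg: PreprocessConfig, seed: int = 0) -> EpochSet:
    """Apply a full preprocessing chain (filter, epoch, reject, reference,
    component cleanup) as configured."""
    filtered = filter_signal(rec, cfg.high_pass_hz, cfg.low_pass_hz)
    ep = epoch(filtered, cfg.epoch_window_ms, cfg.baseline_ms, codes=cfg.epoch_codes)
    if cfg.reject_blinks:
        ep = reject_blink_trials(
            ep,
            amp_threshold_uv=cfg.reject_threshold_uv,
            uniformity_r=cfg.reject_uniformity_r,
            window_ms=cfg.reject_window_ms,
        )
    if cfg.average_reference:
        ep = average_reference(ep)
    if cfg.ica_cleanup:
        ep = clean_components(ep, corr_threshold=cfg.ica_corr_threshold, seed=seed)
    return ep
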