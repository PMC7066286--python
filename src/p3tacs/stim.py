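"""Individualized stimulation parameters and phase-locked scheduling.

Phase convention: the stimulation current is sin(2*pi*f*t) with t = 0 at
a rising zero-crossing (the start of an oscillatory cycle, where the
stimulator emits its trigger).  Peaks therefore fall at T/4 + k*T with
T = 1000/f ms.  The wait inserted between a zero-crossing trigger and
stimulus onset is

    wait = (T/4 - P3Lat) mod T,

the shortest non-negative delay that puts the P300 peak (P3Lat after
stimulus onset) on a stimulation peak, i.e. at phase pi/2.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .spectral import ERSPMap, ersp_window_max


@dataclass
class StimParams:
    """The individualized protocol for one subject."""

    p3_latency_ms: float
    stim_freq_hz: float
    wait_ms: float
    amplitude_ma: float = 1.0
    ramp_s: float = 10.0
    duration_s: float = 1200.0
    mode: str = "stim"

    def __post_init__(self) -> None:
        if self.stim_freq_hz <= 0:
            raise ValueError("stim_freq_hz must be > 0")
        if not 0 <= self.wait_ms < self.period_ms:
            raise ValueError(
                f"wait_ms must be in [0, period={self.period_ms:.1f} ms)"
            )
        if self.mode not in ("stim", "sham"):
            raise ValueError("mode must be 'stim' or 'sham'")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.stim_freq_hz


class LatencyEstimate(NamedTuple):
    latency_ms: float
    amplitude_uv: float
    at_boundary: bool


@dataclass
class PhaseMiss:
    """Online-vs-offline stimulation phase at P300 latency.

    ``miss_rad`` is the circular distance in [0, pi]; ``signed_rad`` the
    wrapped subtraction (offline - online) in (-pi, pi].
    """

    phase_online_rad: float
    phase_offline_rad: float
    miss_rad: float
    signed_rad: float


def _window_argmax(y: np.ndarray, times_ms: np.ndarray, window_ms: Tuple[float, float]):
    """Closed-window maximum; ties resolve to the earliest time."""
    w0, w1 = window_ms
    mask = (times_ms >= w0) & (times_ms <= w1)
    if not mask.any():
        raise ValueError(f"window {window_ms} outside support")
    yw, tw = y[mask], times_ms[mask]
    i = int(np.argmax(yw))  # argmax returns the first (earliest) maximum
    return float(tw[i]), float(yw[i]), i == 0 or i == len(yw) - 1


def estimate_p300_latency(
    erp: np.ndarray,
    times_ms: np.ndarray,
    window_ms: Tuple[float, float] = (300.0, 600.0),
) -> LatencyEstimate:
    """Time of the maximum of the averaged Pz ERP within the closed
    window (default 300-600 ms); boundary maxima are flagged."""
    t, v, boundary = _window_argmax(np.asarray(erp, float), np.asarray(times_ms, float), window_ms)
    return LatencyEstimate(latency_ms=t, amplitude_uv=v, at_boundary=boundary)


def estimate_stim_frequency(m: ERSPMap, p3_latency_ms: float, time_halfwidth_ms: float = 150.0) -> float:
    """Frequency at the ERSP maximum within +-150 ms of the P300 latency,
    searched over the full frequency axis."""
    return ersp_window_max(m, center_time_ms=p3_latency_ms, time_halfwidth_ms=time_halfwidth_ms).freq_hz


def compute_wait(p3_latency_ms: float, stim_freq_hz: float) -> float:
    """Shortest wait (ms, in [0, T)) from a rising zero-crossing trigger
    to stimulus onset such that onset + P3Lat falls on a stimulation peak."""
    if stim_freq_hz <= 0:
        raise ValueError("stim_freq_hz must be > 0")
    period = 1000.0 / stim_freq_hz
    return float((period / 4.0 - p3_latency_ms) % period)


def stimulation_phase_at(latency_ms: float, freq_hz: float, wait_ms: float) -> float:
    """Phase (rad, in [0, 2*pi)) of the stimulation sinusoid at
    ``latency_ms`` after stimulus onset, given the pre-onset wait."""
    if freq_hz <= 0:
        raise ValueError("freq_hz must be > 0")
    return float((2.0 * np.pi * freq_hz * (wait_ms + latency_ms) / 1000.0) % (2.0 * np.pi))


def phase_miss(
    online: StimParams, offline_latency_ms: float, offline_freq_hz: float
) -> PhaseMiss:
    """Circular distance between the stimulation phase at the online and
    the offline P300 latency estimates (both under the delivered wait)."""
    ph_on = stimulation_phase_at(online.p3_latency_ms, online.stim_freq_hz, online.wait_ms)
    ph_off = stimulation_phase_at(offline_latency_ms, offline_freq_hz, online.wait_ms)
    delta = ph_off - ph_on
    signed = float((delta + np.pi) % (2.0 * np.pi) - np.pi)
    return PhaseMiss(
        phase_online_rad=ph_on,
        phase_offline_rad=ph_off,
        miss_rad=abs(signed),
        signed_rad=signed,
    )


def params_from_pre_block(
    ep,
    tfr_cfg=None,
    channel: str = "Pz",
    latency_window_ms: Tuple[float, float] = (300.0, 600.0),
    **stim_kwargs,
) -> StimParams:
    """Online analysis in one step: P300 latency from the retained-target
    ERP at Pz, stimulation frequency from the ERSP window maximum, wait
    from the phase constraint."""
    from .config import TFRConfig
    from .spectral import ersp_from_config

    if tfr_cfg is None:
        tfr_cfg = TFRConfig()
    lat = estimate_p300_latency(ep.erp(channel), ep.times_ms, latency_window_ms)
    m = ersp_from_config(ep, tfr_cfg, channel=channel)
    freq = estimate_stim_frequency(m, lat.latency_ms)
    return StimParams(
        p3_latency_ms=lat.latency_ms,
        stim_freq_hz=freq,
        wait_ms=compute_wait(lat.latency_ms, freq),
        **stim_kwargs,
    )


def schedule_during_block(
    params: StimParams, cfg: SimConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """Simulate the during-block presentation loop.

    After each trial (1 s stimulus + jittered ISI) the presentation
    waits for the next rising zero-crossing trigger of the stimulation,
    inserts ``wait_ms``, then presents.  Onsets are quantized to the
    sampling grid, so every stimulus onset puts the P300 latency on a
    stimulation peak to within one sample.  Trials are presented while
    they still fit inside ``duration_s``.
    """
    if params.duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = cfg.sampling_rate_hz
    period = params.period_ms
    duration_ms = params.duration_s * 1000.0
    rows = []
    t = 0.0
    trial = 0
    while True:
        zc = np.ceil(t / period - 1e-9) * period
        onset = zc + params.wait_ms
        onset = round(onset * fs / 1000.0) / fs * 1000.0  # sample grid
        if onset + cfg.stim_duration_ms > duration_ms:
            break
        isi = rng.uniform(*cfg.isi_range_ms)
        stim_type = "target" if rng.random() < cfg.p_target else "standard"
        rows.append(
            {
                "trial": trial,
                "onset_ms": onset,
                "stimulus_type": stim_type,
                "isi_ms": isi,
                "zero_cross_ms": zc,
            }
        )
        t = onset + cfg.stim_duration_ms + isi
        trial += 1
    return pd.DataFrame(rows, columns=["trial", "onset_ms", "stimulus_type", "isi_ms", "zero_cross_ms"])


def generate_waveform(params: StimParams, rate_hz: float) -> np.ndarray:
    """Stimulator output in mA at ``rate_hz``.

    ``stim`` mode: a DC-free sinusoid with linear ramps over the first
    and last ``ramp_s`` seconds and peak-to-peak ``amplitude_ma`` in the
    plateau.  ``sham`` mode: ramp in over ``ramp_s``, immediately ramp
    out again, zero for the rest of the block.
    """
    if rate_hz < 4 * params.stim_freq_hz:
        raise ValueError("rate_hz must be at least 4x the stimulation frequency")
    n = int(round(params.duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    ramp = params.ramp_s
    if params.mode == "stim":
        env = np.minimum(1.0, np.minimum(t / ramp, (params.duration_s - t) / ramp))
        env = np.clip(env, 0.0, 1.0)
    else:
        env = np.where(
            t < ramp, t / ramp, np.where(t < 2 * ramp, 2.0 - t / ramp, 0.0)
        )
    return (params.amplitude_ma / 2.0) * env * np.sin(2.0 * np.pi * params.stim_freq_hz * t)
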