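"""Synthetic visual-oddball EEG and behavior.

Target trials carry a P300 modelled as an event-related oscillation: a
Gaussian-windowed delta/theta cosine burst whose maximum (the burst
amplitude) falls exactly at ``onset + ero_latency``.  The burst is
maximal at Pz and falls off over the scalp with the cosine of the
great-circle angle from Pz.  Background activity is pink (1/f power)
noise, independent across channels.  A stereotyped biphasic blink
template, largest frontally but with an identical waveform on every
channel, contaminates a configurable fraction of trials within the
first second after stimulus onset.

A behavior stream accompanies the schedule: targets are answered with
probability ``1 - p_omission`` at a truncated-normal reaction time;
standards draw a false alarm with probability ``p_commission``.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import SimConfig
from .io import Recording
from .montage import channel_labels, great_circle_weights

#: lead-in before the first stimulus so a -3 s epoch edge survives (ms)
PRE_ROLL_MS = 4000.0


def generate_trial_sequence(
    n_trials: int,
    p_target: float,
    seed: Optional[int] = None,
    stim_duration_ms: float = 1000.0,
    isi_range_ms: tuple = (1000.0, 2000.0),
) -> pd.DataFrame:
    """Bernoulli standard/target schedule with jittered inter-stimulus gaps.

    Returns a DataFrame with columns ``trial``, ``onset_ms`` (task time,
    first onset at 0), ``stimulus_type`` and ``isi_ms`` (the gap that
    follows the trial's 1 s stimulus).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= p_target <= 1.0:
        raise ValueError(f"p_target must be in [0, 1], got {p_target}")
    lo, hi = isi_range_ms
    if lo > hi:
        raise ValueError("isi_range_ms low must be <= high")
    rng = np.random.default_rng(seed)
    types = np.where(rng.random(n_trials) < p_target, "target", "standard")
    isi = rng.uniform(lo, hi, n_trials)
    onsets = np.concatenate([[0.0], np.cumsum(stim_duration_ms + isi)[:-1]])
    return pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "onset_ms": onsets,
            "stimulus_type": types,
            "isi_ms": isi,
        }
    )


def schedule_from_config(cfg: SimConfig, seed: Optional[int] = None) -> pd.DataFrame:
    return generate_trial_sequence(
        cfg.n_trials,
        cfg.p_target,
        seed=cfg.seed if seed is None else seed,
        stim_duration_ms=cfg.stim_duration_ms,
        isi_range_ms=cfg.isi_range_ms,
    )


def generate_behavior(
    schedule: pd.DataFrame, cfg: SimConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """Per-trial response flags and reaction times.

    Target RTs are truncated-normal(rt_mean, rt_sd) on (0, stimulus +
    that trial's ISI]; commissions get the same RT model.  Columns:
    ``trial``, ``stimulus_type``, ``responded``, ``rt_ms`` (NaN when no
    response).
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = len(schedule)
    is_target = (schedule["stimulus_type"] == "target").to_numpy()
    responded = np.where(
        is_target,
        rng.random(n) >= cfg.p_omission,
        rng.random(n) < cfg.p_commission,
    )
    upper = cfg.stim_duration_ms + schedule["isi_ms"].to_numpy()
    a = (0.0 - cfg.rt_mean_ms) / cfg.rt_sd_ms
    b = (upper - cfg.rt_mean_ms) / cfg.rt_sd_ms
    rt = sps.truncnorm.rvs(
        a, b, loc=cfg.rt_mean_ms, scale=cfg.rt_sd_ms, size=n, random_state=rng
    )
    if cfg.rt_coupled_to_ero:
        # optional latency coupling: RT rides on the P300 peak latency
        jitter = rng.normal(0.0, cfg.rt_sd_ms, n)
        rt = np.clip(cfg.ero_latency_ms + cfg.rt_lag_ms + jitter, 1.0, upper)
    rt = np.where(responded, rt, np.nan)
    return pd.DataFrame(
        {
            "trial": schedule["trial"].to_numpy(),
            "stimulus_type": schedule["stimulus_type"].to_numpy(),
            "responded": responded,
            "rt_ms": rt,
        }
    )


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, fs: float, rms: float) -> np.ndarray:
    """1/f-power noise, flat below 0.1 Hz, normalized to ``rms`` per channel."""
    import scipy.fft as sfft

    # synthesize on an FFT-friendly length, keep the first n_samples
    n_fft = sfft.next_fast_len(n_samples)
    out = np.empty((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 0.1))
    for ch in range(n_channels):
        spec = shape * (
            rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
        )
        spec[0] = 0.0
        x = sfft.irfft(spec, n=n_fft)[:n_samples]
        sd = x.std()
        out[ch] = x * (rms / sd) if sd > 0 else x
    return out


def _blink_template(fs: float) -> np.ndarray:
    """Stereotyped ~400 ms biphasic wave: two opposed half-Gaussians,
    unit peak amplitude."""
    t = np.arange(int(round(0.4 * fs))) * 1000.0 / fs  # ms
    tpl = np.exp(-0.5 * ((t - 110.0) / 45.0) ** 2) - 0.55 * np.exp(
        -0.5 * ((t - 260.0) / 65.0) ** 2
    )
    return tpl / np.abs(tpl).max()


def synthesize_eeg(
    schedule: pd.DataFrame,
    cfg: SimConfig,
    seed: Optional[int] = None,
    behavior: Optional[pd.DataFrame] = None,
) -> Recording:
    """Continuous synthetic recording for a trial schedule.

    The record spans a 4 s lead-in plus the task plus a 4 s + max-ISI
    tail.  Stimulus, and (when ``behavior`` is given) response, markers
    are written as events.  The P300 burst peak equals ``ero_amp_uv`` at
    Pz exactly ``ero_latency_ms`` after each target onset.
    """
    fs = cfg.sampling_rate_hz
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labels = channel_labels(cfg.n_channels, include_eog=True)
    onsets_ms = schedule["onset_ms"].to_numpy() + PRE_ROLL_MS
    last = onsets_ms[-1] + cfg.stim_duration_ms + cfg.isi_range_ms[1] + 4000.0
    n_samples = int(round(last * fs / 1000.0))
    n_ch = len(labels)

    data = _pink_noise(rng, n_ch, n_samples, fs, cfg.noise_rms_uv)
    if cfg.noise_rms_uv == 0:
        data[:] = 0.0

    # parietal spatial profile of the burst; EOG carries none of it
    burst_w = great_circle_weights(labels, "Pz", floor=0.0)
    burst_w[labels.index("EOG")] = 0.0

    is_target = (schedule["stimulus_type"] == "target").to_numpy()
    sigma = cfg.effective_ero_width_ms
    half = int(round(4 * sigma * fs / 1000.0))
    rel = np.arange(-half, half + 1)
    t_rel_ms = rel * 1000.0 / fs
    burst = (
        cfg.ero_amp_uv
        * np.exp(-0.5 * (t_rel_ms / sigma) ** 2)
        * np.cos(2 * np.pi * cfg.ero_freq_hz * t_rel_ms / 1000.0)
    )
    for onset in onsets_ms[is_target]:
        peak = int(round((onset + cfg.ero_latency_ms) * fs / 1000.0))
        lo, hi = peak - half, peak + half + 1
        s0, s1 = max(lo, 0), min(hi, n_samples)
        data[:, s0:s1] += burst_w[:, None] * burst[None, s0 - lo : s1 - lo]

    # blinks: identical waveform everywhere, frontal amplitude gradient
    if cfg.blink_prob > 0 and cfg.blink_amp_uv > 0:
        tpl = _blink_template(fs) * cfg.blink_amp_uv
        blink_w = great_circle_weights(labels, "Fpz", floor=0.12)
        blink_w[labels.index("EOG")] = 1.2
        blink_trials = rng.random(len(schedule)) < cfg.blink_prob
        starts = rng.uniform(0.0, 1000.0 - 400.0, len(schedule))
        for onset, start in zip(onsets_ms[blink_trials], starts[blink_trials]):
            s0 = int(round((onset + start) * fs / 1000.0))
            s1 = min(s0 + len(tpl), n_samples)
            data[:, s0:s1] += blink_w[:, None] * tpl[None, : s1 - s0]

    events = [
        (int(round(o * fs / 1000.0)), str(t))
        for o, t in zip(onsets_ms, schedule["stimulus_type"])
    ]
    if behavior is not None:
        resp = behavior[behavior["responded"]]
        for trial, rt in zip(resp["trial"], resp["rt_ms"]):
            onset = onsets_ms[schedule["trial"].to_numpy() == trial][0]
            events.append((int(round((onset + rt) * fs / 1000.0)), "response"))
    events.sort()
    return Recording(
        data=data,
        sampling_rate_hz=fs,
        channel_labels=labels,
        events=events,
        reference="recording",
    )


def simulate_session(cfg: SimConfig, seed: Optional[int] = None):
    """Schedule + behavior + EEG in one call (single-block convenience).

    Returns ``(schedule, behavior, recording)``; the three stages use
    independent child seeds spawned from ``seed``.
    """
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    s_sched, s_beh, s_eeg = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(3)]
    schedule = schedule_from_config(cfg, seed=s_sched)
    behavior = generate_behavior(schedule, cfg, seed=s_beh)
    rec = synthesize_eeg(schedule, cfg, seed=s_eeg, behavior=behavior)
    return schedule, behavior, rec
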