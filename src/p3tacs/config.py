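"""Configuration objects for simulation, preprocessing and time-frequency analysis.

All durations are milliseconds, amplitudes microvolts and frequencies Hz
unless a suffix says otherwise.  Stimulus onset defines 0 ms in every
stimulus-locked quantity.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np


@dataclass
class SimConfig:
    """Parameters of the synthetic visual-oddball session.

    Defaults reproduce the study conditions: 400 trials per EEG block
    (75% standards / 25% targets), 1000 ms stimuli with a 1000-2000 ms
    jittered inter-stimulus interval, a 32-channel 10-10 montage (plus
    one EOG channel) sampled at 1000 Hz, and a parietal P300 modelled as
    a delta/theta burst peaking 440 ms after target onset at Pz.
    """

    n_trials: int = 400
    p_target: float = 0.25
    stim_duration_ms: float = 1000.0
    isi_range_ms: Tuple[float, float] = (1000.0, 2000.0)
    sampling_rate_hz: float = 1000.0
    n_channels: int = 32
    ero_freq_hz: float = 3.0
    ero_latency_ms: float = 440.0
    ero_amp_uv: float = 10.0
    #: burst-envelope SD; None scales with the carrier (one period,
    #: clipped to 150-500 ms) so the ERO always spans ~2-3 cycles
    ero_width_ms: Optional[float] = None
    noise_rms_uv: float = 12.0
    blink_prob: float = 0.10
    blink_amp_uv: float = 300.0
    rt_mean_ms: float = 450.0
    rt_sd_ms: float = 100.0
    p_omission: float = 0.05
    p_commission: float = 0.002
    rt_coupled_to_ero: bool = False
    rt_lag_ms: float = 50.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("p_target", "blink_prob", "p_omission", "p_commission"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.isi_range_ms
        if lo > hi:
            raise ValueError(f"isi_range_ms low must be <= high, got {self.isi_range_ms}")
        if not 0.0 <= self.ero_latency_ms <= self.stim_duration_ms:
            raise ValueError(
                "ero_latency_ms must lie within [0, stim_duration_ms], "
                f"got {self.ero_latency_ms}"
            )
        for name in ("ero_amp_uv", "noise_rms_uv", "blink_amp_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.ero_width_ms is not None and self.ero_width_ms <= 0:
            raise ValueError("ero_width_ms must be > 0")

    @property
    def effective_ero_width_ms(self) -> float:
        """Burst-envelope SD: explicit value, or one carrier period
        clipped to 150-500 ms (a constant-cycle ERO burst)."""
        if self.ero_width_ms is not None:
            return self.ero_width_ms
        return float(np.clip(1000.0 / self.ero_freq_hz, 150.0, 500.0))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "isi_range_ms" in d:
            d["isi_range_ms"] = tuple(d["isi_range_ms"])
        return cls(**d)


@dataclass
class PreprocessConfig:
    """One preprocessing chain (filters, epoching, rejection, reference, ICA)."""

    high_pass_hz: Optional[float] = 0.5
    low_pass_hz: Optional[float] = 20.0
    epoch_window_ms: Tuple[float, float] = (-3000.0, 4000.0)
    epoch_codes: Tuple[str, ...] = ("target",)
    baseline_ms: Tuple[float, float] = (-50.0, 0.0)
    reject_blinks: bool = True
    reject_threshold_uv: float = 100.0
    reject_uniformity_r: float = 0.8
    reject_window_ms: Tuple[float, float] = (0.0, 1000.0)
    average_reference: bool = False
    ica_cleanup: bool = False
    ica_corr_threshold: float = 0.7


def preprocess_preset(name: str) -> PreprocessConfig:
    """Named chains: ``online`` (between pre and during blocks) and
    ``offline`` (post-hoc, with average reference and component cleanup)."""
    if name == "online":
        return PreprocessConfig()
    if name == "offline":
        return PreprocessConfig(
            high_pass_hz=0.5,
            low_pass_hz=8.0,
            average_reference=True,
            ica_cleanup=True,
        )
    raise ValueError(f"unknown preprocess preset {name!r}; use 'online' or 'offline'")


@dataclass
class TFRConfig:
    """Morlet time-frequency decomposition settings."""

    freq_range_hz: Tuple[float, float] = (1.5, 20.0)
    freq_step_hz: float = 0.5
    n_cycles: float = 3.0
    time_step_ms: float = 24.0
    baseline_ms: Tuple[float, float] = (-3000.0, 0.0)


def tfr_preset(name: str) -> TFRConfig:
    """``online`` grid (1.5-20 Hz / 0.5 Hz / 24 ms) or the finer
    ``offline`` grid (to 10 Hz / 0.25 Hz / 14 ms)."""
    if name == "online":
        return TFRConfig()
    if name == "offline":
        return TFRConfig(
            freq_range_hz=(0.8, 10.0), freq_step_hz=0.25, time_step_ms=14.0
        )
    raise ValueError(f"unknown tfr preset {name!r}; use 'online' or 'offline'")


@dataclass
class StudyConfig:
    """Two-by-two (group x time) synthetic study layout.

    ``effect_amp_multiplier`` scales the post-condition target-burst
    amplitude in the stimulation group; the sham group multiplier is 1.
    Per-subject burst frequency and latency are drawn from truncated
    normal distributions matching the published stimulation-frequency
    spread (mean 3.0 Hz, SD 1.24 Hz) and the pilot latency (440 ms).
    """

    n_per_group: int = 9
    sim: SimConfig = field(default_factory=SimConfig)
    effect_amp_multiplier: float = 1.3
    sham_amp_multiplier: float = 1.0
    freq_mean_hz: float = 3.0
    freq_sd_hz: float = 1.24
    freq_bounds_hz: Tuple[float, float] = (1.5, 7.0)
    latency_mean_ms: float = 440.0
    latency_sd_ms: float = 50.0
    latency_bounds_ms: Tuple[float, float] = (350.0, 550.0)
    during_duration_s: float = 1200.0
    latency_window_ms: Tuple[float, float] = (300.0, 600.0)
    ica_cleanup: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.effect_amp_multiplier <= 0 or self.sham_amp_multiplier <= 0:
            raise ValueError("amplitude multipliers must be > 0")
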