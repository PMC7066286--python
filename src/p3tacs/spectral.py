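"""Morlet-wavelet event-related spectral perturbation (ERSP).

The per-trial complex Morlet transform (a constant 3 cycles per
analysis wavelet, not frequency-scaled) is converted to power, averaged
over retained trials of one condition, and expressed in dB relative to
the mean pre-stimulus baseline power per frequency:

    ERSP(f, t) = 10 log10( <|W x|^2>(f, t) / <|W x|^2>(f, baseline) )

Cells whose wavelet support sticks out of the epoch are marked invalid
(NaN) and excluded from baseline means and window maxima.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .config import TFRConfig
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

#: Gaussian support of the Morlet envelope, in standard deviations each side
_WAVELET_SD_SUPPORT = 5.0


def frequency_grid(freq_range_hz: Tuple[float, float], freq_step_hz: float) -> np.ndarray:
    """Analysis frequencies: integer multiples of the resolution covering
    the requested range (so e.g. 2.25 Hz is on a 0.25 Hz grid)."""
    lo, hi = freq_range_hz
    if lo <= 0 or hi <= lo:
        raise ValueError("freq_range_hz must satisfy 0 < low < high")
    k0 = int(np.ceil(lo / freq_step_hz - 1e-9))
    k1 = int(np.floor(hi / freq_step_hz + 1e-9))
    if k1 < k0:
        raise ValueError("empty frequency grid")
    return np.arange(k0, k1 + 1) * freq_step_hz


@dataclass
class ERSPMap:
    """Frequencies x times baseline-normalized power map (dB)."""

    values: np.ndarray  # freqs x times, NaN where invalid
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    baseline_ms: Tuple[float, float]
    n_cycles: float
    channel: str

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.freqs_hz), len(self.times_ms)):
            raise ValueError("ERSP values shape must be freqs x times")
        if np.any(np.diff(self.freqs_hz) <= 0) or np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("axes must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.freqs_hz, columns=self.times_ms)


@dataclass
class TFWindowMax:
    """Location and value of the maximum inside a time-frequency window."""

    value_db: float
    time_ms: float
    freq_hz: float
    window_time_ms: Tuple[float, float]
    window_freq_hz: Tuple[float, float]
    clipped: bool = False


def wavelet_ersp(
    ep: EpochSet,
    channel: str = "Pz",
    freq_range_hz: Tuple[float, float] = (1.5, 20.0),
    freq_step_hz: float = 0.5,
    n_cycles: float = 3.0,
    time_step_ms: float = 24.0,
    baseline_ms: Tuple[float, float] = (-3000.0, 0.0),
    stimulus_type: Optional[str] = "target",
) -> ERSPMap:
    """Trial-averaged Morlet ERSP at one channel.

    The output time axis is the epoch axis decimated to the requested
    resolution; baseline power is the per-frequency mean over valid
    baseline cells.
    """
    from mne.time_frequency import tfr_array_morlet

    fs = ep.sampling_rate_hz
    freqs = frequency_grid(freq_range_hz, freq_step_hz)
    if freqs[-1] >= fs / 2:
        raise ValueError(f"frequency grid exceeds Nyquist ({fs / 2} Hz)")
    if not (ep.times_ms[0] <= baseline_ms[0] and baseline_ms[1] <= ep.times_ms[-1]):
        raise ValueError("baseline window outside epoch")
    # longest wavelet must fit in the epoch
    min_f = freqs[0]
    support_ms = 2 * _WAVELET_SD_SUPPORT * n_cycles / (2 * np.pi * min_f) * 1000.0
    if support_ms > ep.times_ms[-1] - ep.times_ms[0]:
        raise ValueError(
            f"epoch too short for {min_f} Hz wavelet ({support_ms:.0f} ms support)"
        )

    decim = max(1, int(round(time_step_ms * fs / 1000.0)))
    actual_step = decim * 1000.0 / fs
    if abs(actual_step - time_step_ms) > 1e-6:
        logger.info("wavelet_ersp: time step snapped to %.3f ms", actual_step)

    mask = ep.retained_mask(stimulus_type)
    if not mask.any():
        raise ValueError(f"no retained {stimulus_type!r} epochs")
    ch = ep.channel_index(channel)
    data = ep.data[mask, ch, :][:, None, :]  # trials x 1 x time, µV

    power = tfr_array_morlet(
        data,
        sfreq=fs,
        freqs=freqs,
        n_cycles=n_cycles,
        output="power",
        decim=decim,
        zero_mean=True,
        verbose="error",
    )  # trials x 1 x freqs x times
    mean_power = power[:, 0].mean(axis=0)  # freqs x times
    times = ep.times_ms[::decim]

    # invalidate cells whose wavelet support crosses the epoch edges
    half_ms = _WAVELET_SD_SUPPORT * n_cycles / (2 * np.pi * freqs) * 1000.0
    valid = (times[None, :] >= ep.times_ms[0] + half_ms[:, None]) & (
        times[None, :] <= ep.times_ms[-1] - half_ms[:, None]
    )

    bl_cells = (times >= baseline_ms[0]) & (times <= baseline_ms[1])
    bl = np.where(valid[:, bl_cells], mean_power[:, bl_cells], np.nan)
    if np.all(np.isnan(bl)):
        raise ValueError("no valid baseline cells; baseline window too close to edge")
    bl_mean = np.nanmean(bl, axis=1, keepdims=True)

    with np.errstate(divide="ignore", invalid="ignore"):
        values = 10.0 * np.log10(mean_power / bl_mean)
    values[~valid] = np.nan
    return ERSPMap(
        values=values,
        freqs_hz=freqs,
        times_ms=times,
        baseline_ms=tuple(baseline_ms),
        n_cycles=n_cycles,
        channel=channel,
    )


def ersp_from_config(ep: EpochSet, cfg: TFRConfig, channel: str = "Pz", **kw) -> ERSPMap:
    return wavelet_ersp(
        ep,
        channel=channel,
        freq_range_hz=cfg.freq_range_hz,
        freq_step_hz=cfg.freq_step_hz,
        n_cycles=cfg.n_cycles,
        time_step_ms=cfg.time_step_ms,
        baseline_ms=cfg.baseline_ms,
        **kw,
    )


def ersp_window_max(
    m: ERSPMap,
    center_time_ms: float,
    time_halfwidth_ms: float = 150.0,
    center_freq_hz: Optional[float] = None,
    freq_halfwidth_hz: Optional[float] = None,
) -> TFWindowMax:
    """Global maximum over a time(+frequency) window of the map.

    With ``center_freq_hz=None`` the whole frequency axis is searched
    (the online stimulation-frequency case).  Ties break toward the
    earliest time, then the lowest frequency.  Windows reaching past the
    map are clipped with a flag.
    """
    t0, t1 = center_time_ms - time_halfwidth_ms, center_time_ms + time_halfwidth_ms
    clipped = t0 < m.times_ms[0] or t1 > m.times_ms[-1]
    tmask = (m.times_ms >= t0) & (m.times_ms <= t1)
    if center_freq_hz is None:
        fmask = np.ones(len(m.freqs_hz), dtype=bool)
    else:
        if freq_halfwidth_hz is None:
            raise ValueError("freq_halfwidth_hz required with center_freq_hz")
        f0, f1 = center_freq_hz - freq_halfwidth_hz, center_freq_hz + freq_halfwidth_hz
        clipped = clipped or f0 < m.freqs_hz[0] or f1 > m.freqs_hz[-1]
        fmask = (m.freqs_hz >= f0) & (m.freqs_hz <= f1)
    if not tmask.any() or not fmask.any():
        raise ValueError("window does not intersect the map")
    if clipped:
        logger.info("ersp_window_max: window clipped to map bounds")

    sub = m.values[np.ix_(fmask, tmask)]
    if np.all(np.isnan(sub)):
        raise ValueError("window contains no valid cells")
    best = np.nanmax(sub)
    fi, ti = np.nonzero(sub == best)
    # earliest time first, then lowest frequency
    order = np.lexsort((fi, ti))
    fi, ti = fi[order[0]], ti[order[0]]
    return TFWindowMax(
        value_db=float(best),
        time_ms=float(m.times_ms[tmask][ti]),
        freq_hz=float(m.freqs_hz[fmask][fi]),
        window_time_ms=(t0, t1),
        window_freq_hz=(
            (m.freqs_hz[fmask][0], m.freqs_hz[fmask][-1])
            if center_freq_hz is None
            else (f0, f1)
        ),
        clipped=clipped,
    )
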