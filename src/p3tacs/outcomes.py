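"""Per-subject, per-condition outcome variables.

P300 amplitude is the maximum of the retained-target average ERP at Pz
in the 300-600 ms window; its time is the P300 latency.  Reaction-time
mean (RT-M) and variability (RT-V, the n-1 standard deviation) are
computed over responded targets with RT inside the closed 200-1000 ms
validity window.  Omissions are targets without a button press (they
leave the RT analysis but stay in the ERP averages); commissions are
button presses to standards.
"""
from __future__ import annotations

import logging
from typing import NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .stim import _window_argmax

logger = logging.getLogger(__name__)

OUTCOME_COLUMNS = [
    "subject",
    "group",
    "condition",
    "p3_amp_uv",
    "p3_lat_ms",
    "rt_mean_ms",
    "rt_sd_ms",
    "n_valid_rt",
    "omissions",
    "commissions",
    "ersp_max_db",
    "n_trials_erp",
    "n_targets",
]


class P300Metrics(NamedTuple):
    amp_uv: float
    lat_ms: float
    n_trials: int


class RTMetrics(NamedTuple):
    rt_mean_ms: float
    rt_sd_ms: float
    n_valid: int


def p300_metrics(
    ep: EpochSet,
    channel: str = "Pz",
    window_ms: Tuple[float, float] = (300.0, 600.0),
    stimulus_type: str = "target",
) -> P300Metrics:
    """Amplitude (µV) and latency (ms) of the window maximum of the
    retained-trial average ERP; ties resolve to the earliest time."""
    erp = ep.erp(channel, stimulus_type)
    t, v, _ = _window_argmax(erp, ep.times_ms, window_ms)
    return P300Metrics(amp_uv=v, lat_ms=t, n_trials=int(ep.retained_mask(stimulus_type).sum()))


def reaction_time_metrics(
    behavior: pd.DataFrame, valid_range_ms: Tuple[float, float] = (200.0, 1000.0)
) -> RTMetrics:
    """Mean and sample SD of valid target reaction times.

    With fewer than two valid RTs the SD (and with none, the mean) is
    NaN and a warning is logged.
    """
    targets = behavior[behavior["stimulus_type"] == "target"]
    rt = targets.loc[targets["responded"], "rt_ms"].to_numpy(float)
    valid = rt[(rt >= valid_range_ms[0]) & (rt <= valid_range_ms[1])]
    n = len(valid)
    if n == 0:
        logger.warning("reaction_time_metrics: no valid RTs")
        return RTMetrics(np.nan, np.nan, 0)
    mean = float(valid.mean())
    if n < 2:
        logger.warning("reaction_time_metrics: single valid RT, SD undefined")
        return RTMetrics(mean, np.nan, n)
    return RTMetrics(mean, float(valid.std(ddof=1)), n)


def error_counts(schedule: pd.DataFrame, behavior: pd.DataFrame) -> Tuple[int, int]:
    """(omissions, commissions) from an aligned schedule/behavior pair."""
    merged = schedule[["trial", "stimulus_type"]].merge(
        behavior[["trial", "responded"]], on="trial", how="left", validate="1:1"
    )
    if merged["responded"].isna().any():
        raise ValueError("behavior table not aligned to schedule")
    is_target = merged["stimulus_type"] == "target"
    omissions = int((is_target & ~merged["responded"]).sum())
    commissions = int((~is_target & merged["responded"]).sum())
    return omissions, commissions


def relative_change(pre_value: float, later_value: float) -> float:
    """(later - pre) / pre x 100.  Raises on a zero baseline — use an
    absolute difference there (as done for error counts)."""
    if pre_value == 0:
        raise ZeroDivisionError(
            "relative change undefined for zero baseline; use an absolute difference"
        )
    return (later_value - pre_value) / pre_value * 100.0


def build_outcome_table(records) -> pd.DataFrame:
    """Long-format outcome table, one row per subject x condition.

    ``records`` is an iterable of dicts with at least ``subject``,
    ``group`` and ``condition``; other outcome columns default to NaN.
    Subjects lacking a pre or post row are dropped with a log entry
    (the during condition is optional, behavior-only).
    """
    df = pd.DataFrame(list(records))
    for col in OUTCOME_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[OUTCOME_COLUMNS]
    ok_subjects = []
    for subj, grp in df.groupby("subject"):
        conds = set(grp["condition"])
        if {"pre", "post"}.issubset(conds):
            ok_subjects.append(subj)
        else:
            logger.warning(
                "build_outcome_table: subject %s lacks %s; excluded",
                subj,
                {"pre", "post"} - conds,
            )
    return df[df["subject"].isin(ok_subjects)].reset_index(drop=True)


#: measures compared relatively (%) vs absolutely (difference) across time
RELATIVE_MEASURES = ("p3_amp_uv", "rt_mean_ms", "rt_sd_ms", "ersp_max_db")
ABSOLUTE_MEASURES = ("omissions", "commissions")

COMPARISONS = {
    "pre-to-post": ("pre", "post"),
    "pre-to-during": ("pre", "during"),
    "during-to-post": ("during", "post"),
}


def change_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-subject change records for every measure and time comparison.

    Relative (%) basis for amplitude, RT and ERSP measures; absolute
    differences for error counts (their baseline can be zero).
    """
    frames = []
    for measure in RELATIVE_MEASURES + ABSOLUTE_MEASURES:
        if measure not in outcomes.columns or outcomes[measure].isna().all():
            continue
        wide = outcomes.pivot(
            index=["subject", "group"], columns="condition", values=measure
        )
        relative = measure in RELATIVE_MEASURES
        for comp, (c0, c1) in COMPARISONS.items():
            if c0 not in wide.columns or c1 not in wide.columns:
                continue
            v0 = wide[c0].to_numpy(float)
            v1 = wide[c1].to_numpy(float)
            ok = ~(np.isnan(v0) | np.isnan(v1))
            if relative:
                ok &= v0 != 0
                with np.errstate(divide="ignore", invalid="ignore"):
                    value = (v1 - v0) / v0 * 100.0
            else:
                value = v1 - v0
            if not ok.any():
                continue
            idx = wide.index[ok]
            frames.append(
                pd.DataFrame(
                    {
                        "subject": idx.get_level_values("subject"),
                        "group": idx.get_level_values("group"),
                        "measure": measure,
                        "comparison": comp,
                        "value": value[ok],
                        "basis": "relative" if relative else "absolute",
                    }
                )
            )
    cols = ["subject", "group", "measure", "comparison", "value", "basis"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]
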