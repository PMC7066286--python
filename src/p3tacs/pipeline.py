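"""End-to-end synthetic study orchestration.

Runs the full two-by-two (group x time) design on synthetic cohorts:
simulate the pre block, run the online chain to estimate individualized
stimulation parameters, schedule the phase-locked during block
(behavior only — during-block EEG is contaminated by the stimulation
artifact and is never analyzed), simulate the post block with the
configured amplitude effect, run the offline chain on pre and post,
extract outcomes and the online-vs-offline phase miss, and apply the
group statistics.  Every stage is a pure function of (inputs, config,
seed), so reruns with the same seed are byte-identical.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import SimConfig, StudyConfig, preprocess_preset, tfr_preset
from . import io as pio
from . import sim, stim
from .outcomes import (
    build_outcome_table,
    change_table,
    error_counts,
    p300_metrics,
    reaction_time_metrics,
)
from .preprocess import run_chain
from .spectral import ersp_from_config, ersp_window_max
from .stats import run_hypothesis_suite
from .stim import (
    StimParams,
    estimate_p300_latency,
    estimate_stim_frequency,
    phase_miss,
    schedule_during_block,
)

logger = logging.getLogger(__name__)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def _draw_truncnorm(rng, mean, sd, bounds):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def analyze_subject(
    subject: str,
    group: str,
    cfg: StudyConfig,
    ss: np.random.SeedSequence,
) -> dict:
    """Simulate and analyze one subject; returns outcome rows, the
    delivered StimParams, the offline re-estimates and the during
    schedule."""
    rng = np.random.default_rng(ss.generate_state(4))
    f0 = _draw_truncnorm(rng, cfg.freq_mean_hz, cfg.freq_sd_hz, cfg.freq_bounds_hz)
    lat0 = _draw_truncnorm(rng, cfg.latency_mean_ms, cfg.latency_sd_ms, cfg.latency_bounds_ms)
    base = dataclasses.replace(cfg.sim, ero_freq_hz=f0, ero_latency_ms=lat0)

    seeds = ss.spawn(4)
    online_pp = preprocess_preset("online")
    offline_pp = preprocess_preset("offline")
    offline_pp.ica_cleanup = cfg.ica_cleanup
    tfr_online = tfr_preset("online")
    tfr_offline = tfr_preset("offline")

    # --- pre block and online parameter estimation
    sched_pre, beh_pre, rec_pre = sim.simulate_session(base, seed=_child_seed(seeds[0]))
    ep_online = run_chain(rec_pre, online_pp)
    params = stim.params_from_pre_block(
        ep_online,
        tfr_cfg=tfr_online,
        latency_window_ms=cfg.latency_window_ms,
        duration_s=cfg.during_duration_s,
        mode="stim" if group == "stim" else "sham",
    )

    # --- during block: phase-locked schedule, behavior only
    sched_during = schedule_during_block(params, base, seed=_child_seed(seeds[1]))
    beh_during = sim.generate_behavior(sched_during, base, seed=_child_seed(seeds[1]) + 1)

    # --- post block with the group's amplitude effect
    mult = cfg.effect_amp_multiplier if group == "stim" else cfg.sham_amp_multiplier
    post_cfg = dataclasses.replace(base, ero_amp_uv=base.ero_amp_uv * mult)
    sched_post, beh_post, rec_post = sim.simulate_session(post_cfg, seed=_child_seed(seeds[2]))

    # --- offline chain on pre and post
    ica_seed = _child_seed(seeds[3])
    ep_pre = run_chain(rec_pre, offline_pp, seed=ica_seed)
    ep_post = run_chain(rec_post, offline_pp, seed=ica_seed + 1)

    rows = []
    offline_estimates = {}
    for cond, ep, sched, beh in (
        ("pre", ep_pre, sched_pre, beh_pre),
        ("post", ep_post, sched_post, beh_post),
    ):
        p3 = p300_metrics(ep)
        rt = reaction_time_metrics(beh)
        om, com = error_counts(sched, beh)
        m = ersp_from_config(ep, tfr_offline)
        wm = ersp_window_max(
            m,
            center_time_ms=params.p3_latency_ms,
            time_halfwidth_ms=150.0,
            center_freq_hz=params.stim_freq_hz,
            freq_halfwidth_hz=3.0,
        )
        rows.append(
            {
                "subject": subject,
                "group": group,
                "condition": cond,
                "p3_amp_uv": p3.amp_uv,
                "p3_lat_ms": p3.lat_ms,
                "rt_mean_ms": rt.rt_mean_ms,
                "rt_sd_ms": rt.rt_sd_ms,
                "n_valid_rt": rt.n_valid,
                "omissions": om,
                "commissions": com,
                "ersp_max_db": wm.value_db,
                "n_trials_erp": p3.n_trials,
                "n_targets": int((sched["stimulus_type"] == "target").sum()),
            }
        )
        if cond == "pre":
            off_lat = estimate_p300_latency(ep.erp("Pz"), ep.times_ms, cfg.latency_window_ms)
            off_freq = estimate_stim_frequency(m, off_lat.latency_ms)
            offline_estimates = {
                "latency_ms": off_lat.latency_ms,
                "freq_hz": off_freq,
            }

    rt_d = reaction_time_metrics(beh_during)
    om_d, com_d = error_counts(sched_during, beh_during)
    rows.append(
        {
            "subject": subject,
            "group": group,
            "condition": "during",
            "rt_mean_ms": rt_d.rt_mean_ms,
            "rt_sd_ms": rt_d.rt_sd_ms,
            "n_valid_rt": rt_d.n_valid,
            "omissions": om_d,
            "commissions": com_d,
            "n_targets": int((sched_during["stimulus_type"] == "target").sum()),
        }
    )

    pm = phase_miss(params, offline_estimates["latency_ms"], offline_estimates["freq_hz"])
    return {
        "rows": rows,
        "params": params,
        "true_freq_hz": f0,
        "true_latency_ms": lat0,
        "offline": offline_estimates,
        "phase_miss": pm,
        "during_schedule": sched_during,
    }


def run_study(cfg: StudyConfig, out_dir: Optional[Path] = None) -> dict:
    """Run the whole synthetic study.

    Returns a bundle with the outcome table, change table, group
    statistics, per-subject stimulation parameters and the phase-miss
    table; optionally writes everything under ``out_dir``.
    """
    root = np.random.SeedSequence(cfg.seed)
    subject_seeds = root.spawn(2 * cfg.n_per_group)
    records, params_list, miss_rows = [], [], []
    for i in range(2 * cfg.n_per_group):
        group = "stim" if i < cfg.n_per_group else "sham"
        subject = f"{group}{(i % cfg.n_per_group) + 1:02d}"
        logger.info("run_study: subject %s (%s)", subject, group)
        try:
            res = analyze_subject(subject, group, cfg, subject_seeds[i])
        except Exception as err:
            raise RuntimeError(f"stage failure for subject {subject}: {err}") from err
        records.extend(res["rows"])
        params_list.append((subject, res["params"], res["during_schedule"]))
        pm = res["phase_miss"]
        miss_rows.append(
            {
                "subject": subject,
                "group": group,
                "online_latency_ms": res["params"].p3_latency_ms,
                "online_freq_hz": res["params"].stim_freq_hz,
                "offline_latency_ms": res["offline"]["latency_ms"],
                "offline_freq_hz": res["offline"]["freq_hz"],
                "true_latency_ms": res["true_latency_ms"],
                "true_freq_hz": res["true_freq_hz"],
                "phase_miss_rad": pm.miss_rad,
                "phase_miss_signed_rad": pm.signed_rad,
            }
        )

    outcomes = build_outcome_table(records)
    changes = change_table(outcomes)
    results = run_hypothesis_suite(outcomes)
    miss = pd.DataFrame(miss_rows)

    bundle = {
        "outcomes": outcomes,
        "changes": changes,
        "group_stats": results,
        "phase_miss": miss,
        "stim_params": {s: p for s, p, _ in params_list},
        "config": cfg,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outcomes.to_csv(out_dir / "outcomes.csv", index=False)
        changes.to_csv(out_dir / "changes.csv", index=False)
        results.to_csv(out_dir / "group_stats.csv", index=False)
        miss.to_csv(out_dir / "phase_miss.csv", index=False)
        for subject, params, sched in params_list:
            pio.save_stim_params(params, out_dir / f"stimparams_{subject}.json")
            sched.to_csv(out_dir / f"schedule_during_{subject}.tsv", sep="\t", index=False)
        (out_dir / "report.txt").write_text(render_report(bundle))
    return bundle


def render_report(bundle: dict) -> str:
    """Plain-text study report, including every active design value."""
    cfg: StudyConfig = bundle["config"]
    lines = [
        "p3tacs synthetic study report",
        "=" * 32,
        "",
        f"subjects per group : {cfg.n_per_group}",
        f"seed               : {cfg.seed}",
        f"effect multiplier  : stim {cfg.effect_amp_multiplier} / sham {cfg.sham_amp_multiplier}",
        f"latency window     : {cfg.latency_window_ms} ms",
        f"during duration    : {cfg.during_duration_s} s",
        "",
        "active analysis settings",
        "-" * 32,
        "online chain : HP 0.5 Hz, LP 20 Hz, epochs -3..4 s, baseline -50..0 ms,",
        "               blink rejection 100 uV / r>0.8 in 0..1 s",
        "offline chain: LP 8 Hz, average reference, EOG-ICA cleanup "
        f"({'on' if cfg.ica_cleanup else 'off'})",
        "TFR online   : 1.5-20 Hz / 0.5 Hz / 24 ms, 3 cycles, baseline -3..0 s",
        "TFR offline  : to 10 Hz / 0.25 Hz / 14 ms, 3 cycles",
        "P300 window  : 300-600 ms at Pz; RT validity 200-1000 ms",
        "",
        "group statistics",
        "-" * 32,
        bundle["group_stats"].to_string(index=False),
        "",
        "phase miss (online vs offline)",
        "-" * 32,
        bundle["phase_miss"][
            ["subject", "group", "phase_miss_rad"]
        ].to_string(index=False),
        "",
    ]
    return "\n".join(lines)
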