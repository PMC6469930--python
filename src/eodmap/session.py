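"""Session orchestration: run every analysis stage over one trial bundle.

Per eligible unit (> ``min_spikes`` spikes): spike-triggered EOD rate,
speed and sampling density with circular-shift nulls and significance
tests, peak/dip timing, rate map + place information with both permutation
nulls, stationarity, swim-direction preference and the egocentric landmark
map with its AP/LR preference vector.  Failures are isolated per unit; the
session continues and records the reason.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import egocentric, kinematics, spatial, triggered
from .config import AnalysisConfig
from .eod import instantaneous_eod_rate
from .errors import EodmapError
from .io import TrialBundle

__all__ = ["run_session", "write_report", "sta_tidy_table"]


def _round(x, nd=9):
    """Stable rounding so report JSON is byte-identical across runs."""
    if isinstance(x, float):
        return round(x, nd)
    return x


def analyse_unit(
    name: str,
    bundle: TrialBundle,
    series: dict,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> dict:
    traj = bundle.trajectory
    spikes = bundle.units[name]
    out: dict = {"unit": name, "n_spikes": len(spikes)}

    # --- spike-triggered averages + nulls
    sta = {}
    for var in ("eodr", "speed"):
        sta[var] = triggered.spike_triggered_average(
            traj.times, series[var], spikes,
            half_window=config.sta_half_window_s,
            min_spikes=config.min_spikes, variable=var,
        )
    null = triggered.circular_shift_null(
        spikes, traj.duration, n_shifts=config.n_shifts_sta,
        min_shift=config.min_shift_s, rng=rng,
    )
    triggered.null_triggered_averages(
        traj.times, series["eodr"], null,
        half_window=config.sta_half_window_s, variable="eodr",
    )
    elev = triggered.test_mean_elevation(sta["eodr"], null)
    sta["smpd"] = triggered.st_sampling_density(
        sta["eodr"], sta["speed"], speed_floor=config.speed_floor_cm_s
    )
    out["mean_elevation"] = {
        "H": _round(elev.statistic), "p_kw": _round(elev.p_value),
        "p_permutation": _round(elev.p_permutation),
        "observed_mean_hz": _round(elev.observed_mean),
        "null_mean_hz": _round(elev.null_mean),
    }
    out["peaks"] = {}
    for var, which in (("eodr", "peak"), ("speed", "peak"),
                       ("speed", "dip"), ("smpd", "peak"), ("smpd", "dip")):
        r = triggered.test_peak(sta[var], which=which)
        timing = triggered.peak_dip_timing(sta[var].per_spike, sta[var].lags, mode=which)
        out["peaks"][f"{var}_{which}"] = {
            "lag_s": _round(r.peak_lag), "p": _round(r.p_value),
            "median_per_spike_lag_s": _round(timing.median),
            "sign_test_p": _round(timing.sign_test_p),
            "n_excluded": timing.n_excluded,
        }
    out["_sta"] = sta  # stripped before JSON; kept for tables/plots

    # --- spatial
    occ = spatial.build_occupancy(traj, bundle.arena,
                                  bin_size=config.bin_size_cm,
                                  visit_min=config.visit_min)
    rmap = spatial.build_rate_map(occ, spikes, traj,
                                  clip_percentile=config.display_clip_percentile)
    info = {}
    for method in ("shift", "shuffle"):
        res = spatial.place_info_significance(
            spikes, traj, occ, n_surrogates=config.n_shifts_place,
            method=method, min_shift=config.min_shift_s, rng=rng,
            min_spikes=config.min_spikes,
        )
        info[method] = {
            "bits_per_spike": _round(res.information),
            "null_95th": _round(res.percentile_95),
            "significant": bool(res.significant),
            "p_empirical": _round(res.p_empirical),
            "p_ttest": _round(res.p_ttest),
        }
    stat = spatial.stationarity_check(spikes, traj.duration)
    out["place"] = {
        "mean_rate_hz": _round(rmap.r_m),
        "max_fr_hz": _round(rmap.max_fr),
        "info": info,
        "stationarity_p": _round(stat.p_value),
    }

    # --- direction preference + egocentric landmarks
    labels = kinematics.classify_swim_direction(
        traj, speed_threshold=config.speed_threshold_cm_s,
        smooth_window=config.speed_smooth_frames,
    )
    out["direction_preference_index"] = _round(
        egocentric.direction_preference_index(spikes, labels, traj)
    )
    raster = egocentric.rasterize_arena(bundle.arena, block_px=config.raster_block_px)
    emap = egocentric.accumulate_stlm_ptlm(
        raster, traj, spikes,
        downsample=config.egocentric_downsample,
        window_cm=config.egocentric_window_cm,
        exclusion_percentile=config.ptlm_exclusion_percentile,
        min_spikes=config.min_spikes,
    )
    vec = egocentric.ap_lr_preference(emap, body_length=config.body_length_cm)
    out["egocentric"] = {
        "lr_index": _round(vec.lr_index), "ap_index": _round(vec.ap_index),
        "magnitude": _round(vec.magnitude), "angle_rad": _round(vec.angle),
    }
    return out


def run_session(bundle: TrialBundle, config: AnalysisConfig | None = None) -> dict:
    """Run the full analysis over a trial bundle.

    Deterministic for a given bundle and config (the config seed spawns one
    stream per unit, keyed by sorted unit name).  Returns a JSON-ready
    report; per-unit triggered averages ride along under the ``_sta`` key of
    each unit result for table/figure export and are stripped by
    :func:`write_report`.
    """
    config = config or AnalysisConfig()
    traj = bundle.trajectory
    eodr = instantaneous_eod_rate(bundle.eod, grid=traj.times)
    speed = kinematics.compute_speed(traj, smooth_window=config.speed_smooth_frames)
    series = {"eodr": eodr.rate, "speed": speed}
    down = kinematics.detect_down_states(
        eodr, threshold=config.down_threshold_hz,
        min_duration=config.down_min_duration_s,
    )
    names = sorted(bundle.units)
    streams = np.random.SeedSequence(config.seed).spawn(max(len(names), 1))
    units = {}
    for name, stream in zip(names, streams):
        try:
            units[name] = analyse_unit(name, bundle, series, config,
                                       np.random.default_rng(stream))
        except EodmapError as exc:
            units[name] = {"unit": name, "skipped": str(exc),
                           "n_spikes": len(bundle.units[name])}
    return {
        "trial_id": bundle.trial_id,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "trial": {
            "duration_s": _round(traj.duration),
            "n_frames": traj.n_frames,
            "n_eod_pulses": len(bundle.eod),
            "down_states": [[_round(a), _round(b)] for a, b in down],
        },
        "units": units,
    }


def sta_tidy_table(report: dict) -> pd.DataFrame:
    """Tidy (unit, variable, lag, mean, sem) table of all triggered averages."""
    rows = []
    for name, u in report["units"].items():
        for var, ta in u.get("_sta", {}).items():
            for lag, m, s in zip(ta.lags, ta.mean, ta.sem):
                rows.append((report["trial_id"], name, var, lag, m, s))
    return pd.DataFrame(rows, columns=["trial", "unit", "variable", "lag", "mean", "sem"])


def write_report(report: dict, directory) -> None:
    """Write report.json plus the tidy triggered-average CSV."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    table = sta_tidy_table(report)
    if len(table):
        table.to_csv(d / "sta.csv", index=False, float_format="%.9g")
    clean = {
        **report,
        "units": {k: {kk: vv for kk, vv in u.items() if not kk.startswith("_")}
                  for k, u in report["units"].items()},
    }
    with open(d / "report.json", "w") as fh:
        json.dump(clean, fh, indent=1, sort_keys=True)
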