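"""Self-validation batteries: type-I calibration and parameter recovery.

Runs the full pipeline over seeded synthetic sessions and summarises how
often each significance procedure fires when its target effect is absent
(calibration) and how reliably each injected effect is recovered
(recovery).  Shared by the test suite and the reproduction script.

All batteries use 30-min sessions at 15 Hz tracking — the short end of the
study's 30-60 min trials — and the generator's default behavior.
"""

from __future__ import annotations

import numpy as np

from . import egocentric, kinematics, spatial, synthetic as syn, triggered
from .arena import default_arena
from .eod import instantaneous_eod_rate

__all__ = ["null_calibration", "recovery_battery", "ordering_battery"]

DURATION = 1800.0


def _session(arena, seed, truths, duration=DURATION):
    """One seeded trial plus the derived series every analysis needs."""
    bundle, tt = syn.generate_trial(arena, truths, duration=duration, seed=seed)
    traj = bundle.trajectory
    rate = instantaneous_eod_rate(bundle.eod, grid=traj.times)
    speed = kinematics.compute_speed(traj)
    return bundle, tt, rate, speed


def null_calibration(
    n_trials: int = 40,
    duration: float = DURATION,
    base_seed: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I rates of the four significance procedures.

    Each trial carries one unit with every coupling disabled (uniform
    Poisson at the sparse baseline, spiking through down-states as well),
    so any detection is a false positive: the Kruskal-Wallis mean-elevation
    test on the spike-triggered EOD rate, the Wilcoxon peak test, the
    95th-percentile place-information criterion (circular-shift null) and
    the within-trial stationarity Kruskal-Wallis.
    """
    arena = default_arena()
    kw, peak, place, stat = [], [], [], []
    for k in range(n_trials):
        streams = np.random.SeedSequence(base_seed + k).spawn(4)
        tt = syn.generate_trajectory(arena, duration,
                                     seed=np.random.default_rng(streams[0]))
        traj = tt.trajectory
        eod = syn.generate_eod_train(tt, arena, seed=np.random.default_rng(streams[1]))
        rate = instantaneous_eod_rate(eod, grid=traj.times)
        truth = syn.GroundTruth(baseline_rate=0.5, quiescent_factor=1.0)
        unit = syn.generate_spikes(tt, rate, truth,
                                   seed=np.random.default_rng(streams[2]))
        rng = np.random.default_rng(streams[3])
        ta = triggered.spike_triggered_average(traj.times, rate.rate, unit.spikes)
        null = triggered.circular_shift_null(unit.spikes, traj.duration, rng=rng)
        triggered.null_triggered_averages(traj.times, rate.rate, null)
        kw.append(triggered.test_mean_elevation(ta, null).p_value)
        peak.append(triggered.test_peak(ta, "peak").p_value)
        occ = spatial.build_occupancy(traj, arena)
        place.append(
            spatial.place_info_significance(unit.spikes, traj, occ,
                                            method="shift", rng=rng).significant
        )
        stat.append(spatial.stationarity_check(unit.spikes, traj.duration).p_value)
    return {
        "n_trials": n_trials,
        "alpha": alpha,
        "mean_elevation_kw": float(np.mean(np.asarray(kw) < alpha)),
        "peak_wilcoxon": float(np.mean(np.asarray(peak) < alpha)),
        "place_info_shift": float(np.mean(place)),
        "stationarity_kw": float(np.mean(np.asarray(stat) < alpha)),
    }


RECOVERY_TRUTHS = {
    "place": lambda: syn.GroundTruth(
        baseline_rate=0.5, place_fields=[syn.PlaceField(center=(0.0, 20.0))]),
    "backward": lambda: syn.GroundTruth(baseline_rate=0.5, direction_gain=4.0),
    "posterior": lambda: syn.GroundTruth(
        baseline_rate=0.5, landmark_driver=syn.LandmarkDriver(gain=6.0)),
    "eodr_rise": lambda: syn.GroundTruth(
        baseline_rate=0.5, eod_coupling=syn.Coupling(lag=-0.3, gain=1.5)),
    "speed_rise": lambda: syn.GroundTruth(
        baseline_rate=0.5, speed_coupling=syn.Coupling(lag=0.5, gain=1.2)),
    "speed_dip": lambda: syn.GroundTruth(
        baseline_rate=0.5, speed_coupling=syn.Coupling(lag=-0.5, gain=-2.0)),
}


def recovery_battery(
    n_trials: int = 20,
    duration: float = DURATION,
    base_seed: int = 2000,
) -> dict:
    """Recovery of every injected ground-truth effect across seeded trials.

    Per trial, six units each carry one effect: a place field (detected via
    the shift-null place-information criterion), a backward-swim preference
    (negative direction preference index), a posterior egocentric landmark
    drive (negative AP index), a pre-spike EOD-rate rise at -0.3 s, a
    post-spike speed rise at +0.5 s, and a pre-spike speed dip at -0.5 s
    (peak/dip lags of the triggered averages and per-spike median timings).
    """
    arena = default_arena()
    raster = egocentric.rasterize_arena(arena)
    out = {name: [] for name in
           ("place_sig", "dpi", "ap_index",
            "eodr_peak_lag", "eodr_peak_median",
            "speed_peak_lag", "speed_peak_median",
            "speed_dip_lag", "speed_dip_median")}
    for k in range(n_trials):
        truths = {name: make() for name, make in RECOVERY_TRUTHS.items()}
        bundle, tt, rate, speed = _session(arena, base_seed + k, truths, duration)
        traj = bundle.trajectory
        rng = np.random.default_rng(np.random.SeedSequence(base_seed + 50_000 + k))
        occ = spatial.build_occupancy(traj, arena)
        labels = kinematics.classify_swim_direction(traj)

        res = spatial.place_info_significance(
            bundle.units["place"], traj, occ, method="shift", rng=rng)
        out["place_sig"].append(res.significant)
        out["dpi"].append(egocentric.direction_preference_index(
            bundle.units["backward"], labels, traj))
        emap = egocentric.accumulate_stlm_ptlm(raster, traj, bundle.units["posterior"])
        out["ap_index"].append(egocentric.ap_lr_preference(emap).ap_index)

        for name, values, which in (
            ("eodr_peak", rate.rate, "peak"),
            ("speed_peak", speed, "peak"),
            ("speed_dip", speed, "dip"),
        ):
            unit = "eodr_rise" if name == "eodr_peak" else (
                "speed_rise" if name == "speed_peak" else "speed_dip")
            ta = triggered.spike_triggered_average(traj.times, values,
                                                   bundle.units[unit])
            out[f"{name}_lag"].append(triggered.test_peak(ta, which).peak_lag)
            timing = triggered.peak_dip_timing(ta.per_spike, ta.lags, mode=which)
            out[f"{name}_median"].append(timing.median)
            out.setdefault(f"{name}_pooled", []).append(timing.times)

    dpi = np.asarray(out["dpi"])
    ap = np.asarray(out["ap_index"])
    return {
        "n_trials": n_trials,
        "place_significant_fraction": float(np.mean(out["place_sig"])),
        "dpi_negative_fraction": float(np.mean(dpi < 0)),
        "dpi_mean": float(dpi.mean()),
        "ap_negative_fraction": float(np.mean(ap < 0)),
        "ap_mean": float(ap.mean()),
        "eodr_peak_lag_negative_fraction": float(
            np.mean(np.asarray(out["eodr_peak_lag"]) < 0)),
        "eodr_peak_median_timing": float(np.median(out["eodr_peak_median"])),
        "speed_peak_lag_positive_fraction": float(
            np.mean(np.asarray(out["speed_peak_lag"]) > 0)),
        "speed_peak_median_timing": float(np.median(out["speed_peak_median"])),
        "speed_dip_lag_negative_fraction": float(
            np.mean(np.asarray(out["speed_dip_lag"]) < 0)),
        "speed_dip_lag_median": float(np.median(out["speed_dip_lag"])),
        "speed_dip_median_timing": float(np.median(out["speed_dip_median"])),
        "speed_dip_pooled_median": float(
            np.median(np.concatenate(out["speed_dip_pooled"]))),
        "speed_dip_pooled_sign_p": triggered.sign_test(
            np.concatenate(out["speed_dip_pooled"])),
    }


def ordering_battery(
    n_trials: int = 3,
    duration: float = DURATION,
    base_seed: int = 3000,
) -> dict:
    """Shift-null versus shuffle-null place-information detections.

    Each trial carries a place cell, a spatially uniform unit, and an
    "epoch" unit that fires uniformly but only during the first fifth of
    the trial.  Circularly shifting the whole train preserves that temporal
    clump (high surrogate information -> conservative); shuffling spike
    times destroys it, so the shuffle null should flag at least as many
    units as the shift null.
    """
    arena = default_arena()
    n_shift = n_shuffle = 0
    total = 0
    for k in range(n_trials):
        truths = {
            "place": syn.GroundTruth(baseline_rate=0.5,
                                     place_fields=[syn.PlaceField(center=(0.0, 20.0))]),
            "uniform": syn.GroundTruth(baseline_rate=0.5, quiescent_factor=1.0),
            "epoch_src": syn.GroundTruth(baseline_rate=1.5, quiescent_factor=1.0),
        }
        bundle, tt, rate, speed = _session(arena, base_seed + k, truths, duration)
        traj = bundle.trajectory
        src = bundle.units.pop("epoch_src")
        bundle.units["epoch"] = triggered.SpikeTrain(
            spike_times=src.spike_times[src.spike_times < 0.2 * traj.duration],
            unit_id="epoch", trial_id=src.trial_id, trial_duration=src.trial_duration)
        occ = spatial.build_occupancy(traj, arena)
        for j, (name, unit) in enumerate(sorted(bundle.units.items())):
            total += 1
            for method in ("shift", "shuffle"):
                rng = np.random.default_rng(
                    np.random.SeedSequence(base_seed + 90_000 + 10 * k + j))
                res = spatial.place_info_significance(unit, traj, occ,
                                                      method=method, rng=rng)
                if res.significant:
                    if method == "shift":
                        n_shift += 1
                    else:
                        n_shuffle += 1
    return {"n_units": total, "shift_detections": n_shift,
            "shuffle_detections": n_shuffle}
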