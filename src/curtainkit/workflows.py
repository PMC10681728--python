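"""End-to-end simulate-then-measure experiments.

Each workflow generates synthetic data at a configured ground-truth regime
and pushes it through the full measurement pipeline, returning both the
estimates and the truth so recovery can be scored.  They are what the
recovery test-suites and the reproduction script drive.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import coloc, outcomes, photobleach, simgen
from . import kymo as kymo_mod
from .config import ImagingConfig

__all__ = [
    "translocation_recovery",
    "step_count_recovery",
    "cluster_sizing_recovery",
    "colocalization_recovery",
    "correlation_recovery",
    "survival_recovery",
]

_MAX_SEED = 2**31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _MAX_SEED, size=n)


def translocation_recovery(
    n_tracks: int = 400,
    mean_velocity: float = 81.7,
    sd_velocity: float = 51.0,
    mean_track_length_kb: float = 12.1,
    seed: int = 0,
    config: Optional[ImagingConfig] = None,
    psf_sd: float = 1.2,
    noise_sd: float = 0.0,
    background: float = 10.0,
) -> dict:
    """Simulate a track ensemble, render kymographs, track, and score.

    The generator is calibrated so that the ensemble of *observed* tracks
    (those passing the >2 px start rule) has the requested mean velocity and
    mean track length.  Each track is rendered into its own noiseless (by
    default) kymograph, re-tracked by windowed centroids, motion-classified,
    and its net velocity and track length computed.  Tracks without a
    defined velocity (never started, or no elapsed time) are excluded, as in
    manual scoring.
    """
    if config is None:
        config = ImagingConfig.two_color(frames=6000, shape=(16, 512))
    regime = simgen.calibrate_track_regime(
        mean_velocity, sd_velocity, mean_track_length_kb, config
    )
    seeds = _child_seeds(seed, 2 * n_tracks)
    velocities, lengths, true_velocities = [], [], []
    for i in range(n_tracks):
        track, truth = simgen.simulate_translocation_track(
            v_mean=regime["v_mean"],
            v_sd=regime["v_sd"],
            pause_prob_per_frame=0.0,
            terminate_prob_per_frame=regime["terminate_prob"],
            config=config,
            seed=int(seeds[2 * i]),
        )
        term = truth.per_object["termination_frame"]
        stop = min(track.n_frames, (term if term is not None else track.n_frames) + 15)
        sub = kymo_mod.TranslocationTrack(
            positions=track.positions[:stop], times=track.times[:stop]
        )
        kymograph = simgen.render_kymograph(
            [sub],
            psf_sd=psf_sd,
            noise_sd=noise_sd,
            background=background,
            config=config,
            seed=int(seeds[2 * i + 1]),
        )
        tracked = kymo_mod.track_particle(
            kymograph, start_hint=sub.positions[0], window=9
        )
        kymo_mod.classify_motion(tracked)
        try:
            velocities.append(kymo_mod.compute_velocity(tracked, config))
            lengths.append(kymo_mod.compute_track_length(tracked, config))
            true_velocities.append(truth.per_object["velocity_bp_s"])
        except kymo_mod.UndefinedKinematicsError:
            continue
    velocities = np.array(velocities)
    lengths = np.array(lengths)
    return {
        "velocities_bp_s": velocities,
        "track_lengths_kb": lengths,
        "true_velocities_bp_s": np.array(true_velocities),
        "mean_velocity_bp_s": float(velocities.mean()),
        "mean_track_length_kb": float(lengths.mean()),
        "n_observed": int(velocities.size),
        "regime": regime,
    }


def step_count_recovery(
    n_traces: int = 1000,
    mixture: Optional[dict] = None,
    unit_intensity: float = 100.0,
    unit_sd: float = 10.0,
    snr: float = 5.0,
    bleach_rate: float = 0.025,
    background: float = 50.0,
    frames: int = 1200,
    seed: int = 0,
) -> dict:
    """Simulate a photobleaching cohort and count detected steps per trace.

    True fluorophore counts are drawn from ``mixture`` (count -> share);
    noise SD is ``unit_intensity / snr``.  Returns detected and true counts
    and the detected fraction at each count.
    """
    if mixture is None:
        mixture = {1: 0.07, 2: 0.59, 3: 0.07, 4: 0.26}
    rng = np.random.default_rng(seed)
    ks = np.array(sorted(mixture), dtype=int)
    ps = np.array([mixture[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    true_counts = rng.choice(ks, size=n_traces, p=ps)
    seeds = _child_seeds(seed + 1, n_traces)
    cfg = ImagingConfig.unshuttered(frames=frames)
    noise_sd = unit_intensity / snr

    detected = np.empty(n_traces, dtype=int)
    for i in range(n_traces):
        trace, _ = simgen.simulate_photobleach_trace(
            n_fluors=int(true_counts[i]),
            unit_intensity=unit_intensity,
            unit_sd=unit_sd,
            bleach_rate=bleach_rate,
            noise_sd=noise_sd,
            background=background,
            config=cfg,
            seed=int(seeds[i]),
        )
        events = photobleach.detect_steps(trace)
        detected[i] = sum(1 for e in events if e.direction == "drop")
    frac = {int(k): float((detected == k).mean()) for k in np.unique(detected)}
    return {
        "true_counts": true_counts,
        "detected_counts": detected,
        "detected_fractions": frac,
        "n": n_traces,
    }


def cluster_sizing_recovery(
    n_clusters: int = 201,
    median: float = 7.06,
    sigma: float = 0.6,
    unit_intensity: float = 100.0,
    unit_sd: float = 10.0,
    snr: float = 5.0,
    background: float = 50.0,
    n_calibration_traces: int = 150,
    seed: int = 0,
) -> dict:
    """Calibrate the unit intensity from simulated traces, then size a field.

    Calibration traces carry 2-4 fluorophores (the directly countable
    regime); their pooled drop amplitudes give the single-fluorophore unit
    intensity, which is used to size a log-normal field of ``n_clusters``
    foci by background subtraction and division.
    """
    noise_sd = unit_intensity / snr
    cfg = ImagingConfig.unshuttered(frames=1200)
    rng = np.random.default_rng(seed)
    seeds = _child_seeds(seed + 1, n_calibration_traces)
    amplitudes: list[float] = []
    for i in range(n_calibration_traces):
        n_fluor = int(rng.integers(2, 5))
        trace, _ = simgen.simulate_photobleach_trace(
            n_fluors=n_fluor,
            unit_intensity=unit_intensity,
            unit_sd=unit_sd,
            bleach_rate=0.025,
            noise_sd=noise_sd,
            background=background,
            config=cfg,
            seed=int(seeds[i]),
        )
        amplitudes += [
            e.amplitude
            for e in photobleach.detect_steps(trace)
            if e.direction == "drop"
        ]
    calibration = photobleach.fit_unit_intensity(amplitudes)

    records, truth = simgen.simulate_cluster_field(
        ("lognormal", {"median": median, "sigma": sigma}),
        n_clusters=n_clusters,
        unit_intensity=unit_intensity,
        unit_sd=unit_sd,
        background=background,
        noise_sd=noise_sd,
        seed=seed + 2,
    )
    for r in records:
        photobleach.estimate_cluster_size(r, calibration, background=background)
    summary = photobleach.summarize_cluster_sizes(records)
    return {
        "calibration": calibration,
        "summary": summary,
        "median_estimated": summary["median"],
        "median_true": float(np.median(truth.per_object["sizes"])),
        "records": records,
    }


def colocalization_recovery(
    n_points: int = 142,
    coloc_fraction: float = 0.93,
    jitter_sd: float = 0.3,
    radius: float = 1.0,
    seed: int = 0,
) -> dict:
    """Simulate a two-color field and score its colocalization fraction."""
    data, truth = simgen.simulate_two_color(
        n_points=n_points,
        coloc_fraction=coloc_fraction,
        intensity_corr=0.7,
        jitter_sd=jitter_sd,
        seed=seed,
    )
    res = coloc.colocalize(
        data["points_a"],
        data["points_b"],
        radius=radius,
        intensities_a=data["intensities_a"],
        intensities_b=data["intensities_b"],
    )
    res["true_fraction"] = truth.per_object["n_matched"] / n_points
    return res


def correlation_recovery(
    n_pairs: int = 200, rho: float = 0.2, seed: int = 0
) -> dict:
    """Simulate fully matched pairs at correlation rho and recover Pearson r."""
    data, _ = simgen.simulate_two_color(
        n_points=n_pairs,
        coloc_fraction=1.0,
        intensity_corr=rho,
        jitter_sd=0.0,
        seed=seed,
    )
    res = coloc.colocalize(
        data["points_a"],
        data["points_b"],
        radius=1.0,
        intensities_a=data["intensities_a"],
        intensities_b=data["intensities_b"],
    )
    return coloc.intensity_correlation(res["pairs"])


def survival_recovery(
    survival_fraction: float = 0.416,
    expected_cfu: float = 200.0,
    n_replicates: int = 10,
    seed: int = 0,
) -> dict:
    """Simulate treated/untreated CFU plates and compute percent survival."""
    counts, _ = simgen.simulate_colony_counts(
        true_frequency=survival_fraction,
        cells_plated_selective=expected_cfu,
        dilution_factor=1.0,
        cells_plated_nonselective=expected_cfu,
        n_replicates=n_replicates,
        seed=seed,
    )
    per_rep = outcomes.survival_percentage(counts.selective, counts.nonselective)
    return {
        "per_replicate_pct": per_rep,
        "mean_pct": float(np.mean(per_rep)),
        "sd_pct": float(np.std(per_rep, ddof=1)),
        "n_replicates": n_replicates,
    }
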