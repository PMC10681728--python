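"""Synthetic single-molecule and plate-count data with known ground truth.

Every generator emulates one input class of the quantification pipelines:

* :func:`simulate_photobleach_trace` — per-cluster intensity traces with
  stepwise photobleaching (exponential bleach times), Gaussian camera noise
  and a uniform background, acquired unshuttered at 0.2 s/frame;
* :func:`simulate_cluster_field` — integrated intensities of fluorescent
  foci whose true copy numbers follow a configurable distribution
  (log-normal by default: positive, right-skewed, two parameters);
* :func:`simulate_translocation_track` / :func:`render_kymograph` — particle
  paths with one velocity per track (truncated-at-zero normal), optional
  transient pauses and per-frame termination, rendered into kymographs or
  full image stacks with a Gaussian line-spread profile;
* :func:`simulate_two_color` — paired point/intensity fields with a set
  colocalization fraction and intensity correlation;
* :func:`simulate_colony_counts` — Poisson plate counts for the frequency
  and survival assays.

Every function takes an explicit seed and is bit-for-bit reproducible; each
returns its data together with a :class:`SimTruth` record.

The generator does **not** model EMCCD excess noise, tether stretching
dynamics, Rad51 filaments, or DNA-end effects (tracks are not clipped at a
~50 kb tether boundary; the kymograph is as wide as the camera chip).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, optimize, stats

from .config import ConfigurationError, ImagingConfig
from .kymo import Kymograph, TranslocationTrack, extract_kymograph
from .outcomes import ColonyCounts
from .photobleach import ClusterRecord, IntensityTrace

__all__ = [
    "SimTruth",
    "simulate_photobleach_trace",
    "simulate_cluster_field",
    "simulate_translocation_track",
    "render_kymograph",
    "simulate_two_color",
    "simulate_colony_counts",
    "calibrate_track_regime",
    "truncated_normal_location",
]


@dataclass
class SimTruth:
    """Ground truth attached to one simulated object (or object set)."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)
    per_object: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            if isinstance(v, dict):
                return {str(k): conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            return v

        return {
            "seed": int(self.seed),
            "kind": self.kind,
            "params": conv(self.params),
            "per_object": conv(self.per_object),
        }


# ---------------------------------------------------------------------------
# photobleaching traces and cluster fields
# ---------------------------------------------------------------------------

def simulate_photobleach_trace(
    n_fluors: int,
    unit_intensity: float,
    unit_sd: float,
    bleach_rate: float,
    noise_sd: float,
    background: float,
    config: Optional[ImagingConfig] = None,
    seed: int = 0,
) -> tuple[IntensityTrace, SimTruth]:
    """One cluster's intensity trace under stepwise photobleaching.

    Each of the ``n_fluors`` fluorophores gets an amplitude ~
    N(unit_intensity, unit_sd) and an independent exponential bleach time
    with rate ``bleach_rate`` (1/s); the trace at frame t is background plus
    the sum of surviving amplitudes plus N(0, noise_sd) camera noise.
    """
    if n_fluors < 0:
        raise ValueError("n_fluors must be >= 0")
    if min(unit_intensity, unit_sd, bleach_rate, noise_sd) < 0:
        raise ValueError("intensities and rates must be >= 0")
    if config is None:
        config = ImagingConfig.unshuttered()
    dt = config.frame_interval
    if dt <= 0:
        raise ConfigurationError("non-positive frame interval")
    rng = np.random.default_rng(seed)

    amps = rng.normal(unit_intensity, unit_sd, n_fluors)
    if bleach_rate > 0:
        bleach_times = rng.exponential(1.0 / bleach_rate, n_fluors)
    else:
        bleach_times = np.full(n_fluors, np.inf)

    times = np.arange(config.frames) * dt
    if n_fluors:
        surviving = bleach_times[None, :] > times[:, None]
        signal = surviving @ amps
    else:
        signal = np.zeros(config.frames)
    noise = rng.normal(0.0, noise_sd, config.frames) if noise_sd > 0 else 0.0
    values = background + signal + noise

    with np.errstate(invalid="ignore"):
        bleach_frames = np.where(
            np.isfinite(bleach_times),
            np.ceil(bleach_times / dt).astype(float),
            np.inf,
        )
    truth = SimTruth(
        seed=seed,
        kind="photobleach_trace",
        params={
            "n_fluors": n_fluors,
            "unit_intensity": unit_intensity,
            "unit_sd": unit_sd,
            "bleach_rate": bleach_rate,
            "noise_sd": noise_sd,
            "background": background,
            "frame_interval": dt,
        },
        per_object={
            "amplitudes": amps,
            "bleach_times_s": bleach_times,
            "bleach_frames": bleach_frames,
        },
    )
    trace = IntensityTrace(values=values, frame_interval=dt, background=background)
    return trace, truth


def simulate_cluster_field(
    size_distribution: tuple[str, dict],
    n_clusters: int,
    unit_intensity: float,
    unit_sd: float,
    background: float,
    noise_sd: float,
    seed: int = 0,
    field_width_px: float = 512.0,
) -> tuple[list[ClusterRecord], SimTruth]:
    """A field of fluorescent foci with integer true copy numbers.

    ``size_distribution`` is ``(name, params)``:

    * ``("fixed", {"size": k})`` — every cluster has k copies;
    * ``("lognormal", {"median": m, "sigma": s})`` — sizes are
      round(LogNormal(ln m, s)) clipped to >= 1;
    * ``("empirical", {"probs": {size: prob, ...}})`` — sizes drawn from a
      given table.

    Integrated intensity = background + sum of ``size`` unit draws + noise.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    name, params = size_distribution
    rng = np.random.default_rng(seed)

    if name == "fixed":
        sizes = np.full(n_clusters, int(params["size"]))
    elif name == "lognormal":
        draws = rng.lognormal(np.log(params["median"]), params["sigma"], n_clusters)
        sizes = np.maximum(1, np.round(draws)).astype(int)
    elif name == "empirical":
        table = params["probs"]
        ks = np.array(sorted(table), dtype=int)
        ps = np.array([table[k] for k in ks], dtype=float)
        ps = ps / ps.sum()
        sizes = rng.choice(ks, size=n_clusters, p=ps)
    else:
        raise ValueError(f"unknown size distribution {name!r}")

    positions = rng.uniform(0, field_width_px, n_clusters)
    # sum of `size` iid N(unit, unit_sd) draws, sampled via its exact law
    means = sizes * unit_intensity
    sds = np.sqrt(sizes) * unit_sd
    signal = rng.normal(means, sds) if unit_sd > 0 else means.astype(float)
    noise = rng.normal(0.0, noise_sd, n_clusters) if noise_sd > 0 else 0.0
    intensities = background + signal + noise

    records = [
        ClusterRecord(
            position=float(positions[i]),
            intensity=float(intensities[i]),
            true_size=int(sizes[i]),
        )
        for i in range(n_clusters)
    ]
    truth = SimTruth(
        seed=seed,
        kind="cluster_field",
        params={
            "size_distribution": [name, params],
            "n_clusters": n_clusters,
            "unit_intensity": unit_intensity,
            "unit_sd": unit_sd,
            "background": background,
            "noise_sd": noise_sd,
        },
        per_object={"sizes": sizes, "positions": positions},
    )
    return records, truth


# ---------------------------------------------------------------------------
# translocation tracks and kymographs
# ---------------------------------------------------------------------------

def truncated_normal_location(mean: float, sd: float) -> float:
    """Location mu such that a normal(mu, sd) truncated at zero has the
    requested mean.  (Truncation raises the mean above mu, so mu < mean.)"""
    if sd == 0:
        return mean
    if mean <= 0:
        raise ValueError("mean of a positive velocity must be > 0")

    def tn_mean(mu: float) -> float:
        a = -mu / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd))

    lo, hi = mean - 12 * sd, mean
    return float(optimize.brentq(lambda m: tn_mean(m) - mean, lo, hi, xtol=1e-10))


def simulate_translocation_track(
    v_mean: float,
    v_sd: float,
    pause_prob_per_frame: float,
    pause_len_frames: tuple[int, int] = (2, 4),
    terminate_prob_per_frame: float = 0.0,
    config: Optional[ImagingConfig] = None,
    seed: int = 0,
    start_position: float = 5.0,
) -> tuple[TranslocationTrack, SimTruth]:
    """One particle path: constant per-track velocity, pauses, termination.

    The track's velocity is drawn once from a normal truncated at zero whose
    *mean* equals ``v_mean`` (location solved internally).  Each active
    frame the particle advances ``velocity * frame_interval / bp_per_pixel``
    pixels, then may terminate (frozen permanently) with
    ``terminate_prob_per_frame`` or pause (frozen for a uniform 2-4 frames)
    with ``pause_prob_per_frame``.  Positions clamp at the image edge.
    """
    if not (0 <= pause_prob_per_frame <= 1 and 0 <= terminate_prob_per_frame <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    lo, hi = pause_len_frames
    if lo < 2 or hi > 4 or lo > hi:
        raise ConfigurationError(
            "pause length must lie within 2-4 frames (the defined pause range)"
        )
    if config is None:
        config = ImagingConfig.two_color()
    rng = np.random.default_rng(seed)

    if v_sd > 0:
        mu = truncated_normal_location(v_mean, v_sd)
        v = float(
            stats.truncnorm.rvs(
                -mu / v_sd, np.inf, loc=mu, scale=v_sd, random_state=rng
            )
        )
    else:
        v = float(v_mean)

    step = v * config.frame_interval / config.bp_per_pixel  # px per frame
    width = config.shape[1]
    n = config.frames
    terminated_frame: Optional[int] = None
    pauses: list[tuple[int, int]] = []

    if pause_prob_per_frame == 0:
        # pause-free path, vectorized: each frame the particle first faces
        # the termination draw, then moves, so the number of moves is a
        # geometric count that may be zero (terminate_prob=1 -> stationary)
        if terminate_prob_per_frame > 0:
            m = int(rng.geometric(terminate_prob_per_frame)) - 1
        else:
            m = n  # never terminates within the movie
        moves = np.minimum(np.arange(n), m)
        positions = np.minimum(start_position + moves * step, width - 1.0)
        if m <= n - 1:
            terminated_frame = m + 1
    else:
        positions = np.empty(n)
        positions[0] = start_position
        pause_left = 0
        for t in range(1, n):
            if terminated_frame is not None:
                positions[t] = positions[t - 1]
                continue
            if pause_left > 0:
                positions[t] = positions[t - 1]
                pause_left -= 1
                continue
            if (
                terminate_prob_per_frame > 0
                and rng.random() < terminate_prob_per_frame
            ):
                terminated_frame = t
                positions[t] = positions[t - 1]
                continue
            positions[t] = min(positions[t - 1] + step, width - 1.0)
            if pause_prob_per_frame > 0 and rng.random() < pause_prob_per_frame:
                pause_left = int(rng.integers(lo, hi + 1))
                pauses.append((t + 1, t + pause_left))

    times = np.arange(n) * config.frame_interval
    truth = SimTruth(
        seed=seed,
        kind="translocation_track",
        params={
            "v_mean": v_mean,
            "v_sd": v_sd,
            "pause_prob_per_frame": pause_prob_per_frame,
            "pause_len_frames": [lo, hi],
            "terminate_prob_per_frame": terminate_prob_per_frame,
            "frame_interval": config.frame_interval,
            "bp_per_pixel": config.bp_per_pixel,
        },
        per_object={
            "velocity_bp_s": v,
            "step_px_per_frame": step,
            "pauses": pauses,
            "termination_frame": terminated_frame,
            "start_position": start_position,
        },
    )
    track = TranslocationTrack(positions=positions, times=times)
    return track, truth


def render_kymograph(
    tracks: Sequence[TranslocationTrack],
    psf_sd: float = 1.2,
    noise_sd: float = 0.0,
    background: float = 0.0,
    config: Optional[ImagingConfig] = None,
    seed: int = 0,
    amplitudes: Optional[Sequence[float]] = None,
    stack: bool = False,
):
    """Render tracks into a kymograph (optionally via a full image stack).

    Each frame row is background + a Gaussian line profile (SD ``psf_sd``
    pixels) centered at every live track's position + Gaussian noise.  With
    ``stack=True`` a per-frame 2-D stack is rendered instead (particles sit
    on the center row) and the returned kymograph is extracted from it along
    that row, so the pair is consistent by construction.

    Returns ``Kymograph`` or ``(Kymograph, stack)``.
    """
    if config is None:
        config = ImagingConfig.two_color()
    height, width = config.shape
    if len(tracks) > 0:
        n_frames = tracks[0].n_frames
        if any(tr.n_frames != n_frames for tr in tracks):
            raise ValueError("all tracks must cover the same frame range")
        for tr in tracks:
            if tr.positions.min() < 0 or tr.positions.max() > width - 1:
                raise ValueError("track positions fall outside the image bounds")
    else:
        n_frames = config.frames
    if n_frames < 2:
        raise ValueError("need >= 2 frames")
    if amplitudes is None:
        amplitudes = [500.0] * len(tracks)

    rng = np.random.default_rng(seed)
    xs = np.arange(width, dtype=float)

    def profile_1d():
        out = np.full((n_frames, width), float(background))
        for tr, amp in zip(tracks, amplitudes):
            d = xs[None, :] - tr.positions[:, None]
            out += amp * np.exp(-(d**2) / (2.0 * psf_sd**2))
        return out

    if not stack:
        data = profile_1d()
        if noise_sd > 0:
            data = data + rng.normal(0.0, noise_sd, data.shape)
        return Kymograph(
            data=data,
            frame_interval=config.frame_interval,
            bp_per_pixel=config.bp_per_pixel,
            roi="rendered",
        )

    row = height // 2
    ys = np.arange(height, dtype=float)
    imgs = np.full((n_frames, height, width), float(background))
    for tr, amp in zip(tracks, amplitudes):
        dx2 = (xs[None, None, :] - tr.positions[:, None, None]) ** 2
        dy2 = ((ys - row) ** 2)[None, :, None]
        imgs += amp * np.exp(-(dx2 + dy2) / (2.0 * psf_sd**2))
    if noise_sd > 0:
        imgs = imgs + rng.normal(0.0, noise_sd, imgs.shape)
    roi = np.stack([np.full(width, row, dtype=int), np.arange(width)], axis=1)
    kymo = extract_kymograph(imgs, roi, config)
    return kymo, imgs


def calibrate_track_regime(
    mean_velocity: float,
    sd_velocity: float,
    mean_track_length_kb: float,
    config: Optional[ImagingConfig] = None,
    move_threshold_px: float = 2.0,
) -> dict:
    """Generator parameters whose *observed* track ensemble has the given means.

    The kinematics pipeline only scores tracks that move more than
    ``move_threshold_px`` before terminating, and measures displacement from
    that crossing point on.  With a per-frame termination probability ``p``
    the number of moving frames is geometric and memoryless, so for a track
    of velocity ``v`` the expected measured length is ``v * dt / p``
    (independent of the crossing point) and the expected observed mean
    length is ``E_w[v] * dt / p``, where the expectation weights each
    velocity by its probability ``(1-p)**n_c(v)`` of surviving to the
    crossing frame ``n_c(v)``.  This fixes ``p`` from the target means, and
    the requested generator mean velocity is then solved so the
    selection-weighted mean equals the target.

    Returns ``{"v_mean": ..., "v_sd": ..., "terminate_prob": ...}`` for
    :func:`simulate_translocation_track`.
    """
    if config is None:
        config = ImagingConfig.two_color()
    dt = config.frame_interval
    bpp = config.bp_per_pixel
    p = mean_velocity * dt / (mean_track_length_kb * 1000.0)
    if not 0 < p < 1:
        raise ValueError("targets imply an invalid termination probability")

    def n_cross(v: np.ndarray) -> np.ndarray:
        # first frame index at which cumulative displacement exceeds threshold
        return np.floor(move_threshold_px * bpp / (v * dt)) + 1.0

    def weighted_mean(request_mean: float) -> float:
        mu = truncated_normal_location(request_mean, sd_velocity)
        a = -mu / sd_velocity
        grid = np.linspace(1e-3, request_mean + 8 * sd_velocity, 4000)
        f = stats.truncnorm.pdf(grid, a, np.inf, loc=mu, scale=sd_velocity)
        w = (1.0 - p) ** n_cross(grid)
        return float(np.trapezoid(grid * w * f, grid) / np.trapezoid(w * f, grid))

    m_star = float(
        optimize.brentq(
            lambda m: weighted_mean(m) - mean_velocity,
            max(1e-2, 0.3 * mean_velocity),
            mean_velocity * 1.001,
            xtol=1e-6,
        )
    )
    return {"v_mean": m_star, "v_sd": sd_velocity, "terminate_prob": p}


# ---------------------------------------------------------------------------
# two-color fields and colony counts
# ---------------------------------------------------------------------------

def simulate_two_color(
    n_points: int,
    coloc_fraction: float,
    intensity_corr: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    field_size: float = 512.0,
    intensity_mean: float = 1000.0,
    intensity_sd: float = 150.0,
) -> tuple[dict, SimTruth]:
    """Two-channel point/intensity fields with known matching.

    A ``coloc_fraction`` share of channel-A points receives a channel-B
    partner displaced by an isotropic Gaussian of SD ``jitter_sd`` pixels;
    the remaining B points are placed uniformly.  Matched intensity pairs
    are bivariate normal with Pearson correlation ``intensity_corr``.
    """
    if not 0 <= coloc_fraction <= 1:
        raise ValueError("coloc_fraction must lie in [0, 1]")
    if abs(intensity_corr) > 1:
        raise ValueError("|intensity correlation| must be <= 1")
    rng = np.random.default_rng(seed)

    points_a = rng.uniform(0, field_size, (n_points, 2))
    n_matched = int(round(coloc_fraction * n_points))
    matched_flags = np.zeros(n_points, dtype=bool)
    matched_flags[:n_matched] = True

    partners = points_a[:n_matched] + rng.normal(0, jitter_sd, (n_matched, 2))
    strays = rng.uniform(0, field_size, (n_points - n_matched, 2))
    points_b = np.vstack([partners, strays])

    rho = intensity_corr
    cov = (intensity_sd**2) * np.array([[1.0, rho], [rho, 1.0]])
    pair_int = rng.multivariate_normal([intensity_mean] * 2, cov, n_matched)
    intensities_a = np.empty(n_points)
    intensities_a[:n_matched] = pair_int[:, 0]
    intensities_a[n_matched:] = rng.normal(
        intensity_mean, intensity_sd, n_points - n_matched
    )
    intensities_b = np.empty(points_b.shape[0])
    intensities_b[:n_matched] = pair_int[:, 1]
    intensities_b[n_matched:] = rng.normal(
        intensity_mean, intensity_sd, n_points - n_matched
    )

    data = {
        "points_a": points_a,
        "intensities_a": intensities_a,
        "points_b": points_b,
        "intensities_b": intensities_b,
    }
    truth = SimTruth(
        seed=seed,
        kind="two_color",
        params={
            "n_points": n_points,
            "coloc_fraction": coloc_fraction,
            "intensity_corr": intensity_corr,
            "jitter_sd": jitter_sd,
            "field_size": field_size,
        },
        per_object={"matched": matched_flags, "n_matched": n_matched},
    )
    return data, truth


def simulate_colony_counts(
    true_frequency: float,
    cells_plated_selective: float,
    dilution_factor: float,
    cells_plated_nonselective: float,
    n_replicates: int,
    seed: int = 0,
) -> tuple[ColonyCounts, SimTruth]:
    """Poisson plate counts for a frequency assay.

    Selective counts ~ Poisson(true_frequency * cells_plated_selective);
    non-selective counts ~ Poisson(cells_plated_nonselective / dilution).
    """
    if not 0 <= true_frequency <= 1:
        raise ValueError("true_frequency must lie in [0, 1]")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    rng = np.random.default_rng(seed)
    sel = rng.poisson(true_frequency * cells_plated_selective, n_replicates)
    nonsel = rng.poisson(cells_plated_nonselective / dilution_factor, n_replicates)
    counts = ColonyCounts(
        selective=sel, nonselective=nonsel, dilution_factor=dilution_factor
    )
    truth = SimTruth(
        seed=seed,
        kind="colony_counts",
        params={
            "true_frequency": true_frequency,
            "cells_plated_selective": cells_plated_selective,
            "dilution_factor": dilution_factor,
            "cells_plated_nonselective": cells_plated_nonselective,
            "n_replicates": n_replicates,
        },
        per_object={"selective": sel, "nonselective": nonsel},
    )
    return counts, truth
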