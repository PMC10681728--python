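"""Generator determinism, conservation laws, and distributional recovery."""

import numpy as np
import pytest

from curtainkit import simgen
from curtainkit.config import ConfigurationError, ImagingConfig


class TestPhotobleachTraces:
    def test_no_bleach_no_noise_is_constant(self):
        tr, _ = simgen.simulate_photobleach_trace(
            3, 100.0, 0.0, 0.0, 0.0, 50.0, seed=0
        )
        assert np.all(tr.values == 350.0)

    def test_empty_cluster_is_background(self):
        tr, _ = simgen.simulate_photobleach_trace(0, 100.0, 0.0, 0.1, 0.0, 42.0, seed=0)
        assert np.all(tr.values == 42.0)

    def test_conservation_noiseless(self):
        """With unit_sd = noise_sd = 0 the trace equals background +
        unit * (survivors) exactly, frame by frame."""
        cfg = ImagingConfig.unshuttered(frames=400)
        tr, truth = simgen.simulate_photobleach_trace(
            4, 100.0, 0.0, 0.05, 0.0, 50.0, cfg, seed=3
        )
        times = np.arange(cfg.frames) * cfg.frame_interval
        survivors = (truth.per_object["bleach_times_s"][None, :] > times[:, None]).sum(1)
        assert np.allclose(tr.values, 50.0 + 100.0 * survivors)

    def test_first_bleach_time_matches_exponential_order_statistic(self):
        """Minimum of 5 exponential(0.1/s) clocks has mean 1/(5*0.1) = 2 s."""
        firsts = []
        for s in range(4000):
            _, truth = simgen.simulate_photobleach_trace(
                5, 100.0, 0.0, 0.1, 0.0, 0.0,
                ImagingConfig.unshuttered(frames=2), seed=s,
            )
            firsts.append(truth.per_object["bleach_times_s"].min())
        firsts = np.array(firsts)
        se = firsts.std(ddof=1) / np.sqrt(firsts.size)
        assert abs(firsts.mean() - 2.0) < 3 * se

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            simgen.simulate_photobleach_trace(-1, 100, 0, 0.1, 0, 0, seed=0)
        with pytest.raises(ValueError):
            simgen.simulate_photobleach_trace(2, -5.0, 0, 0.1, 0, 0, seed=0)


class TestClusterFields:
    def test_fixed_size_noiseless_intensity(self):
        records, _ = simgen.simulate_cluster_field(
            ("fixed", {"size": 7}), 10, 100.0, 0.0, 50.0, 0.0, seed=1
        )
        assert all(r.intensity == 50.0 + 700.0 for r in records)

    def test_empirical_frequencies_converge(self):
        probs = {2: 0.59, 4: 0.26, 1: 0.07, 3: 0.07}
        records, truth = simgen.simulate_cluster_field(
            ("empirical", {"probs": probs}), 10_000, 100, 10, 50, 20, seed=2
        )
        sizes = truth.per_object["sizes"]
        for k, p in probs.items():
            se = np.sqrt(p * (1 - p) / sizes.size)
            assert abs((sizes == k).mean() - p) < 3 * se

    def test_lognormal_median_at_cohort_scale(self):
        records, truth = simgen.simulate_cluster_field(
            ("lognormal", {"median": 7.0, "sigma": 0.6}),
            201, 100, 10, 50, 20, seed=4,
        )
        assert abs(np.median(truth.per_object["sizes"]) - 7.0) <= 1.0

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError, match="unknown size distribution"):
            simgen.simulate_cluster_field(("cauchy", {}), 5, 100, 0, 0, 0, seed=0)


class TestTranslocationTracks:
    def test_deterministic_velocity_advances_exactly(self):
        cfg = ImagingConfig.two_color(frames=50)
        track, _ = simgen.simulate_translocation_track(
            100.0, 0.0, 0.0, (2, 4), 0.0, cfg, seed=0
        )
        assert np.allclose(np.diff(track.positions), 0.04)  # 100*0.4/1000

    def test_immediate_termination_is_stationary(self):
        track, truth = simgen.simulate_translocation_track(
            100.0, 0.0, 0.0, (2, 4), 1.0, ImagingConfig.two_color(frames=50), seed=0
        )
        assert np.all(track.positions == track.positions[0])
        assert truth.per_object["termination_frame"] == 1

    def test_velocity_sample_mean_matches_configured_mean(self):
        """The truncated-at-zero velocity distribution is parameterized so
        its mean equals v_mean; the ensemble mean must agree within 3 SE."""
        cfg = ImagingConfig.two_color(frames=2)
        vs = []
        for s in range(8000):
            _, truth = simgen.simulate_translocation_track(
                81.7, 51.0, 0.0, (2, 4), 0.0, cfg, seed=s
            )
            vs.append(truth.per_object["velocity_bp_s"])
        vs = np.array(vs)
        assert np.all(vs >= 0)
        se = vs.std(ddof=1) / np.sqrt(vs.size)
        assert abs(vs.mean() - 81.7) < 3 * se

    def test_pauses_freeze_position(self):
        cfg = ImagingConfig.two_color(frames=400)
        track, truth = simgen.simulate_translocation_track(
            100.0, 0.0, 0.3, (2, 4), 0.0, cfg, seed=7
        )
        pauses = truth.per_object["pauses"]
        assert pauses, "pause probability 0.3 must generate pauses"
        for start, stop in pauses:
            stop = min(stop, cfg.frames - 1)
            frozen = track.positions[start - 1 : stop + 1]
            assert np.all(frozen == frozen[0])

    def test_pause_length_outside_paper_range_rejected(self):
        with pytest.raises(ConfigurationError):
            simgen.simulate_translocation_track(
                100.0, 0.0, 0.1, (2, 6), 0.0, seed=0
            )


class TestKymographRendering:
    def test_stationary_particle_is_constant_ridge(self, two_color_cfg):
        from curtainkit.kymo import TranslocationTrack

        pos = np.full(two_color_cfg.frames, 40.0)
        track = TranslocationTrack(
            positions=pos, times=np.arange(pos.size) * 0.4
        )
        kymo = simgen.render_kymograph(
            [track], psf_sd=1.2, noise_sd=0.0, background=5.0,
            config=two_color_cfg, seed=0,
        )
        assert np.allclose(kymo.data, kymo.data[0])  # every row identical
        assert kymo.data[0].argmax() == 40

    def test_zero_tracks_is_pure_background(self, two_color_cfg):
        kymo = simgen.render_kymograph(
            [], background=7.0, config=two_color_cfg, seed=0
        )
        assert np.all(kymo.data == 7.0)

    def test_stack_mode_consistent_with_extraction(self, two_color_cfg):
        from curtainkit.kymo import TranslocationTrack, extract_kymograph

        pos = 20.0 + 0.05 * np.arange(two_color_cfg.frames)
        track = TranslocationTrack(positions=pos, times=np.arange(pos.size) * 0.4)
        kymo, stack = simgen.render_kymograph(
            [track], psf_sd=1.2, noise_sd=2.0, background=10.0,
            config=two_color_cfg, seed=5, stack=True,
        )
        row = two_color_cfg.shape[0] // 2
        roi = np.stack(
            [np.full(two_color_cfg.shape[1], row), np.arange(two_color_cfg.shape[1])],
            axis=1,
        )
        again = extract_kymograph(stack, roi, two_color_cfg)
        assert np.array_equal(kymo.data, again.data)

    def test_out_of_bounds_track_rejected(self, two_color_cfg):
        from curtainkit.kymo import TranslocationTrack

        pos = np.full(two_color_cfg.frames, 1e4)
        track = TranslocationTrack(positions=pos, times=np.arange(pos.size) * 0.4)
        with pytest.raises(ValueError, match="bounds"):
            simgen.render_kymograph([track], config=two_color_cfg, seed=0)


class TestTwoColor:
    def test_full_colocalization_zero_jitter_identical_coordinates(self):
        data, _ = simgen.simulate_two_color(50, 1.0, 0.0, 0.0, seed=0)
        assert np.array_equal(data["points_a"], data["points_b"])

    def test_perfect_correlation_is_collinear(self):
        data, _ = simgen.simulate_two_color(50, 1.0, 1.0, 0.0, seed=1)
        r = np.corrcoef(data["intensities_a"], data["intensities_b"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_truth_counts_matched_share(self):
        _, truth = simgen.simulate_two_color(142, 0.93, 0.5, 0.3, seed=2)
        assert truth.per_object["n_matched"] == round(0.93 * 142)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            simgen.simulate_two_color(10, 1.5, 0.0, 0.0, seed=0)


class TestColonyCounts:
    def test_zero_frequency_gives_zero_selective_counts(self):
        counts, _ = simgen.simulate_colony_counts(0.0, 1e6, 1e4, 1e6, 20, seed=0)
        assert np.all(counts.selective == 0)

    def test_poisson_mean_of_selective_counts(self):
        freq, cells = 1.03e-5, 3e6
        counts, _ = simgen.simulate_colony_counts(freq, cells, 1e4, 3e6, 10_000, seed=1)
        lam = freq * cells
        se = np.sqrt(lam / counts.n_replicates)
        assert abs(counts.selective.mean() - lam) < 3 * se


class TestDeterminism:
    @pytest.mark.parametrize("seed", [0, 123])
    def test_identical_seed_identical_outputs(self, seed):
        a1, _ = simgen.simulate_photobleach_trace(3, 100, 10, 0.05, 20, 50, seed=seed)
        a2, _ = simgen.simulate_photobleach_trace(3, 100, 10, 0.05, 20, 50, seed=seed)
        assert np.array_equal(a1.values, a2.values)

        f1, t1 = simgen.simulate_cluster_field(
            ("lognormal", {"median": 7, "sigma": 0.6}), 20, 100, 10, 50, 20, seed=seed
        )
        f2, t2 = simgen.simulate_cluster_field(
            ("lognormal", {"median": 7, "sigma": 0.6}), 20, 100, 10, 50, 20, seed=seed
        )
        assert np.array_equal(t1.per_object["sizes"], t2.per_object["sizes"])
        assert [r.intensity for r in f1] == [r.intensity for r in f2]

        k1, _ = simgen.simulate_translocation_track(80, 50, 0.1, (2, 4), 0.01, seed=seed)
        k2, _ = simgen.simulate_translocation_track(80, 50, 0.1, (2, 4), 0.01, seed=seed)
        assert np.array_equal(k1.positions, k2.positions)

        d1, _ = simgen.simulate_two_color(30, 0.8, 0.4, 0.2, seed=seed)
        d2, _ = simgen.simulate_two_color(30, 0.8, 0.4, 0.2, seed=seed)
        assert np.array_equal(d1["points_b"], d2["points_b"])

        c1, _ = simgen.simulate_colony_counts(1e-5, 1e6, 1e4, 1e6, 5, seed=seed)
        c2, _ = simgen.simulate_colony_counts(1e-5, 1e6, 1e4, 1e6, 5, seed=seed)
        assert np.array_equal(c1.selective, c2.selective)
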