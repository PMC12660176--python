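"""Generator tests: geometry, distributions, rendering, movies, pulse-chase."""

import numpy as np
import pytest

from quantalmap import simulate
from quantalmap.simulate import (GroundTruth, MovieSpec, make_geometry,
                                 render_puncta_stack,
                                 simulate_photoconversion_series,
                                 simulate_quantal_movie)


class TestGeometry:
    def test_degenerate_distributions_give_constant_parameters(self):
        gt = make_geometry(1, 10, pr_distribution=("constant", {"value": 0.2}),
                           spont_distribution=("constant", {"value": 0.5}),
                           cac_negative_fraction=0.0, seed=1)
        assert gt.n_az == 10
        assert np.all(gt.true_pr == 0.2)
        assert np.all(gt.true_spont_rate == 0.5)

    def test_all_cac_negative_forces_zero_pr_nonzero_spont(self):
        gt = make_geometry(2, 5, pr_distribution=("uniform", {"low": 0.1,
                                                              "high": 0.5}),
                           cac_negative_fraction=1.0, seed=2)
        assert np.all(~gt.cac_positive)
        assert np.all(gt.true_pr == 0.0)
        assert np.all(gt.true_spont_rate > 0)

    def test_pr_spread_matches_seeded_redraw(self):
        """The Pr draw comes from a dedicated child stream of the seed."""
        gt = make_geometry(3, 15, pr_distribution=("uniform", {"low": 0.0,
                                                               "high": 0.5}),
                           cac_negative_fraction=0.0, seed=7)
        oracle_rng = np.random.default_rng(
            np.random.SeedSequence(7).spawn(4)[1])
        oracle = oracle_rng.uniform(0.0, 0.5, 45)
        assert np.allclose(gt.true_pr, oracle)
        assert (gt.true_pr.max() - gt.true_pr.min()
                == pytest.approx(oracle.max() - oracle.min()))

    def test_deterministic_and_inside_field(self):
        a = make_geometry(3, 8, seed=11)
        b = make_geometry(3, 8, seed=11)
        assert np.array_equal(a.az_centroids, b.az_centroids)
        assert np.array_equal(a.true_pr, b.true_pr)
        ny, nx = a.field_shape
        assert np.all(a.az_centroids >= 0)
        assert np.all(a.az_centroids[:, 0] <= nx * a.pixel_size)
        assert np.all(a.az_centroids[:, 1] <= ny * a.pixel_size)
        # AZ spacing floor within each bouton
        from scipy.spatial.distance import pdist
        for b_idx in range(3):
            pts = a.az_centroids[a.bouton_index == b_idx]
            assert pdist(pts).min() >= 1.0 - 1e-9

    def test_psd_pairing_and_orphans(self):
        gt = make_geometry(2, 6, seed=5)
        assert len(gt.psd_centroids) == gt.n_az
        gt2 = make_geometry(2, 6, seed=5, orphan_psd_fraction=0.5)
        assert len(gt2.psd_centroids) == gt2.n_az + 6

    @pytest.mark.parametrize("kwargs", [
        {"n_boutons": 0, "az_per_bouton": 5},
        {"n_boutons": 2, "az_per_bouton": 5, "cac_negative_fraction": 1.5},
        {"n_boutons": 2, "az_per_bouton": 5,
         "pr_distribution": ("uniform", {"low": 0.5, "high": 0.1})},
        {"n_boutons": 2, "az_per_bouton": 5,
         "pr_distribution": ("nosuch", {})},
        {"n_boutons": 2, "az_per_bouton": 5, "growth_mode": "spiral"},
    ])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            make_geometry(seed=1, **kwargs)

    def test_ground_truth_invariants_enforced(self, two_spot_gt):
        with pytest.raises(ValueError):
            GroundTruth(
                az_centroids=two_spot_gt.az_centroids,
                psd_centroids=two_spot_gt.psd_centroids,
                true_pr=np.array([0.5, 1.5]),  # out of range
                true_spont_rate=two_spot_gt.true_spont_rate,
                age_days=two_spot_gt.age_days,
                cac_positive=two_spot_gt.cac_positive,
                bouton_index=two_spot_gt.bouton_index,
                pixel_size=0.133, field_shape=(64, 64), seed=0)


class TestRenderPuncta:
    def test_single_spot_peaks_at_centroid(self, two_spot_gt):
        stack = render_puncta_stack(two_spot_gt, "az", noise_sd=0.0,
                                    background=0.0, seed=0)
        proj = stack.max(axis=0)
        for x, y in two_spot_gt.az_centroids:
            px = two_spot_gt.pixel_size
            win = proj[int(y / px) - 3:int(y / px) + 4,
                       int(x / px) - 3:int(x / px) + 4]
            iy, ix = np.unravel_index(win.argmax(), win.shape)
            assert abs(iy - 3) <= 1 and abs(ix - 3) <= 1

    def test_empty_geometry_renders_pure_noise(self, two_spot_gt):
        empty = GroundTruth(
            az_centroids=np.empty((0, 2)), psd_centroids=np.empty((0, 2)),
            true_pr=np.empty(0), true_spont_rate=np.empty(0),
            age_days=np.empty(0), cac_positive=np.empty(0, bool),
            bouton_index=np.empty(0, int),
            pixel_size=0.133, field_shape=(32, 32), seed=0)
        stack = render_puncta_stack(empty, "az", noise_sd=2.0,
                                    background=50.0, seed=1)
        assert stack.shape == (5, 32, 32)
        assert abs(stack.mean() - 50.0) < 1.0

    def test_spot_sum_ratio_tracks_requested_intensity(self, two_spot_gt):
        """Background-subtracted integrated spot intensities scale linearly."""
        stack = render_puncta_stack(two_spot_gt, "az",
                                    per_spot_intensity=np.array([1.0, 2.0]),
                                    intensity_per_unit=100.0,
                                    noise_sd=0.0, background=0.0, seed=0)
        proj = stack.max(axis=0)
        half = proj.shape[1] // 2  # spots sit in opposite field quadrants
        s1 = proj[:half, :half].sum()
        s2 = proj[half:, half:].sum()
        assert s2 / s1 == pytest.approx(2.0, rel=0.01)

    def test_centroid_outside_field_raises(self, two_spot_gt):
        bad = np.array([[100.0, 100.0]])
        with pytest.raises(ValueError, match="outside"):
            simulate._render_stack(bad, np.array([1.0]), (32, 32), 0.133,
                                   0.3, 0.0, 3, 0.0,
                                   np.random.default_rng(0))


class TestQuantalMovie:
    def test_certain_release_no_spont(self, two_spot_gt):
        gt = two_spot_gt
        gt.true_pr = np.array([1.0, 1.0])
        gt.true_spont_rate = np.array([0.0, 0.0])
        spec = MovieSpec(duration=10.0, noise_sd=0.0)
        _, events, info = simulate_quantal_movie(gt, spec, seed=1,
                                                 render=False)
        assert info["n_stimulations"] == 10
        assert len(events) == 20
        assert (events["kind"] == "evoked").all()
        assert events.groupby("az_id").size().tolist() == [10, 10]

    def test_silent_nmj_flat_movie(self, two_spot_gt):
        gt = two_spot_gt
        gt.true_pr = np.array([0.0, 0.0])
        gt.true_spont_rate = np.array([0.0, 0.0])
        gt.cac_positive = np.array([False, False])
        movie, events, _ = simulate_quantal_movie(
            gt, MovieSpec(duration=5.0, noise_sd=0.0), seed=1)
        assert len(events) == 0
        assert np.all(movie == movie.flat[0])

    def test_evoked_count_matches_binomial_oracle(self, two_spot_gt):
        """Per-AZ Bernoulli draws come from per-AZ child streams."""
        gt = two_spot_gt
        gt.true_pr = np.array([0.2, 0.2])
        gt.true_spont_rate = np.array([0.0, 0.0])
        spec = MovieSpec(duration=300.0)
        _, events, _ = simulate_quantal_movie(gt, spec, seed=9, render=False)
        streams = np.random.SeedSequence(9).spawn(3)
        for az in (0, 1):
            rng = np.random.default_rng(streams[az + 1])
            oracle = int((rng.uniform(size=300) < 0.2).sum())
            assert (events["az_id"] == az).sum() == oracle

    def test_mean_evoked_count_near_binomial_expectation(self, two_spot_gt):
        gt = two_spot_gt
        gt.true_pr = np.array([0.2, 0.0])
        gt.cac_positive = np.array([True, False])
        gt.true_spont_rate = np.array([0.0, 0.1])
        counts = []
        for s in range(200):
            _, ev, _ = simulate_quantal_movie(
                gt, MovieSpec(duration=300.0), seed=s, render=False)
            counts.append((ev["az_id"] == 0).sum())
        se = np.sqrt(300 * 0.2 * 0.8 / 200)
        assert abs(np.mean(counts) - 60.0) <= 3 * se

    def test_spontaneous_events_avoid_stimulus_frames(self, two_spot_gt):
        gt = two_spot_gt
        gt.true_pr = np.array([0.0, 0.0])
        gt.cac_positive = np.array([False, False])
        gt.true_spont_rate = np.array([30.0, 30.0])
        spec = MovieSpec(duration=60.0)
        _, events, info = simulate_quantal_movie(gt, spec, seed=4,
                                                 render=False)
        assert len(events) > 0
        assert not np.isin(events["frame"], info["stim_frames"]).any()

    def test_rendered_flashes_match_event_log_at_zero_noise(self, two_spot_gt):
        gt = two_spot_gt
        gt.true_pr = np.array([0.3, 0.3])
        gt.true_spont_rate = np.array([2.0, 2.0])
        spec = MovieSpec(duration=30.0, noise_sd=0.0)
        movie, events, _ = simulate_quantal_movie(gt, spec, seed=6)
        flash_frames = set()
        for f in events["frame"]:
            flash_frames.update(range(f, min(f + spec.flash_decay_frames,
                                             movie.shape[0])))
        bright = movie.max(axis=(1, 2)) > spec.background + 1e-3
        assert set(np.nonzero(bright)[0]) == flash_frames
        # frames with a fresh flash carry (at least) the full amplitude
        for f in np.unique(events["frame"]):
            assert movie[f].max() >= spec.background + 0.9 * spec.flash_amplitude

    def test_movie_determinism(self, two_spot_gt):
        spec = MovieSpec(duration=10.0)
        m1, e1, _ = simulate_quantal_movie(two_spot_gt, spec, seed=5)
        m2, e2, _ = simulate_quantal_movie(two_spot_gt, spec, seed=5)
        assert np.array_equal(m1, m2)
        assert e1.equals(e2)

    @pytest.mark.parametrize("bad", [
        MovieSpec(frame_rate=1.0, stim_rate=2.0),
        MovieSpec(duration=-1.0),
        MovieSpec(flash_amplitude=0.0),
    ])
    def test_invalid_spec_raises(self, two_spot_gt, bad):
        with pytest.raises(ValueError):
            simulate_quantal_movie(two_spot_gt, bad, seed=1)


class TestPhotoconversion:
    def test_red_decay_follows_half_life(self, two_spot_gt):
        series = simulate_photoconversion_series(two_spot_gt, 1.0, [0, 1],
                                                 seed=1)
        assert np.allclose(series.red_true[1], 0.5 * series.red_true[0])
        series = simulate_photoconversion_series(two_spot_gt, 2.197, [0, 1],
                                                 seed=1)
        ratio = series.red_true[1] / series.red_true[0]
        assert np.allclose(ratio, 2 ** (-1 / 2.197))
        assert ratio[0] == pytest.approx(0.7294, abs=5e-4)

    def test_complete_conversion_at_t0(self, two_spot_gt):
        """Red at t=0 equals the pre-PC green pool; green restarts at zero."""
        series = simulate_photoconversion_series(two_spot_gt, 2.0, [0, 1],
                                                 seed=2)
        assert np.allclose(series.red_true[0], series.pre_pc_green)
        assert np.allclose(series.green_true[0], 0.0)
        assert np.all(series.green_true[1] > 0)

    @pytest.mark.parametrize("kwargs", [
        {"half_life_days": 0.0, "timepoints": [0, 1]},
        {"half_life_days": 1.0, "timepoints": [-1, 0]},
        {"half_life_days": 1.0, "timepoints": [1, 0]},
    ])
    def test_invalid_series_raises(self, two_spot_gt, kwargs):
        with pytest.raises(ValueError):
            simulate_photoconversion_series(two_spot_gt, seed=1, **kwargs)
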