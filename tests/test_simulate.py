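"""Generator contracts: ground truth is exact where promised."""

import numpy as np
import pytest

from nucleomech import SimConfig
from nucleomech.afm import NM, TipModel, baseline_correct, to_indentation
from nucleomech.simulate import (
    CondensateTruth,
    HertzTruth,
    OccupancyTruth,
    TrackTruth,
    gen_boundary_movie,
    gen_condensate_image,
    gen_force_curve,
    gen_nucleus_volume,
    gen_peak_table,
    gen_tracks,
)


class TestBoundaryMovie:
    def test_static_movie_has_identical_frames(self):
        cfg = SimConfig(seed=0)
        movie, truth = gen_boundary_movie(cfg, n_frames=5, sigma=0.0,
                                          drift_rate=0.0, bleach_rate=0.0)
        assert np.array_equal(movie[0], movie[-1])
        assert np.ptp(truth.radial_position) == 0.0

    def test_ou_stationary_std_matches_sigma(self):
        # long-run per-angle std, averaged over independent angles
        cfg = SimConfig(seed=1)
        _, truth = gen_boundary_movie(cfg, n_angles=16, n_frames=2000,
                                      sigma=0.1, tau=1.0)
        per_angle = truth.radial_position.std(axis=1, ddof=1)
        assert np.mean(per_angle) == pytest.approx(0.1, rel=0.10)

    def test_bleach_decay_closed_form(self):
        cfg = SimConfig(seed=2)
        movie, _ = gen_boundary_movie(cfg, n_frames=500, sigma=0.0,
                                      bleach_rate=0.001)
        ratio = movie[-1].mean() / movie[0].mean()
        assert ratio == pytest.approx(np.exp(-0.001 * 499), rel=1e-5)

    def test_invalid_geometry_rejected(self):
        cfg = SimConfig(seed=0)
        with pytest.raises(ValueError):
            gen_boundary_movie(cfg, R0=-1.0)
        with pytest.raises(ValueError):
            gen_boundary_movie(cfg, psf_sigma=0.0)
        with pytest.raises(ValueError):
            gen_boundary_movie(cfg, n_frames=1)


class TestTracks:
    def test_frozen_particles(self):
        ts = gen_tracks(SimConfig(seed=0), 5, 20, TrackTruth(D_true=0.0))
        for _, g in ts.groups():
            assert np.ptp(g["x"]) == 0.0 and np.ptp(g["y"]) == 0.0

    def test_brownian_ensemble_msd_first_lag(self):
        cfg = SimConfig(seed=1, frame_interval=0.1)
        ts = gen_tracks(cfg, 200, 100, TrackTruth(D_true=0.5, alpha_true=1.0))
        disp = []
        for _, g in ts.groups():
            xy = g[["x", "y"]].to_numpy()
            disp.append(np.sum(np.diff(xy, axis=0) ** 2, axis=1))
        assert np.mean(np.concatenate(disp)) == pytest.approx(0.2, rel=0.1)

    def test_ballistic_limit_is_straight_line(self):
        ts = gen_tracks(SimConfig(seed=2, frame_interval=0.1), 5, 50,
                        TrackTruth(D_true=0.3, alpha_true=2.0))
        for _, g in ts.groups():
            x = g["x"].to_numpy()
            # second differences vanish on a straight line
            assert np.abs(np.diff(x, 2)).max() < 1e-10

    def test_confinement_bounds_positions(self):
        ts = gen_tracks(SimConfig(seed=3, frame_interval=0.1), 20, 200,
                        TrackTruth(D_true=1.0, confinement_radius=1.0))
        r = np.hypot(ts.data["x"], ts.data["y"])
        assert r.max() <= 1.0 + 1e-9

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            TrackTruth(D_true=1.0, alpha_true=2.5)
        with pytest.raises(ValueError):
            TrackTruth(D_true=1.0, alpha_true=0.0)


class TestCondensateImage:
    def test_no_clusters_means_uniform_marker(self):
        from nucleomech.condensates import cluster_enrichment

        marker, _, nmask, cmask = gen_condensate_image(
            SimConfig(seed=0), truth=CondensateTruth(n_clusters=0))
        assert cmask.sum() == 0
        score = cluster_enrichment(marker, nmask, cmask)
        assert score.cluster_enrichment == 1.0

    def test_enrichment_exact_on_truth_masks(self):
        marker, _, nmask, cmask = gen_condensate_image(
            SimConfig(seed=1),
            truth=CondensateTruth(n_clusters=5, enrichment_true=3.0))
        ratio = marker[cmask].mean() / marker[nmask].mean()
        assert ratio == pytest.approx(3.0, abs=1e-12)

    def test_peripheral_bias_one_places_centers_at_rim(self):
        a, b = 6.0, 4.5
        marker, _, nmask, cmask = gen_condensate_image(
            SimConfig(seed=2), nucleus_axes=(a, b),
            truth=CondensateTruth(n_clusters=8, peripheral_bias=1.0,
                                  cluster_radius=0.2))
        from skimage.measure import label, regionprops

        px = SimConfig(seed=2).pixel_size
        cy = (nmask.shape[0] - 1) / 2
        cx = (nmask.shape[1] - 1) / 2
        for p in regionprops(label(cmask)):
            y, x = p.centroid
            rho = np.sqrt((((x - cx) * px) / a) ** 2 + (((y - cy) * px) / b) ** 2)
            assert rho > 0.9

    def test_masks_are_binary_and_nested(self):
        marker, dna, nmask, cmask = gen_condensate_image(
            SimConfig(seed=3), truth=CondensateTruth(n_clusters=4))
        assert nmask.dtype == bool and cmask.dtype == bool
        assert not (cmask & ~nmask).any()
        assert (marker >= 0).all() and (dna >= 0).all()


class TestNucleusVolume:
    def test_sphere_closed_form(self):
        cfg = SimConfig(seed=0, voxel_size=(0.1, 0.1, 0.1))
        _, volume, _ = gen_nucleus_volume(cfg, (5.0, 5.0, 5.0))
        assert volume == pytest.approx(523.5988, abs=1e-3)

    def test_ellipsoid_closed_form(self):
        cfg = SimConfig(seed=0, voxel_size=(0.1, 0.1, 0.1))
        _, volume, _ = gen_nucleus_volume(cfg, (2.0, 4.0, 6.0))
        assert volume == pytest.approx(201.0619, abs=1e-3)

    def test_voxel_count_converges_to_analytic(self):
        cfg = SimConfig(seed=0, voxel_size=(0.1, 0.1, 0.1))
        vol, volume, _ = gen_nucleus_volume(cfg, (5.0, 5.0, 5.0))
        voxelized = vol.labels.astype(bool).sum() * vol.voxel_volume
        assert voxelized == pytest.approx(volume, rel=0.02)

    def test_zero_semi_axis_rejected(self):
        with pytest.raises(ValueError):
            gen_nucleus_volume(SimConfig(seed=0), (0.0, 4.0, 6.0))


class TestForceCurve:
    def test_zero_modulus_gives_pure_baseline(self):
        truth = HertzTruth(E_true=0.0, baseline_slope=2.0)
        curve = gen_force_curve(truth)
        assert np.allclose(curve.deflection, 2.0 * curve.z_piezo)

    def test_sphere_contact_law_closed_form(self):
        tip = TipModel("sphere", radius=0.02)
        truth = HertzTruth(E_true=1000.0, tip=tip)
        curve = gen_force_curve(truth, n_points=2000)
        corrected = baseline_correct(curve)
        ind = to_indentation(corrected, truth.contact_point_true)
        sel = ind.indentation > 1.0
        delta_m = ind.indentation[sel] * NM
        expected = (4 / 3) * (1000.0 / (1 - 0.25)) * np.sqrt(0.02e-6) * delta_m**1.5
        assert np.allclose(ind.force[sel], expected, rtol=1e-9)

    def test_invalid_spring_constant_rejected(self):
        with pytest.raises(ValueError):
            gen_force_curve(HertzTruth(E_true=100.0), k_spring=0.0)


class TestPeakTable:
    def test_zero_cv_gives_identical_replicates(self):
        truth = OccupancyTruth(condition_means=[[1.0, 0.5]], replicate_cv=0.0)
        table = gen_peak_table(SimConfig(seed=0), 50, ["a", "b"], 3, truth)
        means = table.condition_means()
        for cond in ("a", "b"):
            cols = table.sample_meta.index[table.sample_meta["condition"] == cond]
            assert np.allclose(table.signal[cols].std(axis=1), 0.0)

    def test_all_short_peaks_fail_size_filter(self):
        from nucleomech.genomics import size_signal_filter

        truth = OccupancyTruth(condition_means=[[1.0, 1.0]], replicate_cv=0.0)
        table = gen_peak_table(SimConfig(seed=1), 40, ["a", "b"], 2, truth,
                               frac_short=1.0)
        out = size_signal_filter(table)
        assert out.intervals.empty

    def test_intervals_non_overlapping_and_half_open(self):
        truth = OccupancyTruth(condition_means=[[1.0, 0.5]])
        table = gen_peak_table(SimConfig(seed=2), 200, ["a", "b"], 2, truth)
        iv = table.intervals.sort_values("start")
        assert (iv["start"] < iv["end"]).all()
        assert (iv["start"].to_numpy()[1:] >= iv["end"].to_numpy()[:-1]).all()


class TestDeterminism:
    @pytest.mark.parametrize("make", [
        lambda cfg: gen_boundary_movie(cfg, n_frames=5, sigma=0.05)[0],
        lambda cfg: gen_tracks(cfg, 5, 20, TrackTruth(D_true=0.5)).data,
        lambda cfg: gen_condensate_image(
            cfg, truth=CondensateTruth(n_clusters=3))[0],
        lambda cfg: gen_peak_table(
            cfg, 30, ["a", "b"], 2,
            OccupancyTruth(condition_means=[[1.0, 0.5]])).signal,
    ], ids=["boundary", "tracks", "condensate", "peaks"])
    def test_same_seed_bit_identical(self, make):
        a = make(SimConfig(seed=123))
        b = make(SimConfig(seed=123))
        va = a.to_numpy() if hasattr(a, "to_numpy") else a
        vb = b.to_numpy() if hasattr(b, "to_numpy") else b
        assert np.array_equal(va, vb)
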