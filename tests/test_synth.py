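"""Ground-truth consistency and determinism of the synthetic generators."""

import numpy as np
import pytest

from ccopheno.io import CalciumTrace
from ccopheno.synth import (
    CalciumSimParams,
    OrganoidSimParams,
    make_annulus_image,
    make_calcium_trace,
    make_count_matrix,
    make_organoid_video,
    transient_truth_times,
)


class TestAnnulusImage:
    def test_analytic_areas_are_pi_r_squared(self):
        _, areas = make_annulus_image(100, 50, image_size=256)
        assert areas["outer_area"] == pytest.approx(np.pi * 100**2)
        assert areas["inner_area"] == pytest.approx(np.pi * 50**2)
        wall_fraction = 1 - areas["inner_area"] / areas["outer_area"]
        assert wall_fraction == pytest.approx(0.75)

    def test_pixelated_areas_match_analytic_within_2pct(self):
        img, areas = make_annulus_image(100, 50, image_size=256)
        outer_px = float((img > 60).sum())
        inner_px = float((img > 160).sum())
        assert outer_px == pytest.approx(areas["outer_area"], rel=0.02)
        assert inner_px == pytest.approx(areas["inner_area"], rel=0.02)

    def test_solid_disk_when_inner_radius_zero(self):
        img, areas = make_annulus_image(80, 0, image_size=200)
        assert areas["inner_area"] == 0
        assert not (img > 160).any()  # no chamber-intensity pixels

    def test_intensity_zones(self):
        img, _ = make_annulus_image(60, 30, image_size=160, wall_intensity=120,
                                    chamber_intensity=200, background_intensity=40)
        c = (160 - 1) / 2
        assert img[int(c), int(c)] == 200          # chamber core
        assert img[int(c), int(c + 45)] == 120     # wall
        assert img[0, 0] == 40                     # background

    def test_radii_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_annulus_image(50, 60, image_size=200)
        with pytest.raises(ValueError):
            make_annulus_image(120, 50, image_size=200)

    def test_noise_deterministic_under_seed(self):
        a, _ = make_annulus_image(60, 30, image_size=160, noise_sd=5, seed=3)
        b, _ = make_annulus_image(60, 30, image_size=160, noise_sd=5, seed=3)
        np.testing.assert_array_equal(a, b)


class TestOrganoidVideo:
    def test_deterministic_under_seed(self):
        s1, t1 = make_organoid_video(OrganoidSimParams(seed=4, duration=3.0))
        s2, t2 = make_organoid_video(OrganoidSimParams(seed=4, duration=3.0))
        np.testing.assert_array_equal(s1.frames, s2.frames)
        np.testing.assert_array_equal(t1.beat_times, t2.beat_times)

    def test_zero_pulsation_gives_identical_frames_and_zero_fs(self):
        params = OrganoidSimParams(pulsation_fraction=0.0, noise_sd=0.0, duration=2.0)
        stack, truth = make_organoid_video(params)
        assert truth.fractional_shortening == 0.0
        for frame in stack.frames[1:]:
            np.testing.assert_array_equal(frame, stack.frames[0])

    def test_regular_rhythm_has_zero_interval_sd(self):
        params = OrganoidSimParams(beat_interval_mean=1.0, beat_interval_sd=0.0,
                                   duration=30.0, noise_sd=0.0)
        _, truth = make_organoid_video(params)
        assert truth.n_beats == 30
        assert truth.interval_sd == pytest.approx(0.0, abs=1e-12)

    def test_truth_fs_obeys_wall_thickness_formula_exactly(self):
        _, truth = make_organoid_video(OrganoidSimParams(seed=2, duration=3.0))
        t_dia = truth.wall_thickness_dia
        t_sys = truth.wall_thickness_sys
        assert truth.fractional_shortening == pytest.approx(
            100.0 * (t_sys - t_dia) / t_dia, abs=1e-12)

    def test_beat_times_strictly_increasing(self):
        _, truth = make_organoid_video(OrganoidSimParams(seed=9))
        assert np.all(np.diff(truth.beat_times) > 0)

    def test_too_short_duration_warns_with_zero_beats(self):
        params = OrganoidSimParams(duration=0.2, beat_interval_mean=1.0,
                                   contraction_rise_fraction=0.9)
        with pytest.warns(UserWarning, match="zero-beat"):
            _, truth = make_organoid_video(params)
        assert truth.n_beats == 0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            OrganoidSimParams(R_inner_dia=80.0, R_outer_dia=70.0)
        with pytest.raises(ValueError):
            OrganoidSimParams(pulsation_fraction=1.2)


class TestCalciumTrace:
    def test_zero_amplitude_gives_flat_trace(self):
        params = CalciumSimParams(amplitude=0.0, noise_sd=0.0, drift_slope=0.0)
        trace, truth = make_calcium_trace(params)
        assert truth.n_transients == 0
        np.testing.assert_allclose(trace.fluorescence, params.baseline)

    def test_exponential_decay_repolarization_closed_form(self):
        # with an instantaneous upstroke the decay is a pure exponential and
        # repol-x = tau * ln(1/(1-x))
        kin = transient_truth_times(1e-8, 0.5)
        assert kin["repol90"] == pytest.approx(0.5 * np.log(10), abs=1e-6)
        assert kin["repol60"] == pytest.approx(0.5 * np.log(1 / 0.4), abs=1e-6)
        assert kin["repol30"] == pytest.approx(0.5 * np.log(1 / 0.7), abs=1e-6)

    def test_repolarization_ordering(self):
        kin = transient_truth_times(0.08, 0.3)
        assert kin["repol30"] < kin["repol60"] < kin["repol90"]

    def test_deterministic_under_seed(self):
        t1, _ = make_calcium_trace(CalciumSimParams(seed=1))
        t2, _ = make_calcium_trace(CalciumSimParams(seed=1))
        np.testing.assert_array_equal(t1.fluorescence, t2.fluorescence)

    def test_truth_peak_times_match_programmed_rhythm(self):
        params = CalciumSimParams(beat_interval_mean=0.8, beat_interval_sd=0.0,
                                  noise_sd=0.0, duration=30.0)
        _, truth = make_calcium_trace(params)
        np.testing.assert_allclose(np.diff(truth.peak_times), 0.8, atol=1e-9)

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError):
            CalciumSimParams(tau_up=0.5, tau_down=0.2)


class TestCountMatrix:
    def test_programmed_features_and_mito_realized(self):
        m, truth = make_count_matrix(50, 300, features_per_cell=40,
                                     mito_fraction=0.05, seed=0)
        detected = np.asarray((m.counts > 0).sum(axis=0)).ravel()
        np.testing.assert_array_equal(detected, 40)
        totals = np.asarray(m.counts.sum(axis=0)).ravel()
        mito_counts = np.asarray(m.counts[m.mito_flag].sum(axis=0)).ravel()
        np.testing.assert_allclose(mito_counts / totals, 0.05, atol=0.01)
        np.testing.assert_allclose(truth["mito_fraction"], mito_counts / totals)

    def test_per_cell_programming(self):
        feats = np.array([10, 20, 30])
        m, truth = make_count_matrix(3, 100, features_per_cell=feats, seed=1)
        detected = np.asarray((m.counts > 0).sum(axis=0)).ravel()
        np.testing.assert_array_equal(detected, feats)

    def test_mito_genes_have_mt_prefix(self):
        m, _ = make_count_matrix(5, 100, features_per_cell=10, seed=0)
        assert m.mito_flag.sum() >= 1
        assert all(m.gene_ids[i].startswith("MT-") for i in np.flatnonzero(m.mito_flag))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_count_matrix(0, 10)
        with pytest.raises(ValueError):
            make_count_matrix(10, 5, features_per_cell=6)
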