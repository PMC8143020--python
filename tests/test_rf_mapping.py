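import math

import numpy as np
import pytest

from visphys.geometry import polar_to_cartesian
from visphys.neural_preproc import EpochSet
from visphys.rf_mapping import (
    RFMap,
    TuningProfile,
    chord_from_arc,
    combine_maps,
    condition_profiles,
    fit_gaussian_profile,
    fit_vonmises_profile,
    gaussian_fwhm,
    model_map,
    reverse_correlation_map,
    rf_estimate,
    roi_from_map,
    snr_db,
    subsample_analysis,
    vonmises_fwhm,
)
from visphys.simulate import GroundTruthRF, simulate_rf_epochs


def _epochs_from_levels(levels_by_condition, reps=4, fill="window"):
    """EpochSet whose 0-100 ms window mean equals the given level per
    condition (baseline window 0)."""
    conds, rows = [], []
    for cid, level in levels_by_condition.items():
        for _ in range(reps):
            row = np.zeros(280)
            row[100:200] = level
            rows.append(row)
            conds.append(cid)
    data = np.asarray(rows)[:, None, :]
    return EpochSet(
        data=data,
        condition_ids=np.array(conds, dtype=object),
        onset_ms=500.0 * np.arange(len(conds), dtype=float),
    )


class TestWidthFormulas:
    @pytest.mark.parametrize("sigma,expected", [(1.0, 2.35482), (2.0, 4.70964)])
    def test_gaussian_fwhm_closed_form(self, sigma, expected):
        assert gaussian_fwhm(sigma) == pytest.approx(expected, abs=1e-5)

    def test_gaussian_fwhm_matches_grid_search(self):
        sigma = 1.7
        x = np.linspace(-10, 10, 2_000_001)
        y = np.exp(-(x**2) / (2 * sigma**2))
        above = x[y >= 0.5]
        assert gaussian_fwhm(sigma) == pytest.approx(above[-1] - above[0], abs=1e-4)

    def test_vonmises_fwhm_at_ln2(self):
        assert vonmises_fwhm(math.log(2)) == pytest.approx(180.0, abs=1e-9)

    def test_vonmises_gaussian_limit(self):
        kappa = 50.0
        approx = math.degrees(2 * math.sqrt(2 * math.log(2) / kappa))
        assert vonmises_fwhm(kappa) == pytest.approx(approx, rel=0.01)

    def test_vonmises_fwhm_matches_grid_search(self):
        kappa = 4.0
        theta = np.linspace(0, 180, 2_000_001)
        y = np.exp(kappa * (np.cos(np.radians(theta)) - 1))
        half = theta[y >= 0.5][-1]
        assert vonmises_fwhm(kappa) == pytest.approx(2 * half, abs=1e-3)

    def test_vonmises_saturation(self):
        assert vonmises_fwhm(0.2) == 360.0

    @pytest.mark.parametrize(
        "arc,radius,expected",
        [(60.0, 6.0, 6.0), (180.0, 3.0, 6.0)],
    )
    def test_chord_closed_form(self, arc, radius, expected):
        assert chord_from_arc(arc, radius) == pytest.approx(expected)

    def test_chord_small_angle_limit(self):
        arc = 0.1
        radius = 5.0
        arc_len = math.radians(arc) * radius
        assert chord_from_arc(arc, radius) / arc_len == pytest.approx(1.0, abs=1e-6)

    def test_rejections(self):
        with pytest.raises(ValueError):
            gaussian_fwhm(0.0)
        with pytest.raises(ValueError):
            vonmises_fwhm(-1.0)
        with pytest.raises(ValueError):
            chord_from_arc(0.0, 1.0)


class TestProfileFits:
    def test_gaussian_self_consistency(self):
        axis = np.linspace(1, 20, 28)
        y = 1.0 + 5.0 * np.exp(-((axis - 6.0) ** 2) / (2 * 1.2**2))
        fit = fit_gaussian_profile(TuningProfile(axis, y, np.ones(28, int), "annulus"))
        assert fit.converged
        assert fit.offset == pytest.approx(1.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(5.0, abs=1e-6)
        assert fit.loc == pytest.approx(6.0, abs=1e-6)
        assert fit.spread == pytest.approx(1.2, abs=1e-6)

    def test_gaussian_flat_profile_flagged(self):
        axis = np.linspace(1, 20, 10)
        fit = fit_gaussian_profile(TuningProfile(axis, np.full(10, 3.0), np.ones(10, int), "annulus"))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)
        assert "low_amplitude" in fit.flags

    def test_gaussian_offset_equivariance(self):
        axis = np.linspace(1, 20, 28)
        y = 2.0 + 4.0 * np.exp(-((axis - 9.0) ** 2) / (2 * 2.0**2))
        f1 = fit_gaussian_profile(TuningProfile(axis, y, np.ones(28, int), "annulus"))
        f2 = fit_gaussian_profile(TuningProfile(axis, y + 7.0, np.ones(28, int), "annulus"))
        assert f2.offset - f1.offset == pytest.approx(7.0, abs=1e-6)
        assert f2.loc == pytest.approx(f1.loc, abs=1e-6)
        assert f2.spread == pytest.approx(f1.spread, abs=1e-6)

    def test_vonmises_self_consistency(self):
        axis = np.arange(0, 360, 4.5)
        y = 0.5 + 3.0 * np.exp(4.0 * (np.cos(np.radians(axis - 120.0)) - 1.0))
        fit = fit_vonmises_profile(TuningProfile(axis, y, np.ones(axis.size, int), "wedge"))
        assert fit.converged
        assert fit.loc == pytest.approx(120.0, abs=1e-6)
        assert fit.spread == pytest.approx(4.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(3.0, abs=1e-6)

    @pytest.mark.parametrize("delta", [45.0, 200.0, 311.5])
    def test_vonmises_rotation_equivariance(self, delta):
        axis = np.arange(0, 360, 4.5)
        y0 = 1.0 + 2.0 * np.exp(6.0 * (np.cos(np.radians(axis - 90.0)) - 1.0))
        yd = 1.0 + 2.0 * np.exp(6.0 * (np.cos(np.radians(axis - 90.0 - delta)) - 1.0))
        f0 = fit_vonmises_profile(TuningProfile(axis, y0, np.ones(axis.size, int), "wedge"))
        fd = fit_vonmises_profile(TuningProfile(axis, yd, np.ones(axis.size, int), "wedge"))
        assert (fd.loc - f0.loc) % 360 == pytest.approx(delta % 360, abs=1e-5)

    def test_vonmises_high_kappa_approaches_gaussian(self):
        """At kappa = 50 the fitted von Mises matches a Gaussian fit of the
        unwrapped profile."""
        kappa = 50.0
        axis = np.arange(0, 360, 4.5)
        y = 1.0 + 5.0 * np.exp(kappa * (np.cos(np.radians(axis - 180.0)) - 1.0))
        vfit = fit_vonmises_profile(TuningProfile(axis, y, np.ones(axis.size, int), "wedge"))
        gfit = fit_gaussian_profile(TuningProfile(axis, y, np.ones(axis.size, int), "annulus"))
        assert vfit.loc == pytest.approx(gfit.loc, abs=0.05)
        assert vonmises_fwhm(vfit.spread) == pytest.approx(gaussian_fwhm(gfit.spread), rel=0.01)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_profile(TuningProfile([1, 2, 3], [1, 2, 1], [1, 1, 1], "annulus"))


class TestRFEstimate:
    def _fit(self, kind, loc, spread):
        from visphys.rf_mapping import TuningFit

        return TuningFit(kind, 1.0, 0.0, loc, spread, 0.0)

    def test_geometric_mean(self):
        # sigma chosen so rfs_e = 1; kappa so the chord at ecc 6 is 4
        sigma = 1.0 / gaussian_fwhm(1.0)
        arc = 2 * math.degrees(math.asin(4.0 / (2 * 6.0)))
        kappa = math.log(2) / (1 - math.cos(math.radians(arc / 2)))
        est = rf_estimate(self._fit("gaussian", 6.0, sigma), self._fit("von_mises", 45.0, kappa))
        assert est.rfs_e == pytest.approx(1.0, abs=1e-9)
        assert est.rfs_c == pytest.approx(4.0, abs=1e-9)
        assert est.rf_size == pytest.approx(2.0, abs=1e-9)

    def test_saturated_width_flagged(self):
        est = rf_estimate(self._fit("gaussian", 6.0, 1.0), self._fit("von_mises", 0.0, 0.2))
        assert "width_saturated" in est.flags

    def test_roundtrip_on_noiseless_simulation(self, catalog):
        """End-to-end: noiseless epochs from a known RF recover center and
        size within the stimulus-quantization tolerance."""
        rf = GroundTruthRF(eccentricity=6.0, polar_angle=120.0, fwhm_e=2.0,
                           fwhm_c=2.0, gain=5.0, baseline=10.0, noise_sd=1e-9)
        epochs = simulate_rf_epochs(rf, catalog, n_reps=2, rng_seed=0)
        ann, wdg = condition_profiles(epochs, catalog)
        est = rf_estimate(fit_gaussian_profile(ann), fit_vonmises_profile(wdg))
        tx, ty = polar_to_cartesian(6.0, 120.0)
        ex, ey = polar_to_cartesian(est.peak_eccentricity, est.polar_angle)
        # the eccentricity-scaled annulus widths skew profiles slightly
        # outward, so even noiseless recovery carries a small radial bias
        assert math.hypot(tx - ex, ty - ey) < 0.5
        # profile widths include the stimulus-extent broadening, so sizes
        # exceed the generating FWHM slightly but stay within 15%
        assert est.rf_size == pytest.approx(2.0, rel=0.15)


class TestConditionProfiles:
    def test_known_constants_recovered(self):
        levels = {"a0": 1.0, "a1": 5.0, "w0": 2.0}
        ep = _epochs_from_levels(levels)

        class FakeCatalog:
            annulus_ids = ["a0", "a1"]
            wedge_ids = ["w0"]

            def annulus_midpoints(self):
                return np.array([1.0, 2.0])

            def wedge_centers(self):
                return np.array([0.0])

        ann, wdg = condition_profiles(ep, FakeCatalog())
        np.testing.assert_allclose(ann.response, [1.0, 5.0])
        np.testing.assert_allclose(wdg.response, [2.0])
        assert list(ann.n_reps) == [4, 4]

    def test_matches_two_loop_oracle(self, catalog, rng):
        rf = GroundTruthRF()
        ep = simulate_rf_epochs(rf, catalog, n_reps=3, rng_seed=5)
        ann, _ = condition_profiles(ep, catalog)
        resp = ep.data[:, 0, 100:200].mean(axis=1)
        for a, sid in zip(range(len(ann.axis)), catalog.annulus_ids):
            vals = [resp[i] for i in range(ep.n_epochs) if ep.condition_ids[i] == sid]
            assert ann.response[a] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_permutation_invariance(self, catalog):
        ep = simulate_rf_epochs(GroundTruthRF(), catalog, n_reps=2, rng_seed=9)
        perm = np.random.default_rng(0).permutation(ep.n_epochs)
        shuffled = EpochSet(
            data=ep.data[perm],
            condition_ids=ep.condition_ids[perm],
            onset_ms=ep.onset_ms,
            valid=ep.valid[perm],
        )
        a1, w1 = condition_profiles(ep, catalog)
        a2, w2 = condition_profiles(shuffled, catalog)
        np.testing.assert_allclose(a1.response, a2.response)
        np.testing.assert_allclose(w1.response, w2.response)


class TestReverseCorrelation:
    def test_flat_when_responses_equal(self, tiny_catalog):
        """Equal responses and equal repetitions: the bias image cancels and
        the map is flat inside the mapped field."""
        levels = {i: 3.0 for i in tiny_catalog.ids}
        ep = _epochs_from_levels(levels, reps=2)
        amap, wmap = reverse_correlation_map(ep, tiny_catalog)
        for m in (amap, wmap):
            covered = m.coverage
            assert np.allclose(m.values[covered], 3.0)
            assert np.all(m.values[~covered] == 0)

    def test_single_driving_stimulus(self, tiny_catalog):
        levels = {i: 0.0 for i in tiny_catalog.ids}
        levels["a003"] = 2.0
        ep = _epochs_from_levels(levels, reps=2)
        amap, _ = reverse_correlation_map(ep, tiny_catalog)
        mask = tiny_catalog.mask("a003") > 0
        assert np.all(amap.values[mask] > 0)
        assert np.allclose(amap.values[~mask], 0.0)

    def test_unequal_repetitions_bias_normalized(self, tiny_catalog):
        """Two stimuli with equal responses but unequal repetition counts
        still give a flat map after bias division (hand-checkable)."""
        conds = ["a002"] * 7 + ["a003"] * 2 + ["w000"] * 2
        rows = []
        for _ in conds:
            row = np.zeros(280)
            row[100:200] = 4.0
            rows.append(row)
        ep = EpochSet(
            data=np.asarray(rows)[:, None, :],
            condition_ids=np.array(conds, dtype=object),
            onset_ms=500.0 * np.arange(len(conds), dtype=float),
        )
        amap, _ = reverse_correlation_map(ep, tiny_catalog)
        covered = (tiny_catalog.mask("a002") + tiny_catalog.mask("a003")) > 0
        assert np.allclose(amap.values[covered], 4.0)

    def test_matches_bruteforce_weighted_sum(self, tiny_catalog, rng):
        """Exact agreement with the naive per-epoch weighted-mask sum."""
        ids = tiny_catalog.ids
        conds = np.array(rng.choice(ids, size=60), dtype=object)
        data = np.zeros((60, 1, 280))
        resp = rng.uniform(0.5, 4.0, 60)
        data[:, 0, 100:200] = resp[:, None]
        ep = EpochSet(data=data, condition_ids=conds,
                      onset_ms=500.0 * np.arange(60, dtype=float))
        amap, wmap = reverse_correlation_map(ep, tiny_catalog)
        for m, id_set in ((amap, tiny_catalog.annulus_ids), (wmap, tiny_catalog.wedge_ids)):
            num = np.zeros_like(m.values)
            bias = np.zeros_like(m.values)
            for i in range(60):
                if conds[i] in id_set:
                    num += resp[i] * tiny_catalog.mask(conds[i])
                    bias += tiny_catalog.mask(conds[i])
            expected = np.divide(num, bias, out=np.zeros_like(num), where=bias > 0)
            np.testing.assert_allclose(m.values, expected, rtol=1e-6, atol=1e-9)

    def test_linear_in_responses(self, tiny_catalog, rng):
        ids = tiny_catalog.ids
        conds = np.array(rng.choice(ids, size=40), dtype=object)
        base = np.zeros((40, 1, 280))
        base[:, 0, 100:200] = rng.uniform(1, 2, 40)[:, None]
        mk = lambda d: EpochSet(data=d, condition_ids=conds,
                                onset_ms=500.0 * np.arange(40, dtype=float))
        a1, _ = reverse_correlation_map(mk(base), tiny_catalog)
        a2, _ = reverse_correlation_map(mk(2 * base), tiny_catalog)
        np.testing.assert_allclose(a2.values, 2 * a1.values, rtol=1e-9)


class TestMapCombination:
    def _map(self, values, coverage=None):
        from visphys.geometry import MonitorSpec

        return RFMap(values=np.asarray(values, dtype=float),
                     monitor=MonitorSpec(), provenance="annulus", coverage=coverage)

    def test_uniform_product(self):
        a = self._map(np.ones((4, 4)))
        w = self._map(np.ones((4, 4)))
        w.values[0, 0] = 2.0  # give the scale a max
        out = combine_maps(a, w)
        assert out.values.max() == 1.0
        assert out.values.min() == 0.0

    def test_disjoint_supports_degenerate(self):
        a = self._map([[1.0, 0.0], [0.0, 0.0]])
        w = self._map([[0.0, 1.0], [0.0, 0.0]])
        out = combine_maps(a, w)
        assert "degenerate" in out.flags
        assert np.all(out.values == 0)

    def test_simulated_peak_within_one_annulus_width(self, catalog):
        rf = GroundTruthRF(eccentricity=6.0, polar_angle=120.0, noise_sd=1e-9)
        ep = simulate_rf_epochs(rf, catalog, n_reps=1, rng_seed=0)
        amap, wmap = reverse_correlation_map(ep, catalog)
        comb = combine_maps(amap, wmap)
        row, col = np.unravel_index(np.argmax(comb.values), comb.values.shape)
        ecc, ang = catalog.pixel_polar()
        px, py = polar_to_cartesian(ecc[row, col], ang[row, col])
        tx, ty = polar_to_cartesian(6.0, 120.0)
        widths = [a.width for a in catalog.annuli if a.inner_radius <= 6.0 <= a.outer_radius]
        assert math.hypot(px - tx, py - ty) <= widths[0] + 2.0 / catalog.monitor.px_per_deg


class TestModelMapAndROI:
    def _fits(self):
        from visphys.rf_mapping import TuningFit

        g = TuningFit("gaussian", 5.0, 0.0, 8.0, 1.5, 0.0)
        v = TuningFit("von_mises", 5.0, 0.0, 200.0, 30.0, 0.0)
        return g, v

    def test_argmax_at_fitted_center(self, catalog):
        g, v = self._fits()
        m = model_map(g, v, catalog)
        row, col = np.unravel_index(np.argmax(m.values), m.values.shape)
        ecc, ang = catalog.pixel_polar()
        assert ecc[row, col] == pytest.approx(8.0, abs=0.3)
        assert abs((ang[row, col] - 200.0 + 180) % 360 - 180) < 3.0

    def test_halfmax_contours_match_fwhm(self, catalog):
        """Half-max extents of the model image reproduce RFS_e and RFS_c
        within pixel resolution."""
        g, v = self._fits()
        m = model_map(g, v, catalog)
        ecc, ang = catalog.pixel_polar()
        px = 1.0 / catalog.monitor.px_per_deg
        half = m.values >= 0.5
        # radial extent along the fitted polar-angle direction
        on_axis = half & (np.abs((ang - 200.0 + 180) % 360 - 180) < 1.5)
        radial_extent = ecc[on_axis].max() - ecc[on_axis].min()
        assert radial_extent == pytest.approx(gaussian_fwhm(1.5), abs=3 * px)

    def test_roi_connected_and_contains_argmax(self, catalog):
        g, v = self._fits()
        m = model_map(g, v, catalog)
        roi = roi_from_map(m)
        assert roi[np.unravel_index(np.argmax(m.values), m.values.shape)]
        from scipy import ndimage

        _, n_components = ndimage.label(roi)
        assert n_components == 1

    def test_uniform_map_roi_is_everything(self):
        from visphys.geometry import MonitorSpec

        m = RFMap(values=np.ones((5, 5)), monitor=MonitorSpec(), provenance="model")
        assert roi_from_map(m).all()

    def test_roi_matches_threshold_count(self, catalog, rng):
        vals = rng.uniform(0, 1, size=(20, 30))
        from visphys.geometry import MonitorSpec

        m = RFMap(values=vals, monitor=MonitorSpec(), provenance="model")
        roi = roi_from_map(m)
        assert roi.sum() == np.sum(vals > vals.max() / 2)


class TestSNR:
    def _map(self, values):
        from visphys.geometry import MonitorSpec

        return RFMap(values=np.asarray(values, dtype=float),
                     monitor=MonitorSpec(), provenance="combined")

    @pytest.mark.parametrize(
        "inside,outside,expected",
        [(1.0, 1.0, 0.0), (10.0, 1.0, 20.0), (2.0, 1.0, 6.0206)],
    )
    def test_amplitude_db_convention(self, inside, outside, expected):
        values = np.full((2, 2), outside)
        values[0, 0] = inside
        roi = np.zeros((2, 2), dtype=bool)
        roi[0, 0] = True
        assert snr_db(self._map(values), roi) == pytest.approx(expected, abs=1e-3)

    def test_zero_outside_capped(self):
        values = np.zeros((2, 2))
        values[0, 0] = 1.0
        roi = values > 0
        assert snr_db(self._map(values), roi) == 100.0

    def test_requires_nonempty_roi_and_complement(self):
        with pytest.raises(ValueError):
            snr_db(self._map(np.ones((2, 2))), np.ones((2, 2), dtype=bool))


@pytest.fixture(scope="module")
def site(catalog):
    rf = GroundTruthRF(eccentricity=7.0, polar_angle=210.0, fwhm_e=2.5,
                       fwhm_c=2.5, gain=5.0, baseline=10.0, noise_sd=1.0)
    return simulate_rf_epochs(rf, catalog, n_reps=10, rng_seed=77)


@pytest.fixture(scope="module")
def result(site, catalog):
    return subsample_analysis(site, catalog, max_reps=4, n_draws=15,
                              n_boot=200, rng_seed=5)


class TestSubsampling:
    def test_full_data_draw_has_exactly_zero_errors(self, result):
        draws, _, _ = result
        full = draws[draws.full_data]
        assert len(full) == 1
        assert full.pos_err_deg.iloc[0] == 0.0
        assert full.size_err_deg.iloc[0] == 0.0

    def test_snr_improves_from_one_to_max(self, result):
        draws, _, _ = result
        by_r = draws[~draws.full_data].groupby("r").snr_db.mean()
        assert by_r.loc[4] > by_r.loc[1]

    def test_substreams_reproducible(self, site, catalog):
        d1, _, _ = subsample_analysis(site, catalog, max_reps=2, n_draws=5,
                                      n_boot=50, rng_seed=5, include_full=False)
        d2, _, _ = subsample_analysis(site, catalog, max_reps=2, n_draws=5,
                                      n_boot=50, rng_seed=5, include_full=False)
        assert d1.equals(d2)

    def test_truncates_when_too_few_reps(self, catalog):
        rf = GroundTruthRF(noise_sd=1.0)
        ep = simulate_rf_epochs(rf, catalog, n_reps=3, rng_seed=0)
        draws, _, _ = subsample_analysis(ep, catalog, max_reps=9, n_draws=3,
                                         n_boot=50, rng_seed=1)
        assert draws.r.max() == 3
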