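"""Spectral unmixing, learned decoloring, Severinghaus conversion."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paoxsim import oximetry as ox
from paoxsim import spectra as sp


@pytest.fixture(scope="module")
def grid():
    return sp.nir_grid()


@pytest.fixture(scope="module")
def unmixer(grid):
    return ox.LinearSpectralUnmixer(wavelengths=grid.values).fit()


@pytest.fixture(scope="module")
def endmembers(grid):
    return sp.hemoglobin_endmembers(grid)


def melanin_transmission(grid, k):
    lam = np.asarray(grid.values)
    return np.exp(-k * (lam / 500.0) ** -3.5)


class TestLinearUnmix:
    def test_pure_oxygenated_spectrum_recovers_one(self, unmixer, endmembers):
        hbo2, _ = endmembers
        assert unmixer.predict(hbo2)[0] == pytest.approx(1.0)

    def test_exact_two_component_recovery(self, unmixer, endmembers):
        hbo2, hb = endmembers
        res = unmixer.unmix(0.5 * hbo2 + 0.5 * hb)
        assert res.so2_est[0] == pytest.approx(0.5, abs=1e-12)
        assert res.c_hbo2[0] == pytest.approx(0.5, abs=1e-10)

    @given(so2=st.floats(0.0, 1.0), scale=st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariant_exact_inverse(self, so2, scale, unmixer,
                                           endmembers):
        hbo2, hb = endmembers
        spec = scale * (so2 * hbo2 + (1 - so2) * hb)
        assert unmixer.predict(spec)[0] == pytest.approx(so2, abs=1e-9)

    def test_melanin_coloring_biases_towards_oxygenated(self, unmixer,
                                                        endmembers):
        # multiplying a 70%-blood spectrum by a melanin-like decreasing
        # transmission makes the linear estimate overshoot the truth
        hbo2, hb = endmembers
        truth = 0.7
        colored = (truth * hbo2 + (1 - truth) * hb) * \
            melanin_transmission(sp.nir_grid(), 0.5)
        est = unmixer.predict(colored)[0]
        # brute-force least squares agrees with the pseudo-inverse route
        A = np.column_stack(endmembers)
        coef, *_ = np.linalg.lstsq(A, colored, rcond=None)
        assert est == pytest.approx(coef[0] / coef.sum(), abs=1e-9)
        assert est > truth

    def test_rank_deficient_endmembers_rejected(self, grid):
        hbo2, _ = sp.hemoglobin_endmembers(grid)
        with pytest.raises(ValueError, match="depend"):
            ox.Endmembers(grid=grid, matrix=np.column_stack([hbo2, 2 * hbo2]))

    def test_wavelength_count_mismatch_rejected(self, unmixer):
        with pytest.raises(ValueError, match="wavelengths"):
            unmixer.predict(np.ones(7))

    def test_sklearn_param_interface(self):
        est = ox.LinearSpectralUnmixer()
        assert "wavelengths" in est.get_params()
        est.set_params(wavelengths=[700.0, 800.0, 900.0]).fit()
        assert est.n_features_in_ == 3


class TestRegionSo2:
    def test_homogeneous_region_equals_pixel_value(self, unmixer, endmembers):
        hbo2, hb = endmembers
        spec = 0.8 * hbo2 + 0.2 * hb
        res = unmixer.unmix(np.tile(spec, (20, 1)))
        assert ox.region_so2(res) == pytest.approx(0.8)

    def test_negative_coefficient_pixels_excluded(self, unmixer, endmembers):
        hbo2, hb = endmembers
        good = 0.6 * hbo2 + 0.4 * hb
        bad = hbo2 - 0.4 * hb          # negative deoxy coefficient
        res = unmixer.unmix(np.vstack([np.tile(good, (5, 1)),
                                       np.tile(bad, (5, 1))]))
        assert res.valid.sum() == 5
        assert ox.region_so2(res) == pytest.approx(0.6)

    def test_all_invalid_region_raises(self, unmixer, endmembers):
        hbo2, hb = endmembers
        res = unmixer.unmix(hbo2 - 0.5 * hb)
        with pytest.raises(ValueError, match="valid"):
            ox.region_so2(res)

    def test_median_ratio_differs_from_mean_of_ratios(self, unmixer,
                                                      endmembers):
        # skewed c_hbo2 distribution: the median-component ratio is not the
        # mean pixel sO2 (regression guard for the estimator definition)
        hbo2, hb = endmembers
        fracs = np.array([0.1, 0.15, 0.2, 0.9, 0.95])
        spectra = np.stack([f * hbo2 + (1 - f) * hb for f in fracs])
        res = unmixer.unmix(spectra)
        med_ratio = ox.region_so2(res)
        mean_ratio = np.nanmean(res.so2_est)
        assert med_ratio != pytest.approx(mean_ratio, abs=0.01)


class TestNormalization:
    def test_constant_spectrum_maps_to_ones(self):
        np.testing.assert_allclose(ox.normalize_spectrum(np.full(21, 3.3)),
                                   np.ones(21))

    def test_scale_invariance_and_unit_mean(self):
        rng = np.random.default_rng(0)
        x = rng.random((5, 21)) + 0.1
        np.testing.assert_allclose(ox.normalize_spectrum(10 * x),
                                   ox.normalize_spectrum(x))
        np.testing.assert_allclose(ox.normalize_spectrum(x).mean(axis=1), 1.0)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            ox.normalize_spectrum(np.zeros(21))


def synthetic_colored_corpus(grid, n, seed):
    """Blood spectra under random melanin-like coloring (analytic oracle)."""
    rng = np.random.default_rng(seed)
    hbo2, hb = sp.hemoglobin_endmembers(grid)
    so2 = rng.uniform(0, 1, n)
    k = rng.uniform(0.0, 1.0, n)
    scale = rng.lognormal(0, 0.5, n)
    lam = np.asarray(grid.values)
    trans = np.exp(-k[:, None] * (lam / 500.0) ** -3.5)
    spectra = scale[:, None] * (so2[:, None] * hbo2 + (1 - so2)[:, None] * hb) * trans
    return spectra, so2


class TestDecoloring:
    def test_beats_linear_unmixing_on_colored_spectra(self, grid, unmixer):
        X, y = synthetic_colored_corpus(grid, 4000, 1)
        Xt, yt = synthetic_colored_corpus(grid, 800, 2)
        model = ox.SpectralDecoloringRegressor(random_state=0).fit(X, y)
        rmse_learned = np.sqrt(np.mean((model.predict(Xt) - yt) ** 2))
        lin = unmixer.predict(Xt)
        rmse_linear = np.sqrt(np.nanmean((lin - yt) ** 2))
        assert rmse_learned < rmse_linear

    def test_uncolored_blood_is_easy(self, grid):
        rng = np.random.default_rng(3)
        hbo2, hb = sp.hemoglobin_endmembers(grid)
        so2 = rng.uniform(0, 1, 3000)
        X = so2[:, None] * hbo2 + (1 - so2)[:, None] * hb
        model = ox.SpectralDecoloringRegressor(random_state=0).fit(X[:2500],
                                                                   so2[:2500])
        rmse = np.sqrt(np.mean((model.predict(X[2500:]) - so2[2500:]) ** 2))
        assert rmse < 0.02

    def test_same_seed_identical_predictions(self, grid):
        X, y = synthetic_colored_corpus(grid, 2000, 5)
        p1 = ox.SpectralDecoloringRegressor(random_state=7).fit(X, y).predict(X)
        p2 = ox.SpectralDecoloringRegressor(random_state=7).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_outputs_clipped_to_unit_interval(self, grid):
        X, y = synthetic_colored_corpus(grid, 2000, 5)
        model = ox.SpectralDecoloringRegressor(random_state=0).fit(X, y)
        extreme, _ = synthetic_colored_corpus(grid, 200, 6)
        out = model.predict(extreme * 100)
        assert np.all((out >= 0) & (out <= 1))

    def test_permutation_equivariance(self, grid):
        X, y = synthetic_colored_corpus(grid, 1000, 8)
        model = ox.SpectralDecoloringRegressor(random_state=0).fit(X, y)
        perm = np.random.default_rng(0).permutation(200)
        sub, _ = synthetic_colored_corpus(grid, 200, 9)
        np.testing.assert_array_equal(model.predict(sub)[perm],
                                      model.predict(sub[perm]))

    def test_grid_mismatch_rejected(self, grid):
        X, y = synthetic_colored_corpus(grid, 1500, 5)
        model = ox.SpectralDecoloringRegressor(random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="trained"):
            model.predict(np.ones(11))

    def test_constant_labels_warn(self, grid):
        X, _ = synthetic_colored_corpus(grid, 1200, 5)
        with pytest.warns(UserWarning, match="constant"):
            ox.SpectralDecoloringRegressor(random_state=0).fit(
                X, np.full(X.shape[0], 0.5))


class TestTrainingSetBookkeeping:
    def test_small_simulated_training_set(self):
        # tiny corpus: determinism and label/spectrum pairing
        ts1 = ox.build_training_set(n_volumes=2, seed=4, n_photons=3000,
                                    max_voxels_per_volume=300)
        ts2 = ox.build_training_set(n_volumes=2, seed=4, n_photons=3000,
                                    max_voxels_per_volume=300)
        np.testing.assert_array_equal(ts1.spectra, ts2.spectra)
        np.testing.assert_array_equal(ts1.labels, ts2.labels)
        assert ts1.spectra.shape[0] == ts1.labels.shape[0] > 0
        assert np.all((ts1.labels >= 0) & (ts1.labels <= 1))
        np.testing.assert_allclose(ts1.spectra.mean(axis=1), 1.0)


class TestSeveringhaus:
    def test_zero_limit(self):
        assert ox.severinghaus(0.0) == 0.0

    def test_saturation_limit(self):
        assert ox.severinghaus(1000.0) > 0.999

    def test_p50_near_27_mmhg(self):
        assert ox.severinghaus(26.9) == pytest.approx(0.501, abs=0.005)

    def test_strictly_increasing_and_bounded(self):
        p = np.linspace(0.5, 500, 400)
        s = ox.severinghaus(p)
        assert np.all(np.diff(s) > 0)
        assert np.all((s > 0) & (s < 1))

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            ox.severinghaus(-1.0)
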