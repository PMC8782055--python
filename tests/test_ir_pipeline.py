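"""IR preprocessing, band integrals, ratios, PCA and confidence ellipses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2, spearmanr

from sporehit.exceptions import (
    CoverageError,
    DegenerateRatioError,
    InsufficientDataError,
    InvalidInputError,
)
from sporehit.ir_pipeline import (
    DEFAULT_BANDS,
    BandDefinition,
    PreprocessParams,
    band_integral,
    band_ratios,
    confidence_ellipse,
    fit_pca,
    preprocess,
)
from sporehit.sers_analysis import Spectrum
from sporehit.synthetic_data import synth_ir_spectrum

GRID = np.arange(900.0, 1850.0 + 1e-9, 2.0)


class TestPreprocess:
    def test_unit_norm_postcondition(self):
        spec = synth_ir_spectrum({"protein": 2.0, "dpa": 1.0, "carb": 4.0})
        params = PreprocessParams(cut_lo_cm1=GRID[0], cut_hi_cm1=GRID[-1])
        out = preprocess(spec, params)
        assert np.linalg.norm(out.intensities) == pytest.approx(1.0, abs=1e-9)

    def test_fixpoint_spectrum_unchanged(self):
        """A baseline-free, SG-exact, unit-norm spectrum passes through."""
        nu = np.arange(950.0, 1800.0 + 1e-9, 2.0)
        y = (nu - nu[0]) * (nu[-1] - nu)  # concave quadratic, zero at ends
        y = y / np.linalg.norm(y)
        spec = Spectrum(nu, y)
        out = preprocess(spec, PreprocessParams())
        assert np.allclose(out.intensities, y, atol=1e-10)

    def test_savgol_cubic_exactness(self):
        """15-point order-3 Savitzky-Golay reproduces a cubic exactly."""
        nu = np.arange(950.0, 1800.0 + 1e-9, 2.0)
        x = (nu - 1300.0) / 500.0
        y = 1.0 + x - 0.5 * x**2 + 0.25 * x**3
        spec = Spectrum(nu, y)
        out = preprocess(spec, PreprocessParams(baseline="none", sg_order=3, normalize=False))
        m = (nu >= 950.0) & (nu <= 1800.0)
        assert np.allclose(out.intensities, y[m], atol=1e-10)

    def test_linear_baseline_removed(self):
        """Band ratios after preprocessing match the baseline-free truth."""
        clean = synth_ir_spectrum({"protein": 2.0, "dpa": 1.0, "carb": 4.0})
        dirty = synth_ir_spectrum(
            {"protein": 2.0, "dpa": 1.0, "carb": 4.0},
            baseline_slope=0.002, baseline_offset=0.5,
        )
        r_clean = band_ratios(preprocess(clean))
        r_dirty = band_ratios(preprocess(dirty))
        for key in ("dpa_over_protein", "carb_over_protein"):
            assert r_dirty[key] == pytest.approx(r_clean[key], rel=0.01)

    def test_coverage_and_window_errors(self):
        nu = np.arange(1000.0, 1500.0, 2.0)
        spec = Spectrum(nu, np.ones_like(nu))
        with pytest.raises(CoverageError):
            preprocess(spec, PreprocessParams())
        short = Spectrum(np.arange(950.0, 1810.0, 50.0), np.ones(18))
        with pytest.raises(InvalidInputError):
            preprocess(short, PreprocessParams(sg_window=25))


class TestBandIntegral:
    def test_straight_line_integrates_to_zero(self):
        spec = Spectrum(GRID, 0.3 * GRID - 7.0)
        for band in DEFAULT_BANDS.values():
            assert band_integral(spec, band) == pytest.approx(0.0, abs=1e-9)

    def test_triangle_closed_form_area(self):
        """Unit triangle, base 100 cm-1, apex 1: area 1/2 * 100 * 1 = 50."""
        band = BandDefinition("t", 1330.0, 1480.0)
        apex, base = 1400.0, 100.0
        y = np.clip(1.0 - np.abs(GRID - apex) / (base / 2), 0.0, None)
        assert band_integral(Spectrum(GRID, y), band) == pytest.approx(50.0, rel=1e-9)

    @given(a=st.floats(-10.0, 10.0), b=st.floats(-0.1, 0.1))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(1)
        y = rng.normal(0.0, 1.0, GRID.shape)
        spec = Spectrum(GRID, y)
        shifted = Spectrum(GRID, y + a + b * GRID)
        band = DEFAULT_BANDS["dpa"]
        assert band_integral(shifted, band) == pytest.approx(
            band_integral(spec, band), rel=1e-9, abs=1e-9
        )

    def test_band_outside_grid(self):
        spec = Spectrum(np.arange(1000.0, 1400.0, 2.0), np.ones(200))
        with pytest.raises(CoverageError):
            band_integral(spec, DEFAULT_BANDS["protein"])


class TestBandRatios:
    def test_constructed_areas(self):
        """Generator areas (protein 2, DPA 1, carb 4) give ratios (0.5, 2.0)."""
        spec = synth_ir_spectrum({"protein": 2.0, "dpa": 1.0, "carb": 4.0})
        r = band_ratios(spec)
        assert r["dpa_over_protein"] == pytest.approx(0.5, rel=1e-6)
        assert r["carb_over_protein"] == pytest.approx(2.0, rel=1e-6)

    def test_scale_invariance(self):
        spec = synth_ir_spectrum({"protein": 2.0, "dpa": 1.0, "carb": 4.0})
        scaled = Spectrum(spec.wavenumbers, spec.intensities * 7.0)
        r1, r7 = band_ratios(spec), band_ratios(scaled)
        assert r7["dpa_over_protein"] == pytest.approx(r1["dpa_over_protein"], rel=1e-12)
        assert r7["carb_over_protein"] == pytest.approx(r1["carb_over_protein"], rel=1e-12)

    def test_absent_dpa_band(self):
        spec = synth_ir_spectrum({"protein": 2.0, "dpa": 0.0, "carb": 4.0})
        assert band_ratios(spec)["dpa_over_protein"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_protein_degenerate(self):
        spec = Spectrum(GRID, np.zeros_like(GRID))
        with pytest.raises(DegenerateRatioError):
            band_ratios(spec)


class TestPCA:
    def _spectra(self, coeffs, direction=None, second=None):
        nu = np.arange(950.0, 1800.0, 2.0)
        base = np.exp(-0.5 * ((nu - 1400) / 60.0) ** 2)
        d1 = direction if direction is not None else base
        out = []
        for c in coeffs:
            y = 1.0 + c[0] * d1
            if second is not None:
                y = y + c[1] * second
            out.append(Spectrum(nu, y))
        return out

    def test_single_direction_explains_everything(self):
        specs = self._spectra([(c,) for c in (-2.0, -1.0, 0.0, 1.0, 2.0)])
        model = fit_pca(specs, n_components=2)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_two_source_variance_partition(self):
        """Orthogonal sources with variances 9 and 1 split 0.9/0.1."""
        nu = np.arange(950.0, 1800.0, 2.0)
        d1 = np.zeros_like(nu); d1[:212] = 1.0
        d2 = np.zeros_like(nu); d2[213:] = 1.0
        d1, d2 = d1 / np.linalg.norm(d1), d2 / np.linalg.norm(d2)
        a = np.array([-1.0, 1.0]) * 3.0  # sample var 9 (ddof=1 -> 18/... use many points)
        rng = np.random.default_rng(0)
        ca = rng.choice([-3.0, 3.0], size=400)
        cb = rng.choice([-1.0, 1.0], size=400)
        specs = [Spectrum(nu, 1.0 + x * d1 + y * d2) for x, y in zip(ca, cb)]
        model = fit_pca(specs, n_components=2)
        assert model.explained_variance_fraction[0] == pytest.approx(0.9, abs=0.01)
        assert model.explained_variance_fraction[1] == pytest.approx(0.1, abs=0.01)

    def test_round_trip_projection(self):
        specs = self._spectra([(c,) for c in np.linspace(-1, 1, 7)])
        model = fit_pca(specs, n_components=3)
        back = model.transform(specs)
        assert np.allclose(back, model.scores, atol=1e-9)

    def test_loadings_orthonormal_and_fractions_valid(self):
        spec = [synth_ir_spectrum({"protein": 2.0, "dpa": d, "carb": 4.0},
                                  noise_sd=0.01, seed=s)
                for s, d in enumerate(np.linspace(0.5, 2.0, 8))]
        model = fit_pca(spec, n_components=5)
        gram = model.loadings @ model.loadings.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)
        evf = model.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12)
        assert 0 < evf.sum() <= 1 + 1e-12

    def test_all_components_sum_to_one(self):
        rng = np.random.default_rng(5)
        nu = np.arange(950.0, 1800.0, 2.0)
        specs = [Spectrum(nu, 1.0 + rng.normal(0, 0.1, nu.shape)) for _ in range(4)]
        # 4 spectra -> at most 3 nontrivial components
        model = fit_pca(specs, n_components=3)
        assert model.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_too_few_spectra(self):
        specs = self._spectra([(0.0,), (1.0,)])
        with pytest.raises(InsufficientDataError):
            fit_pca(specs)


class TestConfidenceEllipse:
    def test_isotropic_cloud_radius(self, rng):
        """Unit-variance isotropic scores give a circle of radius sqrt(chi2_2(.95))."""
        pts = rng.normal(0.0, 1.0, size=(20000, 2))
        ell = confidence_ellipse(pts, level=0.95)
        expected = np.sqrt(chi2.ppf(0.95, 2))
        assert ell.semi_axes[0] == pytest.approx(expected, rel=0.05)
        assert ell.semi_axes[1] == pytest.approx(expected, rel=0.05)
        assert expected == pytest.approx(2.448, abs=0.002)

    def test_identical_points_degenerate(self):
        pts = np.ones((5, 2))
        ell = confidence_ellipse(pts)
        assert ell.degenerate
        assert ell.semi_axes == (0.0, 0.0)

    def test_rotation_equivariance(self, rng):
        pts = rng.normal(0.0, 1.0, size=(500, 2)) * np.array([3.0, 1.0])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        e1 = confidence_ellipse(pts)
        e2 = confidence_ellipse(pts @ rot.T)
        assert e2.semi_axes == pytest.approx(e1.semi_axes, rel=1e-9)
        delta = (e2.angle_rad - e1.angle_rad - theta) % np.pi
        assert min(delta, np.pi - delta) == pytest.approx(0.0, abs=1e-6)


class TestEndToEnd:
    def test_dose_profile_recovery(self):
        """DPA/protein ratios tracking a prescribed dose profile survive the
        pipeline: Spearman rho 1.0 noiseless, >= 0.9 at 2% noise."""
        doses = np.array([0.0, 250, 500, 1000, 1500, 2000])
        profile = 0.3 + 1.2 * (doses / 258.0) * np.exp(-doses / 258.0)
        def recovered(noise):
            out = []
            for i, (d, p) in enumerate(zip(doses, profile)):
                spec = synth_ir_spectrum(
                    {"protein": 2.0, "dpa": 2.0 * p, "carb": 4.0},
                    noise_sd=noise, seed=100 + i,
                    baseline_slope=0.001, baseline_offset=0.2,
                )
                out.append(band_ratios(preprocess(spec))["dpa_over_protein"])
            return np.array(out)
        rho0 = spearmanr(profile, recovered(0.0)).statistic
        assert rho0 == pytest.approx(1.0, abs=1e-12)
        # 2% of the typical band peak intensity
        peak = np.max(synth_ir_spectrum({"protein": 2.0, "dpa": 1.0, "carb": 4.0}).intensities)
        rho = spearmanr(profile, recovered(0.02 * peak)).statistic
        assert rho >= 0.9
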