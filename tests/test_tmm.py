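"""Transfer-matrix solver: Fresnel limits, closed-form oracles, conservation laws."""

import numpy as np
import pytest

from nacre.colorimetry import peak_stats
from nacre.models import bragg_prediction
from nacre.structure import LayerStack, RefractiveModel, StackSpec, sample_stack
from nacre.tmm import (
    DEFAULT_WAVELENGTHS,
    IncidenceGeometry,
    Spectrum,
    angle_scan,
    ensemble_reflectance,
    fresnel_interface,
    tmm_reflectance,
    tmm_rt,
)


def airy_single_film(d, n_film, wavelengths, n_out=1.63):
    """Independent closed form: multiple-reflection (Airy) summation for one
    film between identical half-spaces at normal incidence."""
    r = (n_out - n_film) / (n_out + n_film)
    phase = np.exp(2j * 2 * np.pi * n_film * d / np.asarray(wavelengths))
    return np.abs(r * (1 - phase) / (1 - r**2 * phase)) ** 2


class TestFresnel:
    def test_normal_incidence_air_aragonite(self):
        r, _ = fresnel_interface(1.00, 1.63, 0.0, "s")
        assert abs(r) ** 2 == pytest.approx(((1.63 - 1) / (1.63 + 1)) ** 2, rel=1e-12)
        assert abs(r) ** 2 == pytest.approx(0.0574, abs=2e-4)

    @pytest.mark.parametrize("theta", [0.0, 17.0, 62.0])
    @pytest.mark.parametrize("pol", ["s", "p"])
    def test_index_matched_interface_reflects_nothing(self, theta, pol):
        r, t = fresnel_interface(1.5, 1.5, theta, pol)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert t == pytest.approx(1.0, abs=1e-15)

    def test_brewster_angle_kills_p_reflection(self):
        theta_b = np.degrees(np.arctan(1.63))
        r, _ = fresnel_interface(1.00, 1.63, theta_b, "p")
        assert abs(r) < 1e-12

    @pytest.mark.parametrize("theta", [0.0, 30.0, 60.0])
    @pytest.mark.parametrize("pol", ["s", "p"])
    def test_interface_energy_identity(self, theta, pol):
        n_a, n_b = 1.00, 1.63
        r, t = fresnel_interface(n_a, n_b, theta, pol)
        ca = np.cos(np.radians(theta))
        cb = np.sqrt(1 - (n_a * np.sin(np.radians(theta)) / n_b) ** 2)
        assert abs(r) ** 2 + (n_b * cb) / (n_a * ca) * abs(t) ** 2 == pytest.approx(1.0, abs=1e-12)


class TestSolver:
    def test_empty_stack_is_bare_interface(self, wl):
        stack = LayerStack(layers=(), n_ambient=1.00, n_substrate=1.63)
        sp = tmm_reflectance(stack, wl)
        assert np.allclose(sp.values, 0.05738, atol=1e-4)
        assert np.ptp(sp.values) < 1e-14

    def test_single_film_matches_airy_closed_form(self, wl):
        """The 4 nm air nanogap between aragonite half-spaces: exact oracle."""
        stack = LayerStack(layers=((1.0, 4.0),), n_ambient=1.63, n_substrate=1.63)
        R = tmm_reflectance(stack, wl).values
        assert np.max(np.abs(R - airy_single_film(4.0, 1.0, wl))) < 1e-10

    def test_random_films_match_airy_closed_form(self, wl):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            d = float(rng.uniform(0.5, 200.0))
            n_film = float(rng.uniform(1.0, 1.6))
            stack = LayerStack(layers=((n_film, d),), n_ambient=1.63, n_substrate=1.63)
            R = tmm_reflectance(stack, wl).values
            assert np.max(np.abs(R - airy_single_film(d, n_film, wl))) < 1e-10

    @pytest.mark.parametrize("theta,pol", [(0.0, "s"), (30.0, "s"), (30.0, "p"),
                                           (60.0, "unpolarized")])
    def test_energy_conservation(self, wl, theta, pol):
        spec = StackSpec(d1_mean=160, d1_sd=8, d2_mean=4, d2_sd=2, n_periods=100, seed=5)
        stack = sample_stack(spec)
        R, T = tmm_rt(stack, wl, IncidenceGeometry(theta=theta, polarization=pol))
        assert np.max(np.abs(R.values + T.values - 1.0)) < 1e-8
        assert np.all(R.values >= 0) and np.all(R.values <= 1)

    def test_reciprocity_between_equal_half_spaces(self, wl):
        """Reflectance is unchanged traversing the stack from the far side."""
        spec = StackSpec(d1_mean=150, d1_sd=15, d2_mean=11, d2_sd=3, n_periods=40,
                         refr=RefractiveModel(n2=1.43, n_ambient=1.63, n_substrate=1.63),
                         seed=9)
        stack = sample_stack(spec)
        fwd = tmm_reflectance(stack, wl).values
        bwd = tmm_reflectance(stack.reversed(), wl).values
        assert np.max(np.abs(fwd - bwd)) < 1e-12

    def test_index_matched_gaps_collapse_to_flat_interface(self, wl):
        spec = StackSpec(d1_mean=160, d2_mean=4, n_periods=50,
                         refr=RefractiveModel(n1=1.63, n2=1.63))
        sp = tmm_reflectance(sample_stack(spec), wl)
        assert np.ptp(sp.values) < 1e-10

    def test_peak_reflectance_grows_with_period_count(self, wl):
        peaks = []
        for n in (5, 20, 80):
            sp = tmm_reflectance(sample_stack(StackSpec(d1_mean=160, d2_mean=4, n_periods=n)), wl)
            peaks.append(sp.values.max())
        assert peaks[0] < peaks[1] < peaks[2] <= 1.0

    def test_periodic_stack_peak_matches_bragg(self, wl):
        sp = tmm_reflectance(sample_stack(StackSpec(d1_mean=160, d2_mean=4, n_periods=300)), wl)
        lam = peak_stats(sp).lambda_max
        pred = bragg_prediction(160, 4).lambda_peak
        assert abs(lam - pred) / pred < 0.02


class TestEnsemble:
    def test_zero_sd_reduces_to_deterministic(self, wl):
        spec = StackSpec(d1_mean=160, d2_mean=4, n_periods=100, seed=3)
        det = tmm_reflectance(sample_stack(spec), wl).values
        ens = ensemble_reflectance(spec, 25, wl).values
        assert np.array_equal(det, ens)

    def test_disorder_broadens_the_band(self, wl):
        ordered = StackSpec(d1_mean=157, d2_mean=4, n_periods=300, seed=1)
        noisy = ordered.with_(d1_sd=15.0)
        f0 = peak_stats(tmm_reflectance(sample_stack(ordered), wl)).fwhm
        f1 = peak_stats(ensemble_reflectance(noisy, 50, wl)).fwhm
        assert f1 > f0

    def test_realization_stream_is_prefix_stable(self):
        """The first k of n realizations are the same draws: the 50- and
        200-rep means differ only by the Monte-Carlo error of the tail."""
        wl = np.arange(450.0, 651.0, 2.0)
        spec = StackSpec(d1_mean=157, d1_sd=8, d2_mean=4, n_periods=60, seed=21)
        m50 = ensemble_reflectance(spec, 50, wl).values
        m200 = ensemble_reflectance(spec, 200, wl).values
        # per-point spread of single realizations, to scale the MC bound
        singles = np.stack([
            ensemble_reflectance(spec.with_(seed=1000 + i), 1, wl).values for i in range(12)
        ])
        se50 = singles.std(axis=0, ddof=1) / np.sqrt(50)
        assert np.all(np.abs(m50 - m200) <= 4 * se50 + 1e-3)

    def test_ensemble_reproducible_for_fixed_seed(self):
        wl = np.arange(450.0, 651.0, 5.0)
        spec = StackSpec(d1_mean=150, d1_sd=15, d2_mean=4, n_periods=50, seed=8)
        a = ensemble_reflectance(spec, 10, wl).values
        b = ensemble_reflectance(spec, 10, wl).values
        assert np.array_equal(a, b)


class TestAngles:
    def test_polarizations_degenerate_at_normal_incidence(self, wl):
        stack = sample_stack(StackSpec(d1_mean=160, d2_mean=4, n_periods=50))
        rs = tmm_reflectance(stack, wl, IncidenceGeometry(0.0, "s")).values
        rp = tmm_reflectance(stack, wl, IncidenceGeometry(0.0, "p")).values
        assert np.max(np.abs(rs - rp)) < 1e-12

    def test_band_blue_shifts_with_angle(self, wl):
        stack = sample_stack(StackSpec(d1_mean=160, d2_mean=4, n_periods=300))
        spectra = angle_scan(stack, wl, thetas=(0.0, 15.0, 30.0, 45.0))
        lams = [peak_stats(sp).lambda_max for sp in spectra]
        assert lams == sorted(lams, reverse=True)
        assert lams[0] > lams[-1]

    def test_angle_dependence_tracks_bragg_snell(self, wl):
        stack = sample_stack(StackSpec(d1_mean=160, d2_mean=4, n_periods=300))
        for theta in (0.0, 20.0, 40.0):
            sp = tmm_reflectance(stack, wl, IncidenceGeometry(theta=theta))
            lam = peak_stats(sp).lambda_max
            pred = bragg_prediction(160, 4, theta=theta).lambda_peak
            assert abs(lam - pred) / pred < 0.03

    def test_angle_scan_range_checked(self, wl):
        stack = sample_stack(StackSpec(n_periods=5))
        with pytest.raises(ValueError):
            angle_scan(stack, wl, thetas=(0.0, 88.0))


class TestSpectrumType:
    def test_csv_round_trip_is_lossless(self, tmp_path, wl):
        sp = tmm_reflectance(sample_stack(StackSpec(n_periods=20)), wl)
        path = tmp_path / "spectrum.csv"
        sp.to_csv(path)
        back = Spectrum.from_csv(path)
        assert np.array_equal(back.wavelengths, sp.wavelengths)
        assert np.array_equal(back.values, sp.values)

    def test_csv_header_enforced(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wl,R\n500,0.5\n")
        with pytest.raises(ValueError, match="header"):
            Spectrum.from_csv(path)

    @pytest.mark.parametrize("wls,vals", [
        ([500, 400], [0.1, 0.2]),          # not increasing
        ([500, 500], [0.1, 0.2]),          # duplicate
        ([400, 500], [0.1]),               # length mismatch
        ([], []),                          # empty
        ([400, 500], [0.1, np.nan]),       # non-finite
    ])
    def test_invalid_spectra_rejected(self, wls, vals):
        with pytest.raises(ValueError):
            Spectrum(np.asarray(wls, dtype=float), np.asarray(vals, dtype=float))

    def test_geometry_validated(self):
        with pytest.raises(ValueError):
            IncidenceGeometry(theta=95.0)
        with pytest.raises(ValueError):
            IncidenceGeometry(polarization="circular")
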