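import numpy as np
import pytest

from pocketflim.errors import CollinearReferencesError
from pocketflim.phasor import (
    DecayHistogram,
    Phasor,
    calibrate_phasor,
    fit_monoexponential,
    phasor_lifetime,
    phasor_transform,
    reference_phasor,
    unmix_image,
    unmix_points,
    unmix_three,
)
from pocketflim.synthetic import simulate_decay, simulate_flim_image, SceneSpec, RegionSpec


def expected_histogram(taus_fracs, n_bins, period, total=1.0) -> DecayHistogram:
    """Noiseless binned expectation of a wrapped multi-exponential decay."""
    edges = np.linspace(0.0, period, n_bins + 1)
    counts = np.zeros(n_bins)
    for tau, frac in taus_fracs:
        m = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
        counts += frac * total * m / m.sum()
    return DecayHistogram(bin_edges=edges, counts=counts, period=period)


class TestPhasorTransform:
    def test_fine_binned_monoexponential_hits_analytic_point(self):
        # omega*tau = 1 -> (g, s) = (1/2, 1/2)
        period = 20.0
        tau = period / (2 * np.pi)
        decay = expected_histogram([(tau, 1.0)], n_bins=1024, period=period)
        p = phasor_transform(decay)
        assert p.g == pytest.approx(0.5, abs=1e-3)
        assert p.s == pytest.approx(0.5, abs=1e-3)

    def test_delta_function_at_time_zero(self):
        edges = np.linspace(0.0, 25.0, 4097)
        counts = np.zeros(4096)
        counts[0] = 1000
        p = phasor_transform(DecayHistogram(edges, counts, 25.0))
        assert p.g == pytest.approx(1.0, abs=2e-3)
        assert p.s == pytest.approx(0.0, abs=2e-3)

    def test_uniform_counts_transform_to_origin(self):
        edges = np.linspace(0.0, 25.0, 257)
        p = phasor_transform(DecayHistogram(edges, np.full(256, 10.0), 25.0))
        assert abs(p.g) < 1e-12 and abs(p.s) < 1e-12

    def test_zero_counts_rejected(self):
        edges = np.linspace(0.0, 25.0, 257)
        with pytest.raises(ValueError, match="zero total"):
            phasor_transform(DecayHistogram(edges, np.zeros(256), 25.0))

    @pytest.mark.parametrize("tau", [0.5, 1.4, 3.0, 5.5, 5.9])
    def test_semicircle_law_for_simulated_monoexponentials(self, tau):
        decay = simulate_decay(tau, 10**5, n_bins=256, period=25.0, seed=17)
        p = phasor_transform(decay)
        dist = np.hypot(p.g - 0.5, p.s) - 0.5
        assert abs(dist) < 5e-3  # shot noise + binning tolerance

    @pytest.mark.parametrize("f", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_linearity_of_intensity_mixtures(self, f):
        period, n_bins = 25.0, 256
        d1 = expected_histogram([(5.9, 1.0)], n_bins, period, total=1000)
        d2 = expected_histogram([(1.4, 1.0)], n_bins, period, total=1000)
        mix = DecayHistogram(
            d1.bin_edges, f * d1.counts + (1 - f) * d2.counts, period
        )
        p1, p2 = phasor_transform(d1), phasor_transform(d2)
        pm = phasor_transform(mix)
        assert pm.g == pytest.approx(f * p1.g + (1 - f) * p2.g, abs=1e-12)
        assert pm.s == pytest.approx(f * p1.s + (1 - f) * p2.s, abs=1e-12)


class TestReferencePhasor:
    def test_omega_tau_one(self):
        p = reference_phasor(1.0, 1.0)
        assert (p.g, p.s) == (0.5, 0.5)

    def test_short_lifetime_limit(self):
        p = reference_phasor(1e-9, 0.2513)
        assert p.g == pytest.approx(1.0, abs=1e-6)
        assert p.s == pytest.approx(0.0, abs=1e-6)

    def test_on_semicircle_at_40mhz(self):
        omega = 2 * np.pi / 25.0
        p = reference_phasor(5.9, omega)
        wt = omega * 5.9
        assert p.g == pytest.approx(1 / (1 + wt**2), rel=1e-12)
        assert p.s == pytest.approx(wt / (1 + wt**2), rel=1e-12)
        assert (p.g - 0.5) ** 2 + p.s**2 == pytest.approx(0.25, rel=1e-12)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            reference_phasor(0.0, 1.0)


class TestPhasorLifetime:
    def test_omega_tau_one_point(self):
        tau_phi, tau_mod = phasor_lifetime(Phasor(0.5, 0.5, omega=2.0))
        assert tau_phi == pytest.approx(0.5)
        assert tau_mod == pytest.approx(0.5)

    def test_mixture_phase_below_modulation(self):
        omega = 2 * np.pi / 25.0
        p1 = reference_phasor(5.9, omega)
        p2 = reference_phasor(1.4, omega)
        mix = Phasor(0.5 * (p1.g + p2.g), 0.5 * (p1.s + p2.s), omega)
        tau_phi, tau_mod = phasor_lifetime(mix)
        assert tau_phi < tau_mod

    def test_origin_of_semicircle(self):
        tau_phi, _ = phasor_lifetime(Phasor(1.0, 0.0, omega=1.0))
        assert tau_phi == 0.0

    def test_nonpositive_g_rejected(self):
        with pytest.raises(ValueError, match="g <= 0"):
            phasor_lifetime(Phasor(0.0, 0.5, omega=1.0))

    def test_roundtrip_with_reference(self):
        omega = 2 * np.pi / 25.0
        for tau in (1.4, 5.5, 5.9):
            tau_phi, tau_mod = phasor_lifetime(reference_phasor(tau, omega))
            assert tau_phi == pytest.approx(tau, rel=1e-12)
            assert tau_mod == pytest.approx(tau, rel=1e-9)


def test_calibration_removes_gaussian_irf_shift():
    """Phasor calibration against a known-lifetime reference corrects an
    IRF-blurred measurement."""
    period, n_bins = 25.0, 512
    target = simulate_decay(4.0, 10**6, n_bins, period, irf_sigma=0.4, seed=3)
    ref = simulate_decay(1.0, 10**6, n_bins, period, irf_sigma=0.4, seed=4)
    p_raw = phasor_transform(target)
    p_cal = calibrate_phasor(p_raw, phasor_transform(ref), tau_ref=1.0)
    tau_phi, _ = phasor_lifetime(p_cal)
    assert tau_phi == pytest.approx(4.0, rel=0.02)
    # uncalibrated phase lifetime is visibly biased by the IRF shift
    assert abs(phasor_lifetime(p_raw)[0] - 4.0) > abs(tau_phi - 4.0)


class TestUnmixThree:
    @staticmethod
    def refs(omega=2 * np.pi / 25.0):
        return [reference_phasor(t, omega) for t in (5.9, 5.5, 1.4)]

    def test_vertex_recovers_unit_fraction(self):
        refs = self.refs()
        for i in range(3):
            f = unmix_three(refs[i], refs)
            expected = np.zeros(3)
            expected[i] = 1.0
            assert f == pytest.approx(expected, abs=1e-10)

    def test_centroid_recovers_equal_fractions(self):
        refs = self.refs()
        centroid = Phasor(np.mean([r.g for r in refs]), np.mean([r.s for r in refs]),
                          refs[0].omega)
        assert unmix_three(centroid, refs) == pytest.approx(np.ones(3) / 3, abs=1e-12)

    def test_interior_points_match_independent_least_squares(self):
        refs = self.refs()
        M = np.array([[r.g for r in refs], [r.s for r in refs], [1, 1, 1]])
        rng = np.random.default_rng(6)
        w = rng.dirichlet(np.ones(3), size=20)
        pts = w @ np.array([[r.g, r.s] for r in refs])
        fractions, residual = unmix_points(pts, refs)
        for i in range(20):
            rhs = np.array([pts[i, 0], pts[i, 1], 1.0])
            lstsq = np.linalg.lstsq(M, rhs, rcond=None)[0]
            assert fractions[i] == pytest.approx(lstsq, abs=1e-10)
            assert fractions[i] == pytest.approx(w[i], abs=1e-10)
        assert residual == pytest.approx(np.zeros(20), abs=1e-12)

    def test_outside_point_projected_with_residual(self):
        refs = self.refs()
        outside = Phasor(0.9, 0.45, refs[0].omega)  # beyond the long-tau edge
        fractions, residual = unmix_points([[outside.g, outside.s]], refs)
        assert residual[0] > 0
        assert fractions[0] == pytest.approx(fractions[0].clip(0), abs=0)
        assert fractions[0].sum() == pytest.approx(1.0)

    def test_collinear_references_rejected(self):
        omega = 1.0
        refs = [Phasor(0.1, 0.1, omega), Phasor(0.5, 0.5, omega), Phasor(0.9, 0.9, omega)]
        with pytest.raises(CollinearReferencesError):
            unmix_three(Phasor(0.5, 0.4, omega), refs)


class TestUnmixImage:
    def test_two_region_pure_scene_recovers_components(self):
        spec = SceneSpec(
            shape=(48, 48),
            components=[("long", 5.9), ("short", 1.4)],
            regions=[
                RegionSpec("ellipse", {"cy": 12, "cx": 24, "ay": 8, "ax": 10},
                           component=0, mean_photons=10_000),
                RegionSpec("ellipse", {"cy": 36, "cx": 24, "ay": 8, "ax": 10},
                           component=1, mean_photons=10_000),
            ],
            seed=5,
        )
        stack, truth = simulate_flim_image(spec)
        res = unmix_image(stack, ref_lifetimes=[5.9, 1.4], period=25.0,
                          intensity_threshold=100)
        for comp_scene, comp_ref in ((0, 0), (1, 1)):
            region = (truth["component_index"] == comp_scene) & res.mask
            mean_frac = np.nanmean(res.fractions[comp_ref][region])
            assert mean_frac >= 0.95

    def test_all_pixels_below_threshold_fully_masked(self):
        stack = np.ones((16, 8, 8))  # 16 photons per pixel
        res = unmix_image(stack, ref_lifetimes=[5.9, 5.5, 1.4], period=25.0,
                          intensity_threshold=100)
        assert not res.mask.any()
        assert np.isnan(res.fractions).all()
        assert res.component_images.sum() == 0

    def test_spatial_binning_identity_on_noiseless_homogeneous_input(self):
        period, n_bins = 25.0, 128
        d = expected_histogram([(5.9, 0.6), (1.4, 0.4)], n_bins, period, total=5000)
        stack = np.tile(d.counts[:, None, None], (1, 12, 12))
        kwargs = dict(ref_lifetimes=[5.9, 5.5, 1.4], period=period,
                      intensity_threshold=100)
        res1 = unmix_image(stack, spatial_binning=1, **kwargs)
        res2 = unmix_image(stack, spatial_binning=2, **kwargs)
        inner = np.zeros((12, 12), dtype=bool)
        inner[2:-2, 2:-2] = True  # windows fully inside the image
        assert np.allclose(res1.fractions[:, inner], res2.fractions[:, inner],
                           atol=1e-6)

    def test_component_images_conserve_intensity(self):
        stack, _ = simulate_flim_image(SceneSpec(
            shape=(32, 32),
            components=[("a", 5.9), ("b", 1.4)],
            regions=[RegionSpec("ellipse", {"cy": 16, "cx": 16, "ay": 10, "ax": 10},
                                component=0, mean_photons=2000),
                     RegionSpec("dots", {"n_dots": 10, "radius": 2.0},
                                component=1, mean_photons=2000)],
            seed=8,
        ))
        res = unmix_image(stack, ref_lifetimes=[5.9, 1.4], period=25.0,
                          intensity_threshold=100)
        total = res.component_images.sum(axis=0)
        assert np.allclose(total[res.mask], res.total_intensity[res.mask], rtol=1e-6)
        assert (total[~res.mask] == 0).all()

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            unmix_image(np.zeros((0, 4, 4)), ref_lifetimes=[5.9, 1.4])


class TestFitMonoexponential:
    def test_noiseless_expectation_recovers_tau_exactly(self):
        decay = expected_histogram([(2.0, 1.0)], n_bins=256, period=25.0,
                                   total=10**6)
        fit = fit_monoexponential(decay)
        assert fit.tau == pytest.approx(2.0, abs=1e-6)
        assert fit.background == pytest.approx(0.0, abs=1e-6)

    def test_simulated_decay_within_three_standard_errors(self):
        decay = simulate_decay(1.8, 10**6, n_bins=256, period=25.0, seed=13)
        fit = fit_monoexponential(decay)
        assert fit.tau_se < 0.01
        assert abs(fit.tau - 1.8) < 3 * fit.tau_se

    def test_background_fraction_recovered(self):
        period, n_bins = 25.0, 256
        pure = expected_histogram([(2.5, 1.0)], n_bins, period, total=9e5)
        flat = np.full(n_bins, 1e5 / n_bins)
        decay = DecayHistogram(pure.bin_edges, pure.counts + flat, period)
        fit = fit_monoexponential(decay)
        assert fit.tau == pytest.approx(2.5, rel=1e-3)
        assert fit.background == pytest.approx(0.1, abs=1e-3)

    def test_all_zero_histogram_rejected(self):
        edges = np.linspace(0.0, 25.0, 257)
        decay = DecayHistogram(edges, np.zeros(256), 25.0)
        with pytest.raises(ValueError):
            fit_monoexponential(decay)

    def test_agrees_with_phasor_phase_lifetime_at_high_counts(self):
        decay = simulate_decay(3.0, 10**6, n_bins=512, period=25.0, seed=21)
        fit = fit_monoexponential(decay)
        tau_phi, _ = phasor_lifetime(phasor_transform(decay))
        assert fit.tau == pytest.approx(tau_phi, rel=0.02)


class TestDecayHistogram:
    def test_nonuniform_bins_rejected(self):
        edges = np.array([0.0, 1.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="uniform"):
            DecayHistogram(edges, np.ones(3), 25.0)

    def test_span_beyond_period_rejected(self):
        edges = np.linspace(0.0, 30.0, 31)
        with pytest.raises(ValueError, match="period"):
            DecayHistogram(edges, np.ones(30), 25.0)

    def test_csv_roundtrip(self, tmp_path):
        decay = simulate_decay(2.0, 10**4, n_bins=64, period=25.0, seed=1)
        path = tmp_path / "d.csv"
        decay.to_csv(path)
        back = DecayHistogram.from_csv(path, period=25.0)
        assert np.allclose(back.counts, decay.counts)
        assert np.allclose(back.bin_edges, decay.bin_edges)
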