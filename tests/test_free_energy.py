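"""Free-energy machinery: Boltzmann inversion, WHAM, tilt profiles,
2D composition and accessible-region extraction."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memgrad.errors import FitConvergenceError, ValidationError
from memgrad.free_energy import (
    CoordinateMapping,
    FreeEnergyProfile,
    FreeEnergySurface,
    UmbrellaWindow,
    accessible_regions,
    boltzmann_invert_density,
    compose_surface_2d,
    tilt_free_energy,
    wham_1d,
)
from memgrad.surrogate import SortingModelParams, UmbrellaBias, simulate_sorting_ensemble
from memgrad.thickness import LinearRegionFit
from memgrad.units import KBT_300K


def _biased_ou_windows(tau=50.0, diffusion=0.04, x_eq=0.0, k_bias=25.0,
                       centers=(-2.0, -1.0, 0.0, 1.0, 2.0), seed=100):
    """Umbrella windows sampled from the biased surrogate SDE.

    Unbiased well: U(x) = kBT (x - x_eq)^2 / (2 D tau)."""
    windows = []
    for i, c in enumerate(centers):
        params = SortingModelParams(
            x_eq=x_eq, tau=tau, diffusion=diffusion, x0=c, n_steps=20000,
            dt=0.5, n_replicas=20, seed=seed + i,
            bias=UmbrellaBias(center=c, stiffness=k_bias),
        )
        ens = simulate_sorting_ensemble(params)
        samples = ens.positions[:, 2000:].ravel()  # discard equilibration
        windows.append(UmbrellaWindow(center=c, stiffness=k_bias, samples=samples))
    return windows


class TestBoltzmannInversion:
    def test_uniform_density_gives_zero_everywhere(self):
        prof = boltzmann_invert_density(np.arange(5.0), np.full(5, 0.2))
        assert np.allclose(prof.values, 0.0)

    def test_density_ratio_e_gives_exactly_one_kbt(self):
        prof = boltzmann_invert_density([0.0, 1.0], [np.e, 1.0])
        assert prof.values[0] == 0.0
        assert prof.values[1] == pytest.approx(1.0, rel=1e-12)

    def test_zero_density_bins_undefined(self):
        prof = boltzmann_invert_density([0, 1, 2], [1.0, 0.0, 0.5])
        assert np.isnan(prof.values[1])

    def test_all_zero_density_rejected(self):
        with pytest.raises(ValidationError):
            boltzmann_invert_density([0, 1], [0.0, 0.0])

    def test_ou_stationary_samples_invert_to_quadratic_well(self):
        params = SortingModelParams(
            x_eq=5.0, tau=100.0, diffusion=0.02, x0=5.0, n_steps=20000,
            dt=1.0, n_replicas=25, seed=8,
        )
        ens = simulate_sorting_ensemble(params)
        samples = ens.positions[:, 2000:].ravel()
        edges = np.linspace(5 - 4, 5 + 4, 41)
        counts, _ = np.histogram(samples, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        prof = boltzmann_invert_density(centers, counts)
        var = 0.02 * 100.0  # D tau
        expected = (centers - 5.0) ** 2 / (2 * var)
        m = prof.defined & (counts > 200)
        # align at the observed reference bin and compare shapes
        assert np.abs((prof.values - expected[prof.reference_index])[m]
                      - (expected - expected[prof.reference_index])[m]).max() < 0.25


class TestWham:
    def test_single_unbiased_window_equals_boltzmann_inversion(self):
        rng = np.random.default_rng(9)
        samples = rng.normal(0.0, 1.0, 5000)
        edges = np.linspace(-3, 3, 31)
        window = UmbrellaWindow(center=0.0, stiffness=0.0, samples=samples)
        res = wham_1d([window], edges, kbt=KBT_300K)
        counts, _ = np.histogram(samples, bins=edges)
        direct = boltzmann_invert_density(res.profile.coordinates, counts)
        m = direct.defined
        assert np.allclose(res.profile.values[m], direct.values[m], atol=1e-12)
        assert res.n_iterations <= 2

    def test_two_window_toy_matches_brute_force_fixed_point(self):
        # independent plain-python iteration of the consistency equations
        rng = np.random.default_rng(10)
        w1 = UmbrellaWindow(0.5, 4.0, rng.normal(0.8, 0.6, 400))
        w2 = UmbrellaWindow(2.5, 4.0, rng.normal(2.2, 0.6, 600))
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        kbt = 2.5
        res = wham_1d([w1, w2], edges, kbt=kbt, tol=1e-14)

        centers = [0.5, 1.5, 2.5]
        n = [np.histogram(w.samples, bins=edges)[0] for w in (w1, w2)]
        c = [[np.exp(-0.5 * w.stiffness * (x - w.center) ** 2 / kbt) for x in centers]
             for w in (w1, w2)]
        f = [1.0, 1.0]
        for _ in range(200000):
            p = [0.0, 0.0, 0.0]
            for j in range(3):
                num = n[0][j] + n[1][j]
                den = sum(sum(n[i]) * f[i] * c[i][j] for i in range(2))
                p[j] = num / den
            z = sum(p)
            p = [pj / z for pj in p]
            f_new = [1.0 / sum(c[i][j] * p[j] for j in range(3)) for i in range(2)]
            f_new = [fi / f_new[0] for fi in f_new]
            if abs(f_new[1] - f[1]) < 1e-15:
                f = f_new
                break
            f = f_new
        brute = -np.log(np.array(p))
        brute -= brute.min()
        assert np.allclose(res.profile.values, brute, atol=1e-9)
        assert np.allclose(np.exp(res.window_free_energies), f, rtol=1e-8)

    def test_biased_ou_umbrellas_recover_quadratic_pmf(self):
        tau, diffusion = 50.0, 0.04
        windows = _biased_ou_windows(tau=tau, diffusion=diffusion)
        edges = np.linspace(-3.0, 3.0, 61)
        res = wham_1d(windows, edges, kbt=KBT_300K)
        x = res.profile.coordinates
        analytic = x**2 / (2.0 * diffusion * tau)  # kBT units
        analytic = analytic - analytic[res.profile.reference_index]
        pooled = sum(np.histogram(w.samples, bins=edges)[0] for w in windows)
        covered = res.profile.defined & (pooled > 500) & (np.abs(x) < 2.5)
        assert covered.sum() > 20
        assert np.abs(res.profile.values[covered] - analytic[covered]).max() < 0.2

    def test_non_overlapping_windows_error_lists_gap(self):
        rng = np.random.default_rng(11)
        w1 = UmbrellaWindow(0.0, 50.0, rng.normal(0.0, 0.05, 500))
        w2 = UmbrellaWindow(5.0, 50.0, rng.normal(5.0, 0.05, 500))
        with pytest.raises(ValidationError, match="overlap"):
            wham_1d([w1, w2], np.linspace(-1, 6, 71), kbt=KBT_300K)

    def test_non_convergence_is_flagged_with_diagnostics(self):
        windows = _biased_ou_windows(centers=(-1.0, 0.0, 1.0), seed=400)
        with pytest.raises(FitConvergenceError) as exc:
            wham_1d(windows, np.linspace(-3, 3, 61), kbt=KBT_300K,
                    tol=1e-14, max_iterations=2)
        assert "n_windows" in exc.value.diagnostics


class TestTiltFreeEnergy:
    def test_isotropic_rod_matches_sine_jacobian(self):
        # isotropic orientation: cos(theta) uniform -> dF = -ln(sin/sin0)
        rng = np.random.default_rng(12)
        theta = np.degrees(np.arccos(rng.uniform(0.0, 1.0, 500_000)))
        prof = tilt_free_energy(theta, bin_width=1.0)
        counts, _ = np.histogram(theta, bins=np.arange(0, 90.5, 1.0))
        centers = prof.coordinates
        theta0 = centers[prof.reference_index]
        expected = -np.log(np.sin(np.radians(centers)) / np.sin(np.radians(theta0)))
        m = prof.defined & (counts > 500)
        assert np.abs(prof.values[m] - expected[m]).max() < 0.15

    def test_modal_bin_is_exact_zero(self):
        rng = np.random.default_rng(13)
        prof = tilt_free_energy(rng.normal(25.0, 5.0, 10000))
        assert prof.values[prof.reference_index] == 0.0
        assert np.nanmin(prof.values) == 0.0

    def test_constant_tilt_single_defined_bin(self):
        prof = tilt_free_energy(np.full(100, 23.2))
        assert np.isfinite(prof.values).sum() == 1
        assert prof.values[prof.reference_index] == 0.0


def _quadratic_surface(kappa_d=200.0, kappa_t=0.01, d_star=4.0, t_star=20.0,
                       d_step=0.005, t_step=0.25):
    d = np.arange(3.0, 5.0, d_step)
    t = np.arange(0.0, 90.0, t_step)
    vals = 0.5 * kappa_d * (d[:, None] - d_star) ** 2 + 0.5 * kappa_t * (t[None, :] - t_star) ** 2
    vals -= vals.min()
    i, j = np.unravel_index(np.argmin(vals), vals.shape)
    return FreeEnergySurface(d, t, vals, (float(d[i]), float(t[j])), mask_above=np.inf)


class TestComposeSurface:
    def test_flat_pmf_broadcasts_tilt_profile(self):
        pmf = FreeEnergyProfile(np.linspace(3, 5, 11), np.zeros(11), 0)
        theta = np.arange(0.0, 90.0, 1.0)
        tilt = FreeEnergyProfile(theta, np.abs(theta - 20.0) / 10.0, 20)
        surface = compose_surface_2d(pmf, [(4.0, tilt)])
        for row in surface.values:
            assert np.allclose(row[np.isfinite(row)],
                               tilt.values[np.isfinite(row)], atol=1e-12)

    def test_global_minimum_at_pmf_minimum_and_window_mode(self):
        d = np.linspace(3, 5, 21)
        pmf = FreeEnergyProfile(d, (d - 4.2) ** 2 * 5.0 - ((d - 4.2) ** 2 * 5.0).min(), 12)
        theta = np.arange(0.0, 90.0, 1.0)
        tilt_a = FreeEnergyProfile(theta, np.abs(theta - 30.0) / 5.0, 30)
        tilt_b = FreeEnergyProfile(theta, np.abs(theta - 10.0) / 5.0, 10)
        surface = compose_surface_2d(pmf, [(3.5, tilt_a), (4.5, tilt_b)])
        d_min, t_min = surface.minimum
        assert d_min == pytest.approx(d[np.argmin(pmf.values)])
        assert t_min == pytest.approx(10.5, abs=1.0)  # nearest window is b

    def test_every_node_is_sum_minus_offset(self):
        rng = np.random.default_rng(14)
        d = np.linspace(3, 5, 9)
        pmf_raw = rng.uniform(0, 3, 9)
        pmf = FreeEnergyProfile(d, pmf_raw - pmf_raw.min(), int(np.argmin(pmf_raw)))
        theta = np.linspace(0, 88, 23)
        tilts, positions = [], np.linspace(3.1, 4.9, 4)
        for k in range(4):
            raw = rng.uniform(0, 4, 23)
            raw[raw.argmin()] = 0.0
            tilts.append((positions[k], FreeEnergyProfile(theta, raw - raw.min(), int(raw.argmin()))))
        surface = compose_surface_2d(pmf, tilts, mask_above=np.inf)
        # brute-force re-addition oracle
        raw_sum = np.empty((9, 23))
        for i in range(9):
            k = np.abs(positions - d[i]).argmin()
            raw_sum[i] = pmf.values[i] + tilts[k][1].values
        assert np.allclose(surface.values, raw_sum - raw_sum.min(), atol=1e-12)

    def test_mapping_applied_and_mask_preserves_minimum(self):
        x = np.linspace(8, 32, 25)
        vals = 0.05 * (x - 20.0) ** 2
        pmf = FreeEnergyProfile(x, vals - vals.min(), 12)
        theta = np.arange(0.0, 90.0, 2.0)
        tilt = FreeEnergyProfile(theta, np.abs(theta - 20.0), 10)
        mapping = CoordinateMapping.from_linear_fit(
            LinearRegionFit(0.077, 2.7, 1.0, (8.0, 32.0))
        )
        surface = compose_surface_2d(pmf, [(20.0, tilt)], mapping=mapping, mask_above=10.0)
        assert surface.d_centers[0] == pytest.approx(2.7 + 0.077 * 8.0)
        assert np.nanmin(surface.values) == 0.0
        assert np.nanmax(surface.values) <= 10.0 + 1e-9


class TestAccessibleRegions:
    def test_quadratic_level_set_width_closed_form(self):
        # width of {0.5 kappa (d-d*)^2 <= n kBT} is 2 sqrt(2 n / kappa)
        surface = _quadratic_surface(kappa_d=200.0)
        regions = accessible_regions(surface, thresholds=(1.0, 2.0))
        (lo, hi), = regions[1.0]["d"]
        assert hi - lo == pytest.approx(2.0 * np.sqrt(2.0 / 200.0), abs=0.015)
        (lo2, hi2), = regions[2.0]["d"]
        assert hi2 - lo2 == pytest.approx(2.0 * np.sqrt(4.0 / 200.0), abs=0.015)

    def test_double_well_splits_then_merges(self):
        d = np.arange(3.0, 5.0, 0.01)
        t = np.arange(0.0, 90.0, 1.0)
        # two thickness minima separated by a 3 kBT barrier (capped walls)
        well = np.minimum(40.0 * (d - 3.5) ** 2, 40.0 * (d - 4.5) ** 2)
        well = np.minimum(well, 3.0)
        vals = np.repeat(well[:, None], len(t), axis=1)
        vals -= vals.min()
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        surface = FreeEnergySurface(d, t, vals, (float(d[i]), float(t[j])), np.inf)
        regions = accessible_regions(surface, thresholds=(1.0, 5.0))
        assert len(regions[1.0]["d"]) == 2
        assert len(regions[5.0]["d"]) == 1

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_nesting_across_thresholds_on_random_surfaces(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.0, 12.0, (15, 18))
        vals -= vals.min()
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        d = np.linspace(3, 5, 15)
        t = np.linspace(0, 85, 18)
        surface = FreeEnergySurface(d, t, vals, (float(d[i]), float(t[j])), np.inf)
        regions = accessible_regions(surface, thresholds=(1.0, 2.0, 5.0, 10.0))

        def covered(intervals, pt):
            return any(lo - 1e-9 <= pt <= hi + 1e-9 for lo, hi in intervals)

        thresholds = [1.0, 2.0, 5.0, 10.0]
        for small, large in zip(thresholds[:-1], thresholds[1:]):
            for axis, grid in (("d", d), ("theta", t)):
                for pt in grid:
                    if covered(regions[small][axis], pt):
                        assert covered(regions[large][axis], pt)
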