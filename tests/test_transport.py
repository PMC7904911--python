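"""Electron transport: stopping power, ranges, scoring, MC properties."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from ymicrodose.constants import MEV_TO_J, WATER_DENSITY_G_CM3
from ymicrodose.dosimetry import MicrosphereConfig
from ymicrodose.errors import InvalidParameterError
from ymicrodose.synthetic import calibrated_common_factor, generate_config
from ymicrodose.transport import (
    DoseGrid,
    TransportParams,
    csda_range,
    run_histories,
    stopping_power,
    transport_electron,
)


class TestStoppingPower:
    def test_collision_values_match_water_tabulations(self):
        # reference collision stopping powers of liquid water
        assert stopping_power(1.0) == pytest.approx(1.849, rel=0.02)
        assert stopping_power(0.1) == pytest.approx(4.115, rel=0.02)

    def test_low_energy_rise(self):
        assert stopping_power(0.05) > stopping_power(0.5)

    def test_total_exceeds_collision(self):
        assert stopping_power(2.0, "total") > stopping_power(2.0, "collision")

    def test_below_grid_minimum_rejected(self):
        with pytest.raises(InvalidParameterError):
            stopping_power(1e-5)
        with pytest.raises(InvalidParameterError):
            stopping_power(1.0, kind="bogus")


class TestCsdaRange:
    def test_endpoint_range_rounds_to_11_mm(self):
        assert round(csda_range(2.27)) == 11

    def test_1mev_range_matches_water_tabulation(self):
        # reference CSDA range at 1 MeV: 0.437 g/cm^2 -> 4.37 mm
        assert csda_range(1.0) == pytest.approx(4.37, rel=0.02)

    def test_strictly_increasing(self):
        assert csda_range(2.27) > csda_range(1.0) > csda_range(0.1)

    def test_at_or_below_cutoff_rejected(self):
        with pytest.raises(InvalidParameterError):
            csda_range(1e-3)


class TestTransportElectron:
    def test_energy_conservation_on_padded_grid(self):
        # 24 mm cube of water encloses the full CSDA range of any Y-90 beta
        grid = DoseGrid.empty((-12000, -12000, -12000), (200, 200, 200), (120, 120, 120))
        params = TransportParams(radiative_losses=False, multiple_scattering=True)
        n = 16
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        E0 = rng.uniform(0.05, 2.27, n)
        transport_electron(np.zeros((n, 3)), dirs, E0, grid, params, rng=1)
        assert grid.total_energy_J() == pytest.approx(E0.sum() * MEV_TO_J, rel=1e-9)

    def test_below_cutoff_deposits_locally(self):
        grid = DoseGrid.empty((0, 0, 0), (10, 10, 10), (3, 3, 3))
        params = TransportParams(energy_cutoff=0.05, radiative_losses=False)
        transport_electron([15.0, 15.0, 15.0], [0.0, 0.0, 1.0], 0.02, grid, params, rng=0)
        energy = grid.values * grid.voxel_mass_g * 1e-3 / MEV_TO_J
        assert energy[1, 1, 1] == pytest.approx(0.02, rel=1e-12)
        assert np.count_nonzero(energy) == 1

    def test_invalid_direction_and_energy_rejected(self):
        grid = DoseGrid.empty((0, 0, 0), (10, 10, 10), (2, 2, 2))
        params = TransportParams()
        with pytest.raises(InvalidParameterError):
            transport_electron([0, 0, 0], [0, 0, 2.0], 1.0, grid, params)
        with pytest.raises(InvalidParameterError):
            transport_electron([0, 0, 0], [0, 0, 1.0], -1.0, grid, params)

    def test_slab_depth_dose_matches_csda_oracle(self):
        """Straight-ahead monoenergetic beam vs the analytic 1-D CSDA solution."""
        E0, dz, nz = 1.0, 50.0, 100
        grid = DoseGrid.empty((-10000, -10000, 0), (20000, 20000, dz), (1, 1, nz))
        params = TransportParams(
            energy_cutoff=0.01,
            step_energy_fraction=0.02,
            multiple_scattering=False,
            radiative_losses=False,
        )
        n = 400
        transport_electron(
            np.zeros((n, 3)), np.tile([0.0, 0.0, 1.0], (n, 1)), np.full(n, E0),
            grid, params, rng=1,
        )
        engine = grid.values[0, 0, :] * grid.voxel_mass_g * 1e-3 / MEV_TO_J / n

        # independent oracle: integrate dE/dz = -S(E) rho, then difference
        sol = solve_ivp(
            lambda z, E: [-stopping_power(max(E[0], 1e-3))],
            (0.0, 0.6), [E0], dense_output=True, max_step=1e-3, rtol=1e-8,
        )
        edges_cm = np.arange(nz + 1) * dz / 1e4
        zstop = brentq(lambda z: sol.sol(z)[0] - params.energy_cutoff, 0, sol.t[-1] - 1e-9)
        Ez = np.array([sol.sol(min(z, zstop))[0] for z in edges_cm])
        oracle = Ez[:-1] - Ez[1:]
        oracle[int(zstop // (dz / 1e4))] += params.energy_cutoff  # residual deposit

        n90 = int(0.9 * csda_range(E0) * 1000 / dz)
        rms = np.sqrt(np.mean((engine[:n90] - oracle[:n90]) ** 2)) / oracle[:n90].mean()
        assert rms < 0.02

    def test_radial_kernel_matches_straight_line_oracle(self):
        """Isotropic point source in the thin layer vs brute-force kernel."""
        from ymicrodose.transport import _RANGE

        E0, T, vox = 0.5, 32.5, 20.0
        nx, ny = 90, 65
        grid = DoseGrid.empty((0, 0, 0), (vox, vox, T), (nx, ny, 1))
        center = np.array([900.0, 650.0, T / 2])
        rng = np.random.default_rng(5)
        n = 4000
        cos_t = rng.uniform(-1, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        sin_t = np.sqrt(1 - cos_t**2)
        dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
        params = TransportParams(
            energy_cutoff=0.01, step_energy_fraction=0.05,
            multiple_scattering=False, radiative_losses=False,
        )
        transport_electron(np.tile(center, (n, 1)), dirs, np.full(n, E0),
                           grid, params, rng=9, prune=True)
        engine = grid.values[:, :, 0] / n

        # oracle: continuous CSDA deposition along the same straight lines
        R0 = _RANGE.range_g_cm2(E0)
        ds = 1.0
        s = np.arange(0.5, R0 / WATER_DENSITY_G_CM3 * 1e4, ds)
        Es = np.interp(R0 - s * 1e-4 * WATER_DENSITY_G_CM3, _RANGE.r, _RANGE.e)
        w = np.where(
            Es > params.energy_cutoff,
            stopping_power(np.maximum(Es, 1e-3)) * WATER_DENSITY_G_CM3 * 1e-4 * ds,
            0.0,
        )
        icut = np.searchsorted(-Es, -params.energy_cutoff)
        if icut < len(s):
            w[icut] = params.energy_cutoff
            w[icut + 1:] = 0.0
        oracle = np.zeros((nx, ny))
        for d in dirs:
            pts = center + np.outer(s, d)
            ij = np.floor(pts[:, :2] / vox).astype(int)
            ok = (
                (pts[:, 2] >= 0) & (pts[:, 2] < T)
                & (ij[:, 0] >= 0) & (ij[:, 0] < nx)
                & (ij[:, 1] >= 0) & (ij[:, 1] < ny)
            )
            np.add.at(oracle, (ij[ok, 0], ij[ok, 1]), w[ok])
        oracle = oracle / n * MEV_TO_J / (grid.voxel_mass_g * 1e-3)

        xc = (np.arange(nx) + 0.5) * vox - center[0]
        yc = (np.arange(ny) + 0.5) * vox - center[1]
        rr = np.hypot(*np.meshgrid(xc, yc, indexing="ij"))
        ring_engine, ring_oracle = [], []
        for r1 in np.arange(40, 320, 40.0):
            m = (rr >= r1) & (rr < r1 + 40)
            ring_engine.append(engine[m].mean())
            ring_oracle.append(oracle[m].mean())
        ring_engine, ring_oracle = np.array(ring_engine), np.array(ring_oracle)
        np.testing.assert_allclose(ring_engine, ring_oracle, rtol=0.05)
        assert np.all(np.diff(ring_engine) < 0)  # radially decreasing profile


@pytest.fixture(scope="module")
def small_run(spectrum):
    config = generate_config(15, seed=21)
    params = TransportParams(n_histories=20_000, seed=22)
    return config, params, run_histories(config, spectrum, params)


class TestRunHistories:
    def test_seed_determinism(self, spectrum, small_run):
        config, params, (grid, result) = small_run
        grid2, result2 = run_histories(config, spectrum, params)
        np.testing.assert_array_equal(grid.values, grid2.values)
        assert result.D_calc == result2.D_calc

    def test_scoring_result_normalization_identity(self, small_run):
        _, _, (_, result) = small_run
        assert result.per_sphere_factor * result.n_spheres == pytest.approx(
            result.D_calc, rel=1e-12
        )

    def test_grid_average_consistent_with_dcalc(self, small_run):
        _, _, (grid, result) = small_run
        # FOV-average of the map equals the scored FOV-cuboid average
        assert grid.fov_average() == pytest.approx(result.D_calc, rel=1e-9)
        assert np.all(grid.values >= 0)

    def test_dcalc_stable_when_doubling_histories(self, spectrum, small_run):
        config, params, (_, r1) = small_run
        from dataclasses import replace

        r2 = run_histories(config, spectrum, replace(params, n_histories=40_000))[1]
        combined_se = np.hypot(r1.mc_standard_error, r2.mc_standard_error)
        assert abs(r1.D_calc - r2.D_calc) < 3 * combined_se

    def test_per_decay_dose_independent_of_sphere_count(self, spectrum, small_run):
        _, _, (_, r15) = small_run
        config216 = generate_config(216, seed=23)
        r216 = run_histories(
            config216, spectrum, TransportParams(n_histories=20_000, seed=24)
        )[1]
        assert r216.per_sphere_factor == pytest.approx(r15.per_sphere_factor, rel=0.06)

    def test_per_sphere_factor_near_study_calibration(self, small_run):
        """The simulated per-sphere dose factor should land near the value
        implied by the printed well doses and sphere counts (~2.8e-8
        Gy/decay/sphere)."""
        _, _, (_, result) = small_run
        assert result.per_sphere_factor == pytest.approx(
            calibrated_common_factor(), rel=0.25
        )

    def test_single_sphere_map_peaks_at_the_sphere(self, spectrum):
        config = MicrosphereConfig(np.array([[900.0, 650.0]]))
        grid, _ = run_histories(
            config, spectrum, TransportParams(n_histories=5_000, seed=3),
            voxel_size_um=(20.0, 20.0, None),
        )
        ix, iy = np.unravel_index(grid.values[:, :, 0].argmax(), grid.values[:, :, 0].shape)
        assert abs((ix + 0.5) * 20 - 900) <= 40
        assert abs((iy + 0.5) * 20 - 650) <= 40

    def test_empty_configuration_rejected(self, spectrum):
        with pytest.raises(InvalidParameterError):
            run_histories(
                MicrosphereConfig(np.empty((0, 2))), spectrum, TransportParams()
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidParameterError):
            TransportParams(step_energy_fraction=0.5)
        with pytest.raises(InvalidParameterError):
            TransportParams(n_histories=0)
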