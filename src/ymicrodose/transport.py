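"""Condensed-history electron transport in water on a voxel dose grid.

The engine realizes the dosimetry chain of the in vitro microsphere model:
decays are sampled homogeneously inside the spheres, beta energies from the
Y-90 spectrum, directions isotropically; each electron is walked through an
unbounded water medium in steps of bounded fractional energy loss, with the
energy lost per step spread along the step and scored into the voxels of a
grid spanning the field of view times one sphere diameter.  Lateral
deflections use the Highland Gaussian multiple-scattering angle per step.
Electrons that leave the thin scoring layer keep being tracked in water and
are scored again if they re-enter; an electron is abandoned once its
residual CSDA range cannot bring it back to the grid.

Stopping powers are computed from the Berger-Seltzer (Moller) collision
formula with the Sternheimer density-effect correction for liquid water;
the small radiative component is estimated with the E*Z/800 rule and, by
default, subtracted from the electron but not deposited (escaping
bremsstrahlung is discarded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    ELECTRON_MASS_MEV,
    MEV_TO_J,
    WATER_DENSITY_G_CM3,
    WATER_EFFECTIVE_Z,
    WATER_MEAN_EXCITATION_MEV,
    WATER_RADIATION_LENGTH_G_CM2,
    WATER_STERNHEIMER,
    WATER_Z_OVER_A,
)
from .decay_source import BetaSpectrum, sample_energies
from .dosimetry import MicrosphereConfig, ScoringResult, sample_decay_position
from .errors import InvalidParameterError

__all__ = [
    "TransportParams",
    "DoseGrid",
    "stopping_power",
    "csda_range",
    "transport_electron",
    "run_histories",
]

_E_GRID_MIN = 1e-3  # MeV; sub-keV electrons are treated as locally deposited


# ----------------------------------------------------------------------
# stopping power and CSDA range


def stopping_power(E, kind: str = "collision"):
    """Mass stopping power of liquid water in MeV cm^2/g.

    ``kind`` is ``collision`` (Berger-Seltzer with density effect),
    ``radiative`` (E*Z/800 estimate) or ``total``.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < _E_GRID_MIN * (1 - 1e-12)):
        raise InvalidParameterError(f"energy below the {_E_GRID_MIN} MeV grid minimum")
    tau = E / ELECTRON_MASS_MEV
    beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
    F = 1.0 - beta2 + (tau**2 / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / (tau + 1.0) ** 2
    # Sternheimer density effect, liquid water
    st = WATER_STERNHEIMER
    x = np.log10(np.sqrt(tau * (tau + 2.0)))
    delta = np.where(
        x < st["x0"],
        0.0,
        np.where(
            x < st["x1"],
            4.6052 * x + st["a"] * np.maximum(st["x1"] - x, 0.0) ** st["m"] - st["C"],
            4.6052 * x - st["C"],
        ),
    )
    arg = tau**2 * (tau + 2.0) / 2.0 / (WATER_MEAN_EXCITATION_MEV / ELECTRON_MASS_MEV) ** 2
    s_col = 0.153536 / beta2 * WATER_Z_OVER_A * (np.log(arg) + F - delta)
    if kind == "collision":
        out = s_col
    elif kind == "radiative":
        out = s_col * E * WATER_EFFECTIVE_Z / 800.0
    elif kind == "total":
        out = s_col * (1.0 + E * WATER_EFFECTIVE_Z / 800.0)
    else:
        raise InvalidParameterError(f"unknown stopping-power kind: {kind!r}")
    return out if out.ndim else float(out)


class _RangeTable:
    """Cached CSDA range table R(E) = int dE'/S_total(E') from the grid minimum."""

    def __init__(self, e_max: float = 3.0, n: int = 4000):
        from scipy.integrate import cumulative_trapezoid

        self.e = np.linspace(_E_GRID_MIN, e_max, n)
        inv = 1.0 / stopping_power(self.e, kind="total")
        self.r = cumulative_trapezoid(inv, self.e, initial=0.0)  # g/cm^2

    def range_g_cm2(self, E):
        return np.interp(E, self.e, self.r)


_RANGE = _RangeTable()


def csda_range(E) -> float | np.ndarray:
    """CSDA range in mm of unit-density water (total stopping power)."""
    E = np.asarray(E, dtype=float)
    if np.any(E <= _E_GRID_MIN):
        raise InvalidParameterError("energy must exceed the tabulation cutoff")
    out = _RANGE.range_g_cm2(E) / WATER_DENSITY_G_CM3 * 10.0  # g/cm^2 -> cm -> mm
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# transport parameters and dose grid


@dataclass(frozen=True)
class TransportParams:
    """Settings of the condensed-history walk.

    energy_cutoff : MeV; electrons below it deposit locally.
    step_energy_fraction : maximum fractional energy loss per step.
    n_histories : decays to simulate in :func:`run_histories`.
    seed : RNG seed for the whole run.
    multiple_scattering : Highland Gaussian deflection per step.
    radiative_losses : subtract radiative losses (not deposited); turn off
        for exact energy-conservation studies.
    batch_size : electrons advanced simultaneously.
    """

    energy_cutoff: float = 0.010
    step_energy_fraction: float = 0.05
    n_histories: int = 100_000
    seed: int = 0
    multiple_scattering: bool = True
    radiative_losses: bool = True
    batch_size: int = 50_000

    def __post_init__(self):
        if not (0 < self.energy_cutoff < 3.0):
            raise InvalidParameterError("energy_cutoff must be in (0, 3) MeV")
        if not (0 < self.step_energy_fraction <= 0.2):
            raise InvalidParameterError("step_energy_fraction must be in (0, 0.2]")
        if self.n_histories < 1:
            raise InvalidParameterError("n_histories must be >= 1")


@dataclass
class DoseGrid:
    """Voxelized dose map: origin/voxel_size in um, values in Gy per decay."""

    origin: np.ndarray
    voxel_size: np.ndarray
    shape: tuple
    values: np.ndarray = field(repr=False)

    @classmethod
    def empty(cls, origin, voxel_size, shape) -> "DoseGrid":
        return cls(
            origin=np.asarray(origin, dtype=float),
            voxel_size=np.asarray(voxel_size, dtype=float),
            shape=tuple(shape),
            values=np.zeros(shape, dtype=float),
        )

    @property
    def voxel_mass_g(self) -> float:
        vx = self.voxel_size
        return float(np.prod(vx) * 1e-12 * WATER_DENSITY_G_CM3)  # um^3 -> cm^3

    @property
    def total_mass_g(self) -> float:
        return self.voxel_mass_g * int(np.prod(self.shape))

    @property
    def extent_um(self) -> np.ndarray:
        return self.voxel_size * np.asarray(self.shape)

    def fov_average(self) -> float:
        """Mass-weighted average dose over the whole grid (uniform voxels)."""
        return float(self.values.mean())

    def total_energy_J(self) -> float:
        """Total energy (J) implied by the per-voxel doses and masses."""
        return float(self.values.sum() * self.voxel_mass_g * 1e-3)


# ----------------------------------------------------------------------
# the condensed-history walk


class _Accumulator:
    """Energy scorer over a grid, flat-indexed, with a per-history tally."""

    def __init__(self, grid: DoseGrid, n_hist: int):
        self.grid = grid
        self.flat = np.zeros(int(np.prod(grid.shape)), dtype=float)
        self.hist = np.zeros(n_hist, dtype=float)
        self.lo = grid.origin
        self.hi = grid.origin + grid.extent_um
        self.nx, self.ny, self.nz = grid.shape

    def deposit(self, points: np.ndarray, weights: np.ndarray, hist: np.ndarray):
        ijk = np.floor((points - self.lo) / self.grid.voxel_size).astype(np.int64)
        inside = (
            (ijk[:, 0] >= 0) & (ijk[:, 0] < self.nx)
            & (ijk[:, 1] >= 0) & (ijk[:, 1] < self.ny)
            & (ijk[:, 2] >= 0) & (ijk[:, 2] < self.nz)
        )
        if not np.any(inside):
            return
        ijk = ijk[inside]
        w = weights[inside]
        flat_idx = (ijk[:, 0] * self.ny + ijk[:, 1]) * self.nz + ijk[:, 2]
        self.flat += np.bincount(flat_idx, weights=w, minlength=self.flat.size)
        self.hist += np.bincount(hist[inside], weights=w, minlength=self.hist.size)

    def finalize_energy_mev(self) -> np.ndarray:
        return self.flat.reshape(self.grid.shape)


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _scatter(dirs: np.ndarray, theta0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate each direction by a Rayleigh(theta0) polar angle, uniform azimuth."""
    n = len(dirs)
    theta = theta0 * np.sqrt(-2.0 * np.log(np.maximum(rng.random(n), 1e-300)))
    theta = np.minimum(theta, np.pi)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    # orthonormal frame perpendicular to dirs
    a = np.zeros_like(dirs)
    small_z = np.abs(dirs[:, 2]) < 0.9
    a[small_z, 2] = 1.0
    a[~small_z, 0] = 1.0
    u = np.cross(dirs, a)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(dirs, u)
    st, ct = np.sin(theta), np.cos(theta)
    out = (
        dirs * ct[:, None]
        + (u * np.cos(phi)[:, None] + v * np.sin(phi)[:, None]) * st[:, None]
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _segment_deposit(acc, p0, p1, w, hist, spacing_um: float,
                     rng: np.random.Generator, max_sub: int = 256):
    """Spread step energies w along the segments p0->p1 as sub-point deposits.

    Sub-points sit at t = (k + u)/m with a per-segment random phase u, which
    makes the voxel allocation unbiased without breaking exact energy
    conservation (each segment always deposits w in total).
    """
    seg = p1 - p0
    length = np.linalg.norm(seg, axis=1)
    # skip segments whose bounding box misses the grid
    lo = np.minimum(p0, p1)
    hi = np.maximum(p0, p1)
    touch = np.all((hi >= acc.lo) & (lo <= acc.hi), axis=1)
    if not np.any(touch):
        return
    p0, seg, length, w, hist = p0[touch], seg[touch], length[touch], w[touch], hist[touch]
    m = np.clip(np.ceil(length / spacing_um).astype(np.int64), 1, max_sub)
    total = int(m.sum())
    rep = np.repeat(np.arange(len(m)), m)
    # sub-point parameter t = (k + u)/m within each segment
    k = np.arange(total) - np.repeat(np.concatenate(([0], np.cumsum(m)[:-1])), m)
    t = (k + rng.random(len(m))[rep]) / m[rep]
    pts = p0[rep] + seg[rep] * t[:, None]
    acc.deposit(pts, (w / m)[rep], hist[rep])


def _walk(
    pos: np.ndarray,
    dirs: np.ndarray,
    E: np.ndarray,
    hist: np.ndarray,
    acc: _Accumulator,
    params: TransportParams,
    rng: np.random.Generator,
    prune: bool,
):
    """Advance a batch of electrons to absorption (in-place consumes arrays)."""
    spacing = float(np.min(acc.grid.voxel_size)) / 3.0
    cut = params.energy_cutoff

    # below-cutoff injections deposit locally
    below = E < cut
    if np.any(below):
        acc.deposit(pos[below], E[below], hist[below])
        pos, dirs, E, hist = pos[~below], dirs[~below], E[~below], hist[~below]

    while len(E):
        dE = params.step_energy_fraction * E
        e_mid = np.maximum(E - 0.5 * dE, _E_GRID_MIN)  # midpoint-rule energy loss
        s_col = stopping_power(e_mid, kind="collision")
        if params.radiative_losses:
            s_tot = s_col * (1.0 + e_mid * WATER_EFFECTIVE_Z / 800.0)
        else:
            s_tot = s_col
        L_um = dE / (s_tot * WATER_DENSITY_G_CM3) * 1e4  # cm -> um
        newpos = pos + dirs * L_um[:, None]
        _segment_deposit(acc, pos, newpos, dE * (s_col / s_tot), hist, spacing, rng)
        E = E - dE
        pos = newpos

        done = E < cut
        if np.any(done):
            acc.deposit(pos[done], E[done], hist[done])
        keep = ~done

        if prune and np.any(keep):
            # abandon electrons whose residual range cannot reach the grid
            resid_um = _RANGE.range_g_cm2(E[keep]) / WATER_DENSITY_G_CM3 * 1e4
            gap = np.maximum(acc.lo - pos[keep], 0.0) + np.maximum(pos[keep] - acc.hi, 0.0)
            dist = np.linalg.norm(gap, axis=1)
            margin = float(np.linalg.norm(acc.grid.voxel_size))
            reachable = dist <= resid_um * 1.05 + margin
            keep_idx = np.flatnonzero(keep)
            keep[keep_idx[~reachable]] = False

        pos, dirs, E, hist = pos[keep], dirs[keep], E[keep], hist[keep]
        if not len(E):
            break

        if params.multiple_scattering:
            pc = np.sqrt(E * (E + 2.0 * ELECTRON_MASS_MEV))
            beta_pc = pc * pc / (E + ELECTRON_MASS_MEV)
            x_over_X0 = (
                params.step_energy_fraction * E / stopping_power(np.maximum(E, _E_GRID_MIN), "total")
            ) / WATER_RADIATION_LENGTH_G_CM2
            theta0 = 13.6 / beta_pc * np.sqrt(x_over_X0) * np.maximum(
                1.0 + 0.038 * np.log(x_over_X0), 0.25
            )
            dirs = _scatter(dirs, theta0, rng)


def transport_electron(
    start,
    direction,
    E0,
    grid: DoseGrid,
    params: TransportParams,
    rng: np.random.Generator | int | None = None,
    *,
    prune: bool = False,
) -> DoseGrid:
    """Transport one electron (or an array of electrons) and score the grid.

    ``start`` (um), ``direction`` (unit vector) and ``E0`` (MeV) may describe
    a single particle or arrays of shape (n, 3)/(n,).  The summed deposited
    energy of all electrons passed here is added onto ``grid.values`` in Gy
    (no per-history normalization; that is :func:`run_histories`' job).
    With ``prune=False`` (default) electrons are followed to absorption, so
    on a grid that encloses the full range the total scored energy equals
    the injected energy exactly.
    """
    start = np.atleast_2d(np.asarray(start, dtype=float))
    direction = np.atleast_2d(np.asarray(direction, dtype=float))
    E0 = np.atleast_1d(np.asarray(E0, dtype=float))
    if np.any(E0 < 0):
        raise InvalidParameterError("energy must be non-negative")
    norms = np.linalg.norm(direction, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise InvalidParameterError("direction must be a unit vector")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    acc = _Accumulator(grid, len(E0))
    _walk(start.copy(), direction.copy(), E0.copy(), np.arange(len(E0)), acc,
          params, rng, prune)
    energy = acc.finalize_energy_mev()
    grid.values += energy * MEV_TO_J / (grid.voxel_mass_g * 1e-3)
    return grid


def run_histories(
    config: MicrosphereConfig,
    spectrum: BetaSpectrum,
    params: TransportParams,
    *,
    voxel_size_um: tuple = (10.0, 10.0, None),
) -> tuple[DoseGrid, ScoringResult]:
    """Simulate ``params.n_histories`` decays of a sphere configuration.

    Each history picks a sphere uniformly (all spheres carry the same
    activity), a decay position homogeneously inside it, an isotropic
    direction and a spectrum energy, then transports the electron.

    Normalization: the FOV-average dose for a *single* decay is essentially
    independent of how many spheres share the FOV, while the dose of the
    whole sample scales with the sphere count.  The returned sample-level
    ``D_calc`` (and the grid values) are therefore expressed in Gy per
    decay-per-sphere: the per-history average times the number of spheres.
    Multiplying by the per-sphere expected decay count
    A0/lambda (1 - e^(-lambda t)) yields the accumulated dose (map).  The
    per-sphere-normalized factor ``D_calc / n_spheres`` is the plain
    per-decay dose, the quantity that is common across configurations.
    """
    if config.n_spheres == 0:
        raise InvalidParameterError("configuration has no spheres")
    vx, vy, vz = voxel_size_um
    if vz is None:
        vz = config.layer_thickness
    nx = int(round(config.fov[0] / vx))
    ny = int(round(config.fov[1] / vy))
    nz = int(round(config.layer_thickness / vz))
    grid = DoseGrid.empty((0.0, 0.0, 0.0), (vx, vy, vz), (nx, ny, nz))

    rng = np.random.default_rng(params.seed)
    acc = _Accumulator(grid, params.n_histories)
    centers = np.column_stack(
        [config.centers, np.full(config.n_spheres, config.layer_thickness / 2.0)]
    )
    radius = config.sphere_diameter / 2.0

    done = 0
    while done < params.n_histories:
        n = min(params.batch_size, params.n_histories - done)
        hist = np.arange(done, done + n)
        which = rng.integers(0, config.n_spheres, n)
        pos = sample_decay_position(centers[which], config.sphere_diameter, rng)
        dirs = _isotropic_directions(rng, n)
        E0 = sample_energies(spectrum, n, rng)
        _walk(pos, dirs, E0, hist, acc, params, rng, prune=True)
        done += n

    energy = acc.finalize_energy_mev()
    n_h = params.n_histories
    n_s = config.n_spheres
    grid.values = energy * MEV_TO_J / (grid.voxel_mass_g * 1e-3) / n_h * n_s

    # per-decay FOV-average dose and its Monte-Carlo standard error
    mass_kg = grid.total_mass_g * 1e-3
    per_hist_gy = acc.hist * MEV_TO_J / mass_kg
    d_per_decay = float(per_hist_gy.mean())
    se = float(per_hist_gy.std(ddof=1) / math.sqrt(n_h)) if n_h > 1 else float("nan")
    result = ScoringResult(
        D_calc=d_per_decay * n_s,
        n_spheres=n_s,
        mc_standard_error=se * n_s,
    )
    return grid, result
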