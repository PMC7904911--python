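"""Geometry and scoring layer of the microsphere dosimetry model.

Holds the sphere configuration inside the microscope field of view (FOV,
1800 um x 1300 um, water layer one sphere diameter thick), the FOV-cuboid
scoring summary with its per-sphere normalization, the accumulated
well-level dose, the 10/70 Gy dose bins used by the plate statistics, and
isodose contour extraction.

Coordinates: FOV origin at the top-left of the micrograph, x rightward,
y downward, continuous um units; voxel indices 0-based with half-open
intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .constants import (
    FOV_HEIGHT_UM,
    FOV_WIDTH_UM,
    SPHERE_DIAMETER_BAND_UM,
    SPHERE_DIAMETER_UM,
)
from .decay_source import DecaySource, cumulative_decays
from .errors import InvalidParameterError

if TYPE_CHECKING:  # avoid a circular import; transport imports this module
    from .transport import DoseGrid

__all__ = [
    "MicrosphereConfig",
    "ScoringResult",
    "DoseBin",
    "WellDose",
    "sample_decay_position",
    "common_dcalc",
    "well_dose",
    "classify_dose",
    "isodose_contours",
]


@dataclass(frozen=True)
class MicrosphereConfig:
    """Sphere centers (um, FOV frame) plus the simulated geometry.

    The water layer is one sphere diameter thick and spheres sit at the
    layer mid-plane, so the layer thickness always equals the diameter.
    """

    centers: np.ndarray
    sphere_diameter: float = SPHERE_DIAMETER_UM
    fov: tuple = (FOV_WIDTH_UM, FOV_HEIGHT_UM)

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "centers", centers)
        lo, hi = SPHERE_DIAMETER_BAND_UM
        if not (lo <= self.sphere_diameter <= hi):
            raise InvalidParameterError(
                f"sphere diameter {self.sphere_diameter} um outside the "
                f"manufacturer band [{lo}, {hi}] um"
            )
        if len(centers):
            if centers[:, 0].min() < 0 or centers[:, 0].max() > self.fov[0] \
                    or centers[:, 1].min() < 0 or centers[:, 1].max() > self.fov[1]:
                raise InvalidParameterError("sphere center outside the FOV")
            if len(centers) > 1:
                from scipy.spatial import cKDTree

                d, _ = cKDTree(centers).query(centers, k=2)
                if d[:, 1].min() < self.sphere_diameter * (1 - 1e-9):
                    raise InvalidParameterError("overlapping spheres in configuration")

    @property
    def n_spheres(self) -> int:
        return len(self.centers)

    @property
    def layer_thickness(self) -> float:
        return self.sphere_diameter


@dataclass(frozen=True)
class ScoringResult:
    """FOV-cuboid average dose per decay and its per-sphere normalization."""

    D_calc: float
    n_spheres: int
    mc_standard_error: float = float("nan")

    @property
    def per_sphere_factor(self) -> float:
        """D_calc divided by the number of spheres in the FOV (Gy/decay/sphere)."""
        return self.D_calc / self.n_spheres


class DoseBin(str, Enum):
    BELOW_10 = "below_10"
    BETWEEN_10_70 = "between_10_70"
    ABOVE_70 = "above_70"


@dataclass(frozen=True)
class WellDose:
    n_spheres: int
    exposure_time: float
    D_t: float
    bin: DoseBin


def sample_decay_position(center, diameter: float, rng: np.random.Generator | int | None = None):
    """Sample uniformly inside the sphere(s) of the given diameter.

    ``center`` is a 3-vector or an (n, 3) array; one point is drawn per row.
    """
    if diameter <= 0:
        raise InvalidParameterError("diameter must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    center = np.asarray(center, dtype=float)
    single = center.ndim == 1
    center = np.atleast_2d(center)
    n = len(center)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = diameter / 2.0 * rng.random(n) ** (1.0 / 3.0)
    out = center + v * r[:, None]
    return out[0] if single else out


def common_dcalc(results: Sequence[ScoringResult]) -> tuple[float, float]:
    """Average per-sphere dose factor across configurations.

    Returns ``(mean, relative_sd_of_mean)`` where the second element is the
    standard deviation of the mean of the per-sphere factors divided by the
    mean (the cross-configuration consistency figure).
    """
    if not results:
        raise InvalidParameterError("need at least one scoring result")
    vals = np.array([r.per_sphere_factor for r in results], dtype=float)
    mean = float(vals.mean())
    if len(vals) > 1:
        rel_sd = float(vals.std(ddof=1) / math.sqrt(len(vals)) / mean)
    else:
        rel_sd = 0.0
    return mean, rel_sd


def classify_dose(D: float) -> DoseBin:
    """Assign the 10/70 Gy dose bin; boundary ties go to the middle bin."""
    if D < 0:
        raise InvalidParameterError("dose must be non-negative")
    if D < 10.0:
        return DoseBin.BELOW_10
    if D <= 70.0:
        return DoseBin.BETWEEN_10_70
    return DoseBin.ABOVE_70


def well_dose(
    n_spheres: int,
    common_factor: float,
    source: DecaySource,
    t: float,
) -> WellDose:
    """Accumulated well dose from the common per-sphere factor.

    D_t = n_spheres * common_factor * [A0/lambda * (1 - e^(-lambda t))],
    with ``common_factor`` in Gy per decay per sphere and ``t`` in hours.
    """
    if n_spheres < 0:
        raise InvalidParameterError("n_spheres must be >= 0")
    if common_factor < 0:
        raise InvalidParameterError("common_factor must be >= 0")
    d_t = n_spheres * common_factor * cumulative_decays(source, t)
    return WellDose(n_spheres=n_spheres, exposure_time=t, D_t=d_t, bin=classify_dose(d_t))


def isodose_contours(
    grid: "DoseGrid",
    levels: Sequence[float],
    source: DecaySource,
    t: float,
) -> list[dict]:
    """Isodose polylines of the accumulated-dose map at the given Gy levels.

    The grid (Gy per decay) is scaled by the expected decay count after an
    exposure of ``t`` hours; contours are extracted on the mid-layer slab
    and returned as dicts with ``level_Gy`` and an (n, 2) ``vertices_um``
    array in FOV (x, y) coordinates.  Levels above the map maximum yield no
    contours.
    """
    from skimage import measure

    levels = list(levels)
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise InvalidParameterError("levels must be strictly increasing")
    scale = cumulative_decays(source, t)
    zmid = grid.shape[2] // 2
    dose_map = grid.values[:, :, zmid] * scale  # indexed [ix, iy]
    out = []
    for level in levels:
        if level > dose_map.max():
            continue
        for poly in measure.find_contours(dose_map, level):
            # index (ix, iy) -> um, voxel centers at (i + 0.5) * voxel
            verts = np.column_stack(
                [
                    (poly[:, 0] + 0.5) * grid.voxel_size[0] + grid.origin[0],
                    (poly[:, 1] + 0.5) * grid.voxel_size[1] + grid.origin[1],
                ]
            )
            out.append({"level_Gy": float(level), "vertices_um": verts})
    return out
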