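"""File formats, run configuration and micrograph-based sphere detection.

Positions travel as ``x_um,y_um`` CSV; dose grids as float32 TIFF (one page
per z-slab) plus a flat CSV and a JSON sidecar with the grid metadata;
isodose contours as GeoJSON-style JSON.  Sphere detection thresholds the
micrograph (Otsu), labels connected components and keeps those whose
equivalent diameter falls inside the manufacturer size band.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .constants import (
    FOV_HEIGHT_UM,
    FOV_WIDTH_UM,
    SPHERE_ACTIVITY_BQ,
    SPHERE_DIAMETER_BAND_UM,
    SPHERE_DIAMETER_UM,
    Y90_DAUGHTER_Z,
    Y90_ENDPOINT_MEV,
    Y90_HALF_LIFE_H,
)
from .dosimetry import MicrosphereConfig
from .errors import FormatError, InvalidParameterError

__all__ = [
    "RunConfig",
    "read_positions",
    "write_positions",
    "detect_spheres",
    "write_dose_grid",
    "read_dose_grid_csv",
    "write_isodose_json",
]


@dataclasses.dataclass
class RunConfig:
    """Run configuration for the CLI pipeline (YAML/JSON serializable)."""

    # physics
    endpoint_energy_MeV: float = Y90_ENDPOINT_MEV
    daughter_Z: int = Y90_DAUGHTER_Z
    half_life_h: float = Y90_HALF_LIFE_H
    activity_Bq: float = SPHERE_ACTIVITY_BQ
    energy_cutoff_MeV: float = 0.010
    n_histories: int = 100_000
    seed: int = 0
    # geometry
    fov_um: tuple = (FOV_WIDTH_UM, FOV_HEIGHT_UM)
    sphere_diameter_um: float = SPHERE_DIAMETER_UM
    voxel_xy_um: float = 10.0
    # plate
    conditions: tuple = ("N", "HP", "H")
    times_h: tuple = (48.0, 72.0, 96.0)
    wells_per_arm: int = 12
    # output
    out_dir: str = "."

    def __post_init__(self):
        for name in ("endpoint_energy_MeV", "half_life_h", "activity_Bq",
                     "energy_cutoff_MeV", "sphere_diameter_um", "voxel_xy_um"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.seed is None:
            raise InvalidParameterError("a seed is mandatory for stochastic stages")

    @classmethod
    def load(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fov_um", "conditions", "times_h"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def dump(self, path) -> None:
        import yaml

        data = dataclasses.asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_positions(path, fov: tuple | None = None,
                   sphere_diameter: float = SPHERE_DIAMETER_UM) -> MicrosphereConfig:
    """Read sphere centers from an ``x_um,y_um`` CSV.

    Raises :class:`FormatError` naming the offending row for missing
    headers, non-numeric/NaN coordinates or centers outside the FOV.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or lines[0].split(",")[:2] != ["x_um", "y_um"]:
        raise FormatError(f"{path}: expected header 'x_um,y_um'")
    fov = fov or (FOV_WIDTH_UM, FOV_HEIGHT_UM)
    centers = []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        try:
            x, y = float(parts[0]), float(parts[1])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: row {i}: cannot parse coordinates") from exc
        if not (np.isfinite(x) and np.isfinite(y)):
            raise FormatError(f"{path}: row {i}: non-finite coordinate")
        if not (0 <= x <= fov[0] and 0 <= y <= fov[1]):
            raise FormatError(f"{path}: row {i}: center ({x}, {y}) outside FOV")
        centers.append((x, y))
    return MicrosphereConfig(np.array(centers).reshape(-1, 2),
                             sphere_diameter=sphere_diameter, fov=tuple(fov))


def write_positions(config: MicrosphereConfig, path) -> None:
    """Write sphere centers as an ``x_um,y_um`` CSV (full float precision)."""
    with open(path, "w") as fh:
        fh.write("x_um,y_um\n")
        for x, y in config.centers:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def detect_spheres(
    image: np.ndarray,
    pixel_size_um: float,
    diameter_band_um: tuple = SPHERE_DIAMETER_BAND_UM,
) -> MicrosphereConfig:
    """Detect bright microspheres in a fluorescence micrograph.

    Otsu threshold -> connected components -> equivalent-diameter filter
    within the size band -> centroids in um.  Multi-channel images are
    reduced by max-projection over channels.  Returns a configuration whose
    diameter is the median detected equivalent diameter (or the nominal
    32.5 um when nothing is detected).
    """
    from skimage import measure
    from skimage.filters import threshold_otsu

    if pixel_size_um <= 0:
        raise InvalidParameterError("pixel_size_um must be positive")
    image = np.asarray(image)
    if image.ndim == 3:
        image = image.max(axis=-1)
    if image.ndim != 2:
        raise FormatError("expected a 2-D (or 2-D multi-channel) image")
    image = image.astype(float)
    if np.ptp(image) == 0:
        centers = np.empty((0, 2))
        fov = (image.shape[1] * pixel_size_um, image.shape[0] * pixel_size_um)
        return MicrosphereConfig(centers, fov=fov)

    mask = image > threshold_otsu(image)
    labels = measure.label(mask)
    lo, hi = diameter_band_um
    centers, diameters = [], []
    for region in measure.regionprops(labels):
        d_um = region.equivalent_diameter_area * pixel_size_um
        if lo <= d_um <= hi:
            r, c = region.centroid  # row (y), col (x)
            centers.append((c * pixel_size_um, r * pixel_size_um))
            diameters.append(d_um)
    fov = (image.shape[1] * pixel_size_um, image.shape[0] * pixel_size_um)
    diameter = float(np.median(diameters)) if diameters else SPHERE_DIAMETER_UM
    return MicrosphereConfig(np.array(centers).reshape(-1, 2),
                             sphere_diameter=diameter, fov=fov)


def write_dose_grid(grid, stem) -> dict:
    """Export a dose grid as float TIFF + CSV + JSON sidecar.

    ``stem`` is the path without extension; returns the paths written.
    """
    import tifffile

    stem = Path(stem)
    tiff_path = stem.with_suffix(".tiff")
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    # one TIFF page per z-slab
    pages = np.moveaxis(grid.values.astype(np.float32), 2, 0)  # (z, x, y)
    tifffile.imwrite(tiff_path, np.swapaxes(pages, 1, 2))  # pages as (y, x)
    ix, iy = np.meshgrid(
        np.arange(grid.shape[0]), np.arange(grid.shape[1]), indexing="ij"
    )
    flat = np.column_stack(
        [ix.ravel(), iy.ravel(), grid.values.sum(axis=2).ravel()]
    )
    np.savetxt(csv_path, flat, delimiter=",",
               header="x_index,y_index,dose_Gy_per_decay", comments="",
               fmt=("%d", "%d", "%.8g"))
    meta = {
        "origin_um": list(map(float, grid.origin)),
        "voxel_size_um": list(map(float, grid.voxel_size)),
        "shape": list(grid.shape),
        "units": "Gy per decay per sphere",
    }
    json_path.write_text(json.dumps(meta, indent=2))
    return {"tiff": tiff_path, "csv": csv_path, "json": json_path}


def read_dose_grid_csv(path) -> np.ndarray:
    """Read back the flat (x_index, y_index, dose) CSV as a 2-D array."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    nx = int(arr[:, 0].max()) + 1
    ny = int(arr[:, 1].max()) + 1
    out = np.zeros((nx, ny))
    out[arr[:, 0].astype(int), arr[:, 1].astype(int)] = arr[:, 2]
    return out


def write_isodose_json(contours: list, path) -> None:
    """GeoJSON-style export of isodose polylines with a level_Gy property."""
    features = [
        {
            "type": "Feature",
            "properties": {"level_Gy": c["level_Gy"]},
            "geometry": {
                "type": "LineString",
                "coordinates": np.asarray(c["vertices_um"]).tolist(),
            },
        }
        for c in contours
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
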