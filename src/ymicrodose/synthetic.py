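"""Synthetic plate generator: what the wet lab produced, in silico.

Generates non-overlapping sphere configurations, per-well sphere counts
with the means/SDs observed in the study conditions, accumulated doses via
the dosimetry chain, and viability readouts from a linear-quadratic (LQ)
dose-response with an oxygen-enhancement divisor and a senescence term.

The viability model: at absorbed dose D under oxygen condition c the
effective dose is D_e = D / OER(c) and the surviving proliferative fraction

    S = exp(-alpha * D_e - beta * D_e^2).

BrdU (DNA synthesis) reads 100*S.  A fraction of the radiation-arrested
cells becomes senescent; senescent cells stay metabolically active (more so
than cycling cells), which inflates the resazurin-reduction readout:

    AB% = 100 * min(1, S + gain * senescence_yield * (1 - S)) + noise.

Defaults are calibrated so that wells just above 70 Gy in normoxia read
~53% of control on the metabolic assay, while hypoxia (OER 2.5) retains
the ordering hypoxia > hypoxia-physioxia > normoxia in radiosensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import (
    FOV_HEIGHT_UM,
    FOV_WIDTH_UM,
    SPHERE_DIAMETER_UM,
)
from .decay_source import DecaySource, cumulative_decays, y90_source
from .dosimetry import MicrosphereConfig, classify_dose, well_dose
from .errors import CapacityError, InvalidParameterError

__all__ = [
    "Condition",
    "ViabilityParams",
    "PlateDataset",
    "DEFAULT_COUNT_STATS",
    "WELL_ANCHORS_48H",
    "calibrated_common_factor",
    "generate_config",
    "viability_response",
    "generate_plate",
]

#: oxygen conditions: N normoxia (~19% O2), HP hypoxia-physioxia (5%),
#: H hypoxia (1%)
Condition = ("N", "HP", "H")

#: per-(condition, time_h) sphere-count mean/SD observed across wells in the
#: three oxygenation arms of the study
DEFAULT_COUNT_STATS: dict = {
    ("N", 48): (69.0, 109.0),
    ("N", 72): (92.0, 124.0),
    ("N", 96): (87.0, 11.0),
    ("H", 48): (59.0, 62.0),
    ("H", 72): (93.0, 153.0),
    ("H", 96): (122.0, 42.0),
    ("HP", 48): (53.0, 52.0),
    ("HP", 72): (59.0, 46.0),
    ("HP", 96): (165.0, 21.0),
}

#: 48 h (mean dose Gy, mean sphere count) anchors per condition used to
#: calibrate the common per-sphere dose factor from the printed well tables
WELL_ANCHORS_48H: dict = {"N": (14.4, 69.0), "H": (12.4, 59.0), "HP": (11.1, 53.0)}


def calibrated_common_factor(source: DecaySource | None = None) -> float:
    """Common per-sphere dose factor (Gy/decay/sphere) from the 48 h anchors.

    Averages dose-per-sphere over the three oxygenation arms at 48 h and
    divides by the expected per-sphere decay count; the transport engine
    reproduces this figure to ~10%.
    """
    source = source or y90_source()
    decays_48h = cumulative_decays(source, 48.0)
    per_sphere = [d / n for d, n in WELL_ANCHORS_48H.values()]
    return float(np.mean(per_sphere) / decays_48h)


@dataclass(frozen=True)
class ViabilityParams:
    """LQ + senescence dose-response parameters.

    alpha (Gy^-1), beta (Gy^-2): LQ coefficients at full oxygenation.
    oer : oxygen-enhancement divisor per condition (N=1; H largest).
    senescence_yield : fraction of arrested cells that become senescent.
    senescence_metabolic_gain : metabolic signal of a senescent cell
        relative to a cycling one (>= 1).
    readout_noise_sd : Gaussian noise on the percent readouts (% points).
    """

    alpha: float = 0.05
    beta: float = 5e-4
    oer: dict = field(default_factory=lambda: {"N": 1.0, "HP": 1.5, "H": 2.5})
    senescence_yield: float = 0.35
    senescence_metabolic_gain: float = 1.5
    readout_noise_sd: float = 5.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise InvalidParameterError("alpha and beta must be >= 0")
        if any(v < 1.0 for v in self.oer.values()):
            raise InvalidParameterError("OER divisors must be >= 1")
        if not 0.0 <= self.senescence_yield <= 1.0:
            raise InvalidParameterError("senescence_yield must be in [0, 1]")
        if self.senescence_metabolic_gain < 1.0:
            raise InvalidParameterError("senescence_metabolic_gain must be >= 1")
        if self.readout_noise_sd < 0:
            raise InvalidParameterError("readout_noise_sd must be >= 0")


@dataclass
class PlateDataset:
    """Per-well records of a synthetic plate experiment."""

    wells: pd.DataFrame

    COLUMNS = (
        "well_id", "condition", "time_h", "n_spheres", "dose_Gy",
        "ab_reduced_pct", "brdu_pct", "senescent_fraction", "bin",
    )

    def to_csv(self, path) -> None:
        self.wells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlateDataset":
        from .errors import FormatError

        df = pd.read_csv(path)
        missing = set(cls.COLUMNS[:8]) - set(df.columns)
        if missing:
            raise FormatError(f"plate CSV missing columns: {sorted(missing)}")
        return cls(df)


def generate_config(
    n_spheres: int,
    fov: tuple = (FOV_WIDTH_UM, FOV_HEIGHT_UM),
    diameter: float = SPHERE_DIAMETER_UM,
    seed: int | np.random.Generator | None = None,
    *,
    max_tries: int = 200,
) -> MicrosphereConfig:
    """Place ``n_spheres`` non-overlapping spheres uniformly in the FOV.

    Uniform rejection sampling of centers at least one diameter apart;
    raises :class:`CapacityError` when the packing cannot be realized
    within the retry budget.
    """
    if n_spheres < 0:
        raise InvalidParameterError("n_spheres must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = diameter / 2.0
    lo = np.array([r, r])
    hi = np.array([fov[0] - r, fov[1] - r])
    pts = np.empty((0, 2))
    for _ in range(max_tries):
        if len(pts) >= n_spheres:
            break
        cand = rng.uniform(lo, hi, size=(max(64, n_spheres), 2))
        for row in cand:
            if len(pts) >= n_spheres:
                break
            if len(pts) == 0 or np.hypot(*(pts - row).T).min() >= diameter:
                pts = np.vstack([pts, row])
    else:
        raise CapacityError(
            f"could not place {n_spheres} spheres of {diameter} um in "
            f"{fov[0]} x {fov[1]} um after {max_tries} rounds"
        )
    return MicrosphereConfig(pts, sphere_diameter=diameter, fov=tuple(fov))


def viability_response(
    dose: float | np.ndarray,
    condition: str,
    params: ViabilityParams,
    rng: np.random.Generator | int | None = None,
):
    """Viability readouts at the given absorbed dose(s).

    Returns ``(ab_reduced_pct, brdu_pct, senescent_fraction)``; readouts are
    percent of untreated control, with Gaussian noise of
    ``params.readout_noise_sd`` (deterministic at zero noise).
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise InvalidParameterError("dose must be >= 0")
    if condition not in params.oer:
        raise InvalidParameterError(f"unknown condition {condition!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    d_eff = dose / params.oer[condition]
    S = np.exp(-params.alpha * d_eff - params.beta * d_eff**2)
    senescent = params.senescence_yield * (1.0 - S)
    brdu = 100.0 * S
    ab = 100.0 * np.minimum(S + params.senescence_metabolic_gain * senescent, 1.0)
    if params.readout_noise_sd > 0:
        ab = np.maximum(ab + rng.normal(0.0, params.readout_noise_sd, size=ab.shape), 0.0)
        brdu = np.maximum(brdu + rng.normal(0.0, params.readout_noise_sd, size=brdu.shape), 0.0)
    if dose.ndim == 0:
        return float(ab), float(brdu), float(senescent)
    return ab, brdu, senescent


def _truncated_counts(mean, sd, n, rng):
    """Rounded normal truncated at zero (some study SDs exceed the means)."""
    if sd < 0 or mean < 0:
        raise InvalidParameterError("count mean and sd must be >= 0")
    if sd == 0:
        return np.full(n, int(round(mean)))
    from scipy.stats import truncnorm

    a = (0.0 - mean) / sd
    draws = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    return np.round(draws).astype(int)


def generate_plate(
    n_wells: int,
    condition: str,
    time_h: float,
    sphere_count_mean: float | None = None,
    sphere_count_sd: float | None = None,
    params: ViabilityParams | None = None,
    source: DecaySource | None = None,
    common_factor: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> PlateDataset:
    """Simulate one plate arm: counts -> doses -> viability readouts.

    Sphere counts come from a zero-truncated rounded normal with the given
    mean/SD (defaults: the observed statistics for the condition/time);
    doses from the common per-sphere factor via the decay-accumulation
    formula; readouts from :func:`viability_response`.
    """
    if n_wells < 1:
        raise InvalidParameterError("n_wells must be >= 1")
    params = params or ViabilityParams()
    source = source or y90_source()
    if common_factor is None:
        common_factor = calibrated_common_factor(source)
    if sphere_count_mean is None or sphere_count_sd is None:
        try:
            mean_sd = DEFAULT_COUNT_STATS[(condition, int(time_h))]
        except KeyError as exc:
            raise InvalidParameterError(
                f"no default sphere-count statistics for {(condition, time_h)}; "
                "pass sphere_count_mean/sd explicitly"
            ) from exc
        sphere_count_mean = sphere_count_mean if sphere_count_mean is not None else mean_sd[0]
        sphere_count_sd = sphere_count_sd if sphere_count_sd is not None else mean_sd[1]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = _truncated_counts(sphere_count_mean, sphere_count_sd, n_wells, rng)
    doses = np.array(
        [well_dose(int(c), common_factor, source, time_h).D_t for c in counts]
    )
    ab, brdu, senescent = viability_response(doses, condition, params, rng)
    df = pd.DataFrame(
        {
            "well_id": [f"{condition}{int(time_h)}h_{i:03d}" for i in range(n_wells)],
            "condition": condition,
            "time_h": time_h,
            "n_spheres": counts,
            "dose_Gy": doses,
            "ab_reduced_pct": ab,
            "brdu_pct": brdu,
            "senescent_fraction": senescent,
            "bin": [classify_dose(d).value for d in doses],
        }
    )
    return PlateDataset(df)
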