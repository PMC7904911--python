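"""Plate-level statistics linking absorbed dose to viability.

Reproduces the structure of the study's summary tables: per-condition
descriptives with a Wilcoxon signed-rank test against control, dose/count
correlations, the 10/70 Gy dose-bin percentages, and the below/above-
threshold Mann-Whitney comparison of the metabolic readout.

All hypothesis tests are two-sided and uncorrected by default (a Holm
option is available); small samples use exact null distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import DoseBin, classify_dose
from .errors import DegenerateDataError, InvalidParameterError
from .synthetic import PlateDataset

__all__ = [
    "percent_reduced_ab",
    "correlate",
    "compare_paired",
    "compare_groups",
    "bin_table",
    "threshold_split_table",
    "condition_summary",
    "holm_adjust",
]

# molar extinction coefficients of resazurin (oxidized) and resorufin
# (reduced) at the two read wavelengths of the metabolic assay
_EOX_570, _EOX_600 = 80586.0, 117216.0
_ERED_570, _ERED_600 = 155677.0, 14652.0


def _reduction_signal(absorbances: np.ndarray) -> np.ndarray:
    """Per-well reduced-dye signal from (A570, A600) absorbance pairs."""
    a570, a600 = absorbances[:, 0], absorbances[:, 1]
    return _EOX_600 * a570 - _EOX_570 * a600


def percent_reduced_ab(treated, control) -> np.ndarray:
    """Metabolic readout as percent of untreated control.

    Inputs are either per-well pre-computed reduction values (1-D) or raw
    two-wavelength absorbances as (n, 2) arrays of (570 nm, 600 nm)
    readings, in which case the standard two-wavelength reduction formula
    is applied first.  The result is 100 * treated / mean(control).
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.ndim == 2:
        if treated.shape[1] != 2 or control.ndim != 2 or control.shape[1] != 2:
            raise InvalidParameterError("two-wavelength input must be (n, 2) arrays")
        treated = _reduction_signal(treated)
        control = _reduction_signal(control)
    ref = control.mean()
    if ref <= 0:
        raise InvalidParameterError("control reduction must be positive")
    return 100.0 * treated / ref


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value (Pearson or Spearman)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidParameterError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise InvalidParameterError(f"unknown correlation method: {method!r}")
    return float(r), float(p)


def compare_paired(treated, control_reference) -> float:
    """Two-sided Wilcoxon signed-rank p-value of treated vs paired control.

    ``control_reference`` may be a per-well paired control array or a
    scalar reference level (e.g. 100 for percent-of-control readouts).
    Exact null distribution for n <= 25, normal approximation above.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.broadcast_to(
        np.asarray(control_reference, dtype=float), treated.shape
    )
    diffs = treated - control
    if len(diffs) < 5:
        raise InvalidParameterError("need >= 5 paired observations")
    if np.all(diffs == 0):
        raise DegenerateDataError("all paired differences are zero")
    res = stats.wilcoxon(diffs, alternative="two-sided", method="auto")
    return float(res.pvalue)


def compare_groups(a, b) -> float:
    """Two-sided Mann-Whitney U p-value (exact for small tie-free samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidParameterError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)


def bin_table(plate: PlateDataset) -> pd.DataFrame:
    """Percentage of wells per 10/70 Gy dose bin, by condition and time.

    Percentages are computed on the raw well counts and sum to 100 per row
    before rounding.
    """
    df = plate.wells
    if df.empty:
        raise InvalidParameterError("plate has no wells")
    rows = []
    for (cond, t), grp in df.groupby(["condition", "time_h"], sort=False):
        bins = grp["dose_Gy"].map(lambda d: classify_dose(d).value)
        n = len(grp)
        rows.append(
            {
                "condition": cond,
                "time_h": t,
                "mean_dose_Gy": grp["dose_Gy"].mean(),
                "pct_above_70": 100.0 * (bins == DoseBin.ABOVE_70.value).sum() / n,
                "pct_10_to_70": 100.0 * (bins == DoseBin.BETWEEN_10_70.value).sum() / n,
                "pct_below_10": 100.0 * (bins == DoseBin.BELOW_10.value).sum() / n,
            }
        )
    return pd.DataFrame(rows)


def threshold_split_table(plate: PlateDataset, threshold: float = 10.0) -> pd.DataFrame:
    """Medians of the metabolic readout below/above a dose threshold + U test.

    One row per (condition, time).  A one-sided split (all wells on the same
    side of the threshold) is reported with NaN median/p and
    ``degenerate=True`` rather than raised.
    """
    df = plate.wells
    if df.empty:
        raise InvalidParameterError("plate has no wells")
    rows = []
    for (cond, t), grp in df.groupby(["condition", "time_h"], sort=False):
        below = grp.loc[grp["dose_Gy"] < threshold, "ab_reduced_pct"]
        above = grp.loc[grp["dose_Gy"] >= threshold, "ab_reduced_pct"]
        degenerate = below.empty or above.empty
        rows.append(
            {
                "condition": cond,
                "time_h": t,
                "threshold_Gy": threshold,
                "median_below": below.median() if not below.empty else np.nan,
                "median_above": above.median() if not above.empty else np.nan,
                "n_below": len(below),
                "n_above": len(above),
                "p_mannwhitney": np.nan if degenerate else compare_groups(below, above),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def condition_summary(plate: PlateDataset, control_reference: float = 100.0) -> pd.DataFrame:
    """Descriptive statistics per condition/time with a signed-rank p-value.

    Mean/SD of the metabolic readout, sphere count and dose, plus the
    Wilcoxon signed-rank p of the readout against the control level.
    """
    df = plate.wells
    if df.empty:
        raise InvalidParameterError("plate has no wells")
    rows = []
    for (cond, t), grp in df.groupby(["condition", "time_h"], sort=False):
        try:
            p = compare_paired(grp["ab_reduced_pct"].to_numpy(), control_reference)
        except (DegenerateDataError, InvalidParameterError):
            p = np.nan
        rows.append(
            {
                "condition": cond,
                "time_h": t,
                "ab_mean": grp["ab_reduced_pct"].mean(),
                "ab_sd": grp["ab_reduced_pct"].std(ddof=1),
                "spheres_mean": grp["n_spheres"].mean(),
                "spheres_sd": grp["n_spheres"].std(ddof=1),
                "dose_mean_Gy": grp["dose_Gy"].mean(),
                "dose_sd_Gy": grp["dose_Gy"].std(ddof=1),
                "wilcoxon_p": p,
            }
        )
    return pd.DataFrame(rows)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (off by default everywhere; opt-in)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
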