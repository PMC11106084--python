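"""Dilution calibrations, pit→hit→dose conversion and clonogenic survival.

The survival model is the pure exponential SF(D) = exp(−kD) with no
shoulder, appropriate for high-LET alpha irradiation; the mean lethal dose
is D₀ = 1/k.  Fits are performed on ln SF, constrained through SF(0) = 1,
unweighted by default (a 1/SD² weighted variant is available behind a
flag).  Uncertainties combine by the first-order delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DilutionCalibration",
    "SurvivalPoint",
    "SurvivalFit",
    "DoseConversion",
    "fit_linear_calibration",
    "pits_to_hits_and_dose",
    "fit_exponential_survival",
    "predict_sf",
    "average_dose_rate",
    "colony_survival",
]

#: observation-field area used for pit counting, μm²
DEFAULT_FIELD_AREA_UM2 = 98_826.0


@dataclass
class DilutionCalibration:
    """Linear response vs daughter-medium dilution fraction."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    field_area_um2: float = DEFAULT_FIELD_AREA_UM2
    through_origin: bool = True
    n_points: int = 0

    def predict(self, dilution) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(dilution, dtype=float)


@dataclass
class SurvivalPoint:
    """One clonogenic-survival observation."""

    dose_gy: float | None
    surviving_fraction: float
    sd: float = 0.0
    n_dishes: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.surviving_fraction <= 1.0:
            raise ValueError("surviving fraction must lie in (0, 1]")
        if self.dose_gy is not None and self.dose_gy < 0:
            raise ValueError("dose must be non-negative")


@dataclass
class SurvivalFit:
    """Exponential (shoulderless) survival fit SF = exp(−k·D)."""

    slope_per_gy: float
    d0_gy: float = field(default=math.nan)
    r_squared: float = math.nan
    slope_se: float = math.nan
    ci95: tuple[float, float] = (math.nan, math.nan)

    def __post_init__(self) -> None:
        if not self.slope_per_gy > 0:
            raise ValueError("survival slope must be positive")
        if math.isnan(self.d0_gy):
            self.d0_gy = 1.0 / self.slope_per_gy


@dataclass
class DoseConversion:
    """Pit-count → hit-count and absorbed-dose conversion factors."""

    dose_per_pit_gy: float
    hits_per_pit: float
    dose_per_pit_sd: float = 0.0
    hits_per_pit_sd: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.dose_per_pit_gy <= 0 or self.hits_per_pit <= 0:
            raise ValueError("conversion factors must be positive")
        for sd in (self.dose_per_pit_sd, self.hits_per_pit_sd):
            if not math.isfinite(sd) or sd < 0:
                raise ValueError("conversion SDs must be finite and non-negative")


def fit_linear_calibration(
    pairs,
    through_origin: bool = True,
    field_area_um2: float = DEFAULT_FIELD_AREA_UM2,
) -> DilutionCalibration:
    """Least-squares line through (dilution, response) pairs.

    ``pairs`` is an iterable of (dilution, response); replicate responses
    per dilution are welcome.  With ``through_origin`` (the default, since
    zero dose gives zero excess response) the intercept is pinned at 0.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (dilution, response) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("dilutions have zero variance; cannot calibrate")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("dilution fractions must lie in [0, 1]")
    n = len(x)
    if through_origin:
        sxx = float(np.sum(x * x))
        slope = float(np.sum(x * y)) / sxx
        intercept = 0.0
        resid = y - slope * x
        dof = n - 1
        slope_se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        dof = n - 2
        sxx = float(np.sum((x - x.mean()) ** 2))
        slope_se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return DilutionCalibration(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        slope_se=slope_se,
        field_area_um2=field_area_um2,
        through_origin=through_origin,
        n_points=n,
    )


def pits_to_hits_and_dose(
    mean_pits: float,
    conv: DoseConversion,
    mean_pits_sd: float = 0.0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Scale a mean pit count per nucleus to total hits and absorbed dose.

    Returns ``((hits, hits_sd), (dose_gy, dose_sd))``; relative errors of
    the pit count and of the conversion factor combine in quadrature.
    """
    if mean_pits < 0 or mean_pits_sd < 0:
        raise ValueError("pit count and its SD must be non-negative")
    hits = mean_pits * conv.hits_per_pit
    dose = mean_pits * conv.dose_per_pit_gy
    if mean_pits > 0:
        rel_pits2 = (mean_pits_sd / mean_pits) ** 2
        hits_sd = hits * math.sqrt(rel_pits2 + (conv.hits_per_pit_sd / conv.hits_per_pit) ** 2)
        dose_sd = dose * math.sqrt(rel_pits2 + (conv.dose_per_pit_sd / conv.dose_per_pit_gy) ** 2)
    else:
        hits_sd = dose_sd = 0.0
    return (hits, hits_sd), (dose, dose_sd)


def fit_exponential_survival(
    points: list[SurvivalPoint], weighted: bool = False
) -> SurvivalFit:
    """Origin-constrained regression of ln SF on dose.

    The one-parameter model ln SF = −k·D is fit by (optionally 1/SD²-
    weighted) least squares; r² is reported on the log scale and the 95%
    interval on k comes from the regression standard error.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 survival points")
    dose = np.array([p.dose_gy for p in points], dtype=float)
    sf = np.array([p.surviving_fraction for p in points], dtype=float)
    if np.any(sf <= 0):
        raise ValueError("all surviving fractions must be positive")
    if np.ptp(dose) == 0:
        raise ValueError("all doses identical; cannot fit a slope")
    y = np.log(sf)
    if weighted:
        sd_log = np.array(
            [p.sd / p.surviving_fraction if p.sd > 0 else 1.0 for p in points]
        )
        w = 1.0 / sd_log**2
    else:
        w = np.ones_like(dose)
    sxx = float(np.sum(w * dose * dose))
    k = -float(np.sum(w * dose * y)) / sxx
    resid = y + k * dose
    dof = max(len(points) - 1, 1)
    sigma2 = float(np.sum(w * resid**2)) / dof
    k_se = math.sqrt(sigma2 / sxx)
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return SurvivalFit(
        slope_per_gy=k,
        r_squared=r2,
        slope_se=k_se,
        ci95=(k - 1.96 * k_se, k + 1.96 * k_se),
    )


def predict_sf(fit: SurvivalFit, dose_gy: float) -> float:
    """Surviving fraction exp(−k·D) predicted by a fitted curve."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    return math.exp(-fit.slope_per_gy * dose_gy)


def average_dose_rate(total_dose_gy: float, duration_min: float) -> float:
    """Mean dose rate of a protracted exposure, Gy/min."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    return total_dose_gy / duration_min


def colony_survival(
    plated: int, colonies: int, plating_efficiency: float
) -> SurvivalPoint:
    """Surviving fraction from a colony-formation count.

    SF = (colonies/plated) / PE with a binomial standard error attached.
    """
    if plated <= 0:
        raise ValueError("number of plated cells must be positive")
    if not 0.0 < plating_efficiency <= 1.0:
        raise ValueError("plating efficiency must lie in (0, 1]")
    if colonies > plated:
        raise ValueError("cannot score more colonies than plated cells")
    p_hat = colonies / plated
    sf = p_hat / plating_efficiency
    se = math.sqrt(p_hat * (1.0 - p_hat) / plated) / plating_efficiency
    return SurvivalPoint(dose_gy=None, surviving_fraction=min(sf, 1.0), sd=se)
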