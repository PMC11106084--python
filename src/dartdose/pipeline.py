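"""End-to-end analysis: pit calibration → dose conversion → survival fit.

Mirrors the daughter-medium experiment: per-field etch-pit counts at
several DM dilutions give a linear pit–dilution calibration; pit counts
per nucleus are scaled to total nucleus hits and absorbed dose through the
Monte-Carlo conversion; colony counts give surviving fractions; and the
origin-constrained exponential fit of SF against dose yields the survival
slope k and mean lethal dose D₀ = 1/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import (
    DoseConversion,
    SurvivalPoint,
    average_dose_rate,
    colony_survival,
    fit_exponential_survival,
    fit_linear_calibration,
    pits_to_hits_and_dose,
    predict_sf,
)

__all__ = ["PipelineError", "run_full_pipeline", "conversion_from_tally"]

DEFAULT_EXPOSURE_MIN = 24.0 * 60.0


class PipelineError(ValueError):
    """The analysis cannot proceed (e.g. a zero pit-dilution slope)."""


def conversion_from_tally(tally) -> DoseConversion:
    """Build a :class:`DoseConversion` from a microdosimetry tally."""
    from .mc import dose_per_detected_pit

    (dpp, dpp_se), (hpp, hpp_se) = dose_per_detected_pit(tally)
    return DoseConversion(
        dose_per_pit_gy=dpp,
        hits_per_pit=hpp,
        dose_per_pit_sd=dpp_se,
        hits_per_pit_sd=hpp_se,
        provenance=f"microdose MC, n_decays={tally.n_decays}",
    )


def run_full_pipeline(
    pit_table: pd.DataFrame,
    colony_table: pd.DataFrame,
    conversion: DoseConversion,
    plating_efficiency: float,
    nucleus_area_um2: float = 280.0,
    field_area_um2: float = 98_826.0,
    exposure_min: float = DEFAULT_EXPOSURE_MIN,
    reference_dilution: float = 0.5,
    weighted_fit: bool = False,
) -> dict:
    """Run the full dosimetry-and-survival analysis on tabulated counts.

    Returns a plain dict (JSON-serializable) with the calibration, the
    per-dilution hit/dose table, the survival fit (on both the dose axis
    and the pit axis), and reference-level predictions.
    """
    pairs = pit_table[["dilution", "pit_count"]].to_numpy(dtype=float)
    calibration = fit_linear_calibration(pairs, field_area_um2=field_area_um2)
    if calibration.slope <= 0:
        raise PipelineError(
            "pit-dilution calibration slope is not positive; the pit input "
            "carries no dose signal and conversion to dose is refused"
        )

    dilutions = sorted(colony_table["dilution"].unique())
    per_dilution = []
    points: list[SurvivalPoint] = []
    pit_points: list[SurvivalPoint] = []
    for d in dilutions:
        pits_per_field = float(calibration.predict(d))
        mean_pits = pits_per_field * nucleus_area_um2 / field_area_um2
        (hits, hits_sd), (dose, dose_sd) = pits_to_hits_and_dose(mean_pits, conversion)
        sub = colony_table[colony_table["dilution"] == d]
        plated = int(sub["plated"].sum())
        colonies = int(sub["colonies"].sum())
        point = colony_survival(plated, colonies, plating_efficiency)
        point.dose_gy = dose
        point.n_dishes = len(sub)
        points.append(point)
        pit_points.append(
            SurvivalPoint(
                dose_gy=mean_pits,  # pit axis reuses the dose slot
                surviving_fraction=point.surviving_fraction,
                sd=point.sd,
                n_dishes=len(sub),
            )
        )
        per_dilution.append(
            {
                "dilution": d,
                "pits_per_field": pits_per_field,
                "pits_per_nucleus": mean_pits,
                "hits_per_nucleus": hits,
                "hits_per_nucleus_sd": hits_sd,
                "dose_gy": dose,
                "dose_gy_sd": dose_sd,
                "plated": plated,
                "colonies": colonies,
                "surviving_fraction": point.surviving_fraction,
                "surviving_fraction_se": point.sd,
            }
        )

    fit = fit_exponential_survival(points, weighted=weighted_fit)
    pit_fit = fit_exponential_survival(pit_points, weighted=weighted_fit)

    ref_pits = (
        float(calibration.predict(reference_dilution))
        * nucleus_area_um2 / field_area_um2
    )
    (_, _), (ref_dose, ref_dose_sd) = pits_to_hits_and_dose(ref_pits, conversion)
    return {
        "calibration": {
            "slope_pits_per_field": calibration.slope,
            "slope_se": calibration.slope_se,
            "r_squared": calibration.r_squared,
            "field_area_um2": field_area_um2,
        },
        "conversion": {
            "dose_per_pit_gy": conversion.dose_per_pit_gy,
            "hits_per_pit": conversion.hits_per_pit,
            "provenance": conversion.provenance,
        },
        "per_dilution": per_dilution,
        "survival": {
            "slope_per_gy": fit.slope_per_gy,
            "slope_se": fit.slope_se,
            "ci95": list(fit.ci95),
            "d0_gy": fit.d0_gy,
            "r_squared": fit.r_squared,
        },
        "survival_pit_axis": {
            "slope_per_pit": pit_fit.slope_per_gy,
            "d0_pits": pit_fit.d0_gy,
            "r_squared": pit_fit.r_squared,
        },
        "reference": {
            "dilution": reference_dilution,
            "pits_per_nucleus": ref_pits,
            "dose_gy": ref_dose,
            "dose_gy_sd": ref_dose_sd,
            "predicted_sf": predict_sf(fit, ref_dose),
            "average_dose_rate_gy_per_min": average_dose_rate(ref_dose, exposure_min),
            "exposure_min": exposure_min,
        },
    }
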