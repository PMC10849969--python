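"""Targeted quantification: internal-standard ratios, linear calibration,
and conversion of back-calculated concentrations to mg per kg of sample.

Calibration responses are peak-area ratios (analyte / deuterated internal
standard) regressed on standard concentrations in uM by unweighted ordinary
least squares (a 1/x-weighted mode is available); the fitted line is then
inverted to quantify unknowns, and concentrations are expressed in mg per
kg of the original sample using the analyte's molecular mass, the
extraction volume, and the extracted sample mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "normalize_to_internal_standard",
    "fit_calibration",
    "quantify",
]


@dataclass(frozen=True)
class CalibrationCurve:
    analyte_id: str
    concentrations: tuple[float, ...]  # uM
    responses: tuple[float, ...]  # area ratio, unitless
    slope: float
    intercept: float
    r_squared: float

    @property
    def lowest_point(self) -> float:
        return min(self.concentrations)


@dataclass(frozen=True)
class QuantResult:
    analyte_id: str
    sample_id: str
    concentration_uM: float
    concentration_mg_per_kg: float
    below_lod: bool
    below_lowest_standard: bool = False


def normalize_to_internal_standard(analyte_area: float, is_area: float) -> float:
    """Peak-area ratio of analyte to its deuterated internal standard."""
    if is_area <= 0:
        raise ValueError(f"internal-standard area must be positive, got {is_area}")
    if analyte_area < 0:
        raise ValueError("analyte area must be non-negative")
    return analyte_area / is_area


def fit_calibration(
    points: Sequence[tuple[float, float]],
    analyte_id: str = "",
    weighted_1_over_x: bool = False,
) -> CalibrationCurve:
    """Fit response = slope * concentration + intercept by least squares."""
    if len(points) < 3:
        raise ValueError("calibration requires >= 3 points")
    conc = np.array([c for c, _ in points], dtype=float)
    resp = np.array([r for _, r in points], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("calibration concentrations must be strictly positive")
    if np.all(conc == conc[0]):
        raise ValueError("calibration concentrations must not be identical")
    if weighted_1_over_x:
        w = 1.0 / conc
        x = np.vstack([conc, np.ones_like(conc)]).T
        wsqrt = np.sqrt(w)
        slope, intercept = np.linalg.lstsq(x * wsqrt[:, None], resp * wsqrt, rcond=None)[0]
        fitted = slope * conc + intercept
        ss_res = float(np.sum(w * (resp - fitted) ** 2))
        ss_tot = float(np.sum(w * (resp - np.average(resp, weights=w)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = scipy.stats.linregress(conc, resp)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return CalibrationCurve(
        analyte_id=analyte_id,
        concentrations=tuple(conc), responses=tuple(resp),
        slope=float(slope), intercept=float(intercept),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
    )


def quantify(
    response_ratio: float,
    curve: CalibrationCurve,
    sample_mass_g: float,
    extraction_volume_mL: float,
    molecular_mass_Da: float,
    sample_id: str = "",
) -> QuantResult:
    """Back-calculate concentration from a response ratio and express it in
    mg of analyte per kg of sample.

    mg/kg = conc[uM] * 1e-6 mol/L * M[g/mol] * V[L] * 1e3 mg/g / (m[g]/1000 kg)
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    if sample_mass_g <= 0 or extraction_volume_mL <= 0 or molecular_mass_Da <= 0:
        raise ValueError("sample mass, volume and molecular mass must be positive")
    conc_uM = (response_ratio - curve.intercept) / curve.slope
    below_lod = conc_uM < 0
    if below_lod:
        conc_uM = 0.0
    grams = conc_uM * 1e-6 * molecular_mass_Da * (extraction_volume_mL / 1000.0)
    mg_per_kg = (grams * 1e3) / (sample_mass_g / 1000.0)
    return QuantResult(
        analyte_id=curve.analyte_id,
        sample_id=sample_id,
        concentration_uM=conc_uM,
        concentration_mg_per_kg=mg_per_kg,
        below_lod=below_lod,
        below_lowest_standard=conc_uM < curve.lowest_point,
    )
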