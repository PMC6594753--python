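"""Solubility determination and thermodynamics of the solution process.

The aqueous solubility of a drug too insoluble for direct spectrophotometry
is measured by extracting a saturated aqueous stock into a small volume of
1-octanol (concentrating the drug e.g. 20-fold), reading the extract's
optical density at the drug's absorption peak against a linear calibration
line, and dividing by the concentration factor.  Solubilities measured at
two temperatures give the standard enthalpy of solution by the two-point
van't Hoff relation; the standard free energy follows from a single
solubility against the 1 M standard state; their difference is the entropy
term.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import linregress

from .constants import R_GAS

__all__ = [
    "CalibrationCurve",
    "SolubilityMeasurement",
    "SolutionThermo",
    "fit_calibration",
    "extract_concentration",
    "aqueous_solubility",
    "distribution_coefficient",
    "enthalpy_of_solution",
    "gibbs_of_solution",
    "entropy_term",
    "solution_thermodynamics",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear optical-density calibration: OD = slope * conc + intercept."""

    slope: float  # OD per M
    intercept: float  # OD
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def __call__(self, conc: float) -> float:
        return self.slope * conc + self.intercept


@dataclass(frozen=True)
class SolubilityMeasurement:
    """A (solubility, temperature, pH) triple."""

    s: float  # mol/L
    temperature: float  # K
    ph: float = 7.1

    def __post_init__(self) -> None:
        if self.s <= 0 or self.temperature <= 0:
            raise ValueError("solubility and temperature must be positive")


@dataclass(frozen=True)
class SolutionThermo:
    """Standard thermodynamic parameters of the solution process (J/mol)."""

    dh: float
    dg: float
    t_ref: float

    @property
    def tds(self) -> float:
        return self.dh - self.dg


def fit_calibration(
    conc: Sequence[float], od: Sequence[float]
) -> CalibrationCurve:
    """Ordinary least-squares calibration line through (conc, OD) points."""
    if len(conc) < 3:
        raise ValueError("need at least 3 calibration points")
    if len(set(conc)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    res = linregress(conc, od)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def extract_concentration(od: float, cal: CalibrationCurve) -> float:
    """Invert the calibration line: concentration = (OD - intercept)/slope."""
    if od < cal.intercept:
        raise ValueError(
            f"OD {od} below the calibration intercept {cal.intercept}; "
            "non-physical negative concentration"
        )
    return (od - cal.intercept) / cal.slope


def aqueous_solubility(extract_conc: float, concentration_factor: float) -> float:
    """Aqueous solubility from the extract concentration and the volume
    ratio of the extraction (e.g. 20:1 water:octanol gives factor 20)."""
    if extract_conc <= 0 or concentration_factor <= 0:
        raise ValueError("inputs must be positive")
    return extract_conc / concentration_factor


def distribution_coefficient(s_solvent: float, s_aq: float) -> tuple[float, float]:
    """Solvent/water distribution coefficient (D, logD) from the ratio of
    saturation solubilities at matched pH."""
    if s_solvent <= 0 or s_aq <= 0:
        raise ValueError("solubilities must be positive")
    d = s_solvent / s_aq
    return d, math.log10(d)


def enthalpy_of_solution(
    m1: SolubilityMeasurement, m2: SolubilityMeasurement
) -> float:
    """Two-point van't Hoff enthalpy of solution (J/mol):
    dH = R T1 T2 / (T2 - T1) * ln(S(T2)/S(T1)).
    Symmetric under exchanging the two measurements."""
    if m1.temperature == m2.temperature:
        raise ValueError("need two distinct temperatures")
    if m1.ph != m2.ph:
        warnings.warn("solubilities measured at different pH", stacklevel=2)
    t1, t2 = m1.temperature, m2.temperature
    return R_GAS * t1 * t2 / (t2 - t1) * math.log(m2.s / m1.s)


def gibbs_of_solution(m: SolubilityMeasurement) -> float:
    """Standard free energy of solution dG = -R T ln(S / 1 M), in J/mol."""
    return -R_GAS * m.temperature * math.log(m.s)


def entropy_term(dh: float, dg: float) -> float:
    """T dS = dH - dG (J/mol)."""
    return dh - dg


def solution_thermodynamics(
    m1: SolubilityMeasurement, m2: SolubilityMeasurement
) -> SolutionThermo:
    """Full two-temperature analysis, referenced to the lower temperature."""
    lo, hi = sorted((m1, m2), key=lambda m: m.temperature)
    dh = enthalpy_of_solution(lo, hi)
    dg = gibbs_of_solution(lo)
    return SolutionThermo(dh=dh, dg=dg, t_ref=lo.temperature)
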