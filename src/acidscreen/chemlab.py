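"""Media chemistry and photometry conversions.

Culture-medium pH in a CO2 incubator is set by the open bicarbonate buffer
system and follows the Henderson-Hasselbalch relation

    pH = pKa + log10([HCO3-] / [dissolved CO2]),

with [dissolved CO2] = s * pCO2, where s is the CO2 solubility coefficient
and pCO2 the partial pressure of CO2 in the humidified gas phase.  A series
of media mixed from 44 mM NaHCO3 and 44 mM NaCl stocks spans a pH range at
constant osmolarity; this module designs such series, predicts their pH and
buffering capacity, and converts ratiometric dye readouts (phenol red,
cSNARF1, HPTS) and Stern-Volmer O2 quenching into chemical quantities.

All concentrations are mM, pressures mmHg, times hours. Constants default
to 37 degC values and are exposed as keyword arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# 37 degC physiological constants for the open CO2/HCO3- system
CO2_PKA = 6.1
CO2_SOLUBILITY_MM_PER_MMHG = 0.0307
BAROMETRIC_MMHG = 760.0
WATER_VAPOR_MMHG = 47.0

HEPES_PKA = 7.5
MES_PKA = 6.1

LN10 = math.log(10.0)


def dissolved_co2(co2_pct: float, *, solubility: float = CO2_SOLUBILITY_MM_PER_MMHG,
                  barometric: float = BAROMETRIC_MMHG,
                  vapor: float = WATER_VAPOR_MMHG) -> float:
    """Dissolved CO2 (mM) at a given gas-phase CO2 fraction (percent)."""
    if co2_pct <= 0:
        raise ValueError("co2_pct must be positive")
    return solubility * (co2_pct / 100.0) * (barometric - vapor)


def hh_pH(hco3_mM: float, co2_pct: float, *, pKa: float = CO2_PKA,
          solubility: float = CO2_SOLUBILITY_MM_PER_MMHG,
          barometric: float = BAROMETRIC_MMHG,
          vapor: float = WATER_VAPOR_MMHG) -> float:
    """Predict medium pH from bicarbonate concentration and CO2 fraction.

    Henderson-Hasselbalch for the open system: 22 mM HCO3- under 5% CO2
    equilibrates to pH 7.40.
    """
    if hco3_mM <= 0:
        raise ValueError("hco3_mM must be positive (pH undefined at 0 mM)")
    co2 = dissolved_co2(co2_pct, solubility=solubility, barometric=barometric,
                        vapor=vapor)
    return pKa + math.log10(hco3_mM / co2)


def hh_hco3(target_pH: float, co2_pct: float, *, pKa: float = CO2_PKA,
            solubility: float = CO2_SOLUBILITY_MM_PER_MMHG,
            barometric: float = BAROMETRIC_MMHG,
            vapor: float = WATER_VAPOR_MMHG) -> float:
    """Bicarbonate concentration (mM) needed to reach ``target_pH``.

    Exact algebraic inverse of :func:`hh_pH`.
    """
    co2 = dissolved_co2(co2_pct, solubility=solubility, barometric=barometric,
                        vapor=vapor)
    return co2 * 10.0 ** (target_pH - pKa)


@dataclass(frozen=True)
class MediumSpec:
    """One medium of the iso-osmolar NaHCO3/NaCl mixing series."""

    hco3_mM: float
    nacl_mM: float
    co2_pct: float
    hepes_mM: float
    mes_mM: float
    predicted_pH: float

    def __post_init__(self) -> None:
        for name in ("hco3_mM", "nacl_mM", "hepes_mM", "mes_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def bicarb_series(hco3_list, co2_pct: float = 5.0, *, total_mM: float = 44.0,
                  hepes_mM: float = 0.0, mes_mM: float = 0.0) -> list[MediumSpec]:
    """Design an iso-osmolar NaHCO3/NaCl series (NaCl = total - HCO3-).

    Mirrors mixing 44 mM NaHCO3 and 44 mM NaCl stocks in varying ratio, so
    the summed monovalent sodium salt stays at ``total_mM``.
    """
    specs = []
    for hco3 in hco3_list:
        if not 0 < hco3 <= total_mM:
            raise ValueError(
                f"hco3 must be in (0, {total_mM}] mM, got {hco3}")
        specs.append(MediumSpec(
            hco3_mM=float(hco3),
            nacl_mM=float(total_mM - hco3),
            co2_pct=float(co2_pct),
            hepes_mM=float(hepes_mM),
            mes_mM=float(mes_mM),
            predicted_pH=hh_pH(hco3, co2_pct),
        ))
    return specs


def buffering_capacity(hepes_mM: float, mes_mM: float, hco3_mM: float,
                       pH, *, hepes_pKa: float = HEPES_PKA,
                       mes_pKa: float = MES_PKA):
    """Buffering capacity beta (mM per pH unit) at a given pH.

    Each closed-system buffer of total concentration C and dissociation
    constant Ka contributes 2.303*C*Ka*h/(Ka+h)^2 where h = 10^-pH; the
    open CO2/HCO3- system contributes 2.303*[HCO3-] (pCO2 clamped by the
    incubator, so CO2 does not deplete).
    """
    pH = np.asarray(pH, dtype=float)
    h = 10.0 ** (-pH)
    beta = np.zeros_like(pH)
    for conc, pka in ((hepes_mM, hepes_pKa), (mes_mM, mes_pKa)):
        if conc < 0:
            raise ValueError("buffer concentrations must be >= 0")
        ka = 10.0 ** (-pka)
        beta = beta + LN10 * conc * ka * h / (ka + h) ** 2
    if hco3_mM < 0:
        raise ValueError("hco3_mM must be >= 0")
    beta = beta + LN10 * hco3_mM
    return beta if beta.ndim else float(beta)


@dataclass(frozen=True)
class CalibrationCurve:
    """Ratiometric dye calibration: a sigmoid between two ratio plateaus.

    ``R_acid`` and ``R_base`` are the ratio limits at very low and very high
    pH; either orientation (ratio rising or falling with pH) is allowed as
    long as the two plateaus differ. ``pKa_app`` is the apparent pKa from a
    nigericin-clamp (or equivalent) calibration.
    """

    R_acid: float
    R_base: float
    pKa_app: float

    def __post_init__(self) -> None:
        if self.R_acid == self.R_base:
            raise ValueError("R_acid and R_base must differ")
        if not 5.0 <= self.pKa_app <= 9.0:
            raise ValueError("pKa_app outside the plausible [5, 9] range")


def ratio_from_pH(pH, calib: CalibrationCurve):
    """Forward ratio model: R(pH) on the calibration sigmoid."""
    pH = np.asarray(pH, dtype=float)
    t = 10.0 ** (pH - calib.pKa_app)
    R = (calib.R_acid + calib.R_base * t) / (1.0 + t)
    return R if R.ndim else float(R)


def ratiometric_pH(R, calib: CalibrationCurve):
    """Invert a measured dye ratio to pH.

    pH = pKa_app + log10((R - R_acid)/(R_base - R)). Ratios outside the
    open interval between the two plateaus cannot be inverted and come back
    as NaN with the censoring mask set.

    Returns
    -------
    (pH, censored) : ndarray pair (scalars for scalar input)
    """
    R = np.asarray(R, dtype=float)
    lo, hi = sorted((calib.R_acid, calib.R_base))
    censored = ~((R > lo) & (R < hi))
    num = R - calib.R_acid
    den = calib.R_base - R
    with np.errstate(divide="ignore", invalid="ignore"):
        pH = np.where(censored, np.nan,
                      calib.pKa_app + np.log10(np.abs(num) / np.abs(den)))
    if pH.ndim == 0:
        return float(pH), bool(censored)
    return pH, censored


def fit_calibration(pH_points, R_points) -> CalibrationCurve:
    """Least-squares fit of the 3-parameter ratio sigmoid to calibration data.

    Requires >= 4 points that actually span the sigmoid (points sitting on a
    single plateau leave pKa_app unidentifiable and raise).
    """
    from scipy.optimize import least_squares

    pH_points = np.asarray(pH_points, dtype=float)
    R_points = np.asarray(R_points, dtype=float)
    if pH_points.size < 4:
        raise ValueError("need at least 4 calibration points")
    spread = R_points.max() - R_points.min()
    if spread <= 1e-12 * max(1.0, abs(R_points).max()):
        raise ValueError("calibration points lie on one plateau; "
                         "pKa_app unidentifiable")

    def resid(theta):
        calib = CalibrationCurve(R_acid=theta[0], R_base=theta[1],
                                 pKa_app=min(max(theta[2], 5.0), 9.0))
        return ratio_from_pH(pH_points, calib) - R_points

    x0 = np.array([R_points[np.argmin(pH_points)],
                   R_points[np.argmax(pH_points)],
                   float(np.median(pH_points))])
    # nudge identical plateau guesses apart so the model is defined at x0
    if abs(x0[0] - x0[1]) < 1e-9:
        x0[1] += max(1e-3, 0.1 * spread)
    sol = least_squares(resid, x0, bounds=([-np.inf, -np.inf, 5.0],
                                           [np.inf, np.inf, 9.0]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    fitted = CalibrationCurve(*sol.x)
    rel_resid = np.linalg.norm(sol.fun) / max(spread, 1e-12)
    if rel_resid > 10.0:
        raise ValueError("calibration fit did not converge")
    return fitted


def stern_volmer_O2(F0: float, F, Ksv: float):
    """O2 concentration from collisional quenching: F0/F = 1 + Ksv*[O2].

    ``Ksv`` has inverse-concentration units, so the result is in the
    reciprocal units of Ksv (per-mM Ksv gives mM O2).
    """
    F = np.asarray(F, dtype=float)
    if Ksv <= 0:
        raise ValueError("Ksv must be positive")
    if np.any(F <= 0):
        raise ValueError("F must be positive")
    if np.any(F > F0):
        raise ValueError("F exceeds F0: negative quenching is unphysical")
    o2 = (F0 / F - 1.0) / Ksv
    return o2 if o2.ndim else float(o2)


def ros_index(F_dcf, F_hoechst):
    """ROS index: oxidation-sensitive dye signal per unit nuclear stain.

    Normalizing H2DCFDA fluorescence to Hoechst makes the index invariant
    to cell number (both channels scale with cells).
    """
    F_hoechst = np.asarray(F_hoechst, dtype=float)
    if np.any(F_hoechst <= 0):
        raise ValueError("Hoechst signal must be positive")
    idx = np.asarray(F_dcf, dtype=float) / F_hoechst
    return idx if idx.ndim else float(idx)


@dataclass(frozen=True)
class FluxRates:
    """Metabolic exchange rates from endpoint medium assays."""

    glucose_consumption: float  # mM * mL / (h * biomass unit)
    lactate_production: float
    lactate_glucose_ratio: float
    exceeds_glycolytic_stoichiometry: bool


def flux_rates(glucose_initial_mM: float, glucose_final_mM: float,
               lactate_initial_mM: float, lactate_final_mM: float,
               duration_h: float, biomass: float,
               volume_mL: float = 1.0) -> FluxRates:
    """Glucose consumption and lactate production rates per unit biomass.

    rate = delta-concentration * volume / (duration * biomass). Pure
    glycolysis yields at most 2 lactate per glucose; a larger ratio is
    flagged (it implies another lactate source or assay error).
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if biomass <= 0:
        raise ValueError("biomass must be positive")
    glc = (glucose_initial_mM - glucose_final_mM) * volume_mL / (duration_h * biomass)
    lac = (lactate_final_mM - lactate_initial_mM) * volume_mL / (duration_h * biomass)
    ratio = lac / glc if glc != 0 else math.inf if lac > 0 else 0.0
    return FluxRates(glucose_consumption=glc, lactate_production=lac,
                     lactate_glucose_ratio=ratio,
                     exceeds_glycolytic_stoichiometry=bool(ratio > 2.0 + 1e-12))
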