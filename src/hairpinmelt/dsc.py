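"""DSC analysis: excess heat capacity, enthalpies and cooperativity.

The processing chain mirrors standard peptide calorimetry.  A buffer-buffer
reference scan is subtracted; a chemical baseline is taken as the straight
line through the scan values at user-chosen (or automatically detected)
onset/offset temperatures; the excess heat capacity is integrated for the
calorimetric enthalpy ΔH_cal; and the van't Hoff enthalpy follows from the
two-state relation

    ΔH_vH = 4·R·Tm²·Cp_exc(Tm) / ΔH_cal

with Tm the temperature of the excess-heat-capacity maximum.  The ratio
r_vH = ΔH_vH/ΔH_cal diagnoses cooperativity: ≈1 means a two-state
transition, ≫1 a broad non-cooperative (or multi-event) process.  The
cumulative excess enthalpy is additionally fitted with a logistic
Y(T) = ΔH·(1 − 1/(1 + exp((T − T_half)/w))) giving the half-enthalpy
temperature T_half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .types import DSCThermogram

__all__ = [
    "R_KJ",
    "ExcessCurve",
    "DSCResult",
    "EnthalpyFitResult",
    "subtract_reference",
    "excess_heat_capacity",
    "calorimetric_enthalpy",
    "vant_hoff_enthalpy",
    "vant_hoff_ratio",
    "excess_enthalpy_fit",
    "auto_onset_offset",
    "DSCAnalysis",
]

#: gas constant, kJ·mol⁻¹·K⁻¹
R_KJ = 8.314e-3

# cooperativity verdict thresholds on r_vH
TWO_STATE_BAND = (0.8, 1.25)
NON_COOPERATIVE_ABOVE = 4.0


@dataclass(frozen=True)
class ExcessCurve:
    """Baseline-subtracted excess heat capacity, zero outside [onset, offset]."""

    temperatures: np.ndarray
    cp_exc: np.ndarray
    onset: float
    offset: float
    baseline_intercept: float
    baseline_slope: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures",
                           np.asarray(self.temperatures, dtype=float))
        object.__setattr__(self, "cp_exc", np.asarray(self.cp_exc, dtype=float))
        if not self.onset < self.offset:
            raise ValueError("onset must be below offset")

    @property
    def window(self) -> np.ndarray:
        T = self.temperatures
        return (T >= self.onset) & (T <= self.offset)


@dataclass(frozen=True)
class EnthalpyFitResult:
    """Logistic fit of the cumulative excess enthalpy."""

    dh_cal_fit: float     # plateau (kJ/mol)
    t_half: float         # half-enthalpy temperature (K)
    width: float          # logistic width (K)
    residuals: np.ndarray
    converged: bool


@dataclass(frozen=True)
class DSCResult:
    """Full calorimetric summary of one thermogram."""

    tm: float                     # temperature of max Cp_exc (K)
    dcp_at_tm: float              # Cp_exc(Tm) (kJ/mol/K)
    dh_cal: float                 # kJ/mol
    dh_vh: float                  # kJ/mol
    r_vh: float
    verdict: str
    excess: ExcessCurve
    enthalpy_fit: Optional[EnthalpyFitResult] = None

    def summary(self) -> str:
        lines = [
            "DSC analysis",
            f"  Tm               = {self.tm:.2f} K",
            f"  Cp_exc(Tm)       = {self.dcp_at_tm:.4f} kJ/mol/K",
            f"  dH_cal           = {self.dh_cal:.3f} kJ/mol",
            f"  dH_vH            = {self.dh_vh:.2f} kJ/mol",
            f"  r_vH             = {self.r_vh:.2f}  ({self.verdict})",
        ]
        if self.enthalpy_fit is not None and self.enthalpy_fit.converged:
            lines.append(
                f"  T_1/2 (enthalpy) = {self.enthalpy_fit.t_half:.2f} K "
                f"(width {self.enthalpy_fit.width:.2f} K)"
            )
        return "\n".join(lines)


def subtract_reference(thermogram: DSCThermogram,
                       reference: Optional[DSCThermogram] = None) -> DSCThermogram:
    """Subtract a buffer-buffer reference scan, interpolated to the sample grid.

    The result is restricted to the overlap of the two temperature ranges;
    disjoint ranges are an error.  ``reference=None`` falls back to the
    reference attached to the thermogram, or is a no-op.
    """
    reference = reference if reference is not None else thermogram.reference
    if reference is None:
        return thermogram
    lo = max(thermogram.temperatures[0], reference.temperatures[0])
    hi = min(thermogram.temperatures[-1], reference.temperatures[-1])
    if lo >= hi:
        raise ValueError("sample and reference scans do not overlap in temperature")
    mask = (thermogram.temperatures >= lo) & (thermogram.temperatures <= hi)
    T = thermogram.temperatures[mask]
    ref_cp = np.interp(T, reference.temperatures, reference.heat_capacity)
    return DSCThermogram(T, thermogram.heat_capacity[mask] - ref_cp,
                         scan_rate=thermogram.scan_rate,
                         concentration=thermogram.concentration)


def auto_onset_offset(thermogram: DSCThermogram) -> Tuple[float, float]:
    """Heuristic transition window: longest linear pre-/post-transition ends.

    Grows a window from each end of the scan while a local straight-line fit
    leaves residuals below twice a robust noise estimate (median absolute
    successive difference / sqrt(2) / 0.6745); the window ends become
    onset/offset.  Manual onset/offset always take precedence.
    """
    T, cp = thermogram.temperatures, thermogram.heat_capacity
    n = len(T)
    noise = np.median(np.abs(np.diff(cp))) / (np.sqrt(2) * 0.6745)
    noise = max(noise, 1e-12)

    def grow(idx: np.ndarray) -> int:
        best = 3
        for m in range(3, len(idx) + 1):
            sel = idx[:m]
            coef = np.polyfit(T[sel], cp[sel], 1)
            resid = cp[sel] - np.polyval(coef, T[sel])
            if np.max(np.abs(resid)) < 2.0 * noise:
                best = m
            else:
                break
        return best

    n_lo = grow(np.arange(n))
    n_hi = grow(np.arange(n)[::-1])
    i_on = min(n_lo - 1, n - 2)
    i_off = max(n - n_hi, i_on + 1)
    return float(T[i_on]), float(T[i_off])


def excess_heat_capacity(thermogram: DSCThermogram,
                         onset: Optional[float] = None,
                         offset: Optional[float] = None) -> ExcessCurve:
    """Subtract the linear onset/offset chord; zero outside the window.

    The chemical baseline is the straight line through
    (onset, Cp(onset)) and (offset, Cp(offset)); the excess heat capacity is
    Cp − baseline inside [onset, offset] and identically zero outside.
    Omitted onset/offset are chosen by :func:`auto_onset_offset`.
    """
    T, cp = thermogram.temperatures, thermogram.heat_capacity
    if onset is None or offset is None:
        a_on, a_off = auto_onset_offset(thermogram)
        onset = a_on if onset is None else onset
        offset = a_off if offset is None else offset
    # tolerate float-grid round-off at the scan edges
    eps = 1e-6 * max(1.0, T[-1] - T[0])
    if not (T[0] - eps <= onset < offset <= T[-1] + eps):
        raise ValueError(
            f"onset/offset ({onset}, {offset}) outside scan range [{T[0]}, {T[-1]}]"
        )
    onset = float(np.clip(onset, T[0], T[-1]))
    offset = float(np.clip(offset, T[0], T[-1]))
    cp_on = float(np.interp(onset, T, cp))
    cp_off = float(np.interp(offset, T, cp))
    slope = (cp_off - cp_on) / (offset - onset)
    intercept = cp_on - slope * onset
    exc = cp - (intercept + slope * T)
    exc[(T < onset) | (T > offset)] = 0.0
    return ExcessCurve(T, exc, onset, offset, intercept, slope)


def calorimetric_enthalpy(curve: ExcessCurve) -> float:
    """ΔH_cal: trapezoidal integral of Cp_exc over [onset, offset] (kJ/mol)."""
    w = curve.window
    return float(np.trapezoid(curve.cp_exc[w], curve.temperatures[w]))


def vant_hoff_enthalpy(tm: float, dcp_at_tm: float, dh_cal: float) -> float:
    """Two-state van't Hoff enthalpy from peak height, midpoint and area.

    ΔH_vH = 4·R·Tm²·Cp_exc(Tm)/ΔH_cal, all enthalpies kJ/mol.
    """
    if dh_cal <= 0:
        raise ValueError("dh_cal must be > 0 for the van't Hoff enthalpy")
    if tm <= 0:
        raise ValueError("tm must be > 0")
    return 4.0 * R_KJ * tm**2 * dcp_at_tm / dh_cal


def vant_hoff_ratio(dh_vh: float, dh_cal: float) -> Tuple[float, str]:
    """r_vH = ΔH_vH/ΔH_cal plus a cooperativity verdict.

    Verdict: ``two-state`` for r within [0.8, 1.25], ``non-cooperative``
    above 4, else ``intermediate``.
    """
    if dh_cal <= 0:
        raise ValueError("dh_cal must be > 0")
    r = dh_vh / dh_cal
    if TWO_STATE_BAND[0] <= r <= TWO_STATE_BAND[1]:
        verdict = "two-state"
    elif r > NON_COOPERATIVE_ABOVE:
        verdict = "non-cooperative"
    else:
        verdict = "intermediate"
    return r, verdict


def _enthalpy_logistic(T, dh, t_half, w):
    return dh * (1.0 - 1.0 / (1.0 + np.exp((T - t_half) / w)))


def excess_enthalpy_fit(curve: ExcessCurve) -> EnthalpyFitResult:
    """Fit the cumulative excess enthalpy with a logistic in temperature.

    Y(T) = ΔH·(1 − 1/(1 + exp((T − T_half)/w))): T_half is the temperature
    at which the enthalpy reaches 50% of its plateau; the width w makes the
    otherwise dimensionally rigid logistic match arbitrary transition
    widths and is reported alongside.
    """
    w = curve.window
    T = curve.temperatures[w]
    H = np.concatenate([[0.0], cumulative_trapezoid(curve.cp_exc[w], T)])
    total = H[-1]
    if total <= 0:
        return EnthalpyFitResult(0.0, float(T[len(T) // 2]), 1.0,
                                 H - H, converged=False)
    t_half0 = float(np.interp(0.5 * total, H, T))
    w0 = max((np.interp(0.75 * total, H, T) - np.interp(0.25 * total, H, T)) / 2.2,
             0.1)
    try:
        popt, _ = curve_fit(_enthalpy_logistic, T, H,
                            p0=[total, t_half0, w0],
                            bounds=([0.0, T[0] - 50.0, 1e-3],
                                    [np.inf, T[-1] + 50.0, 1e3]),
                            maxfev=20000)
        converged = True
    except (RuntimeError, ValueError):
        popt, converged = np.array([total, t_half0, w0]), False
    resid = H - _enthalpy_logistic(T, *popt)
    return EnthalpyFitResult(float(popt[0]), float(popt[1]), float(popt[2]),
                             resid, converged)


class DSCAnalysis:
    """End-to-end DSC model for one thermogram.

    Parameters
    ----------
    thermogram : DSCThermogram
        The (molar) scan; an attached reference scan is subtracted first.
    onset, offset : float, optional
        Manual transition window (K).  Whichever is omitted is auto-detected.
    """

    def __init__(self, thermogram: DSCThermogram,
                 reference: Optional[DSCThermogram] = None,
                 onset: Optional[float] = None, offset: Optional[float] = None):
        self.thermogram = thermogram
        self.reference = reference
        self.onset = onset
        self.offset = offset

    def fit(self) -> DSCResult:
        corrected = subtract_reference(self.thermogram, self.reference)
        curve = excess_heat_capacity(corrected, self.onset, self.offset)
        w = curve.window
        i = int(np.argmax(curve.cp_exc[w]))
        tm = float(curve.temperatures[w][i])
        dcp = float(curve.cp_exc[w][i])
        dh_cal = calorimetric_enthalpy(curve)
        dh_vh = vant_hoff_enthalpy(tm, dcp, dh_cal)
        r, verdict = vant_hoff_ratio(dh_vh, dh_cal)
        efit = excess_enthalpy_fit(curve)
        return DSCResult(tm, dcp, dh_cal, dh_vh, r, verdict, curve, efit)
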