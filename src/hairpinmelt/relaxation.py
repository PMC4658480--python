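"""¹⁵N relaxation: mono-exponential R1/R2 fits and heteronuclear NOE.

Longitudinal and transverse rates come from nonlinear least squares of
I(t) = I0·exp(−R·t) against the peak intensities at each relaxation delay,
with 1σ uncertainties from the fit covariance.  The heteronuclear NOE is
the saturated/unsaturated peak-height ratio with its uncertainty fixed at
5% of the value.  Delays are seconds, rates s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .types import IntensityTable

__all__ = ["RelaxationFit", "RelaxationModel", "fit_rate", "het_noe",
           "profile_compare", "NOE_UNCERTAINTY_FRACTION"]

#: fractional uncertainty assigned to every heteronuclear NOE value
NOE_UNCERTAINTY_FRACTION = 0.05


@dataclass(frozen=True)
class RelaxationFit:
    """One residue's relaxation observable.

    ``value`` is a rate in s⁻¹ for kinds R1/R2 and the dimensionless
    intensity ratio for NOE; ``i0`` is the fitted zero-delay intensity
    (rates only).
    """

    residue_number: int
    kind: str
    value: float
    uncertainty: float
    i0: Optional[float] = None
    i0_uncertainty: Optional[float] = None
    converged: bool = True


def _decay(t, i0, r):
    return i0 * np.exp(-r * t)


class RelaxationModel:
    """Mono-exponential decay model for one :class:`IntensityTable`."""

    def __init__(self, table: IntensityTable,
                 sigma: Optional[np.ndarray] = None):
        if table.experiment_kind not in ("R1", "R2"):
            raise ValueError(
                f"rate fitting needs an R1/R2 table, got {table.experiment_kind}"
            )
        if len(table) < 3:
            raise ValueError(f"need >= 3 delay points, got {len(table)}")
        if np.ptp(table.delays) == 0:
            raise ValueError("all relaxation delays are equal; rate is unidentifiable")
        self.table = table
        self.sigma = sigma

    def start_params(self) -> np.ndarray:
        t, I = self.table.delays, self.table.intensities
        pos = I > 0
        if pos.sum() >= 2:
            slope, logi0 = np.polyfit(t[pos], np.log(I[pos]), 1)
            return np.array([np.exp(logi0), max(-slope, 1e-9)])
        return np.array([max(I.max(), 1e-9), 1.0])

    def fit(self) -> RelaxationFit:
        t, I = self.table.delays, self.table.intensities
        p0 = self.start_params()
        try:
            popt, pcov = curve_fit(_decay, t, I, p0=p0, sigma=self.sigma,
                                   bounds=([0.0, 0.0], [np.inf, np.inf]),
                                   maxfev=20000)
            err = np.sqrt(np.abs(np.diag(pcov)))
            converged = bool(np.all(np.isfinite(popt)))
        except (RuntimeError, ValueError):
            popt, err, converged = p0, np.full(2, np.nan), False
        return RelaxationFit(self.table.residue_number, self.table.experiment_kind,
                             float(popt[1]), float(err[1]), float(popt[0]),
                             float(err[0]), converged)


def fit_rate(table: IntensityTable,
             sigma: Optional[np.ndarray] = None) -> RelaxationFit:
    """Convenience wrapper: ``RelaxationModel(table, sigma).fit()``."""
    return RelaxationModel(table, sigma).fit()


def het_noe(sat: float, unsat: float, residue_number: int = 0) -> RelaxationFit:
    """Heteronuclear NOE = sat/unsat peak heights; uncertainty 5% of |value|."""
    if unsat == 0:
        raise ValueError("unsaturated intensity must be nonzero")
    value = sat / unsat
    return RelaxationFit(residue_number, "NOE", float(value),
                         NOE_UNCERTAINTY_FRACTION * abs(value))


def profile_compare(fits_a: Iterable[RelaxationFit],
                    fits_b: Iterable[RelaxationFit]) -> pd.DataFrame:
    """Per-residue differences (A − B) with quadrature-propagated errors.

    Residues are matched on (residue_number, kind); returns columns
    ``residue_number, kind, value_a, value_b, delta, delta_uncertainty``.
    """
    def index(fits: Iterable[RelaxationFit]) -> Dict[Tuple[int, str], RelaxationFit]:
        return {(f.residue_number, f.kind): f for f in fits}

    a, b = index(fits_a), index(fits_b)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared (residue, experiment) pairs")
    rows = []
    for key in shared:
        fa, fb = a[key], b[key]
        rows.append(dict(
            residue_number=key[0], kind=key[1],
            value_a=fa.value, value_b=fb.value, delta=fa.value - fb.value,
            delta_uncertainty=float(np.hypot(fa.uncertainty, fb.uncertainty)),
        ))
    return pd.DataFrame(rows)
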