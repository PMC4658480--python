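"""Per-proton sigmoidal melt-curve fitting.

Each proton's chemical shift δ(T) across the temperature series is fitted
with a five-parameter Boltzmann sigmoid with a linear baseline anchored at
the midpoint:

    δ(T) = B·(T − x0) + A2 + (A1 − A2) / (1 + exp((T − x0)/dx))

A1 and A2 are the starting (low-temperature) and final (high-temperature)
amplitudes, B the baseline slope, x0 the transition midpoint — reported as
that proton's melting temperature Tm — and dx the logistic width parameter
(the actual slope of the sigmoid at x0 is (A2 − A1)/(4·dx) + B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .types import MeltSeries, ProtonID

__all__ = [
    "boltzmann_sigmoid",
    "eval_melt_model",
    "MeltCurveModel",
    "MeltFit",
    "fit_melt_curve",
    "FilterCriteria",
    "filter_fits",
]

PARAM_NAMES = ("A1", "A2", "B", "x0", "dx")

# bounds relative to the data range keep the optimiser out of degenerate
# plateau solutions
_DX_BOUNDS = (0.5, 50.0)
_X0_MARGIN = 10.0


def boltzmann_sigmoid(T, A1, A2, B, x0, dx):
    """Evaluate the five-parameter melt model at temperature(s) ``T``."""
    if dx <= 0:
        raise ValueError(f"dx must be > 0, got {dx}")
    T = np.asarray(T, dtype=float)
    return B * (T - x0) + A2 + (A1 - A2) / (1.0 + np.exp((T - x0) / dx))


#: spec-facing alias
eval_melt_model = boltzmann_sigmoid


@dataclass(frozen=True)
class MeltFit:
    """Fitted melt-curve parameters for one proton.

    ``params``/``bse`` are ordered (A1, A2, B, x0, dx); ``x0`` is the
    proton's melting temperature.  ``rsquared`` is the coefficient of
    determination and ``resid_sd`` the residual standard deviation (ppm).
    """

    proton: ProtonID
    params: np.ndarray
    bse: np.ndarray
    resid_sd: float
    rsquared: float
    converged: bool
    n_obs: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", np.asarray(self.params, dtype=float))
        object.__setattr__(self, "bse", np.asarray(self.bse, dtype=float))

    A1 = property(lambda self: self.params[0])
    A2 = property(lambda self: self.params[1])
    B = property(lambda self: self.params[2])
    x0 = property(lambda self: self.params[3])
    dx = property(lambda self: self.params[4])

    @property
    def tm(self) -> float:
        """Melting temperature (K); alias of the fitted midpoint x0."""
        return self.x0

    @property
    def tm_err(self) -> float:
        return float(self.bse[3])

    @property
    def amplitude(self) -> float:
        """Total transition amplitude |A1 − A2| (ppm)."""
        return float(abs(self.A1 - self.A2))

    def predict(self, T) -> np.ndarray:
        return boltzmann_sigmoid(T, *self.params)

    def summary(self) -> str:
        lines = [f"Melt-curve fit: {self.proton}  (n={self.n_obs}, "
                 f"converged={self.converged})"]
        for name, v, e in zip(PARAM_NAMES, self.params, self.bse):
            lines.append(f"  {name:>3} = {v:12.5f} +/- {e:.5f}")
        lines.append(f"  R^2 = {self.rsquared:.5f}   resid SD = {self.resid_sd:.5f} ppm")
        return "\n".join(lines)


class MeltCurveModel:
    """Boltzmann sigmoid model for one :class:`MeltSeries`.

    Parameters
    ----------
    series : MeltSeries
        The observed melting series (>= 6 points).
    weights : array-like, optional
        Per-point standard deviations; omitted means unweighted least
        squares.
    """

    def __init__(self, series: MeltSeries, weights: Optional[Sequence[float]] = None):
        self.series = series
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    # -- initialisation -----------------------------------------------------
    @staticmethod
    def _solve_linear(T: np.ndarray, d: np.ndarray, x0: float,
                      dx: float) -> Tuple[np.ndarray, float]:
        """Best (A1, A2, B) for fixed (x0, dx); the model is linear in them.

        Returns the full parameter vector and the residual sum of squares.
        """
        s = 1.0 / (1.0 + np.exp((T - x0) / dx))
        X = np.column_stack([s, 1.0 - s, T - x0])
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        ssr = float(np.sum((d - X @ coef) ** 2))
        return np.array([coef[0], coef[1], coef[2], x0, dx]), ssr

    def start_params(self) -> np.ndarray:
        """Deterministic coarse grid-search starting values.

        Scans candidate midpoints (the observed temperatures and the
        steepest finite-difference d(δ)/dT location) against a short list of
        widths, solving the linear parameters (A1, A2, B) exactly at each
        node, and starts from the best node.
        """
        T, d = self.series.temperatures, self.series.shifts
        dd = np.diff(d) / np.diff(T)
        mid = np.argmax(np.abs(dd))
        x0_candidates = np.unique(np.concatenate(
            [T, [0.5 * (T[mid] + T[mid + 1])]]))
        best, best_ssr = None, np.inf
        for x0 in x0_candidates:
            for dx in (1.0, 2.0, 5.0, 10.0, 20.0):
                params, ssr = self._solve_linear(T, d, x0, dx)
                if ssr < best_ssr:
                    best, best_ssr = params, ssr
        return best

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        T = self.series.temperatures
        lo = np.array([-np.inf, -np.inf, -np.inf, T[0] - _X0_MARGIN, _DX_BOUNDS[0]])
        hi = np.array([np.inf, np.inf, np.inf, T[-1] + _X0_MARGIN, _DX_BOUNDS[1]])
        return lo, hi

    # -- fitting ------------------------------------------------------------
    def fit(self) -> MeltFit:
        """Least-squares fit; never raises on optimiser failure.

        A failed optimisation, or a solution pinned at the x0/dx bounds,
        is returned with ``converged=False``.
        """
        T, d = self.series.temperatures, self.series.shifts
        p0 = self.start_params()
        lo, hi = self.bounds()
        p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
        try:
            popt, pcov = curve_fit(
                boltzmann_sigmoid, T, d, p0=p0, sigma=self.weights,
                bounds=(lo, hi), maxfev=20000,
                xtol=1e-13, ftol=1e-13, gtol=1e-13,
            )
            converged = bool(np.all(np.isfinite(popt)))
        except (RuntimeError, ValueError):
            popt, pcov = p0, np.full((5, 5), np.nan)
            converged = False
        resid = d - boltzmann_sigmoid(T, *popt)
        dof = max(len(T) - 5, 1)
        resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
        ss_tot = float(np.sum((d - d.mean()) ** 2))
        rsq = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        bse = np.sqrt(np.abs(np.diag(pcov))) if np.all(np.isfinite(pcov)) else \
            np.full(5, np.nan)
        # a solution pinned at the x0 or dx bound is not trustworthy
        at_bound = (
            np.isclose(popt[3], lo[3]) or np.isclose(popt[3], hi[3])
            or np.isclose(popt[4], lo[4]) or np.isclose(popt[4], hi[4])
        )
        if at_bound:
            converged = False
        return MeltFit(self.series.proton, popt, bse, resid_sd, rsq, converged,
                       len(T))


def fit_melt_curve(series: MeltSeries,
                   weights: Optional[Sequence[float]] = None) -> MeltFit:
    """Convenience wrapper: ``MeltCurveModel(series, weights).fit()``."""
    return MeltCurveModel(series, weights).fit()


# ---------------------------------------------------------------------------
# curve selection

@dataclass(frozen=True)
class FilterCriteria:
    """Acceptance rules separating usable sigmoidal melts from flat/failed ones."""

    min_amplitude_to_noise: float = 5.0   # |A1-A2| / resid SD
    min_rsquared: float = 0.9
    require_converged: bool = True


@dataclass(frozen=True)
class RejectedFit:
    fit: MeltFit
    reason: str


def filter_fits(
    fits: Iterable[MeltFit],
    criteria: FilterCriteria = FilterCriteria(),
) -> Tuple[List[MeltFit], List[RejectedFit]]:
    """Partition fits into (accepted, rejected-with-reason).

    The partition is exhaustive and disjoint; each rejection carries a
    machine-readable reason string (first failed rule wins, checked in the
    order amplitude, convergence, goodness — a flat curve is reported as
    amplitude-limited even when the optimiser also gave up on it).
    """
    accepted: List[MeltFit] = []
    rejected: List[RejectedFit] = []
    for f in fits:
        if f.resid_sd > 0 and f.amplitude < criteria.min_amplitude_to_noise * f.resid_sd:
            rejected.append(RejectedFit(f, "amplitude-below-threshold"))
        elif criteria.require_converged and not f.converged:
            rejected.append(RejectedFit(f, "not-converged"))
        elif f.rsquared < criteria.min_rsquared:
            rejected.append(RejectedFit(f, "goodness-below-threshold"))
        else:
            accepted.append(f)
    return accepted, rejected
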