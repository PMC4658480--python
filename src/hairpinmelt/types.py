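"""Core record types shared by every analysis stage.

The unit records of the pipeline: a proton identity, one proton's chemical
shift as a function of temperature (the melting series), a DSC thermogram,
and a relaxation peak-intensity table.  All temperatures are kelvin, shifts
ppm, heat capacities kJ·mol⁻¹·K⁻¹, delays seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ProtonID",
    "MeltSeries",
    "DSCThermogram",
    "IntensityTable",
    "EXPERIMENT_KINDS",
]

#: permitted relaxation experiment labels
EXPERIMENT_KINDS = ("R1", "R2", "NOE_sat", "NOE_unsat")

# temperature sanity window for solution NMR melts (K)
_T_MIN, _T_MAX = 250.0, 400.0


@dataclass(frozen=True, order=True)
class ProtonID:
    """Identity of a single observed proton.

    Parameters
    ----------
    residue_number : int
        One-based position in the peptide sequence.
    residue_type : str
        One- or three-letter amino-acid code (stored as given).
    atom_name : str
        Proton label, e.g. ``HN``, ``HA``, ``HE1``.
    """

    residue_number: int
    atom_name: str
    residue_type: str = field(compare=False, default="X")

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")

    def __str__(self) -> str:  # e.g. "W5:HE1"
        return f"{self.residue_type}{self.residue_number}:{self.atom_name}"


@dataclass(frozen=True)
class MeltSeries:
    """One proton's chemical shift across a temperature series.

    ``temperatures`` must be strictly increasing, within [250, 400] K, and
    hold at least 6 points (a 5-parameter sigmoid needs >= 6 observations).
    """

    proton: ProtonID
    temperatures: np.ndarray
    shifts: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        d = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "shifts", d)
        if T.ndim != 1 or d.ndim != 1 or len(T) != len(d):
            raise ValueError("temperatures and shifts must be 1-D and equal length")
        if len(T) < 6:
            raise ValueError(
                f"melting series for {self.proton} has {len(T)} points; >= 6 required"
            )
        if np.any(np.diff(T) <= 0):
            raise ValueError(f"temperatures must be strictly increasing ({self.proton})")
        if T[0] < _T_MIN or T[-1] > _T_MAX:
            raise ValueError(
                f"temperatures outside [{_T_MIN}, {_T_MAX}] K for {self.proton}"
            )
        if not np.all(np.isfinite(d)):
            raise ValueError(f"non-finite shift value in series for {self.proton}")

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class DSCThermogram:
    """A DSC scan: molar heat capacity versus temperature.

    Attributes
    ----------
    temperatures, heat_capacity : ndarray
        Strictly increasing kelvin grid and Cp in kJ·mol⁻¹·K⁻¹; >= 20 points.
    scan_rate : float, optional
        Heating rate in K·min⁻¹.
    concentration : float, optional
        Sample concentration in mol·L⁻¹ (only needed to convert raw
        instrument heats to molar units).
    reference : DSCThermogram, optional
        Buffer-buffer scan recorded at the same rate.
    """

    temperatures: np.ndarray
    heat_capacity: np.ndarray
    scan_rate: Optional[float] = None
    concentration: Optional[float] = None
    reference: Optional["DSCThermogram"] = None

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        cp = np.asarray(self.heat_capacity, dtype=float)
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "heat_capacity", cp)
        if len(T) != len(cp):
            raise ValueError("temperature and heat-capacity traces differ in length")
        if len(T) < 20:
            raise ValueError(f"thermogram has {len(T)} points; >= 20 required")
        if np.any(np.diff(T) <= 0):
            raise ValueError("thermogram temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperatures)

    def with_heat_capacity(self, cp: Sequence[float]) -> "DSCThermogram":
        return replace(self, heat_capacity=np.asarray(cp, dtype=float))


@dataclass(frozen=True)
class IntensityTable:
    """Peak intensities of one residue at a series of relaxation delays."""

    residue_number: int
    delays: np.ndarray
    intensities: np.ndarray
    experiment_kind: str = "R1"

    def __post_init__(self) -> None:
        t = np.asarray(self.delays, dtype=float)
        I = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "delays", t)
        object.__setattr__(self, "intensities", I)
        if self.experiment_kind not in EXPERIMENT_KINDS:
            raise ValueError(
                f"experiment_kind must be one of {EXPERIMENT_KINDS}, "
                f"got {self.experiment_kind!r}"
            )
        if len(t) != len(I):
            raise ValueError("delays and intensities differ in length")
        if np.any(t < 0):
            raise ValueError("relaxation delays must be non-negative")

    def __len__(self) -> int:
        return len(self.delays)
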