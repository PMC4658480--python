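"""Synthetic data with known ground truth.

Every analysis stage in this package is validated by parameter recovery:
the generators here draw per-proton melting curves, two-state DSC
thermograms and mono-exponential relaxation decays from the same models the
fitting stages assume, record every drawn parameter, and are bit-reproducible
for a fixed seed.

The packaged default melting dataset emulates a 17-residue designed
β-hairpin (sequence KQLLWIRSGDRPWYYTS) whose 30 usable proton melt curves
fall into three Tm classes: the β-strand residues (mean 316.5 K, SD 0.5 K,
13 protons), the β-turn residues (319.3 K, SD 0.3 K, 5 protons) and the two
tryptophan side chains (320.1 K, SD 0.6 K, 12 aromatic protons).  The
atom-type split of the roster is 6 HN, 7 Hα, 5 aliphatic and 12 aromatic
protons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .meltfit import boltzmann_sigmoid
from .types import DSCThermogram, IntensityTable, MeltSeries, ProtonID

__all__ = [
    "TmClass",
    "MeltSimSpec",
    "DSCSimSpec",
    "generate_melt_series",
    "generate_dsc_thermogram",
    "generate_relaxation_decays",
    "generate_noe_pairs",
    "default_melt_spec",
    "mutant_melt_spec",
    "default_dsc_spec",
    "melt_series_to_frame",
    "R_KJ",
    "R1_DELAYS_S",
    "R2_DELAYS_S",
]

#: gas constant, kJ·mol⁻¹·K⁻¹
R_KJ = 8.314e-3

#: ¹⁵N R1 relaxation delay set (s)
R1_DELAYS_S = np.array([0.010, 0.050, 0.100, 0.150, 0.200, 0.300, 0.400])
#: ¹⁵N R2 relaxation delay set (s)
R2_DELAYS_S = np.array([0.015, 0.030, 0.060, 0.090, 0.120, 0.150, 0.165])


@dataclass(frozen=True)
class TmClass:
    """One Gaussian Tm cluster: label, mean (K), SD (K), number of protons."""

    label: str
    tm_mean: float
    tm_sd: float
    n_protons: int

    def __post_init__(self) -> None:
        if self.tm_sd < 0:
            raise ValueError("tm_sd must be >= 0")
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")


@dataclass(frozen=True)
class MeltSimSpec:
    """Specification of a synthetic per-proton melting dataset."""

    classes: Tuple[TmClass, ...]
    temperatures: np.ndarray = field(
        default_factory=lambda: np.arange(278.0, 343.0 + 1e-9, 5.0)
    )
    dx: float = 5.0                       # transition width (K)
    amplitude_range: Tuple[float, float] = (0.1, 0.5)   # |A1-A2| (ppm)
    baseline_slope_range: Tuple[float, float] = (-0.003, 0.003)  # ppm/K
    noise_sd: float = 0.005               # ppm
    seed: int = 0

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "classes", tuple(self.classes))
        if len(T) < 6:
            raise ValueError("temperature grid must hold >= 6 points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for c in self.classes:
            if not (T[0] <= c.tm_mean <= T[-1]):
                raise ValueError(
                    f"class {c.label!r}: Tm mean {c.tm_mean} K outside grid "
                    f"[{T[0]}, {T[-1]}] K"
                )

    @property
    def n_protons(self) -> int:
        return sum(c.n_protons for c in self.classes)


@dataclass(frozen=True)
class DSCSimSpec:
    """Specification of a synthetic two-state DSC thermogram.

    The excess heat capacity follows the van't Hoff form

        Cp_exc(T) = ΔH_cal · (ΔH_vH / (R·T²)) · K/(1+K)²,
        K(T) = exp[-(ΔH_vH/R)(1/T - 1/Tm)]

    i.e. ΔH_cal · d f_u/dT with f_u = K/(1+K) the unfolded fraction.  The
    area of the transition is ΔH_cal while its width is set independently
    by ΔH_vH, so the van't Hoff ratio r = ΔH_vH/ΔH_cal is freely tunable
    above or below 1.  The peak height at Tm is exactly
    ΔH_cal·ΔH_vH/(4·R·Tm²); the integral over the grid equals ΔH_cal only
    insofar as the grid spans the transition.
    """

    dh_vh: float                          # van't Hoff enthalpy (kJ/mol)
    dh_cal: float                         # calorimetric enthalpy (kJ/mol)
    tm: float                             # midpoint (K)
    baseline_intercept: float = 0.0       # kJ/mol/K
    baseline_slope: float = 0.0           # kJ/mol/K per K
    noise_sd: float = 0.0                 # kJ/mol/K
    temperatures: np.ndarray = field(
        default_factory=lambda: np.arange(280.0, 350.0 + 1e-9, 0.05)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "temperatures", T)
        if self.dh_vh <= 0:
            raise ValueError("dh_vh must be > 0")
        if self.dh_cal < 0:
            raise ValueError("dh_cal must be >= 0")
        if not (T[0] <= self.tm <= T[-1]):
            raise ValueError(f"Tm {self.tm} K outside grid [{T[0]}, {T[-1]}] K")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# the packaged proton roster (class label, residue number, type, atom)

_TRP_RING = ("HD1", "HE1", "HE3", "HZ2", "HZ3", "HH2")

HPLW_PROTON_ROSTER: Tuple[Tuple[str, int, str, str], ...] = tuple(
    [
        # β-strand class: 4 HN + 5 Hα + 4 aliphatic side chain = 13
        ("strand", 3, "L", "HN"), ("strand", 3, "L", "HA"), ("strand", 3, "L", "HD1"),
        ("strand", 4, "L", "HN"), ("strand", 4, "L", "HA"), ("strand", 4, "L", "HD1"),
        ("strand", 6, "I", "HN"), ("strand", 6, "I", "HA"), ("strand", 6, "I", "HG2"),
        ("strand", 12, "P", "HA"), ("strand", 12, "P", "HD2"),
        ("strand", 14, "Y", "HN"), ("strand", 14, "Y", "HA"),
        # β-turn class: 2 HN + 2 Hα + 1 aliphatic = 5
        ("turn", 7, "R", "HN"), ("turn", 10, "D", "HN"),
        ("turn", 8, "S", "HA"), ("turn", 9, "G", "HA"), ("turn", 8, "S", "HB"),
        # tryptophan class: 12 aromatic ring protons
        *[("trp", 5, "W", a) for a in _TRP_RING],
        *[("trp", 13, "W", a) for a in _TRP_RING],
    ]
)

# representative plateau chemical shifts by atom flavour (ppm)
_BASE_SHIFT = {"HN": 8.30, "HA": 4.40, "aromatic": 7.25, "aliphatic": 1.10, "HB": 3.90}


def _base_shift(atom: str) -> float:
    if atom == "HN":
        return _BASE_SHIFT["HN"]
    if atom == "HA":
        return _BASE_SHIFT["HA"]
    if atom in _TRP_RING:
        return _BASE_SHIFT["aromatic"]
    if atom == "HB":
        return _BASE_SHIFT["HB"]
    return _BASE_SHIFT["aliphatic"]


def default_melt_spec(noise_sd: float = 0.005, seed: int = 0) -> MeltSimSpec:
    """The packaged default dataset: 3 Tm classes, 30 protons, 278-343 K."""
    return MeltSimSpec(
        classes=(
            TmClass("strand", 316.5, 0.5, 13),
            TmClass("turn", 319.3, 0.3, 5),
            TmClass("trp", 320.1, 0.6, 12),
        ),
        noise_sd=noise_sd,
        seed=seed,
    )


def mutant_melt_spec(noise_sd: float = 0.005, seed: int = 0) -> MeltSimSpec:
    """Trp→Val mutant-like dataset: one unfolding event at 311 ± 0.9 K."""
    return MeltSimSpec(
        classes=(TmClass("all", 311.0, 0.9, 30),),
        noise_sd=noise_sd,
        seed=seed,
    )


def default_dsc_spec(noise_sd: float = 0.0, seed: int = 0,
                     temperatures: Optional[Sequence[float]] = None) -> DSCSimSpec:
    """Two-state thermogram at the hairpin's calorimetric parameters.

    ΔH_vH = 127.1 kJ/mol, ΔH_cal = 3.9 kJ/mol, Tm = 316.4 K; default grid is
    the 280-350 K scan window at 0.05 K steps.
    """
    kwargs = {} if temperatures is None else {"temperatures": np.asarray(temperatures)}
    return DSCSimSpec(dh_vh=127.1, dh_cal=3.9, tm=316.4, noise_sd=noise_sd,
                      seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# generators

def _roster_for(spec: MeltSimSpec) -> List[Tuple[str, ProtonID]]:
    """Assign proton identities to the spec's classes.

    When the class structure matches the packaged hairpin roster the real
    residue/atom labels are used; otherwise synthetic labels res i / H i.
    """
    by_label: Dict[str, List[ProtonID]] = {}
    for label, resnum, rtype, atom in HPLW_PROTON_ROSTER:
        by_label.setdefault(label, []).append(ProtonID(resnum, atom, rtype))
    out: List[Tuple[str, ProtonID]] = []
    counter = 1
    for c in spec.classes:
        pool = by_label.get(c.label, [])
        if len(pool) == c.n_protons:
            out.extend((c.label, p) for p in pool)
        else:
            for _ in range(c.n_protons):
                out.append((c.label, ProtonID(counter, "H1", "X")))
                counter += 1
    return out


def generate_melt_series(spec: MeltSimSpec) -> Tuple[List[MeltSeries], pd.DataFrame]:
    """Draw a melting dataset and its ground-truth parameter table.

    For each proton, Tm is drawn from its class Gaussian, the plateau
    amplitudes and the baseline slope from the spec's ranges; the sigmoid is
    evaluated on the grid and i.i.d. Gaussian noise added.  Identical seeds
    give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.temperatures
    series: List[MeltSeries] = []
    truth_rows = []
    for label, proton in _roster_for(spec):
        cls = next(c for c in spec.classes if c.label == label)
        x0 = rng.normal(cls.tm_mean, cls.tm_sd)
        amp = rng.uniform(*spec.amplitude_range) * rng.choice([-1.0, 1.0])
        base = _base_shift(proton.atom_name)
        a1 = base
        a2 = base + amp
        b = rng.uniform(*spec.baseline_slope_range)
        clean = boltzmann_sigmoid(T, a1, a2, b, x0, spec.dx)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=T.shape) \
            if spec.noise_sd > 0 else clean
        series.append(MeltSeries(proton, T, noisy))
        truth_rows.append(
            dict(residue_number=proton.residue_number, residue_type=proton.residue_type,
                 atom_name=proton.atom_name, class_label=label,
                 A1=a1, A2=a2, B=b, x0=x0, dx=spec.dx, noise_sd=spec.noise_sd)
        )
    return series, pd.DataFrame(truth_rows)


def two_state_excess_cp(T: np.ndarray, dh_vh: float, dh_cal: float, tm: float) -> np.ndarray:
    """Noiseless van't Hoff excess heat capacity (kJ·mol⁻¹·K⁻¹)."""
    T = np.asarray(T, dtype=float)
    lnK = -(dh_vh / R_KJ) * (1.0 / T - 1.0 / tm)
    # K/(1+K)^2 written via logistic for numerical stability at large |lnK|
    f = 1.0 / (1.0 + np.exp(-lnK))
    return dh_cal * (dh_vh / (R_KJ * T**2)) * f * (1.0 - f)


def generate_dsc_thermogram(spec: DSCSimSpec) -> Tuple[DSCThermogram, Dict[str, float]]:
    """Draw a DSC thermogram plus its ground-truth parameter record."""
    rng = np.random.default_rng(spec.seed)
    T = spec.temperatures
    exc = two_state_excess_cp(T, spec.dh_vh, spec.dh_cal, spec.tm)
    cp = exc + spec.baseline_intercept + spec.baseline_slope * T
    if spec.noise_sd > 0:
        cp = cp + rng.normal(0.0, spec.noise_sd, size=T.shape)
    truth = dict(dh_vh=spec.dh_vh, dh_cal=spec.dh_cal, tm=spec.tm,
                 baseline_intercept=spec.baseline_intercept,
                 baseline_slope=spec.baseline_slope,
                 r_vh=spec.dh_vh / spec.dh_cal if spec.dh_cal > 0 else np.inf,
                 peak_height=spec.dh_cal * spec.dh_vh / (4 * R_KJ * spec.tm**2))
    return DSCThermogram(T, cp, scan_rate=1.0), truth


def generate_relaxation_decays(
    rates: Dict[int, float],
    delays: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    i0: float = 1.0,
    kind: str = "R1",
) -> List[IntensityTable]:
    """Mono-exponential decays I0·exp(-R·t) + noise, one table per residue."""
    t = np.asarray(delays, dtype=float)
    if t.size == 0:
        raise ValueError("delays must be non-empty")
    if np.any(t < 0):
        raise ValueError("negative relaxation delay")
    rng = np.random.default_rng(seed)
    out = []
    for resnum in sorted(rates):
        r = rates[resnum]
        if r < 0:
            raise ValueError(f"residue {resnum}: rate must be >= 0")
        I = i0 * np.exp(-r * t)
        if noise_sd > 0:
            I = I + rng.normal(0.0, noise_sd, size=t.shape)
        out.append(IntensityTable(resnum, t, I, kind))
    return out


def generate_noe_pairs(
    ratios: Dict[int, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    i0: float = 1.0,
) -> List[Tuple[IntensityTable, IntensityTable]]:
    """Saturated/unsaturated intensity pairs (ratio·I0, I0) per residue."""
    rng = np.random.default_rng(seed)
    out = []
    for resnum in sorted(ratios):
        sat = ratios[resnum] * i0
        unsat = i0
        if noise_sd > 0:
            sat += rng.normal(0.0, noise_sd)
            unsat += rng.normal(0.0, noise_sd)
        out.append((
            IntensityTable(resnum, [0.0], [sat], "NOE_sat"),
            IntensityTable(resnum, [0.0], [unsat], "NOE_unsat"),
        ))
    return out


def melt_series_to_frame(series: Sequence[MeltSeries]) -> pd.DataFrame:
    """Long-format table in the layout :func:`hairpinmelt.io.read_shift_table` reads."""
    rows = []
    for s in series:
        for T, d in zip(s.temperatures, s.shifts):
            rows.append(dict(temperature=T, residue_number=s.proton.residue_number,
                             residue_type=s.proton.residue_type,
                             atom_name=s.proton.atom_name, shift=d))
    return pd.DataFrame(rows)
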