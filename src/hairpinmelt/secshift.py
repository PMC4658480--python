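"""Secondary Hα chemical shifts against random-coil references.

ΔδHα = δ_obs − δ_random-coil per residue and temperature.  Sustained
positive deviations (≥ +0.1 ppm) mark β-strand, negative (≤ −0.1 ppm)
helix, the rest coil.  The default reference table is the random-coil Hα
set of Wishart, Bigam, Holm, Hodges & Sykes (1995) J. Biomol. NMR 5, 67-81
(1H shifts of X in GGXAGG at pH 5, 25 °C); any residue-type → shift mapping
may be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RANDOM_COIL_HA",
    "SecondaryShiftProfile",
    "delta_halpha",
    "compare_profiles",
    "classify_delta",
]

#: Wishart et al. (1995) random-coil Hα shifts, ppm, one-letter codes.
RANDOM_COIL_HA: Dict[str, float] = {
    "A": 4.32, "C": 4.55, "D": 4.64, "E": 4.35, "F": 4.62,
    "G": 3.96, "H": 4.73, "I": 4.17, "K": 4.32, "L": 4.34,
    "M": 4.48, "N": 4.74, "P": 4.42, "Q": 4.34, "R": 4.34,
    "S": 4.47, "T": 4.35, "V": 4.12, "W": 4.66, "Y": 4.55,
}

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y",
}

#: classification threshold, ppm (symmetric about zero)
DEFAULT_THRESHOLD = 0.1


def _one_letter(residue_type: str) -> str:
    rt = residue_type.strip().upper()
    if len(rt) == 1:
        return rt
    return _THREE_TO_ONE.get(rt, rt)


def classify_delta(delta: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    if delta >= threshold:
        return "strand"
    if delta <= -threshold:
        return "helix"
    return "coil"


@dataclass(frozen=True)
class SecondaryShiftProfile:
    """Per-residue ΔδHα (ppm) and structure class at each temperature.

    ``delta`` and ``classes`` are DataFrames indexed by residue number with
    one column per temperature (K).
    """

    delta: pd.DataFrame
    classes: pd.DataFrame
    threshold: float = DEFAULT_THRESHOLD

    def residues_in_class(self, cls: str, temperature: float) -> list:
        col = self.classes[temperature]
        return list(col.index[col == cls])


def delta_halpha(
    assignments: pd.DataFrame,
    reference_set: Optional[Mapping[str, float]] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> SecondaryShiftProfile:
    """Secondary Hα shifts from an assignment table.

    Parameters
    ----------
    assignments : DataFrame
        Columns ``residue_number, residue_type, temperature, shift``
        (one Hα observation per residue per temperature).
    reference_set : mapping, optional
        residue type (one- or three-letter) → random-coil Hα shift (ppm);
        defaults to :data:`RANDOM_COIL_HA`.
    threshold : float
        Class boundary in ppm, symmetric about zero.

    Raises
    ------
    KeyError
        If a residue type is absent from the reference set.
    """
    ref = dict(RANDOM_COIL_HA if reference_set is None else reference_set)
    ref = {_one_letter(k): v for k, v in ref.items()}
    required = ["residue_number", "residue_type", "temperature", "shift"]
    missing = [c for c in required if c not in assignments.columns]
    if missing:
        raise ValueError(f"assignment table missing column(s) {missing}")
    df = assignments.copy()
    df["one"] = df["residue_type"].map(_one_letter)
    unknown = df.loc[~df["one"].isin(ref), ["residue_number", "residue_type"]]
    if len(unknown):
        r = unknown.iloc[0]
        raise KeyError(
            f"residue {int(r['residue_number'])} ({r['residue_type']}) has no "
            "random-coil reference value"
        )
    df["delta"] = df["shift"] - df["one"].map(ref)
    delta = df.pivot_table(index="residue_number", columns="temperature",
                           values="delta")
    classes = delta.map(lambda d: classify_delta(d, threshold) if np.isfinite(d)
                        else "undefined")
    return SecondaryShiftProfile(delta, classes, threshold)


def compare_profiles(profile_a: SecondaryShiftProfile,
                     profile_b: SecondaryShiftProfile) -> pd.DataFrame:
    """Per-residue ΔΔδ table (A − B) with class-change bookkeeping.

    Profiles must share residue numbering; only shared residues/temperatures
    are compared.  Returns a long-format table with columns
    ``residue_number, temperature, ddelta, class_a, class_b, changed``.
    ``compare_profiles(A, B).ddelta == -compare_profiles(B, A).ddelta``.
    """
    residues = profile_a.delta.index.intersection(profile_b.delta.index)
    temps = profile_a.delta.columns.intersection(profile_b.delta.columns)
    if len(residues) == 0:
        raise ValueError("profiles share no residue numbers")
    rows = []
    for res in residues:
        for t in temps:
            da = profile_a.delta.loc[res, t]
            db = profile_b.delta.loc[res, t]
            ca = profile_a.classes.loc[res, t]
            cb = profile_b.classes.loc[res, t]
            rows.append(dict(residue_number=res, temperature=t, ddelta=da - db,
                             class_a=ca, class_b=cb, changed=ca != cb))
    return pd.DataFrame(rows)
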