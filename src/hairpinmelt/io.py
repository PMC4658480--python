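"""Delimited-text readers/writers and structured JSON reports.

All tabular inputs are comma- or tab-separated with a mandatory header
(no positional columns).  Temperatures are stored in kelvin internally;
degrees Celsius are accepted only behind an explicit flag.  Reports are a
single JSON document per run carrying every fitted parameter plus
provenance (input checksum, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .types import DSCThermogram, IntensityTable, MeltSeries, ProtonID

__all__ = [
    "read_shift_table",
    "read_dsc_trace",
    "read_intensity_table",
    "write_report",
    "read_report",
    "load_config",
    "file_checksum",
]

SHIFT_COLUMNS = ["temperature", "residue_number", "residue_type", "atom_name", "shift"]

PathLike = Union[str, Path]


def _read_table(path: PathLike, dialect: Optional[str] = None) -> pd.DataFrame:
    """Read a delimited table, sniffing comma vs tab when not told."""
    sep = {"csv": ",", "tsv": "\t", None: None}.get(dialect, dialect)
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                       skip_blank_lines=True, comment="#")


def read_shift_table(path: PathLike, dialect: Optional[str] = None) -> List[MeltSeries]:
    """Read a per-proton chemical-shift melting table.

    The file must carry the columns ``temperature, residue_number,
    residue_type, atom_name, shift``.  Returns one :class:`MeltSeries` per
    unique proton, rows sorted by temperature.  A header-only file yields an
    empty list; duplicated (temperature, proton) rows and non-numeric shifts
    are hard errors.
    """
    df = _read_table(path, dialect)
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return []
    for col in ("temperature", "shift"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing {col} value "
                f"{df.loc[bad[0], col]!r} at data row {bad[0] + 1}"
            )
        df[col] = vals
    dup = df.duplicated(subset=["temperature", "residue_number", "atom_name"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate row for T={row['temperature']} K, "
            f"residue {row['residue_number']}, atom {row['atom_name']}"
        )
    out: List[MeltSeries] = []
    keys = df[["residue_number", "atom_name"]].drop_duplicates()
    for _, (resnum, atom) in keys.iterrows():
        sub = df[(df["residue_number"] == resnum) & (df["atom_name"] == atom)]
        sub = sub.sort_values("temperature")
        proton = ProtonID(int(resnum), str(atom), str(sub["residue_type"].iloc[0]))
        out.append(MeltSeries(proton, sub["temperature"].to_numpy(),
                              sub["shift"].to_numpy()))
    # deterministic order regardless of input row order
    out.sort(key=lambda s: (s.proton.residue_number, s.proton.atom_name))
    return out


def read_dsc_trace(
    path: PathLike,
    *,
    dialect: Optional[str] = None,
    celsius: bool = False,
    scan_rate: Optional[float] = None,
    concentration: Optional[float] = None,
    reference_path: Optional[PathLike] = None,
) -> DSCThermogram:
    """Read a two-column temperature / heat-capacity trace.

    Columns are taken as the first two numeric columns (header names are
    free).  ``celsius=True`` converts the temperature axis with x + 273.15.
    A second file may be attached as a buffer-buffer reference scan.
    """
    df = _read_table(path, dialect)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need two columns (temperature, heat capacity)")
    T = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    cp = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    if celsius:
        T = T + 273.15
    order = np.argsort(T, kind="stable")
    T, cp = T[order], cp[order]
    if np.any(np.diff(T) <= 0):
        i = int(np.argmin(np.diff(T)))
        raise ValueError(f"{path}: duplicated temperature {T[i]:.6g} K after sorting")
    reference = None
    if reference_path is not None:
        reference = read_dsc_trace(reference_path, dialect=dialect, celsius=celsius)
    return DSCThermogram(T, cp, scan_rate=scan_rate, concentration=concentration,
                         reference=reference)


def read_intensity_table(path: PathLike, dialect: Optional[str] = None) -> List[IntensityTable]:
    """Read per-residue relaxation intensities.

    Required columns: ``residue_number, delay, intensity, experiment_kind``.
    Returns one table per (residue, experiment) pair, delays sorted.
    """
    df = _read_table(path, dialect)
    required = ["residue_number", "delay", "intensity", "experiment_kind"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out: List[IntensityTable] = []
    for (resnum, kind), sub in df.groupby(["residue_number", "experiment_kind"], sort=True):
        sub = sub.sort_values("delay")
        out.append(IntensityTable(int(resnum), sub["delay"].to_numpy(dtype=float),
                                  sub["intensity"].to_numpy(dtype=float), str(kind)))
    return out


# ---------------------------------------------------------------------------
# reports

def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        d["__type__"] = type(obj).__name__
        return d
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(results: Any, path: PathLike, *, seed: Optional[int] = None,
                 input_path: Optional[PathLike] = None,
                 extra: Optional[Dict[str, Any]] = None) -> Dict[str, Any]:
    """Serialise any stage result to a round-trippable JSON report.

    The report embeds provenance: the package version, the seed used (if
    any) and a SHA-256 checksum of the input file (if any).  Returns the
    document written.
    """
    from . import __version__

    doc: Dict[str, Any] = {
        "provenance": {
            "package": "hairpinmelt",
            "version": __version__,
            "seed": seed,
            "input": str(input_path) if input_path else None,
            "input_sha256": file_checksum(input_path) if input_path else None,
        },
        "results": _jsonable(results),
    }
    if extra:
        doc.update(_jsonable(extra))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return doc


def read_report(path: PathLike) -> Dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


def file_checksum(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: PathLike) -> Dict[str, Any]:
    """Load a YAML/JSON key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
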