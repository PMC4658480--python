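"""End-to-end orchestration: validated config, staged runs, synthesis report.

A :class:`PipelineConfig` selects which stages run (melt → landscape, DSC,
secondary shifts, relaxation), each driven either by input files or by a
simulation spec — never both.  Reports are JSON, stamped with the seed and
package version; a synthesis section combines the stage outputs into the
folding-pathway statement (ordered events, DSC cooperativity verdict, and
their mutual consistency) without recomputing any number.
"""

from __future__ import annotations

import fnmatch
import logging
from pathlib import Path
from typing import Any, Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io as hio
from . import simulate as sim
from .dsc import DSCAnalysis
from .landscape import TmLandscape, folding_sequence, group_tms
from .meltfit import FilterCriteria, filter_fits, fit_melt_curve
from .relaxation import fit_rate, het_noe
from .secshift import delta_halpha
from .types import ProtonID

__all__ = ["PipelineConfig", "ClassRule", "build_class_map", "run_pipeline"]

logger = logging.getLogger(__name__)


class ClassRule(BaseModel):
    """One class-map rule: residue list/range + atom glob → label."""

    residues: str            # e.g. "3-6,12,14"
    atoms: str = "*"         # fnmatch pattern, e.g. "H*", "HE?"
    label: str

    def residue_set(self) -> set:
        out: set = set()
        for part in self.residues.split(","):
            part = part.strip()
            if "-" in part:
                lo, hi = part.split("-")
                out.update(range(int(lo), int(hi) + 1))
            elif part:
                out.add(int(part))
        return out

    def matches(self, proton: ProtonID) -> bool:
        return (proton.residue_number in self.residue_set()
                and fnmatch.fnmatch(proton.atom_name, self.atoms))


def build_class_map(rules: Sequence[ClassRule]):
    """First-matching-rule class map usable by :func:`group_tms`."""

    def lookup(proton: ProtonID) -> Optional[str]:
        for rule in rules:
            if rule.matches(proton):
                return rule.label
        return None

    return lookup


class MeltStage(BaseModel):
    input: Optional[str] = None
    simulate: Optional[Literal["default", "mutant"]] = None
    noise_sd: float = 0.005
    class_rules: List[ClassRule] = Field(default_factory=list)
    unmapped: Literal["error", "other", "drop"] = "error"
    min_amplitude_to_noise: float = 5.0
    min_rsquared: float = 0.9
    k_max: int = 4

    @model_validator(mode="after")
    def _one_source(self) -> "MeltStage":
        if (self.input is None) == (self.simulate is None):
            raise ValueError("melt stage needs exactly one of input / simulate")
        return self


class DSCStage(BaseModel):
    input: Optional[str] = None
    reference: Optional[str] = None
    simulate: Optional[Dict[str, float]] = None   # dh_vh, dh_cal, tm, ...
    celsius: bool = False
    onset: Optional[float] = None
    offset: Optional[float] = None

    @model_validator(mode="after")
    def _one_source(self) -> "DSCStage":
        if (self.input is None) == (self.simulate is None):
            raise ValueError("dsc stage needs exactly one of input / simulate")
        return self


class SecShiftStage(BaseModel):
    input: str
    threshold: float = 0.1


class RelaxStage(BaseModel):
    input: str


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML/JSON on disk)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    output_dir: str = "hairpinmelt_out"
    melt: Optional[MeltStage] = None
    dsc: Optional[DSCStage] = None
    secshift: Optional[SecShiftStage] = None
    relax: Optional[RelaxStage] = None

    @model_validator(mode="after")
    def _any_stage(self) -> "PipelineConfig":
        if not any([self.melt, self.dsc, self.secshift, self.relax]):
            raise ValueError("configuration enables no stages")
        return self

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.model_validate(hio.load_config(path))


# ---------------------------------------------------------------------------

def _run_melt(cfg: MeltStage, seed: int, outdir: Path) -> Dict[str, Any]:
    if cfg.simulate is not None:
        spec = (sim.default_melt_spec if cfg.simulate == "default"
                else sim.mutant_melt_spec)(noise_sd=cfg.noise_sd, seed=seed)
        series, truth = sim.generate_melt_series(spec)
        sim.melt_series_to_frame(series).to_csv(outdir / "melt_input.csv", index=False)
        truth.to_csv(outdir / "melt_truth.csv", index=False)
        class_map = {
            ProtonID(int(r.residue_number), r.atom_name, r.residue_type): r.class_label
            for r in truth.itertuples()
        }
        lookup = class_map.get
    else:
        series = hio.read_shift_table(cfg.input)
        lookup = build_class_map(cfg.class_rules)
    fits = [fit_melt_curve(s) for s in series]
    criteria = FilterCriteria(cfg.min_amplitude_to_noise, cfg.min_rsquared)
    accepted, rejected = filter_fits(fits, criteria)
    result = TmLandscape(accepted, lookup, unmapped=cfg.unmapped).fit(
        k_max=cfg.k_max, seed=seed)
    report = {
        "n_curves": len(fits),
        "n_accepted": len(accepted),
        "rejections": [{"proton": str(r.fit.proton), "reason": r.reason}
                       for r in rejected],
        "tm_table": [{"proton": str(f.proton), "tm": f.tm, "tm_err": f.tm_err,
                      "rsquared": f.rsquared} for f in accepted],
        "events": [{"label": e.label, "mean_tm": e.mean_tm, "sd_tm": e.sd_tm,
                    "n": e.n, "shapiro_p": e.shapiro_p,
                    "qq_correlation": e.qq_correlation} for e in result.events],
        "folding_order": result.sequence.order(),
        "separations": [{"delta": d, "combined_sd": c, "flag": f}
                        for d, c, f in result.sequence.separations],
        "k_selected": result.k_selected,
        "components": [{"mean": m, "sd": s, "weight": w}
                       for m, s, w in result.components],
    }
    hio.write_report(report, outdir / "melt_report.json", seed=seed,
                     input_path=cfg.input)
    return report


def _run_dsc(cfg: DSCStage, seed: int, outdir: Path) -> Dict[str, Any]:
    if cfg.simulate is not None:
        spec = sim.DSCSimSpec(seed=seed, **cfg.simulate)
        thermo, _ = sim.generate_dsc_thermogram(spec)
        reference = None
    else:
        thermo = hio.read_dsc_trace(cfg.input, celsius=cfg.celsius,
                                    reference_path=cfg.reference)
        reference = thermo.reference
    res = DSCAnalysis(thermo, reference, cfg.onset, cfg.offset).fit()
    np.savetxt(outdir / "dsc_excess.csv",
               np.column_stack([res.excess.temperatures, res.excess.cp_exc]),
               delimiter=",", header="temperature,cp_exc", comments="")
    report = {
        "tm": res.tm, "dcp_at_tm": res.dcp_at_tm, "dh_cal": res.dh_cal,
        "dh_vh": res.dh_vh, "r_vh": res.r_vh, "verdict": res.verdict,
        "onset": res.excess.onset, "offset": res.excess.offset,
        "t_half": res.enthalpy_fit.t_half if res.enthalpy_fit else None,
        "enthalpy_fit_width": res.enthalpy_fit.width if res.enthalpy_fit else None,
    }
    hio.write_report(report, outdir / "dsc_report.json", seed=seed,
                     input_path=cfg.input)
    return report


def _run_secshift(cfg: SecShiftStage, seed: int, outdir: Path) -> Dict[str, Any]:
    import pandas as pd

    df = pd.read_csv(cfg.input, sep=None, engine="python")
    profile = delta_halpha(df, threshold=cfg.threshold)
    profile.delta.to_csv(outdir / "secshift_delta.csv")
    profile.classes.to_csv(outdir / "secshift_classes.csv")
    report = {
        "n_residues": int(profile.delta.shape[0]),
        "temperatures": [float(t) for t in profile.delta.columns],
        "strand_residues": {
            str(t): profile.residues_in_class("strand", t)
            for t in profile.classes.columns
        },
    }
    hio.write_report(report, outdir / "secshift_report.json", seed=seed,
                     input_path=cfg.input)
    return report


def _run_relax(cfg: RelaxStage, seed: int, outdir: Path) -> Dict[str, Any]:
    tables = hio.read_intensity_table(cfg.input)
    fits = []
    noe_parts: Dict[int, Dict[str, float]] = {}
    for t in tables:
        if t.experiment_kind in ("R1", "R2"):
            fits.append(fit_rate(t))
        else:
            key = "sat" if t.experiment_kind == "NOE_sat" else "unsat"
            noe_parts.setdefault(t.residue_number, {})[key] = float(t.intensities[0])
    for resnum, parts in sorted(noe_parts.items()):
        if {"sat", "unsat"} <= parts.keys():
            fits.append(het_noe(parts["sat"], parts["unsat"], resnum))
    report = {"fits": [{"residue_number": f.residue_number, "kind": f.kind,
                        "value": f.value, "uncertainty": f.uncertainty,
                        "i0": f.i0} for f in fits]}
    hio.write_report(report, outdir / "relax_report.json", seed=seed,
                     input_path=cfg.input)
    return report


def _synthesis(melt: Optional[Dict], dsc: Optional[Dict]) -> Dict[str, Any]:
    """Combine stage outputs; every number is copied from a stage report."""
    out: Dict[str, Any] = {}
    if melt:
        out["folding_order"] = melt["folding_order"]
        out["n_events"] = len(melt["events"])
    if dsc:
        out["dsc_verdict"] = dsc["verdict"]
        out["r_vh"] = dsc["r_vh"]
    if melt and dsc:
        multi_event = len(melt["events"]) > 1
        broad = dsc["verdict"] != "two-state"
        out["consistent"] = multi_event == broad
        out["statement"] = (
            "multi-event Tm landscape and non-two-state DSC ratio agree"
            if (multi_event and broad) else
            "single-event landscape and two-state DSC ratio agree"
            if (not multi_event and not broad) else
            "landscape and DSC cooperativity disagree; inspect stage reports"
        )
    return out


def run_pipeline(config: PipelineConfig) -> Dict[str, Any]:
    """Run every enabled stage; returns the combined report bundle.

    Deterministic for a fixed seed.  A stage failure propagates after the
    preceding stages' reports are already on disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: Dict[str, Any] = {"seed": config.seed}
    melt_report = dsc_report = None
    if config.melt:
        logger.info("stage melt")
        melt_report = _run_melt(config.melt, config.seed, outdir)
        bundle["melt"] = melt_report
    if config.dsc:
        logger.info("stage dsc")
        dsc_report = _run_dsc(config.dsc, config.seed, outdir)
        bundle["dsc"] = dsc_report
    if config.secshift:
        logger.info("stage secshift")
        bundle["secshift"] = _run_secshift(config.secshift, config.seed, outdir)
    if config.relax:
        logger.info("stage relax")
        bundle["relax"] = _run_relax(config.relax, config.seed, outdir)
    bundle["synthesis"] = _synthesis(melt_report, dsc_report)
    hio.write_report(bundle, outdir / "pipeline_report.json", seed=config.seed)
    return bundle
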