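"""One-command orchestration: reduce -> fit -> oscillator -> transition report.

``run_analysis`` drives the full elastic-scan analysis for one or two samples
(e.g. wild type vs mutant): empty-cell subtraction, reference normalisation,
temperature binning, summed-intensity transition detection, Gaussian and/or
bimodal MSD extraction, low-temperature Einstein-oscillator fits, and — for a
pair of samples — per-temperature MSD differences with propagated errors.

Every output table carries the analysis conventions (MSD scale, timescale
convention, cross-section table version) and a run manifest records inputs
and parameter values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import composition as comp_mod
from .composition import CROSS_SECTION_TABLE_VERSION
from .fitting import (
    MSD_CONVENTION,
    MSDSeries,
    fit_oscillator,
    msd_vs_temperature,
)
from .instruments import InstrumentProfile, builtin_profile, observable_timescale
from .reduction import (
    bin_by_temperature,
    detect_slope_changes,
    normalize_to_reference,
    read_scan,
    subtract_empty_cell,
    summed_intensity,
)

logger = logging.getLogger("einscan")

__all__ = ["RunConfig", "run_analysis"]


@dataclass
class RunConfig:
    """Configuration of one analysis run (flags and config file share fields)."""

    instrument: str
    scans: List[str]
    labels: Optional[List[str]] = None
    empty_cell: Optional[str] = None
    transmission: float = 0.95
    reference_temperature: float = 20.0
    bin_width: float = 5.0
    models: Tuple[str, ...] = ("gaussian", "bimodal")
    fractions: Tuple[float, float] = (0.26, 0.74)
    fasta: Optional[str] = None  # if set, fractions are recomputed from sequence
    hydration: float = 0.28
    out_dir: str = "einscan-out"
    seed: int = 0
    max_breakpoints: int = 2
    transition_t_min: float = 100.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        if not self.scans:
            raise ValueError("at least one scan file is required")
        for p in self.scans:
            if not Path(p).exists():
                raise FileNotFoundError(f"scan file not found: {p}")
        if self.empty_cell and not Path(self.empty_cell).exists():
            raise FileNotFoundError(f"empty-cell file not found: {self.empty_cell}")
        if not all(0 < f < 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1)")
        for m in self.models:
            if m not in ("gaussian", "bimodal"):
                raise ValueError(f"unknown model {m!r}")


def _analyse_one(
    path: str,
    label: str,
    profile: InstrumentProfile,
    cfg: RunConfig,
) -> dict:
    raw = read_scan(path)
    applied = ["read_scan"]
    if cfg.empty_cell:
        empty = read_scan(cfg.empty_cell)
        raw = subtract_empty_cell(raw, empty, transmission=cfg.transmission)
        applied.append(f"subtract_empty_cell(transmission={cfg.transmission})")
    scan = normalize_to_reference(raw, cfg.reference_temperature)
    applied.append(f"normalize_to_reference({cfg.reference_temperature} K)")
    scan = bin_by_temperature(scan, cfg.bin_width)
    applied.append(f"bin_by_temperature({cfg.bin_width} K)")

    ser = summed_intensity(scan, profile.summed_intensity_q_window)
    transitions = detect_slope_changes(
        ser, max_breakpoints=cfg.max_breakpoints, t_min=cfg.transition_t_min
    )

    series: Dict[str, MSDSeries] = {}
    oscillators: Dict[str, dict] = {}
    for model in cfg.models:
        for s in msd_vs_temperature(
            scan, profile, model=model, fractions=cfg.fractions
        ):
            series[s.model] = s
            try:
                osc = fit_oscillator(
                    s,
                    profile.oscillator_fit_t_max,
                    reference_temperature=cfg.reference_temperature,
                )
                oscillators[s.model] = asdict(osc)
            except ValueError as exc:
                oscillators[s.model] = {"error": str(exc)}
    logger.info("analysed %s (%s): %s", label, profile.name, "; ".join(applied))
    return {
        "label": label,
        "scan": scan,
        "summed": ser,
        "transitions": transitions,
        "series": series,
        "oscillators": oscillators,
        "corrections": applied,
    }


def _difference_series(a: MSDSeries, b: MSDSeries) -> pd.DataFrame:
    """Per-temperature MSD difference (a - b) with errors in quadrature."""
    if not np.allclose(a.temperatures, b.temperatures):
        raise ValueError("samples are on different temperature grids")
    return pd.DataFrame(
        {
            "temperature_K": a.temperatures,
            "msd_difference_A2": a.msd - b.msd,
            "difference_error_A2": np.hypot(a.msd_error, b.msd_error),
            "model": a.model,
        }
    )


def run_analysis(config: RunConfig) -> dict:
    """Run the full pipeline; write CSV/JSON bundle to ``config.out_dir``.

    Returns the in-memory report bundle (results keyed by sample label, plus
    ``differences`` when two samples are given).
    """
    config.validate()
    profile = builtin_profile(config.instrument)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fractions = config.fractions
    comp_report = None
    if config.fasta:
        seq = comp_mod.read_sequence(config.fasta)
        classes = comp_mod.classify_hydrogens(seq)
        fractions = (round(classes.a1, 2), round(classes.a2, 2))
        comp = comp_mod.count_atoms(seq)
        budget = comp_mod.scattering_budget(
            comp, classes, hydration=config.hydration, ligand=comp_mod.PALMITATE
        )
        comp_report = {
            "n_residues": len(seq),
            "hydrogen_fraction_of_atoms": comp.hydrogen_fraction,
            "a1_methyl": classes.a1,
            "a2_nonmethyl": 1 - classes.a1,
            "solvent_incoherent_share": budget.solvent_incoherent_share,
            "coherent_share": budget.coherent_share,
            "ligand_h_share": budget.ligand_h_share,
        }
        config = RunConfig(**{**asdict(config), "fractions": fractions})

    labels = config.labels or [Path(p).stem for p in config.scans]
    results = [
        _analyse_one(p, lab, profile, config)
        for p, lab in zip(config.scans, labels)
    ]

    conventions = {
        "msd_convention": MSD_CONVENTION,
        "timescale_convention": "t = hbar / deltaE (FWHM)",
        "observable_timescale_ps": observable_timescale(profile),
        "cross_section_table": CROSS_SECTION_TABLE_VERSION,
    }

    bundle: dict = {
        "instrument": profile.to_dict(),
        "conventions": conventions,
        "composition": comp_report,
        "samples": {},
    }
    for res in results:
        lab = res["label"]
        frames = [s.to_frame() for s in res["series"].values()]
        msd_table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        msd_table.to_csv(out / f"msd_{lab}.csv", index=False)
        pd.DataFrame(
            {
                "temperature_K": res["summed"].temperatures,
                "summed_intensity": res["summed"].values,
                "error": res["summed"].errors,
            }
        ).to_csv(out / f"summed_{lab}.csv", index=False)
        bundle["samples"][lab] = {
            "oscillators": res["oscillators"],
            "transitions": res["transitions"].to_dict(),
            "corrections": res["corrections"],
        }

    diff_table = None
    if len(results) == 2:
        diffs = []
        common = set(results[0]["series"]) & set(results[1]["series"])
        for key in sorted(common):
            diffs.append(
                _difference_series(results[0]["series"][key], results[1]["series"][key])
            )
        if diffs:
            diff_table = pd.concat(diffs, ignore_index=True)
            diff_table.to_csv(out / "msd_difference.csv", index=False)
            bundle["differences"] = {
                "order": f"{labels[0]} - {labels[1]}",
                "table": "msd_difference.csv",
            }

    manifest = {k: v for k, v in asdict(config).items()}
    manifest["conventions"] = conventions
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=str)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    # attach non-serialised objects for programmatic use
    bundle["series"] = {res["label"]: res["series"] for res in results}
    bundle["difference_table"] = diff_table
    return bundle
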