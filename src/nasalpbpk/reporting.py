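"""Pipeline orchestration: run a configured population simulation, write
summary tables, per-subject NCA and a reproducibility manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__, reference
from .model import Regimen
from .physiology import build_physiology
from .population import DEFAULT_SEED, PopulationSpec, PopulationResult, popsim, summarize

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """A single simulation scenario.

    ``regimen`` is either ``single`` (one dose, 72 h follow-up) or ``bid``
    (twice daily for seven days with a single final-day dose).
    """

    population: Literal["US", "CN"] = "US"
    route: Literal["intranasal", "oral"] = "intranasal"
    dose_mg: float = 0.06
    regimen: Literal["single", "bid"] = "single"
    n_subjects: int = 300
    cv: float = 0.38
    seed: int = DEFAULT_SEED
    output_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be > 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.population not in ("US", "CN"):
            raise ValueError("population must be US or CN")
        if self.regimen not in ("single", "bid"):
            raise ValueError("regimen must be single or bid")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ReportBundle:
    config: RunConfig
    result: PopulationResult
    systemic_summary: pd.DataFrame
    nasal_summary: pd.DataFrame
    output_dir: Path


def build_regimen(config: RunConfig) -> Regimen:
    dose_ng = config.dose_mg * 1e6
    if config.regimen == "single":
        return Regimen.single_dose(dose_ng, route=config.route)
    return Regimen.bid(dose_ng, route=config.route)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute simulate/popsim/NCA for a scenario and write the report files.

    Writes: ``systemic_summary.csv`` / ``nasal_summary.csv`` (mean, SD, CV%
    per NCA parameter — the published table layout), ``nca_systemic.csv`` /
    ``nca_nasal.csv`` per subject, ``profiles.csv`` (time, conc, subject)
    for spaghetti plots, ``manifest.json`` and ``run.log``.
    """
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phys = build_physiology()
    typ = reference.SYSTEMIC_BY_POPULATION[config.population]
    frac = (reference.NASAL_DEPOSITION if config.route == "intranasal"
            else reference.ORAL_DEPOSITION)
    regimen = build_regimen(config)
    spec = PopulationSpec(n=config.n_subjects, cv_CL=config.cv,
                          cv_Vc=config.cv, seed=config.seed)
    result = popsim(typ, spec, phys, frac, regimen,
                    nca_dose=config.dose_mg * 1e6)
    t_sim = time.time()

    systemic = summarize(result.ncas)
    nasal = summarize(result.nasal_ncas)
    systemic.to_csv(out_dir / "systemic_summary.csv")
    nasal.to_csv(out_dir / "nasal_summary.csv")
    result.nca_frame("systemic").to_csv(out_dir / "nca_systemic.csv", index=False)
    result.nca_frame("nasal").to_csv(out_dir / "nca_nasal.csv", index=False)

    profiles = pd.concat([
        pd.DataFrame({"time_h": result.grid, "conc_ng_ml": sim.C_plasma,
                      "nasal_conc_ng_ml": sim.C_nasal, "subject": i + 1})
        for i, sim in enumerate(result.simulations)
    ], ignore_index=True)
    profiles.to_csv(out_dir / "profiles.csv", index=False)

    manifest = {
        "package": "nasalpbpk", "version": __version__,
        "config": asdict(config),
        "physiology": phys.to_flat_dict(),
        "systemic_typical": {"tlag": typ.tlag, "ka": typ.ka,
                             "Vc": typ.Vc, "CL": typ.CL},
        "deposition": {"F1": frac.F1, "F2": frac.F2, "F3": frac.F3,
                       "F4": frac.F4, "F5": frac.F5},
        "seed": config.seed,
        "n_dose_events": len(regimen.events),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with open(out_dir / "run.log", "w") as fh:
        fh.write(f"simulate+nca: {t_sim - t0:.2f} s\n")
        fh.write(f"summaries+io: {time.time() - t_sim:.2f} s\n")
    return ReportBundle(config=config, result=result,
                        systemic_summary=systemic, nasal_summary=nasal,
                        output_dir=out_dir)


def compare_populations(bundle_a: ReportBundle, bundle_b: ReportBundle
                        ) -> pd.DataFrame:
    """Elementwise mean-parameter ratios (b / a), systemic and nasal.

    Both bundles must share route, dose and regimen (matched scenarios).
    """
    ca, cb = bundle_a.config, bundle_b.config
    if (ca.route, ca.dose_mg, ca.regimen) != (cb.route, cb.dose_mg, cb.regimen):
        raise ValueError("bundles have mismatched regimens")
    rows = {}
    for which in ("systemic", "nasal"):
        sa = getattr(bundle_a, f"{which}_summary")["mean"]
        sb = getattr(bundle_b, f"{which}_summary")["mean"]
        common = sa.index.intersection(sb.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[which] = sb[common] / sa[common]
    out = pd.DataFrame(rows)
    out.index.name = "parameter"
    return out
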