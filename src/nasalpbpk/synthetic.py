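"""Synthetic observed-like concentration–time datasets.

The clinical mean profiles behind the reference fits are published only as
figures, so recovery studies and end-to-end tests run on emulated data:
the model's true mean profile on the clinical sampling grid, perturbed by
mean-one multiplicative lognormal error (optionally plus additive Gaussian
error) and censored below the assay LLOQ to zero — the convention of the
source studies, where sub-LLOQ values enter arithmetic means as 0.

Defaults: 10% proportional error, no additive error, LLOQ 0.05 ng/mL.
The true LLOQ of the reference assay is unpublished; 0.05 ng/mL is a
plausible bioanalytical placeholder and is flagged in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import ObservedSeries
from .model import (DepositionFractions, DoseEvent, Regimen, SystemicParams,
                    default_grid, simulate)
from .physiology import PhysiologyConstants, build_physiology
from . import reference


@dataclass(frozen=True)
class NoiseSpec:
    proportional_sd: float = 0.10
    additive_sd: float = 0.0  # ng/mL
    lloq: float = 0.05  # ng/mL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_sd < 0 or self.additive_sd < 0 or self.lloq < 0:
            raise ValueError("noise magnitudes and lloq must be >= 0")


def generate_observed(phys: PhysiologyConstants, sys: SystemicParams,
                      frac: DepositionFractions, regimen: Regimen,
                      grid: Sequence[float] | None = None,
                      noise: NoiseSpec = NoiseSpec(),
                      label: str = "synthetic") -> ObservedSeries:
    """Simulate the true plasma profile, add error, censor below LLOQ.

    Multiplicative error is lognormal with mean 1 (mu = -sigma^2/2,
    sigma^2 = ln(1+sd^2)) so that averaging replicates is unbiased; the
    time-0 pre-dose sample is dropped (assay baseline).
    """
    grid = default_grid(regimen) if grid is None else np.asarray(grid, float)
    sim = simulate(phys, sys, frac, regimen, grid)
    keep = grid > 0
    times = grid[keep]
    true = sim.C_plasma[keep]
    rng = np.random.default_rng(noise.seed)
    values = true.copy()
    if noise.proportional_sd > 0:
        sigma2 = np.log(1.0 + noise.proportional_sd ** 2)
        values = values * rng.lognormal(mean=-sigma2 / 2.0,
                                        sigma=np.sqrt(sigma2), size=len(values))
    if noise.additive_sd > 0:
        values = values + rng.normal(0.0, noise.additive_sd, size=len(values))
    values = np.clip(values, 0.0, None)
    values[values < noise.lloq] = 0.0
    dose = sum(ev.amount for ev in regimen.events)
    route = regimen.events[0].route if regimen.events else "oral"
    return ObservedSeries(
        label=label, times=tuple(times), conc=tuple(values),
        lloq=noise.lloq, dose=dose, route=route,
        meta={
            "truth": {"tlag": sys.tlag, "ka": sys.ka, "Vc": sys.Vc, "CL": sys.CL,
                      "F1": frac.F1, "F2": frac.F2},
            "noise": {"proportional_sd": noise.proportional_sd,
                      "additive_sd": noise.additive_sd,
                      "lloq": noise.lloq, "lloq_is_placeholder": True,
                      "seed": noise.seed},
        })


def generate_fit_suite(seed: int = 0, noise: NoiseSpec | None = None,
                       phys: PhysiologyConstants | None = None
                       ) -> dict[str, ObservedSeries]:
    """The three canonical estimation datasets.

    ``us_oral`` (1 mg tablet, American parameters), ``cn_oral`` (1 mg,
    Chinese parameters) and ``us_intranasal`` (0.12 mg spray, American
    systemic parameters with the reference deposition fractions).  Each
    series carries its generating truth in ``meta['truth']``.
    """
    phys = phys or build_physiology()
    base = noise or NoiseSpec()
    out: dict[str, ObservedSeries] = {}
    configs = [
        ("us_oral", reference.US_SYSTEMIC, reference.ORAL_DEPOSITION,
         Regimen.single_dose(reference.ORAL_DOSE_NG, route="oral")),
        ("cn_oral", reference.CN_SYSTEMIC, reference.ORAL_DEPOSITION,
         Regimen.single_dose(reference.ORAL_DOSE_NG, route="oral")),
        ("us_intranasal", reference.US_SYSTEMIC, reference.NASAL_DEPOSITION,
         Regimen.single_dose(reference.NASAL_SINGLE_DOSE_NG, route="intranasal")),
    ]
    for i, (label, sys, frac, regimen) in enumerate(configs):
        spec = NoiseSpec(proportional_sd=base.proportional_sd,
                         additive_sd=base.additive_sd, lloq=base.lloq,
                         seed=seed * 1000 + i)
        out[label] = generate_observed(phys, sys, frac, regimen,
                                       noise=spec, label=label)
    return out


def write_series(series: ObservedSeries, csv_path: str | Path,
                 meta_path: str | Path | None = None) -> None:
    """Write the tidy CSV (time_h, conc_ng_ml) plus a metadata YAML."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_h": series.times, "conc_ng_ml": series.conc}
                 ).to_csv(csv_path, index=False)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".yaml")
    meta = {"label": series.label, "dose_mg": series.dose / 1e6,
            "route": series.route, "lloq_ng_ml": series.lloq,
            **{k: v for k, v in series.meta.items()}}
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))


def read_series(csv_path: str | Path, meta_path: str | Path | None = None
                ) -> ObservedSeries:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".yaml")
    meta = yaml.safe_load(meta_path.read_text())
    return ObservedSeries(
        label=meta.get("label", csv_path.stem),
        times=tuple(df["time_h"]), conc=tuple(df["conc_ng_ml"]),
        lloq=float(meta["lloq_ng_ml"]), dose=float(meta["dose_mg"]) * 1e6,
        route=meta["route"],
        meta={k: v for k, v in meta.items()
              if k not in ("label", "dose_mg", "route", "lloq_ng_ml")})
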