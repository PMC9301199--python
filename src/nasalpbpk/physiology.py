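"""Fixed physiological and permeability parameters of the respiratory tract.

The respiratory tract is split into four absorbing segments — nasal cavity
(``Nose``), bronchi (``BB``), bronchioles (``bb``) and alveoli (``AL``) —
each with an epithelial lining fluid (ELF) layer sitting on a mucosal
tissue layer.  Drug deposited in ELF permeates into tissue and from tissue
into the central circulation; the diffusional conductance of each barrier
is a permeability–surface-area product ``PS_x = Peff * S_x``.

The effective in-vivo permeability of the drug is not measured directly;
it is scaled from a reference compound with a known airway ``Peff``
(budesonide) through the ratio of Caco-2 apparent permeabilities::

    Peff_drug = Peff_ref * Papp_drug / Papp_ref

Internal units throughout the package: amount ng, volume mL, time h,
concentration ng/mL, clearance mL/h, permeability cm/s (converted at the
PS step).  Literature values quoted in L or L/h are converted x1000 at
load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import yaml

SEGMENTS = ("Nose", "BB", "bb", "AL")

#: cm/s * m^2 -> mL/h  (1e4 cm^2 per m^2, 3600 s per h, 1 cm^3 = 1 mL)
_CM_S_M2_TO_ML_H = 1.0e4 * 3600.0


class PhysiologyError(ValueError):
    """Invalid physiological parameter or derivation input."""


@dataclass(frozen=True)
class Geometry:
    """Respiratory surface areas and nasal layer thicknesses (SI units).

    S_* are segment surface areas in m^2; H_Nose is the nasal ELF (mucus)
    thickness and D_Nose the nasal mucosal tissue thickness, both in m.
    """

    S_Nose: float = 0.0246
    H_Nose: float = 1.0e-6
    D_Nose: float = 1.15e-4
    S_BB: float = 0.75
    S_bb: float = 0.75
    S_AL: float = 140.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise PhysiologyError(f"Geometry.{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class PermeabilityInputs:
    """Caco-2 Papp of drug and reference, plus the reference airway Peff (cm/s)."""

    Papp_drug: float = 26.145e-6
    Papp_ref: float = 11.4e-6
    Peff_ref: float = 2.228e-6

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise PhysiologyError(
                    f"PermeabilityInputs.{name} must be > 0, got {value!r}"
                )


def scale_peff(inputs: PermeabilityInputs) -> float:
    """Effective airway permeability of the drug, cm/s.

    Scales the reference compound's in-vivo Peff by the ratio of in-vitro
    Caco-2 apparent permeabilities.
    """
    return inputs.Peff_ref * inputs.Papp_drug / inputs.Papp_ref


def ps_from_peff(peff_cm_s: float, surface_m2: float) -> float:
    """Permeability–surface product in mL/h from Peff (cm/s) and area (m^2)."""
    if peff_cm_s < 0 or surface_m2 < 0:
        raise PhysiologyError("peff and surface must be non-negative")
    return peff_cm_s * surface_m2 * _CM_S_M2_TO_ML_H


def derive_nasal_volumes(geometry: Geometry) -> tuple[float, float]:
    """Nasal ELF and tissue volumes (mL) as area x layer thickness.

    Returns ``(V_Nose_ELF, V_Nose_tissue)``.  Note the shipped default
    constants keep the literature value for V_Nose_ELF (2.459e-4 L), which
    exceeds this direct geometric product tenfold; see
    :func:`build_physiology`.
    """
    m3_to_ml = 1.0e6
    return (
        geometry.S_Nose * geometry.H_Nose * m3_to_ml,
        geometry.S_Nose * geometry.D_Nose * m3_to_ml,
    )


@dataclass(frozen=True)
class PhysiologyConstants:
    """Assembled fixed parameters (ng/mL/h unit system).

    Fractions are dimensionless in [0, 1]; ``kmcc_*`` are mucociliary
    clearance rate constants (1/h) moving ELF contents mouthward
    (bb -> BB -> pharynx -> swallowed); volumes in mL; PS in mL/h.
    """

    FA: float = 0.9
    fu_ELF: float = 1.0
    fu_tissue: float = 1.0
    fu_p: float = 0.8
    kmcc_bb: float = 0.083
    kmcc_BB: float = 0.417
    V_ELF: Mapping[str, float] = field(
        default_factory=lambda: {"Nose": 0.2459, "BB": 2.1, "bb": 2.1, "AL": 20.8}
    )
    V_tissue: Mapping[str, float] = field(
        default_factory=lambda: {"Nose": 2.828, "BB": 38.0, "bb": 38.0, "AL": 381.0}
    )
    PS: Mapping[str, float] = field(
        default_factory=lambda: {"Nose": 4.5, "BB": 138.0, "bb": 138.0, "AL": 25728.0}
    )
    Peff: float = 5.110e-6

    def __post_init__(self) -> None:
        for name in ("FA", "fu_ELF", "fu_tissue", "fu_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhysiologyError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("kmcc_bb", "kmcc_BB", "Peff"):
            if getattr(self, name) < 0:
                raise PhysiologyError(f"{name} must be >= 0")
        for name in ("V_ELF", "V_tissue", "PS"):
            mapping = getattr(self, name)
            if set(mapping) != set(SEGMENTS):
                raise PhysiologyError(
                    f"{name} keys must be exactly {set(SEGMENTS)}, got {set(mapping)}"
                )
            for seg, v in mapping.items():
                if v < 0:
                    raise PhysiologyError(f"{name}[{seg}] must be >= 0, got {v!r}")
            object.__setattr__(self, name, dict(mapping))

    # -- serialization -----------------------------------------------------

    def to_flat_dict(self) -> dict[str, float]:
        """Flatten to scalar fields (``V_ELF_Nose`` style keys)."""
        out: dict[str, float] = {
            "FA": self.FA,
            "fu_ELF": self.fu_ELF,
            "fu_tissue": self.fu_tissue,
            "fu_p": self.fu_p,
            "kmcc_bb": self.kmcc_bb,
            "kmcc_BB": self.kmcc_BB,
            "Peff": self.Peff,
        }
        for seg in SEGMENTS:
            out[f"V_ELF_{seg}"] = self.V_ELF[seg]
            out[f"V_tissue_{seg}"] = self.V_tissue[seg]
            out[f"PS_{seg}"] = self.PS[seg]
        return out

    @classmethod
    def from_flat_dict(cls, data: Mapping[str, float]) -> "PhysiologyConstants":
        kwargs: dict = {
            k: data[k]
            for k in ("FA", "fu_ELF", "fu_tissue", "fu_p", "kmcc_bb", "kmcc_BB", "Peff")
            if k in data
        }
        for group in ("V_ELF", "V_tissue", "PS"):
            keys = [f"{group}_{seg}" for seg in SEGMENTS]
            if any(k in data for k in keys):
                kwargs[group] = {seg: data[f"{group}_{seg}"] for seg in SEGMENTS}
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        flat = self.to_flat_dict()
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(flat, sort_keys=False))
        else:
            path.write_text(json.dumps(flat, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "PhysiologyConstants":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_flat_dict(data)


def build_physiology(
    geometry: Geometry | None = None,
    perm: PermeabilityInputs | None = None,
    overrides: Mapping[str, object] | None = None,
) -> PhysiologyConstants:
    """Assemble the full fixed-parameter set.

    Reference-sourced fields take their literature defaults; Peff is scaled
    from the permeability inputs and each segment PS computed as
    ``Peff * S``; the nasal tissue volume is the geometric product
    ``S_Nose * D_Nose``.  The nasal ELF volume keeps the literature default
    (2.459e-4 L) rather than the geometric product ``S_Nose * H_Nose``
    (which is tenfold smaller); downstream reference results were produced
    with the literature value.  ``overrides`` (field name -> value, nested
    mappings allowed for V_ELF/V_tissue/PS) are applied last and validated.
    """
    geometry = geometry or Geometry()
    perm = perm or PermeabilityInputs()
    peff = scale_peff(perm)
    _, v_nose_tissue = derive_nasal_volumes(geometry)
    base = PhysiologyConstants()
    ps = {
        "Nose": ps_from_peff(peff, geometry.S_Nose),
        "BB": ps_from_peff(peff, geometry.S_BB),
        "bb": ps_from_peff(peff, geometry.S_bb),
        "AL": ps_from_peff(peff, geometry.S_AL),
    }
    v_tissue = dict(base.V_tissue)
    v_tissue["Nose"] = v_nose_tissue
    result = replace(base, Peff=peff, PS=ps, V_tissue=v_tissue)
    if overrides:
        fields: dict = {}
        for key, value in overrides.items():
            if not hasattr(result, key):
                raise PhysiologyError(f"unknown physiology field {key!r}")
            if key in ("V_ELF", "V_tissue", "PS"):
                merged = dict(getattr(result, key))
                merged.update(value)  # type: ignore[arg-type]
                fields[key] = merged
            else:
                fields[key] = value
        result = replace(result, **fields)
    return result
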