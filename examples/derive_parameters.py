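"""Derive the fixed respiratory-tract parameters.

Builds the full physiological parameter set from the nasal geometry and
the Caco-2 permeability scaling, and prints it as a flat table.  The PS
values are diffusional clearances (Peff x surface area): note how the
huge alveolar surface (140 m^2) dwarfs the nasal one (0.0246 m^2).
"""

import pandas as pd

from nasalpbpk import build_physiology

phys = build_physiology()
table = pd.DataFrame(sorted(phys.to_flat_dict().items()),
                     columns=["parameter", "value"])
print(table.to_string(index=False))
print(f"\nEffective permeability {phys.Peff:.4g} cm/s scaled from the "
      "budesonide airway reference via the Caco-2 Papp ratio.")
print("PS (mL/h):", {k: round(v, 3) for k, v in phys.PS.items()})
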