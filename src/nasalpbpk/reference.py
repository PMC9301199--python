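"""Published reference parameter sets for varenicline.

Systemic disposition parameters were estimated from mean oral
concentration–time profiles (1 mg tablet) in American and Chinese adults;
deposition fractions from the mean plasma profile after a 0.12 mg nasal
spray in Americans.  They serve as the typical-subject values for
simulation and as ground truth for synthetic-data recovery studies.
"""

from __future__ import annotations

from .model import MG_TO_NG, DepositionFractions, Regimen, SystemicParams

#: oral disposition, American adults (tlag h, ka 1/h, Vc mL, CL mL/h)
US_SYSTEMIC = SystemicParams(tlag=0.371, ka=1.036, Vc=194352.0, CL=10001.0)

#: oral disposition, Chinese adults
CN_SYSTEMIC = SystemicParams(tlag=0.156, ka=1.064, Vc=190823.0, CL=11320.0)

#: nasal-spray deposition: 54.7% to absorbing nasal mucosa, a vanishing
#: pharyngeal (swallowed) fraction, nothing below the pharynx (spray
#: droplets are far larger than the ~10 um cut-off for lower-airway
#: penetration); the remainder lands on the non-absorbing vestibule.
NASAL_DEPOSITION = DepositionFractions(F1=0.547, F2=7.6375e-7)

#: oral dosing always routes everything to the GI depot
ORAL_DEPOSITION = DepositionFractions(F1=0.0, F2=0.0)

ORAL_DOSE_NG = 1.0 * MG_TO_NG          # 1 mg tablet
NASAL_SINGLE_DOSE_NG = 0.12 * MG_TO_NG  # 0.12 mg spray (PK study)
NASAL_LABEL_DOSE_NG = 0.06 * MG_TO_NG   # 0.06 mg per delivery, BID (label)

SYSTEMIC_BY_POPULATION = {"US": US_SYSTEMIC, "CN": CN_SYSTEMIC}


def labelled_bid_regimen(n_days: int = 7) -> Regimen:
    """0.06 mg intranasal BID for ``n_days`` with a single final-day dose."""
    return Regimen.bid(NASAL_LABEL_DOSE_NG, route="intranasal", n_days=n_days)
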