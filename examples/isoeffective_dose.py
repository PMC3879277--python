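"""Dose-rate dependence of deterministic effects: pneumonitis vs bone marrow.

Derives domain lethalities from each endpoint's alpha/beta ratio
(pneumonitis 3 Gy, bone marrow syndrome 8 Gy, both with eps_i = 0.00333
and the median fast-repair half-life of 0.5 h) and compares the
mechanistic isoeffective dose -- the protracted dose matching the survival
of the acute D50 -- with the empirical inverse-dose-rate D50 law used in
radiation protection.
"""

import numpy as np

from globlekin import (
    BONE_MARROW,
    PNEUMONITIS,
    GlobleParameters,
    empirical_d50,
    globle_from_lq,
    isoeffective_dose,
)

endpoints = {
    "pneumonitis": (PNEUMONITIS, 3.0, 10.0),
    "bone marrow": (BONE_MARROW, 8.0, 3.0),
}

for name, (law, alpha_beta, ref_dose) in endpoints.items():
    eps_i, eps_c = globle_from_lq(0.1, 0.1 / alpha_beta)
    params = GlobleParameters(eps_i=eps_i, eps_c=eps_c, hlt_i=0.5)
    print(f"\n{name}: alpha/beta = {alpha_beta} Gy -> eps_c = {eps_c:.3f}; "
          f"acute D50 = {ref_dose} Gy")
    print("rate_Gy/h   D_iso_Gy  D50_empirical_Gy")
    for rate in [100.0, 30.0, 10.0, 3.0, 1.0]:
        d_iso = isoeffective_dose(rate, ref_dose, params)
        d50 = empirical_d50(rate, law)
        print(f"{rate:9.1f}  {d_iso:9.2f}  {d50:16.2f}")

print(
    "\nFor pneumonitis the mechanistic prediction tracks the empirical law "
    "down to ~3 Gy/h;\nbelow that the empirical D50 diverges while the "
    "isoeffective dose converges to the\nfinite value set by the purely "
    "linear low-dose-rate survival curve."
)
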