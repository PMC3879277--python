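"""Correspondence with the LQ model extended by the Lea-Catcheside factor.

For a hypothetical cell line with alpha/beta = 1 Gy, compares the
Lea-Catcheside protraction factor G(r, T) with its mechanistic equivalent:
the second-order Taylor coefficient of -ln S at D = 0, normalized by the
static beta.  The two agree closely wherever the quadratic term matters;
the relative deviation blows up only at long protraction, where both
factors are already near zero (the kinetic model keeps a small finite
second moment while the LQ one vanishes).
"""

import numpy as np

from globlekin import GlobleParameters, compare_g_factors, lq_from_globle

params = GlobleParameters(eps_i=0.00083, eps_c=0.17, hlt_i=0.5)
lq = lq_from_globle(params)
print(
    f"alpha = {lq.alpha:.4f}/Gy, beta = {lq.beta:.4f}/Gy^2 "
    f"(alpha/beta = {lq.alpha / lq.beta:.2f} Gy), r = ln2/{params.hlt_i} h"
)

table = compare_g_factors(params, np.logspace(-2, 2, 9))
print("\n   T_h        G    g_equiv  rel_dev")
for row in table.itertuples():
    print(f"{row.T_h:7.2f}  {row.G:7.4f}  {row.g_equiv:7.4f}  {row.rel_dev:+8.2%}")

print(
    "\ng_equiv is the kinetic model's protraction factor; agreement within a "
    "few percent\nfor G >= 0.05 shows the model reduces to LQ + Lea-Catcheside "
    "up to second order in dose."
)
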