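"""Calibration round trip on a synthetic clonogenic dataset.

Generates a noisy dose-rate experiment (4 dose rates x 10 doses,
sigma_lnS = 0.15) from known parameters and recovers them by seeded
differential evolution on the log-survival least-squares objective.
"""

import numpy as np

from globlekin import (
    GlobleParameters,
    NoiseModel,
    fit_parameters,
    generate_constant_rate_dataset,
)

truth = GlobleParameters(eps_i=0.005, eps_c=0.2, hlt_i=0.5)
data = generate_constant_rate_dataset(
    truth,
    dose_rates=[90.0, 4.56, 0.96, 0.29],
    doses=np.arange(1, 11),
    noise=NoiseModel(sigma_ln_s=0.15, seed=42),
)
print(f"dataset: {len(data)} observations, sigma_lnS = 0.15")

result = fit_parameters(data, seed=0)
print(f"converged: {result.converged}, SSR = {result.ssr:.4f}, "
      f"{result.n_evaluations} objective evaluations\n")
print("param     truth    fitted   rel_err")
for key in ("eps_i", "eps_c", "hlt_i"):
    t, f = getattr(truth, key), getattr(result.params, key)
    print(f"{key:6s}  {t:8.4f}  {f:8.4f}  {f / t - 1:+7.1%}")

print(
    "\nWith realistic clonogenic scatter the three parameters come back "
    "within ~10-25%;\non noise-free data the recovery is exact to optimizer "
    "precision."
)
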