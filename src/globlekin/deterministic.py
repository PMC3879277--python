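"""Dose-rate dependence of deterministic radiation effects.

Clinically, the dose D50 at which half of exposed persons develop a
deterministic effect (pneumonitis, bone marrow syndrome, ...) rises as the
dose rate drops.  An empirical radiation-protection rule writes this as a
linear function of the inverse dose rate,

    D50(rate) = d50_acute + slope / rate,

with endpoint-specific constants (pneumonitis: 10 Gy and 30 Gy^2/h; bone
marrow syndrome: 3 Gy and 0.07 Gy^2/h).  Because cell killing drives these
endpoints, the GLOBLE offers a mechanistic counterpart: the *isoeffective
dose*, the protracted dose producing the same cell survival as an acute
reference dose.  The dose-rate effect predicted this way depends only on
the lethality ratio eps_i/eps_c (hence on the endpoint's alpha/beta ratio)
and on the repair half-life, not on the absolute lethalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kinetics import (
    constant_rate_neg_log_survival,
    low_rate_limit_neg_log_survival,
)
from .parameters import GlobleParameters
from .static import acute_survival

__all__ = ["D50Model", "empirical_d50", "isoeffective_dose", "PNEUMONITIS", "BONE_MARROW"]


@dataclass(frozen=True)
class D50Model:
    """Empirical inverse-dose-rate law for a deterministic endpoint."""

    d50_acute: float  # Gy; D50 after acute exposure
    slope: float  # Gy^2/h; extent of the dose-rate effect

    def __post_init__(self) -> None:
        if self.d50_acute < 0 or self.slope < 0:
            raise ValueError("d50_acute and slope must be >= 0")


PNEUMONITIS = D50Model(d50_acute=10.0, slope=30.0)
BONE_MARROW = D50Model(d50_acute=3.0, slope=0.07)


def empirical_d50(dose_rate, model: D50Model):
    """Empirical D50 at a given dose rate (Gy/h); diverges as rate -> 0."""
    dose_rate = np.asarray(dose_rate, dtype=float)
    if np.any(dose_rate <= 0):
        raise ValueError(
            "dose_rate must be positive: the empirical law diverges at zero rate"
        )
    d = model.d50_acute + model.slope / dose_rate
    return float(d) if d.ndim == 0 else d


def isoeffective_dose(
    dose_rate: float,
    reference_dose: float,
    params: GlobleParameters,
    dose_tol: float = 1e-4,
    max_dose_factor: float = 1e6,
) -> float:
    """Protracted dose matching the survival of an acute reference dose.

    Solves constant_rate_survival(D, rate) = acute_survival(reference_dose)
    for D by bracketed root finding on the strictly decreasing map
    D -> ln S.  The result is always >= reference_dose (protraction spares).

    Raises ``ValueError`` when the target survival is unreachable at this
    dose rate, i.e. the protracted -ln S saturates below the acute target —
    the low-dose-rate asymptote is reported in the message.
    """
    if dose_rate <= 0:
        raise ValueError(f"dose_rate must be positive, got {dose_rate}")
    if reference_dose < 0:
        raise ValueError(f"reference_dose must be >= 0, got {reference_dose}")
    if reference_dose == 0:
        return 0.0
    target = -np.log(acute_survival(reference_dose, params))

    def f(dose: float) -> float:
        return float(constant_rate_neg_log_survival(dose, dose_rate, params)) - target

    lo = reference_dose
    if f(lo) >= 0:  # acute limit: the reference dose itself already matches
        return lo
    hi = 2.0 * reference_dose
    while f(hi) < 0:
        hi *= 2.0
        if hi > max_dose_factor * reference_dose:
            asymptote = float(
                low_rate_limit_neg_log_survival(hi, dose_rate, params)
            )
            raise ValueError(
                f"isoeffect target -ln S = {target:.4g} not bracketed below "
                f"{hi:.3g} Gy at {dose_rate} Gy/h; the low-dose-rate "
                f"asymptote reaches only -ln S = {asymptote:.4g}"
            )
    return float(brentq(f, lo, hi, xtol=dose_tol))
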