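"""Static GLOBLE model: survival after acute (instantaneous) photon doses.

For an acute dose D the DSB count per giant-loop domain is Poisson with
mean lambda = dsb_yield * D / n_domains.  Domains with exactly one DSB carry
an isolated DSB, domains with two or more carry a clustered DSB.  Survival
is the Poisson zero-class probability of lethal events,

    S(D) = exp(-eps_i * n_i - eps_c * n_c),

with n_i = N_L * lambda * exp(-lambda) and
n_c = N_L * (1 - exp(-lambda) - lambda * exp(-lambda)).

A second-order Taylor expansion of -ln S at D = 0 gives the mapping to the
linear-quadratic (LQ) model:

    alpha = eps_i * alpha_DSB
    beta  = alpha_DSB^2 / (2 N_L) * (eps_c - 2 eps_i)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import GlobleParameters, LQParameters

__all__ = [
    "LesionCounts",
    "lambda_per_domain",
    "class_probabilities",
    "expected_lesion_counts",
    "acute_survival",
    "lq_from_globle",
    "globle_from_lq",
]


@dataclass(frozen=True)
class LesionCounts:
    """Expected per-cell lesion numbers after an acute dose.

    ``n_i``/``n_c`` are expected numbers of isolated/clustered DSB domains;
    ``l_i``/``l_c`` the expected lethal events they generate; ``total`` their sum.
    """

    n_i: float
    n_c: float
    l_i: float
    l_c: float

    @property
    def total(self) -> float:
        return self.l_i + self.l_c


def _check_dose(dose) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError(f"dose must be non-negative, got {dose}")
    return dose


def lambda_per_domain(dose, params: GlobleParameters):
    """Mean number of DSBs per domain after an acute dose (Gy)."""
    dose = _check_dose(dose)
    lam = params.dsb_yield * dose / params.n_domains
    return lam if lam.ndim else float(lam)


def class_probabilities(lam):
    """Poisson probabilities (p0, p1, p_multi) for 0, 1 and >=2 DSBs per domain.

    ``p_multi`` is computed as 1 - p0 - p1 so the three probabilities sum to
    one exactly.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError(f"lambda must be non-negative, got {lam}")
    p0 = np.exp(-lam)
    p1 = lam * p0
    p_multi = 1.0 - (p0 + p1)
    if lam.ndim:
        return p0, p1, p_multi
    return float(p0), float(p1), float(p_multi)


def expected_lesion_counts(dose: float, params: GlobleParameters) -> LesionCounts:
    """Expected isolated/clustered DSB domains and lethal events per cell."""
    lam = lambda_per_domain(dose, params)
    p0, p1, pm = class_probabilities(lam)
    n_i = params.n_domains * p1
    n_c = params.n_domains * pm
    return LesionCounts(n_i=n_i, n_c=n_c, l_i=params.eps_i * n_i, l_c=params.eps_c * n_c)


def acute_survival(dose, params: GlobleParameters):
    """Surviving fraction after an acute dose delivered instantaneously."""
    lam = lambda_per_domain(dose, params)
    p0 = np.exp(-lam)
    p1 = lam * p0
    pm = 1.0 - p0 - p1
    neg_log_s = params.n_domains * (params.eps_i * p1 + params.eps_c * pm)
    s = np.exp(-neg_log_s)
    return s if np.ndim(dose) else float(s)


def lq_from_globle(params: GlobleParameters) -> LQParameters:
    """LQ coefficients equivalent to the GLOBLE parameters at D -> 0.

    Isolated DSBs carry the initial linear slope (alpha); both classes enter
    the quadratic term.  The restitution rate is identified with the total
    processing rate of isolated DSBs, r = ln 2 / hlt_i.
    """
    alpha = params.eps_i * params.dsb_yield
    beta = params.dsb_yield**2 / (2.0 * params.n_domains) * (
        params.eps_c - 2.0 * params.eps_i
    )
    return LQParameters(alpha=alpha, beta=beta, repair_rate=np.log(2.0) / params.hlt_i)


def globle_from_lq(
    alpha: float,
    beta: float,
    n_domains: float = 3000.0,
    dsb_yield: float = 30.0,
) -> tuple[float, float]:
    """Invert the LQ mapping: (alpha, beta) -> (eps_i, eps_c).

    Raises ``ValueError`` if either lethality falls outside [0, 1] — the
    given LQ pair is then not representable with the chosen structural
    constants.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    eps_i = alpha / dsb_yield
    eps_c = 2.0 * eps_i + 2.0 * n_domains * beta / dsb_yield**2
    if not 0.0 <= eps_i <= 1.0:
        raise ValueError(f"derived eps_i = {eps_i} outside [0, 1]")
    if not 0.0 <= eps_c <= 1.0:
        raise ValueError(f"derived eps_c = {eps_c} outside [0, 1]")
    return eps_i, eps_c
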