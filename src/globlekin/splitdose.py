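"""Closed-form survival for two-fraction split-dose experiments.

Two acute fractions d1 and d2 (classically equal, d1 = d2 = d) are
separated by a repair gap t1.  The first fraction distributes the N_L
domains Poisson-wise over (no DSB | isolated | clustered).  During the gap
each damage class decays single-exponentially with its total processing
rate k_x = ln 2 / hlt_x, a share eps_x of the processed damage turning
lethal.  The second fraction redistributes the surviving non-lethal domains
with the same Poisson weights, and all damage present afterwards is
processed to completion.  The expected total number of lethal events L
gives S = exp(-L).

Two limits pin the algebra: at t1 = 0 the result equals the acute survival
at d1 + d2 exactly, and as t1 -> inf it approaches
-ln S = L1 + (1 - L1/N_L) L2 with L1, L2 the single-fraction lethal-event
numbers (full sublethal-damage recovery; only the overlap of lethal domains
is shared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import GlobleParameters
from .static import class_probabilities, lambda_per_domain

__all__ = ["SplitDoseState", "state_after_first_fraction", "split_dose_survival"]


@dataclass(frozen=True)
class SplitDoseState:
    """Expected domain counts in a split-dose bookkeeping step.

    ``n0``/``ni``/``nc`` count domains without DSB / with an isolated DSB /
    with a clustered DSB; ``li_gap``/``lc_gap`` count domains that turned
    lethal during the repair gap.
    """

    n0: float
    ni: float
    nc: float
    li_gap: float = 0.0
    lc_gap: float = 0.0


def state_after_first_fraction(d: float, params: GlobleParameters) -> SplitDoseState:
    """Domain counts immediately after the first acute fraction."""
    lam = lambda_per_domain(d, params)
    p0, p1, pm = class_probabilities(lam)
    N = params.n_domains
    return SplitDoseState(n0=N * p0, ni=N * p1, nc=N * pm)


def split_dose_survival(
    d: float,
    t1: float,
    params: GlobleParameters,
    d2: float | None = None,
) -> float:
    """Surviving fraction after two acute fractions separated by ``t1`` hours.

    Parameters
    ----------
    d : float
        First (and by default second) fraction dose in Gy.
    t1 : float
        Repair gap between the fractions in hours.
    params : GlobleParameters
        Cell-line parameters.
    d2 : float, optional
        Unequal second fraction dose; defaults to ``d``.
    """
    if t1 < 0:
        raise ValueError(f"gap t1 must be >= 0 h, got {t1}")
    d2 = d if d2 is None else d2

    after_first = state_after_first_fraction(d, params)
    N = params.n_domains
    k_i = np.log(2.0) / params.hlt_i
    k_c = np.log(2.0) / params.hlt_c

    # repair during the gap: exponential decay of each class; a share eps_x
    # of the processed damage ends lethal
    decay_i = np.exp(-k_i * t1)
    decay_c = np.exp(-k_c * t1)
    ni_pre = after_first.ni * decay_i
    nc_pre = after_first.nc * decay_c
    li_gap = params.eps_i * after_first.ni * (1.0 - decay_i)
    lc_gap = params.eps_c * after_first.nc * (1.0 - decay_c)
    # lethal domains are excluded from the pool the second fraction can hit
    n0_pre = N - ni_pre - nc_pre - li_gap - lc_gap

    # second fraction: Poisson redistribution of the non-lethal domains
    p0, p1, pm = class_probabilities(lambda_per_domain(d2, params))
    ni_post = n0_pre * p1 + ni_pre * p0
    nc_post = n0_pre * pm + ni_pre * (1.0 - p0) + nc_pre

    total_lethal = (
        li_gap + lc_gap + params.eps_i * ni_post + params.eps_c * nc_post
    )
    return float(np.exp(-total_lethal))
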