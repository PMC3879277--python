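"""Kinetic GLOBLE: five-level dynamics of DSB induction and repair.

During irradiation, giant-loop domains move between five levels tracked as
population-averaged fractions:

* ``f0`` — no DSB and no lethal event,
* ``fi`` — one unprocessed DSB (isolated),
* ``fc`` — two or more unprocessed DSBs (clustered),
* ``li`` — lethal event(s) from processing an isolated DSB (absorbing),
* ``lc`` — lethal event(s) from processing a clustered DSB (absorbing).

With per-domain DSB induction rate d' = dsb_yield * dose_rate / n_domains
and first-order processing rates k_x = ln 2 / hlt_x split into viable repair
(r_x = (1 - eps_x) k_x, back to f0) and lethal misrepair (m_x = eps_x k_x,
into l_x), the coupled system reads

    f0' = -d' f0 + r_i fi + r_c fc
    fi' =  d' f0 - d' fi - k_i fi
    fc' =  d' fi - k_c fc
    li' =  m_i fi
    lc' =  m_c fc

There is no fc -> fi transition: a clustered DSB cannot revert to an
isolated one.  The system is linear with piecewise-constant coefficients,
so each constant-rate segment is propagated exactly by a matrix
exponential; instantaneous pulses are applied as an exact Poisson
redistribution of the non-lethal levels.  Survival after the schedule ends
is obtained from the closure at infinite time,

    li(inf) = li(T) + eps_i fi(T),   lc(inf) = lc(T) + eps_c fc(T),
    S = exp(-N_L * (li(inf) + lc(inf))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .parameters import GlobleParameters
from .schedules import IrradiationSchedule, Pulse, Segment
from .static import class_probabilities

__all__ = [
    "LevelState",
    "TransitionRates",
    "transition_rates",
    "induction_rate",
    "rate_matrix",
    "apply_pulse",
    "evolve_schedule",
    "evolve_trajectory",
    "survival_after_schedule",
    "constant_rate_survival",
    "constant_rate_neg_log_survival",
    "low_rate_limit_survival",
    "low_rate_limit_neg_log_survival",
]

_CONSERVATION_TOL = 1e-8


@dataclass(frozen=True)
class LevelState:
    """Occupation fractions of the five GLOBLE levels (sum to one)."""

    f0: float
    fi: float
    fc: float
    li: float
    lc: float

    @classmethod
    def pristine(cls) -> "LevelState":
        """Undamaged population: every domain on the f0 level."""
        return cls(1.0, 0.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "LevelState":
        return cls(*(float(v) for v in x))

    def as_array(self) -> np.ndarray:
        return np.array([self.f0, self.fi, self.fc, self.li, self.lc])

    def validate(self, tol: float = 1e-7) -> None:
        x = self.as_array()
        if np.any(x < -tol) or np.any(x > 1 + tol):
            raise ValueError(f"level fractions outside [0, 1]: {x}")
        if abs(x.sum() - 1.0) > max(tol, _CONSERVATION_TOL):
            raise ValueError(f"level fractions must sum to 1, got {x.sum()!r}")


@dataclass(frozen=True)
class TransitionRates:
    """First-order processing rates (per hour) for the two DSB classes.

    ``k_x = r_x + m_x`` is the total processing rate ln 2 / hlt_x;
    ``m_x = eps_x * k_x`` leads to a lethal event, ``r_x`` to viable repair.
    """

    k_i: float
    k_c: float
    r_i: float
    r_c: float
    m_i: float
    m_c: float


def transition_rates(params: GlobleParameters) -> TransitionRates:
    """Derive viable-repair and lethal-misrepair rates from half-life times."""
    k_i = np.log(2.0) / params.hlt_i
    k_c = np.log(2.0) / params.hlt_c
    return TransitionRates(
        k_i=k_i,
        k_c=k_c,
        r_i=(1.0 - params.eps_i) * k_i,
        r_c=(1.0 - params.eps_c) * k_c,
        m_i=params.eps_i * k_i,
        m_c=params.eps_c * k_c,
    )


def induction_rate(dose_rate, params: GlobleParameters):
    """Per-domain DSB induction rate d' (per hour) at a given dose rate (Gy/h)."""
    dose_rate = np.asarray(dose_rate, dtype=float)
    if np.any(dose_rate < 0):
        raise ValueError(f"dose_rate must be >= 0 Gy/h, got {dose_rate}")
    d = params.dsb_yield * dose_rate / params.n_domains
    return d if d.ndim else float(d)


def rate_matrix(dose_rate: float, params: GlobleParameters) -> np.ndarray:
    """Generator matrix A of the five-level system, x' = A x."""
    d = induction_rate(dose_rate, params)
    tr = transition_rates(params)
    return np.array(
        [
            [-d, tr.r_i, tr.r_c, 0.0, 0.0],
            [d, -(d + tr.k_i), 0.0, 0.0, 0.0],
            [0.0, d, -tr.k_c, 0.0, 0.0],
            [0.0, tr.m_i, 0.0, 0.0, 0.0],
            [0.0, 0.0, tr.m_c, 0.0, 0.0],
        ]
    )


def apply_pulse(state: np.ndarray, dose: float, params: GlobleParameters) -> np.ndarray:
    """Exact Poisson redistribution of the non-lethal levels by an acute dose.

    With per-domain mean lambda and (p0, p1, pm) = P(0), P(1), P(>=2) DSBs:
    undamaged domains split over (f0, fi, fc) with those weights; domains
    already holding an isolated DSB stay isolated with probability p0 and
    become clustered otherwise; clustered and lethal levels are unchanged
    (lethal levels are absorbing, and further DSBs cannot promote a
    clustered DSB beyond its class).
    """
    if dose < 0:
        raise ValueError(f"pulse dose must be >= 0 Gy, got {dose}")
    lam = params.dsb_yield * dose / params.n_domains
    p0, p1, pm = class_probabilities(lam)
    f0, fi, fc, li, lc = state
    return np.array(
        [f0 * p0, f0 * p1 + fi * p0, fc + f0 * pm + fi * (1.0 - p0), li, lc]
    )


def _propagate(state: np.ndarray, duration: float, dose_rate: float,
               params: GlobleParameters) -> np.ndarray:
    if duration == 0.0:
        return state
    return expm(rate_matrix(dose_rate, params) * duration) @ state


def evolve_schedule(
    schedule: IrradiationSchedule,
    params: GlobleParameters,
    initial: LevelState | None = None,
) -> LevelState:
    """State of the five levels at the end of an irradiation schedule."""
    state = (initial or LevelState.pristine())
    state.validate()
    x = state.as_array()
    for element in schedule.elements:
        if isinstance(element, Pulse):
            x = apply_pulse(x, element.dose, params)
        else:
            x = _propagate(x, element.duration, element.dose_rate, params)
    return LevelState.from_array(x)


def evolve_trajectory(
    schedule: IrradiationSchedule,
    params: GlobleParameters,
    initial: LevelState | None = None,
    points_per_segment: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Level occupations sampled along the schedule.

    Returns ``(times, states)`` with ``states[k]`` = (f0, fi, fc, li, lc) at
    ``times[k]``; each segment contributes ``points_per_segment`` interior
    samples plus its endpoint, and pulses appear as a discontinuity at a
    repeated time stamp.
    """
    state = (initial or LevelState.pristine())
    state.validate()
    x = state.as_array()
    t = 0.0
    times = [t]
    states = [x]
    for element in schedule.elements:
        if isinstance(element, Pulse):
            x = apply_pulse(x, element.dose, params)
            times.append(t)
            states.append(x)
        else:
            if element.duration == 0.0:
                continue
            A = rate_matrix(element.dose_rate, params)
            local = np.linspace(0.0, element.duration, points_per_segment + 1)[1:]
            props = expm(A[None, :, :] * local[:, None, None])
            for dt, P in zip(local, props):
                times.append(t + dt)
                states.append(P @ x)
            x = states[-1]
            t += element.duration
    return np.asarray(times), np.asarray(states)


def survival_after_schedule(
    schedule: IrradiationSchedule,
    params: GlobleParameters,
    initial: LevelState | None = None,
) -> float:
    """Surviving fraction after the schedule, damage processed to completion.

    Uses the infinite-time closure li(inf) = li + eps_i*fi,
    lc(inf) = lc + eps_c*fc; no post-exposure integration is needed.
    """
    end = evolve_schedule(schedule, params, initial)
    li_inf = end.li + params.eps_i * end.fi
    lc_inf = end.lc + params.eps_c * end.fc
    return float(np.exp(-params.n_domains * (li_inf + lc_inf)))


def constant_rate_neg_log_survival(
    doses, dose_rates, params: GlobleParameters
) -> np.ndarray:
    """-ln S for single constant-rate exposures, vectorized over observations.

    ``doses`` and ``dose_rates`` broadcast together; each pair (D, rate)
    defines a protraction time T = D / rate.  The five-level propagator
    exp(A*T) is evaluated for the whole stack at once.
    """
    doses, dose_rates = np.broadcast_arrays(
        np.asarray(doses, dtype=float), np.asarray(dose_rates, dtype=float)
    )
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if np.any(dose_rates <= 0):
        raise ValueError(
            "dose rates must be positive; use low_rate_limit_survival for the "
            "zero-rate asymptote"
        )
    shape = doses.shape
    doses = doses.ravel()
    dose_rates = dose_rates.ravel()
    T = doses / dose_rates

    d = induction_rate(dose_rates, params)
    tr = transition_rates(params)
    n = doses.size
    A = np.zeros((n, 5, 5))
    A[:, 0, 0] = -d
    A[:, 0, 1] = tr.r_i
    A[:, 0, 2] = tr.r_c
    A[:, 1, 0] = d
    A[:, 1, 1] = -(d + tr.k_i)
    A[:, 2, 1] = d
    A[:, 2, 2] = -tr.k_c
    A[:, 3, 1] = tr.m_i
    A[:, 4, 2] = tr.m_c
    P = expm(A * T[:, None, None])
    end = P[:, :, 0]  # pristine initial state selects the first column
    fi, fc, li, lc = end[:, 1], end[:, 2], end[:, 3], end[:, 4]
    neg_log_s = params.n_domains * (
        li + params.eps_i * fi + lc + params.eps_c * fc
    )
    return neg_log_s.reshape(shape)


def constant_rate_survival(dose: float, dose_rate: float,
                           params: GlobleParameters) -> float:
    """Surviving fraction after dose D delivered at a constant dose rate."""
    if np.ndim(dose) == 0 and dose == 0:
        return 1.0
    s = np.exp(-constant_rate_neg_log_survival(dose, dose_rate, params))
    return float(s) if s.ndim == 0 else s


def low_rate_limit_neg_log_survival(
    doses, dose_rates, params: GlobleParameters
) -> np.ndarray:
    """-ln S in the vanishing-dose-rate limit (no clustered DSBs form).

    At very low rates every DSB is processed before a second one can appear
    in the same domain, so the clustered pathway is eliminated and the
    system reduces to (f0, fi, li).  The reduced linear system is solved
    exactly over the protraction time and closed with
    li(inf) = li(T) + eps_i fi(T).
    """
    doses, dose_rates = np.broadcast_arrays(
        np.asarray(doses, dtype=float), np.asarray(dose_rates, dtype=float)
    )
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if np.any(dose_rates <= 0):
        raise ValueError("dose rates must be positive")
    shape = doses.shape
    doses = doses.ravel()
    dose_rates = dose_rates.ravel()
    T = doses / dose_rates

    d = induction_rate(dose_rates, params)
    tr = transition_rates(params)
    n = doses.size
    A = np.zeros((n, 3, 3))
    A[:, 0, 0] = -d
    A[:, 0, 1] = tr.r_i
    A[:, 1, 0] = d
    A[:, 1, 1] = -(d + tr.k_i)
    A[:, 2, 1] = tr.m_i
    P = expm(A * T[:, None, None])
    fi, li = P[:, 1, 0], P[:, 2, 0]
    neg_log_s = params.n_domains * (li + params.eps_i * fi)
    return neg_log_s.reshape(shape)


def low_rate_limit_survival(dose: float, dose_rate: float,
                            params: GlobleParameters) -> float:
    """Surviving fraction in the isolated-DSB-only low-dose-rate limit."""
    s = np.exp(-low_rate_limit_neg_log_survival(dose, dose_rate, params))
    return float(s) if s.ndim == 0 else s
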