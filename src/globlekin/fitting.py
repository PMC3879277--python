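"""Least-squares calibration of GLOBLE parameters on log-survival data.

A clonogenic dataset is a list of observations (irradiation schedule,
surviving fraction).  Following the established protocol, the sum of
squared residuals on ln S is minimized over the three free parameters
(eps_i, eps_c, hlt_i) with a seeded differential-evolution global search
followed by an L-BFGS-B polish; hlt_c, n_domains and dsb_yield stay fixed.
Wide box bounds (eps in [0, 1], hlt_i in [0.01, 24] h) make the global
search well posed; hits on a bound are reported in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .kinetics import constant_rate_neg_log_survival, survival_after_schedule
from .parameters import GlobleParameters
from .schedules import IrradiationSchedule
from .splitdose import split_dose_survival
from .static import acute_survival

__all__ = [
    "SurvivalObservation",
    "FitResult",
    "model_log_survival",
    "predict_log_survival",
    "ssr_objective",
    "fit_parameters",
    "DEFAULT_BOUNDS",
]

DEFAULT_BOUNDS = {"eps_i": (0.0, 1.0), "eps_c": (0.0, 1.0), "hlt_i": (0.01, 24.0)}
_PENALTY = 1e12  # SSR stand-in when the model survival is non-finite


@dataclass(frozen=True)
class SurvivalObservation:
    """One clonogenic-assay measurement: a schedule and its surviving fraction."""

    schedule: IrradiationSchedule
    surviving_fraction: float
    weight: float = 1.0
    cell_line: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.surviving_fraction <= 1.0:
            raise ValueError(
                f"surviving_fraction must lie in (0, 1] (its log is taken), "
                f"got {self.surviving_fraction}"
            )
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a GLOBLE calibration."""

    params: GlobleParameters
    ssr: float
    n_obs: int
    converged: bool
    seed: int | None
    bounds_hit: dict
    n_evaluations: int
    optimizer_settings: dict

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "ssr": self.ssr,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "seed": self.seed,
            "bounds_hit": self.bounds_hit,
            "n_evaluations": self.n_evaluations,
            "optimizer_settings": self.optimizer_settings,
        }


def model_log_survival(
    schedules: list[IrradiationSchedule], params: GlobleParameters
) -> np.ndarray:
    """Model ln S for every schedule, dispatched by schedule type.

    Acute schedules use the static closed form, split schedules the
    two-fraction closed form, constant-rate schedules the batched kinetic
    propagator, and arbitrary segment schedules the general evolver.
    """
    out = np.empty(len(schedules))
    cr_idx, cr_dose, cr_rate = [], [], []
    for k, sched in enumerate(schedules):
        if sched.kind == "acute":
            out[k] = np.log(acute_survival(sched.total_dose, params))
        elif sched.kind == "split":
            out[k] = np.log(
                split_dose_survival(
                    sched.elements[0].dose,
                    sched.gap,
                    params,
                    d2=sched.elements[2].dose,
                )
            )
        elif sched.kind == "constant_rate" and sched.total_dose > 0:
            cr_idx.append(k)
            cr_dose.append(sched.total_dose)
            cr_rate.append(sched.elements[0].dose_rate)
        else:
            out[k] = np.log(survival_after_schedule(sched, params))
    if cr_idx:
        out[np.array(cr_idx)] = -constant_rate_neg_log_survival(
            np.array(cr_dose), np.array(cr_rate), params
        )
    return out


def predict_log_survival(
    dataset: list[SurvivalObservation], params: GlobleParameters
) -> np.ndarray:
    """Model ln S for every observation in a dataset."""
    return model_log_survival([o.schedule for o in dataset], params)


def ssr_objective(
    free_params,
    dataset: list[SurvivalObservation],
    fixed: dict | None = None,
) -> float:
    """Weighted sum of squared residuals on ln S at (eps_i, eps_c, hlt_i).

    ``fixed`` may override the structural constants ``hlt_c``, ``n_domains``
    and ``dsb_yield``.  Parameter combinations that produce a non-finite
    model survival return a large finite penalty instead of raising, so
    global optimizers can traverse them.
    """
    eps_i, eps_c, hlt_i = (float(v) for v in free_params)
    fixed = fixed or {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # eps_i > eps_c candidates are legal here
            params = GlobleParameters(
                eps_i=eps_i,
                eps_c=eps_c,
                hlt_i=hlt_i,
                hlt_c=fixed.get("hlt_c", 5.0),
                n_domains=fixed.get("n_domains", 3000.0),
                dsb_yield=fixed.get("dsb_yield", 30.0),
            )
            log_s = predict_log_survival(dataset, params)
    except (ValueError, FloatingPointError):
        return _PENALTY
    if not np.all(np.isfinite(log_s)):
        return _PENALTY
    obs_log_s = np.log([o.surviving_fraction for o in dataset])
    weights = np.array([o.weight for o in dataset])
    return float(np.sum(weights * (log_s - obs_log_s) ** 2))


def fit_parameters(
    dataset: list[SurvivalObservation],
    bounds: dict | None = None,
    seed: int | None = None,
    fixed: dict | None = None,
    maxiter: int = 150,
    popsize: int = 15,
    tol: float = 1e-8,
) -> FitResult:
    """Global least-squares calibration of (eps_i, eps_c, hlt_i).

    Differential evolution over the box ``bounds`` (defaults to
    ``DEFAULT_BOUNDS``), deterministic for a given ``seed``, followed by the
    optimizer's local polish.  Requires at least three observations (three
    free parameters); a dataset whose schedules all share one total dose is
    flagged as non-identifiable with a warning.
    """
    if len(dataset) < 3:
        raise ValueError(
            f"need at least 3 observations to fit 3 parameters, got {len(dataset)}"
        )
    doses = {round(o.schedule.total_dose, 12) for o in dataset}
    if len(doses) == 1:
        warnings.warn(
            "all observations share a single total dose; the three GLOBLE "
            "parameters are unlikely to be identifiable",
            stacklevel=2,
        )
    bounds = bounds or DEFAULT_BOUNDS
    box = [tuple(bounds[k]) for k in ("eps_i", "eps_c", "hlt_i")]
    result = differential_evolution(
        ssr_objective,
        bounds=box,
        args=(dataset, fixed),
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=tol,
        polish=True,
        updating="deferred",
    )
    eps_i, eps_c, hlt_i = (float(v) for v in result.x)
    fixed = fixed or {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = GlobleParameters(
            eps_i=eps_i,
            eps_c=eps_c,
            hlt_i=hlt_i,
            hlt_c=fixed.get("hlt_c", 5.0),
            n_domains=fixed.get("n_domains", 3000.0),
            dsb_yield=fixed.get("dsb_yield", 30.0),
        )
    names = ("eps_i", "eps_c", "hlt_i")
    bounds_hit = {
        name: bool(
            abs(v - lo) < 1e-9 * (hi - lo) or abs(v - hi) < 1e-9 * (hi - lo)
        )
        for name, v, (lo, hi) in zip(names, result.x, box)
    }
    return FitResult(
        params=params,
        ssr=float(result.fun),
        n_obs=len(dataset),
        converged=bool(result.success),
        seed=seed,
        bounds_hit=bounds_hit,
        n_evaluations=int(result.nfev),
        optimizer_settings={
            "method": "differential_evolution",
            "maxiter": maxiter,
            "popsize": popsize,
            "tol": tol,
            "polish": "L-BFGS-B",
        },
    )
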