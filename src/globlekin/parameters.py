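"""Cell-line parameter set for the GLOBLE model.

The model describes a cell nucleus as ``n_domains`` chromatin giant-loop
domains (~2 Mbp each).  Radiation induces DNA double strand breaks (DSBs)
Poisson-distributed over the domains with a yield ``dsb_yield`` per Gy per
cell.  A domain carrying exactly one unprocessed DSB holds an *isolated*
DSB (fast repair, low lethality ``eps_i``); a domain with two or more
coexisting DSBs holds a *clustered* DSB (slow repair, high lethality
``eps_c``).  Repair of each class is first order with half-life times
``hlt_i`` and ``hlt_c`` (hours).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["GlobleParameters", "LQParameters", "read_parameters"]

_PARAM_KEYS = {"eps_i", "eps_c", "hlt_i", "hlt_c", "n_domains", "dsb_yield"}


@dataclass(frozen=True)
class GlobleParameters:
    """Cell-line-specific lethalities, half-life times and structural constants.

    Parameters
    ----------
    eps_i : float
        Probability of a lethal event per isolated DSB (dimensionless, in [0, 1]).
    eps_c : float
        Probability of a lethal event per clustered DSB (dimensionless, in [0, 1]).
    hlt_i : float
        Half-life time of isolated DSBs in hours (fast repair component, ~0.5 h).
    hlt_c : float, default 5.0
        Half-life time of clustered DSBs in hours (slow repair component).
    n_domains : float, default 3000
        Number of giant-loop domains per nucleus (6000 Mbp genome / 2 Mbp loop).
    dsb_yield : float, default 30.0
        DSB induction yield per Gy per cell.
    name : str, optional
        Label (e.g. a cell line) carried through fits and fixtures.
    """

    eps_i: float
    eps_c: float
    hlt_i: float
    hlt_c: float = 5.0
    n_domains: float = 3000.0
    dsb_yield: float = 30.0
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.eps_i <= 1.0:
            raise ValueError(f"eps_i must lie in [0, 1], got {self.eps_i}")
        if not 0.0 <= self.eps_c <= 1.0:
            raise ValueError(f"eps_c must lie in [0, 1], got {self.eps_c}")
        if not self.hlt_i > 0:
            raise ValueError(f"hlt_i must be positive, got {self.hlt_i}")
        if not self.hlt_c > 0:
            raise ValueError(f"hlt_c must be positive, got {self.hlt_c}")
        if not self.n_domains >= 1:
            raise ValueError(f"n_domains must be >= 1, got {self.n_domains}")
        if not self.dsb_yield > 0:
            raise ValueError(f"dsb_yield must be positive, got {self.dsb_yield}")
        if self.eps_i > self.eps_c:
            # empirically eps_i << eps_c; the converse is unusual but not forbidden
            warnings.warn(
                f"eps_i ({self.eps_i}) exceeds eps_c ({self.eps_c}); "
                "isolated DSBs are normally far less lethal than clustered ones",
                stacklevel=2,
            )

    def with_updates(self, **kwargs) -> "GlobleParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in sorted(_PARAM_KEYS)}
        if self.name is not None:
            d["name"] = self.name
        return d


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic survival parameters -ln S = alpha*D + G*beta*D^2.

    ``repair_rate`` is the first-order sublethal-damage restitution rate r
    (per hour) entering the Lea-Catcheside protraction factor G.
    """

    alpha: float
    beta: float
    repair_rate: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.repair_rate is not None and self.repair_rate <= 0:
            raise ValueError(
                f"repair_rate must be positive when given, got {self.repair_rate}"
            )

    @property
    def alpha_beta_ratio(self) -> float:
        return self.alpha / self.beta


def read_parameters(path: str | Path) -> GlobleParameters:
    """Read a GlobleParameters set from a YAML or JSON file.

    Required keys: ``eps_i``, ``eps_c``, ``hlt_i``.  Optional: ``hlt_c``,
    ``n_domains``, ``dsb_yield``, ``name``.  Unknown keys are rejected.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    unknown = set(data) - _PARAM_KEYS - {"name"}
    if unknown:
        raise ValueError(
            f"unknown parameter keys in {path}: {', '.join(sorted(unknown))}"
        )
    missing = {"eps_i", "eps_c", "hlt_i"} - set(data)
    if missing:
        raise ValueError(f"missing required keys in {path}: {', '.join(sorted(missing))}")
    return GlobleParameters(**data)
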