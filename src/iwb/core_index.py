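"""Static aggregation layer.

Cobb-Douglas integrated wellbeing over an arbitrary set of named domains,
its marginal contributions, and the bounded financial-wellbeing index that
maps (objective wealth, subjective index) into [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from iwb.errors import BoundaryError, InvalidScenarioError

#: Absolute tolerance on the constant-returns normalisation sum(theta) == 1.
THETA_SUM_TOL = 1e-12


@dataclass(frozen=True)
class ElasticityVector:
    """Per-domain Cobb-Douglas exponents, positive and summing to one.

    Parameters
    ----------
    theta
        Mapping from domain name to its elasticity. Every entry must be
        strictly positive and the entries must sum to 1 within
        ``THETA_SUM_TOL`` (constant returns to scale).
    """

    theta: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.theta:
            raise InvalidScenarioError("elasticities: at least one domain is required")
        for name, value in self.theta.items():
            if not math.isfinite(value):
                raise InvalidScenarioError(
                    f"elasticities[{name}]: must be finite, got {value!r}"
                )
            if value <= 0.0:
                raise InvalidScenarioError(
                    f"elasticities[{name}]: every elasticity must be > 0, got {value}"
                )
        total = math.fsum(self.theta.values())
        if abs(total - 1.0) > THETA_SUM_TOL:
            raise InvalidScenarioError(
                f"elasticities: entries must sum to 1 (constant returns to scale); "
                f"got sum = {total!r}"
            )
        object.__setattr__(self, "theta", dict(self.theta))

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.theta)

    def __getitem__(self, domain: str) -> float:
        return self.theta[domain]


@dataclass(frozen=True)
class DomainLevels:
    """Per-domain wellbeing indices, each in [0, 1]."""

    x: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.x.items():
            if not math.isfinite(value) or not 0.0 <= value <= 1.0:
                raise InvalidScenarioError(
                    f"levels[{name}]: domain index must lie in [0, 1], got {value!r}"
                )
        object.__setattr__(self, "x", dict(self.x))

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.x)

    def __getitem__(self, domain: str) -> float:
        return self.x[domain]


@dataclass(frozen=True)
class FinancialIndexParams:
    """Parameters of the financial-wellbeing index.

    ``wealth_scale`` is the half-saturation point of the wealth map (in
    currency units): objective wealth equal to ``wealth_scale`` maps to an
    objective component of 0.5. ``objective_weight`` is the geometric weight
    on the objective component, strictly inside (0, 1).
    """

    wealth_scale: float
    objective_weight: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.wealth_scale) and self.wealth_scale > 0.0):
            raise InvalidScenarioError(
                f"fin_index.wealth_scale: must be > 0, got {self.wealth_scale!r}"
            )
        if not (0.0 < self.objective_weight < 1.0):
            raise InvalidScenarioError(
                f"fin_index.objective_weight: must lie in (0, 1), "
                f"got {self.objective_weight!r}"
            )


@dataclass(frozen=True)
class FinancialState:
    """Objective wealth (a nonnegative currency stock) and subjective index."""

    OF: float
    SF: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.OF) and self.OF >= 0.0):
            raise InvalidScenarioError(
                f"financial state: OF must be >= 0 (no-borrowing), got {self.OF!r}"
            )
        if not (math.isfinite(self.SF) and 0.0 <= self.SF <= 1.0):
            raise InvalidScenarioError(
                f"financial state: SF must lie in [0, 1], got {self.SF!r}"
            )


def validate_elasticities(theta: Mapping[str, float]) -> ElasticityVector:
    """Validate raw per-domain weights and return them as an ElasticityVector.

    Raises
    ------
    InvalidScenarioError
        If any entry is nonpositive or the entries do not sum to 1 within
        ``THETA_SUM_TOL``.
    """
    return ElasticityVector(theta)


def _check_same_domains(levels: DomainLevels, theta: ElasticityVector) -> None:
    if set(levels.domains) != set(theta.domains):
        raise InvalidScenarioError(
            f"domain mismatch: levels cover {sorted(levels.domains)} but "
            f"elasticities cover {sorted(theta.domains)}"
        )


def integrated_wellbeing(levels: DomainLevels, theta: ElasticityVector) -> float:
    """Cobb-Douglas integrated wellbeing, IW = prod_i x_i ** theta_i.

    Bounded in [0, 1]; zero whenever any single domain index is zero
    (complementarity), one iff every domain index is one. The convention
    0 ** theta = 0 is used for theta > 0 (never 1).
    """
    _check_same_domains(levels, theta)
    log_iw = 0.0
    for name in theta.domains:
        x = levels[name]
        if x == 0.0:
            return 0.0
        log_iw += theta[name] * math.log(x)
    return math.exp(log_iw)


def marginal_iw(levels: DomainLevels, theta: ElasticityVector, domain: str) -> float:
    """Marginal contribution of one domain: dIW/dx_d = theta_d * IW / x_d.

    Strictly positive, and strictly decreasing in x_d when theta_d < 1
    (diminishing marginal returns).

    Raises
    ------
    BoundaryError
        If the requested domain's level is zero (the marginal is not
        finite at the boundary).
    """
    _check_same_domains(levels, theta)
    if domain not in theta.domains:
        raise InvalidScenarioError(f"unknown domain {domain!r}")
    x_d = levels[domain]
    if x_d == 0.0:
        raise BoundaryError(f"marginal_iw undefined at x[{domain}] = 0")
    return theta[domain] * integrated_wellbeing(levels, theta) / x_d


def financial_index(state: FinancialState, params: FinancialIndexParams) -> float:
    """Financial-wellbeing index F = (OF/(OF+s))**lam * SF**(1-lam).

    Strictly increasing in both OF and SF, bounded in [0, 1]; zero when
    either OF or SF is zero, approaching 1 as OF grows with SF = 1.
    """
    lam = params.objective_weight
    objective = state.OF / (state.OF + params.wealth_scale)
    if objective == 0.0 or state.SF == 0.0:
        return 0.0
    return objective**lam * state.SF ** (1.0 - lam)
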