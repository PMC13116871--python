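"""Per-period state transitions.

Physical decay along a bounded logistic, saturating health investment,
health-span/lifespan maps with a threshold regime, labour income, resource
flow, budget feasibility and wealth accounting. All functions are pure;
the lifecycle simulator composes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from iwb.errors import InvalidAllocationError, InvalidScenarioError

#: Grid resolution used for the numeric slope check h' > g' at load time.
_SLOPE_GRID_POINTS = 100


@dataclass(frozen=True)
class PhysicalParams:
    """Physical-wellbeing dynamics parameters.

    ``alpha_min``/``alpha_max`` bound the logistic decay rate (per period),
    ``tau`` is the transition speed, ``t0`` the inflexion age. ``p_bar_h``
    is the health-span threshold on the physical index. ``kappa`` caps the
    per-period investment gain and ``c0`` sets its currency saturation
    scale.
    """

    alpha_min: float
    alpha_max: float
    tau: float
    t0: float
    p_bar_h: float
    kappa: float
    c0: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_min < self.alpha_max < 1.0):
            raise InvalidScenarioError(
                "physical: decay bounds must satisfy 0 < alpha_min < alpha_max < 1; "
                f"got alpha_min={self.alpha_min!r}, alpha_max={self.alpha_max!r}"
            )
        if not self.tau > 0.0:
            raise InvalidScenarioError(f"physical.tau: must be > 0, got {self.tau!r}")
        if not self.kappa > 0.0:
            raise InvalidScenarioError(
                f"physical.kappa: must be > 0, got {self.kappa!r}"
            )
        if not self.c0 > 0.0:
            raise InvalidScenarioError(f"physical.c0: must be > 0, got {self.c0!r}")
        if not 0.0 < self.p_bar_h < 1.0:
            raise InvalidScenarioError(
                f"physical.p_bar_h: threshold must lie in (0, 1), got {self.p_bar_h!r}"
            )


@dataclass(frozen=True)
class SpanParams:
    """Health-span and lifespan map parameters.

    Health span: H(P) = h_max * ((P - p_bar_h)/(1 - p_bar_h))**a above the
    threshold, 0 at or below it. Lifespan: T(P) = t_min + (t_max - t_min)*P**b.
    The cross-field requirements H <= T and h' > g' >= 0 on the supra-
    threshold range are validated numerically by ``validate_span_shapes``.
    """

    h_max: float
    a: float
    t_min: float
    t_max: float
    b: float

    def __post_init__(self) -> None:
        if not self.h_max > 0.0:
            raise InvalidScenarioError(f"spans.h_max: must be > 0, got {self.h_max!r}")
        if not self.a >= 1.0:
            raise InvalidScenarioError(f"spans.a: curvature must be >= 1, got {self.a!r}")
        if not self.t_min >= 0.0:
            raise InvalidScenarioError(f"spans.t_min: must be >= 0, got {self.t_min!r}")
        if not self.t_max >= self.h_max:
            raise InvalidScenarioError(
                "spans: h_max must not exceed t_max (health span <= lifespan); "
                f"got h_max={self.h_max!r}, t_max={self.t_max!r}"
            )
        if not self.t_max > self.t_min:
            raise InvalidScenarioError(
                f"spans: t_max must exceed t_min; got t_min={self.t_min!r}, "
                f"t_max={self.t_max!r}"
            )
        if not self.b > 0.0:
            raise InvalidScenarioError(f"spans.b: must be > 0, got {self.b!r}")


def validate_span_shapes(spans: SpanParams, p_bar_h: float) -> None:
    """Numerically enforce H(P) <= T(P) everywhere and h'(P) > g'(P) >= 0
    on the supra-threshold range (P_bar_H, 1].

    Raises
    ------
    InvalidScenarioError
        Naming the violated inequality and the offending grid point.
    """
    grid = np.linspace(p_bar_h + 1e-6, 1.0, _SLOPE_GRID_POINTS)
    h = np.array([health_span(p, spans, p_bar_h) for p in grid])
    g = np.array([lifespan(p, spans) for p in grid])
    bad = np.nonzero(h > g + 1e-12)[0]
    if bad.size:
        p = grid[bad[0]]
        raise InvalidScenarioError(
            f"spans: health span exceeds lifespan (H <= T violated) at P={p:.6f}: "
            f"H={h[bad[0]]:.6f} > T={g[bad[0]]:.6f}"
        )
    step = 1e-6
    for p in grid[:-1]:
        dh = (health_span(p + step, spans, p_bar_h) - health_span(p - step, spans, p_bar_h)) / (2 * step)
        dg = (lifespan(p + step, spans) - lifespan(p - step, spans)) / (2 * step)
        if not dg >= -1e-12:
            raise InvalidScenarioError(
                f"spans: lifespan slope must satisfy g' >= 0; got g'={dg:.6g} at P={p:.6f}"
            )
        if not dh > dg:
            raise InvalidScenarioError(
                "spans: health span must respond more steeply than lifespan "
                f"(h' > g' violated) at P={p:.6f}: h'={dh:.6g}, g'={dg:.6g}"
            )


@dataclass(frozen=True)
class EconomyParams:
    """Labour income and interest-rate parameters.

    Income at full physical wellbeing is ``y_max`` per period and scales as
    P**eta inside the health span. ``r_path`` is the exogenous per-period
    interest-rate sequence; a scalar is broadcast to all periods.
    """

    y_max: float
    eta: float
    r_path: tuple[float, ...] | float = 0.0

    def __post_init__(self) -> None:
        if not self.y_max >= 0.0:
            raise InvalidScenarioError(
                f"economy.y_max: must be >= 0, got {self.y_max!r}"
            )
        if not self.eta > 0.0:
            raise InvalidScenarioError(f"economy.eta: must be > 0, got {self.eta!r}")
        if isinstance(self.r_path, (int, float)):
            object.__setattr__(self, "r_path", float(self.r_path))
        else:
            object.__setattr__(self, "r_path", tuple(float(r) for r in self.r_path))

    def rate_at(self, period_index: int) -> float:
        """Interest rate for a zero-based period index; the final entry of a
        finite path is held thereafter."""
        if isinstance(self.r_path, float):
            return self.r_path
        if not self.r_path:
            return 0.0
        return self.r_path[min(period_index, len(self.r_path) - 1)]


@dataclass(frozen=True)
class Allocation:
    """Per-period spending split: health spending C_OF and retained
    financial investment I_OF, both nonnegative currency amounts."""

    C_OF: float
    I_OF: float = 0.0

    def __post_init__(self) -> None:
        if self.C_OF < 0.0 or self.I_OF < 0.0:
            raise InvalidAllocationError(
                f"allocation components must be >= 0; got C_OF={self.C_OF!r}, "
                f"I_OF={self.I_OF!r}"
            )


def decay_rate(t: float, params: PhysicalParams) -> float:
    """Logistic decay rate alpha(t) = alpha_min + (alpha_max - alpha_min) /
    (1 + exp(-tau*(t - t0))). Strictly increasing in t, bounded in
    (alpha_min, alpha_max)."""
    u = params.tau * (t - params.t0)
    # overflow-safe logistic
    if u >= 0.0:
        sig = 1.0 / (1.0 + math.exp(-u))
    else:
        e = math.exp(u)
        sig = e / (1.0 + e)
    return params.alpha_min + (params.alpha_max - params.alpha_min) * sig


def physical_investment(C: float, params: PhysicalParams) -> float:
    """Wellbeing increment from health spending: I_P(C) = kappa*(1 - exp(-C/c0)).

    Zero at zero spend, strictly increasing, strictly concave, bounded by
    kappa.
    """
    if C < 0.0:
        raise InvalidAllocationError(f"health spending must be >= 0, got {C!r}")
    return params.kappa * -math.expm1(-C / params.c0)


def step_physical(P: float, C: float, t: float, params: PhysicalParams) -> float:
    """One-period physical update: P' = min(1, max(0, (1 - alpha_t)*P + I_P(C)))."""
    alpha = decay_rate(t, params)
    return min(1.0, max(0.0, (1.0 - alpha) * P + physical_investment(C, params)))


def step_domain(
    x: float, C: float, delta: float, invest: Callable[[float], float]
) -> float:
    """General n-domain progress step: x' = min(1, (1 - delta)*x + I(C)),
    floored at 0, with a constant decay rate delta in [0, 1]."""
    if not 0.0 <= delta <= 1.0:
        raise InvalidScenarioError(f"decay rate delta must lie in [0, 1], got {delta!r}")
    if C < 0.0:
        raise InvalidAllocationError(f"spending must be >= 0, got {C!r}")
    return min(1.0, max(0.0, (1.0 - delta) * x + invest(C)))


def health_span(P: float, spans: SpanParams, p_bar_h: float) -> float:
    """Health span H(P): zero at or below the threshold p_bar_h, rising
    continuously to h_max at P = 1 with curvature a."""
    if P <= p_bar_h:
        return 0.0
    return spans.h_max * ((P - p_bar_h) / (1.0 - p_bar_h)) ** spans.a


def lifespan(P: float, spans: SpanParams) -> float:
    """Lifespan T(P) = t_min + (t_max - t_min) * P**b, nondecreasing in P."""
    return spans.t_min + (spans.t_max - spans.t_min) * P**spans.b


def labour_income(P_prev: float, params: EconomyParams, H_prev: float) -> float:
    """Labour income: y_max * P**eta while the previous-period health span
    is positive, zero otherwise (no income outside the health span)."""
    if H_prev <= 0.0:
        return 0.0
    return params.y_max * P_prev**params.eta


def resource_flow(
    P_prev: float,
    OF_prev: float,
    r_prev: float,
    params: EconomyParams,
    H_prev: float,
) -> float:
    """Per-period resource inflow GR = Y(P_prev) + r_prev * OF_prev."""
    if OF_prev < 0.0:
        raise InvalidScenarioError(f"wealth must be >= 0, got {OF_prev!r}")
    return labour_income(P_prev, params, H_prev) + r_prev * OF_prev


def budget_feasible(alloc: Allocation, OF_prev: float, GR: float) -> bool:
    """No-borrowing budget check: C_OF + I_OF <= OF_prev + GR."""
    return alloc.C_OF + alloc.I_OF <= OF_prev + GR


def step_wealth(
    OF_prev: float,
    r_prev: float,
    Y: float,
    C_OF: float,
    in_healthspan: bool,
) -> float:
    """Wealth accounting: OF' = OF + r*OF + Y*[in span] - C_OF.

    Raises
    ------
    InvalidAllocationError
        If the result would be negative (an infeasible allocation slipped
        past the budget check).
    """
    OF_next = OF_prev + r_prev * OF_prev + (Y if in_healthspan else 0.0) - C_OF
    if OF_next < 0.0:
        raise InvalidAllocationError(
            f"wealth would become negative ({OF_next!r}); allocation infeasible"
        )
    return OF_next


def step_resources_general(
    R: float,
    levels: Mapping[str, float],
    total_spend: float,
    income_fn: Callable[[Mapping[str, float]], float],
) -> float:
    """General resource update R' = R + Y(x) - sum(C_i) under no-borrowing."""
    income = income_fn(levels)
    if total_spend > R + income:
        raise InvalidAllocationError(
            f"total spending {total_spend!r} exceeds resources {R + income!r}"
        )
    return R + income - total_spend
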