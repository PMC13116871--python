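"""Lifecycle simulation: composes the per-period transitions into full
trajectories under an allocation policy."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from iwb.core_index import (
    DomainLevels,
    ElasticityVector,
    FinancialIndexParams,
    FinancialState,
    financial_index,
    integrated_wellbeing,
)
from iwb.dynamics import (
    Allocation,
    EconomyParams,
    PhysicalParams,
    SpanParams,
    decay_rate,
    health_span,
    labour_income,
    lifespan,
    step_physical,
    step_wealth,
    validate_span_shapes,
)
from iwb.errors import InvalidScenarioError

logger = logging.getLogger(__name__)

#: Column order of a trajectory record; writers and readers rely on it.
TRAJECTORY_FIELDS = (
    "age",
    "P",
    "alpha",
    "H",
    "T",
    "Y",
    "r",
    "OF",
    "SF",
    "F",
    "IW",
    "C_OF",
    "I_OF",
)

#: Canonical two-domain names used by the simulator.
FINANCIAL, PHYSICAL = "financial", "physical"


@dataclass(frozen=True)
class Scenario:
    """A fully parameterised simulation configuration."""

    elasticities: ElasticityVector
    physical: PhysicalParams
    spans: SpanParams
    economy: EconomyParams
    fin_index: FinancialIndexParams
    initial_P: float
    initial_OF: float
    initial_SF: float
    start_age: float
    horizon: int
    name: str = "scenario"

    def __post_init__(self) -> None:
        if set(self.elasticities.domains) != {FINANCIAL, PHYSICAL}:
            raise InvalidScenarioError(
                "scenario elasticities must cover exactly the domains "
                f"{{'financial', 'physical'}}; got {sorted(self.elasticities.domains)}"
            )
        if not 0.0 <= self.initial_P <= 1.0:
            raise InvalidScenarioError(
                f"initial.p: must lie in [0, 1], got {self.initial_P!r}"
            )
        if not self.initial_OF >= 0.0:
            raise InvalidScenarioError(
                f"initial.of: must be >= 0, got {self.initial_OF!r}"
            )
        if not 0.0 <= self.initial_SF <= 1.0:
            raise InvalidScenarioError(
                f"initial.sf: must lie in [0, 1], got {self.initial_SF!r}"
            )
        if not (isinstance(self.horizon, int) and self.horizon >= 1):
            raise InvalidScenarioError(
                f"horizon: must be an integer >= 1, got {self.horizon!r}"
            )
        validate_span_shapes(self.spans, self.physical.p_bar_h)


@dataclass(frozen=True)
class Policy:
    """Allocation rule mapping (available resources, state, age) to health
    spending. Emitted allocations are clipped to the budget, so every policy
    is feasible by construction (clips are logged)."""

    kind: str
    rule: Callable[[float, float, float, float], float]

    def allocate(self, available: float, P: float, OF: float, age: float) -> Allocation:
        requested = self.rule(available, P, OF, age)
        if requested < 0.0:
            requested = 0.0
        c_of = min(requested, available)
        if c_of < requested:
            logger.warning(
                "policy %s clipped: requested %.6g > available %.6g at age %.1f",
                self.kind,
                requested,
                available,
                age,
            )
        return Allocation(C_OF=c_of, I_OF=available - c_of)

    @staticmethod
    def constant_fraction(phi: float) -> "Policy":
        """Spend a fixed fraction phi of available resources on health."""
        if not 0.0 <= phi <= 1.0:
            raise InvalidScenarioError(f"policy.phi: must lie in [0, 1], got {phi!r}")
        return Policy(kind=f"constant_fraction({phi})", rule=lambda av, P, OF, age: phi * av)

    @staticmethod
    def fixed_amount(amount: float) -> "Policy":
        """Spend a fixed currency amount per period (clipped to the budget)."""
        if amount < 0.0:
            raise InvalidScenarioError(
                f"policy.amount: must be >= 0, got {amount!r}"
            )
        return Policy(kind=f"fixed_amount({amount})", rule=lambda av, P, OF, age: amount)

    @staticmethod
    def zero_spend() -> "Policy":
        """Never spend on health; all resources stay invested."""
        return Policy(kind="zero_spend", rule=lambda av, P, OF, age: 0.0)


@dataclass(frozen=True)
class TrajectorySummary:
    years_in_healthspan: int
    terminal_OF: float
    terminal_F: float
    mean_IW: float
    min_IW: float


@dataclass(frozen=True)
class Trajectory:
    """Per-period records of a simulated lifespan plus a terminal summary."""

    records: tuple[dict, ...]
    scenario_name: str = "scenario"
    policy_kind: str = "policy"

    def __len__(self) -> int:
        return len(self.records)

    def column(self, name: str) -> list[float]:
        if name not in TRAJECTORY_FIELDS:
            raise KeyError(f"unknown trajectory field {name!r}")
        return [rec[name] for rec in self.records]

    @property
    def summary(self) -> TrajectorySummary:
        return trajectory_summary(self)


def simulate(scenario: Scenario, policy: Policy, *, stop_at_lifespan: bool = False) -> Trajectory:
    """Simulate a lifespan trajectory under an allocation policy.

    Each period, in order: evaluate the decay rate, compute the period's
    resource inflow (labour income from the current state plus interest),
    ask the policy for an allocation (clipped to the budget), record the
    period, then advance physical wellbeing and wealth. Runs to the fixed
    horizon, or stops early once age exceeds the state-dependent lifespan
    estimate when ``stop_at_lifespan`` is set.
    """
    phys, spans, econ, fin = (
        scenario.physical,
        scenario.spans,
        scenario.economy,
        scenario.fin_index,
    )
    P = scenario.initial_P
    OF = scenario.initial_OF
    SF = scenario.initial_SF

    records: list[dict] = []
    for k in range(scenario.horizon):
        age = scenario.start_age + k
        H = health_span(P, spans, phys.p_bar_h)
        T = lifespan(P, spans)
        if stop_at_lifespan and age > T:
            break
        alpha = decay_rate(age, phys)
        r = econ.rate_at(k)
        Y = labour_income(P, econ, H)
        available = OF + Y + r * OF
        alloc = policy.allocate(available, P, OF, age)
        state = FinancialState(OF=OF, SF=SF)
        F = financial_index(state, fin)
        IW = integrated_wellbeing(
            DomainLevels({FINANCIAL: F, PHYSICAL: P}), scenario.elasticities
        )
        records.append(
            {
                "age": float(age),
                "P": P,
                "alpha": alpha,
                "H": H,
                "T": T,
                "Y": Y,
                "r": r,
                "OF": OF,
                "SF": SF,
                "F": F,
                "IW": IW,
                "C_OF": alloc.C_OF,
                "I_OF": alloc.I_OF,
            }
        )
        P = step_physical(P, alloc.C_OF, age, phys)
        OF = step_wealth(OF, r, Y, alloc.C_OF, in_healthspan=H > 0.0)
    if not records:
        raise InvalidScenarioError("simulation produced no periods")
    return Trajectory(
        records=tuple(records),
        scenario_name=scenario.name,
        policy_kind=policy.kind,
    )


def trajectory_summary(traj: Trajectory) -> TrajectorySummary:
    """Terminal summary: years with positive health span, terminal wealth
    and financial index, mean and minimum integrated wellbeing."""
    if not traj.records:
        raise InvalidScenarioError("cannot summarise an empty trajectory")
    iw = traj.column("IW")
    return TrajectorySummary(
        years_in_healthspan=sum(1 for h in traj.column("H") if h > 0.0),
        terminal_OF=traj.records[-1]["OF"],
        terminal_F=traj.records[-1]["F"],
        mean_IW=math.fsum(iw) / len(iw),
        min_IW=min(iw),
    )
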