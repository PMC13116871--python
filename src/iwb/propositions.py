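"""Numerical certification of the model's three comparative-statics claims.

1. Health spending has intertemporal option value: it preserves the
   income-earning regime and thereby the wealth and financial-index paths.
2. Joint dominance in the two domain indices implies dominance in
   integrated wellbeing (exact algebra, no tolerance).
3. The return required to hit a wealth target falls with physical
   wellbeing, at a rate -Y'(P)/OF_prev, and the relationship is convex
   under concave income.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from iwb.core_index import DomainLevels, ElasticityVector, integrated_wellbeing
from iwb.errors import BoundaryError, InvalidScenarioError
from iwb.lifecycle_sim import FINANCIAL, PHYSICAL, Policy, Scenario, Trajectory, simulate
from iwb.dynamics import labour_income

_FD_STEP = 1e-5
_REL_TOL = 1e-6
_ABS_FLOOR = 1e-12


@dataclass(frozen=True)
class Check:
    """One verified inequality: a label, the logged inputs, the computed
    quantities and the boolean outcome."""

    label: str
    passed: bool
    details: dict


@dataclass(frozen=True)
class PropositionReport:
    proposition: str
    checks: tuple[Check, ...]
    narrative: str

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)


def required_return(
    OF_target: float,
    OF_prev: float,
    Y: float,
    I_OF: float,
    C_OF: float,
) -> float:
    """Return needed to reach OF_target from OF_prev given labour income:
    r = (OF_target - OF_prev - Y - I_OF + C_OF) / OF_prev.

    Raises
    ------
    BoundaryError
        If OF_prev <= 0 (the rearrangement is undefined).
    """
    if OF_prev <= 0.0:
        raise BoundaryError(f"required_return undefined for OF_prev <= 0, got {OF_prev!r}")
    return (OF_target - OF_prev - Y - I_OF + C_OF) / OF_prev


def required_return_curve(
    P_grid: Sequence[float],
    wealth_target: float,
    scenario: Scenario,
    *,
    OF_prev: float | None = None,
    I_OF: float = 0.0,
    C_OF: float = 0.0,
) -> list[tuple[float, float]]:
    """Required return as a function of physical wellbeing, holding the
    wealth target fixed. Every grid point must lie strictly inside the
    labour-income regime (P > threshold); out-of-regime points are rejected
    rather than silently included.
    """
    of_prev = scenario.initial_OF if OF_prev is None else OF_prev
    if of_prev <= 0.0:
        raise BoundaryError(f"required_return_curve needs OF_prev > 0, got {of_prev!r}")
    p_bar = scenario.physical.p_bar_h
    curve = []
    for P in P_grid:
        if not p_bar < P <= 1.0:
            raise InvalidScenarioError(
                f"P={P!r} is outside the labour-income regime (threshold {p_bar})"
            )
        Y = labour_income(P, scenario.economy, H_prev=1.0)
        curve.append((P, required_return(wealth_target, of_prev, Y, I_OF, C_OF)))
    return curve


def _weakly_increasing(values: Sequence[float], tol: float = 0.0) -> bool:
    return all(b >= a - tol for a, b in zip(values, values[1:]))


def check_prop1(
    scenario: Scenario, spend_levels: Sequence[float]
) -> PropositionReport:
    """Certify the option-value chain of health spending on simulated
    trajectories under ordered fixed-amount spend levels.

    Links verified across the ordered levels: (i) pointwise higher physical
    path; (ii) at least as many income periods; (iii) weakly higher
    cumulative labour income; (iv) weakly higher terminal wealth;
    (v) weakly higher terminal financial index. The fixture must straddle
    the threshold: the lowest level loses the income regime within the
    horizon while the highest keeps it; otherwise the report is
    inconclusive rather than failed.
    """
    levels = sorted(spend_levels)
    trajs = [simulate(scenario, Policy.fixed_amount(c)) for c in levels]

    lo, hi = trajs[0], trajs[-1]
    lo_loses_regime = any(h == 0.0 for h in lo.column("H"))
    hi_keeps_regime = all(h > 0.0 for h in hi.column("H"))
    if not (lo_loses_regime and hi_keeps_regime):
        raise InvalidScenarioError(
            "inconclusive fixture: the lowest spend level must cross below the "
            "health-span threshold within the horizon and the highest must stay "
            f"above it (lowest crosses: {lo_loses_regime}, highest stays: {hi_keeps_regime})"
        )

    checks: list[Check] = []
    for (c_a, t_a), (c_b, t_b) in zip(zip(levels, trajs), zip(levels[1:], trajs[1:])):
        p_a, p_b = t_a.column("P"), t_b.column("P")
        checks.append(
            Check(
                label=f"(i) P path nondecreasing in spend: {c_a} -> {c_b}",
                passed=all(pb >= pa for pa, pb in zip(p_a, p_b)),
                details={"spend": (c_a, c_b), "P_low": p_a, "P_high": p_b},
            )
        )
        inc_a = sum(1 for h in t_a.column("H") if h > 0.0)
        inc_b = sum(1 for h in t_b.column("H") if h > 0.0)
        checks.append(
            Check(
                label=f"(ii) income periods nondecreasing: {c_a} -> {c_b}",
                passed=inc_b >= inc_a,
                details={"spend": (c_a, c_b), "periods": (inc_a, inc_b)},
            )
        )
        y_a, y_b = math.fsum(t_a.column("Y")), math.fsum(t_b.column("Y"))
        checks.append(
            Check(
                label=f"(iii) cumulative labour income nondecreasing: {c_a} -> {c_b}",
                passed=y_b >= y_a - _ABS_FLOOR,
                details={"spend": (c_a, c_b), "cumulative_Y": (y_a, y_b)},
            )
        )
    of_path = [t.records[-1]["OF"] for t in trajs]
    f_path = [t.records[-1]["F"] for t in trajs]
    checks.append(
        Check(
            label="(iv) terminal wealth weakly increasing across spend levels",
            passed=_weakly_increasing(of_path, tol=_ABS_FLOOR)
            and of_path[-1] > of_path[0],
            details={"spend": levels, "terminal_OF": of_path},
        )
    )
    checks.append(
        Check(
            label="(v) terminal financial index weakly increasing across spend levels",
            passed=_weakly_increasing(f_path, tol=_ABS_FLOOR) and f_path[-1] > f_path[0],
            details={"spend": levels, "terminal_F": f_path},
        )
    )
    report = PropositionReport(
        proposition="prop1",
        checks=tuple(checks),
        narrative=(
            "Higher health spending keeps physical wellbeing above the "
            "health-span threshold for longer, preserving labour income, which "
            "accumulates into higher terminal wealth and a higher financial "
            "index. Wealth accounting treats retained investment as the "
            "unspent remainder of resources, so no inflow is double-counted."
        ),
    )
    return report


def check_prop2(
    traj_pairs: Sequence[tuple[Trajectory, Trajectory]],
    theta: ElasticityVector,
) -> PropositionReport:
    """Exact dominance check: wherever both F and P weakly dominate,
    integrated wellbeing weakly dominates. Pure algebra, zero tolerance."""
    checks: list[Check] = []
    for idx, (t_a, t_b) in enumerate(traj_pairs):
        if len(t_a) != len(t_b):
            raise InvalidScenarioError(
                f"pair {idx}: trajectories differ in length ({len(t_a)} vs {len(t_b)})"
            )
        violations = []
        for k, (ra, rb) in enumerate(zip(t_a.records, t_b.records)):
            if ra["F"] >= rb["F"] and ra["P"] >= rb["P"]:
                iw_a = integrated_wellbeing(
                    DomainLevels({FINANCIAL: ra["F"], PHYSICAL: ra["P"]}), theta
                )
                iw_b = integrated_wellbeing(
                    DomainLevels({FINANCIAL: rb["F"], PHYSICAL: rb["P"]}), theta
                )
                if not iw_a >= iw_b:
                    violations.append((k, iw_a, iw_b))
        checks.append(
            Check(
                label=f"pair {idx}: IW dominates at every jointly dominating period",
                passed=not violations,
                details={"violations": violations, "periods": len(t_a)},
            )
        )
    return PropositionReport(
        proposition="prop2",
        checks=tuple(checks),
        narrative=(
            "Integrated wellbeing is a monotone function of both domain "
            "indices, so joint weak dominance in (F, P) transfers exactly to "
            "the composite index."
        ),
    )


def check_prop3(
    scenario: Scenario,
    P_grid: Sequence[float],
    *,
    wealth_target: float | None = None,
    OF_prev: float | None = None,
) -> PropositionReport:
    """Certify that the required return falls with physical wellbeing.

    Compares the analytic slope -Y'(P)/OF_prev against central finite
    differences of the required-return curve (relative tolerance 1e-6),
    asserts negativity of the slope throughout, and asserts convexity
    (positive second differences) when income is concave in P.
    """
    of_prev = scenario.initial_OF if OF_prev is None else OF_prev
    target = 1.1 * of_prev if wealth_target is None else wealth_target
    grid = np.asarray(sorted(P_grid), dtype=float)
    curve = required_return_curve(grid, target, scenario, OF_prev=of_prev)
    r = np.array([pt[1] for pt in curve])

    econ = scenario.economy
    analytic = -econ.y_max * econ.eta * grid ** (econ.eta - 1.0) / of_prev

    fd = np.empty_like(grid)
    for i, P in enumerate(grid):
        h = _FD_STEP
        y_plus = labour_income(min(P + h, 1.0), econ, H_prev=1.0)
        y_minus = labour_income(P - h, econ, H_prev=1.0)
        r_plus = required_return(target, of_prev, y_plus, 0.0, 0.0)
        r_minus = required_return(target, of_prev, y_minus, 0.0, 0.0)
        fd[i] = (r_plus - r_minus) / (min(P + h, 1.0) - (P - h))

    rel_err = np.abs(analytic - fd) / np.maximum(np.abs(analytic), _ABS_FLOOR)
    first_diff = np.diff(r)
    second_diff = np.diff(r, n=2)

    checks = [
        Check(
            label="slope negative throughout the income regime",
            passed=bool(np.all(analytic < 0.0) and np.all(first_diff < 0.0)),
            details={"analytic_slope": analytic.tolist(), "first_differences": first_diff.tolist()},
        ),
        Check(
            label="analytic slope -Y'(P)/OF_prev matches central differences",
            passed=bool(np.all(rel_err < _REL_TOL)),
            details={"max_relative_error": float(rel_err.max())},
        ),
    ]
    if econ.eta < 1.0:
        checks.append(
            Check(
                label="curve convex under concave income (second differences positive)",
                passed=bool(np.all(second_diff > 0.0)),
                details={"second_differences": second_diff.tolist()},
            )
        )
    return PropositionReport(
        proposition="prop3",
        checks=tuple(checks),
        narrative=(
            "Labour income substitutes for investment return inside the "
            "health span: each unit of income lowers the return required to "
            "reach the wealth target by 1/OF_prev, so the required-return "
            "curve is decreasing in physical wellbeing and convex when income "
            "is concave."
        ),
    )
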