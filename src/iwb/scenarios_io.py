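"""Scenario configuration loading, named baseline fixtures and text writers.

Configs are YAML documents with a versioned ``schema`` field. Validation is
strict: unknown keys are rejected and every numeric invariant is enforced
with an error message naming the offending field.
"""

from __future__ import annotations

import io
import math
import os
from typing import Any, Mapping, TextIO

import yaml

from iwb.core_index import ElasticityVector, FinancialIndexParams
from iwb.dynamics import EconomyParams, PhysicalParams, SpanParams
from iwb.errors import InvalidScenarioError
from iwb.lifecycle_sim import TRAJECTORY_FIELDS, Scenario, Trajectory
from iwb.propositions import PropositionReport

SCHEMA = "iwb-scenario/1"

_SECTION_KEYS = {
    "schema": None,
    "name": None,
    "elasticities": {"financial", "physical"},
    "physical": {"alpha_min", "alpha_max", "tau", "t0", "p_bar_h", "kappa", "c0"},
    "spans": {"h_max", "a", "t_min", "t_max", "b"},
    "economy": {"y_max", "eta", "r", "r_path"},
    "fin_index": {"wealth_scale", "objective_weight"},
    "initial": {"p", "of", "sf"},
    "start_age": None,
    "horizon": None,
    "policy": {"kind", "phi", "amount"},
}

_REQUIRED = (
    "schema",
    "elasticities",
    "physical",
    "spans",
    "economy",
    "fin_index",
    "initial",
    "start_age",
    "horizon",
)


def _check_keys(doc: Mapping[str, Any]) -> None:
    unknown = set(doc) - set(_SECTION_KEYS)
    if unknown:
        raise InvalidScenarioError(f"unknown top-level keys: {sorted(unknown)}")
    missing = [k for k in _REQUIRED if k not in doc]
    if missing:
        raise InvalidScenarioError(f"missing required keys: {missing}")
    for key, allowed in _SECTION_KEYS.items():
        if allowed is None or key not in doc:
            continue
        section = doc[key]
        if not isinstance(section, Mapping):
            raise InvalidScenarioError(f"{key}: must be a mapping of fields")
        bad = set(section) - allowed
        if bad:
            raise InvalidScenarioError(f"{key}: unknown keys {sorted(bad)}")


def scenario_from_dict(doc: Mapping[str, Any], *, normalise_theta: bool = False) -> Scenario:
    """Build a validated Scenario from a parsed configuration mapping.

    ``normalise_theta`` rescales the elasticities to sum to one; by default
    they must already satisfy the constant-returns normalisation.
    """
    _check_keys(doc)
    if doc["schema"] != SCHEMA:
        raise InvalidScenarioError(
            f"schema: expected {SCHEMA!r}, got {doc['schema']!r}"
        )
    theta = {k: float(v) for k, v in doc["elasticities"].items()}
    if normalise_theta:
        total = math.fsum(theta.values())
        if total <= 0.0:
            raise InvalidScenarioError("elasticities: cannot normalise a nonpositive sum")
        theta = {k: v / total for k, v in theta.items()}
    econ = dict(doc["economy"])
    if "r" in econ and "r_path" in econ:
        raise InvalidScenarioError("economy: give either 'r' or 'r_path', not both")
    r_path = econ.pop("r_path", None)
    r_const = econ.pop("r", 0.0)
    return Scenario(
        elasticities=ElasticityVector(theta),
        physical=PhysicalParams(**{k: float(v) for k, v in doc["physical"].items()}),
        spans=SpanParams(**{k: float(v) for k, v in doc["spans"].items()}),
        economy=EconomyParams(
            y_max=float(econ.pop("y_max")),
            eta=float(econ.pop("eta")),
            r_path=tuple(float(r) for r in r_path) if r_path is not None else float(r_const),
        ),
        fin_index=FinancialIndexParams(
            wealth_scale=float(doc["fin_index"]["wealth_scale"]),
            objective_weight=float(doc["fin_index"]["objective_weight"]),
        ),
        initial_P=float(doc["initial"]["p"]),
        initial_OF=float(doc["initial"]["of"]),
        initial_SF=float(doc["initial"]["sf"]),
        start_age=float(doc["start_age"]),
        horizon=int(doc["horizon"]),
        name=str(doc.get("name", "scenario")),
    )


def scenario_to_dict(scenario: Scenario) -> dict[str, Any]:
    """Serialise a Scenario back to its configuration mapping (round-trip
    inverse of ``scenario_from_dict``)."""
    econ: dict[str, Any] = {
        "y_max": scenario.economy.y_max,
        "eta": scenario.economy.eta,
    }
    if isinstance(scenario.economy.r_path, float):
        econ["r"] = scenario.economy.r_path
    else:
        econ["r_path"] = list(scenario.economy.r_path)
    p = scenario.physical
    s = scenario.spans
    return {
        "schema": SCHEMA,
        "name": scenario.name,
        "elasticities": dict(scenario.elasticities.theta),
        "physical": {
            "alpha_min": p.alpha_min,
            "alpha_max": p.alpha_max,
            "tau": p.tau,
            "t0": p.t0,
            "p_bar_h": p.p_bar_h,
            "kappa": p.kappa,
            "c0": p.c0,
        },
        "spans": {"h_max": s.h_max, "a": s.a, "t_min": s.t_min, "t_max": s.t_max, "b": s.b},
        "economy": econ,
        "fin_index": {
            "wealth_scale": scenario.fin_index.wealth_scale,
            "objective_weight": scenario.fin_index.objective_weight,
        },
        "initial": {"p": scenario.initial_P, "of": scenario.initial_OF, "sf": scenario.initial_SF},
        "start_age": scenario.start_age,
        "horizon": scenario.horizon,
    }


def load_scenario(source: str | os.PathLike | TextIO | Mapping[str, Any], **kwargs) -> Scenario:
    """Load and fully validate a Scenario from a YAML path, stream or
    already-parsed mapping."""
    if isinstance(source, Mapping):
        return scenario_from_dict(source, **kwargs)
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise InvalidScenarioError("scenario document must be a YAML mapping")
    return scenario_from_dict(doc, **kwargs)


def dump_scenario(scenario: Scenario, path: str | os.PathLike | None = None) -> str:
    """Serialise a scenario to YAML text, optionally writing it to disk."""
    text = yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def baseline_scenarios() -> dict[str, Scenario]:
    """Named baseline fixtures realising the model's qualitative regimes.

    - ``steady-midlife``: physical wellbeing stays comfortably above the
      health-span threshold for the whole horizon even without spending.
    - ``threshold-straddling``: zero health spending drops below the
      threshold mid-horizon while sustained spending stays above it (the
      option-value fixture).
    - ``post-healthspan``: starts below the threshold, so labour income is
      zero throughout and wealth grows by interest only.
    - ``symmetric-static``: symmetric elasticities; companion fixture for
      the linear-investment static-allocation oracle.
    """
    common_spans = {"h_max": 50.0, "a": 1.0, "t_min": 40.0, "t_max": 85.0, "b": 1.0}
    fin = {"wealth_scale": 250.0, "objective_weight": 0.5}
    scenarios = {
        "steady-midlife": {
            "schema": SCHEMA,
            "name": "steady-midlife",
            "elasticities": {"financial": 0.5, "physical": 0.5},
            "physical": {
                "alpha_min": 0.004,
                "alpha_max": 0.03,
                "tau": 0.12,
                "t0": 75.0,
                "p_bar_h": 0.3,
                "kappa": 0.05,
                "c0": 20.0,
            },
            "spans": common_spans,
            "economy": {"y_max": 80.0, "eta": 0.8, "r": 0.03},
            "fin_index": fin,
            "initial": {"p": 0.9, "of": 100.0, "sf": 0.7},
            "start_age": 30.0,
            "horizon": 40,
        },
        "threshold-straddling": {
            "schema": SCHEMA,
            "name": "threshold-straddling",
            "elasticities": {"financial": 0.5, "physical": 0.5},
            "physical": {
                "alpha_min": 0.04,
                "alpha_max": 0.16,
                "tau": 0.15,
                "t0": 60.0,
                "p_bar_h": 0.45,
                "kappa": 0.12,
                "c0": 25.0,
            },
            "spans": common_spans | {"h_max": 40.0},
            "economy": {"y_max": 120.0, "eta": 0.8, "r": 0.02},
            "fin_index": fin,
            "initial": {"p": 0.75, "of": 150.0, "sf": 0.7},
            "start_age": 45.0,
            "horizon": 25,
        },
        "post-healthspan": {
            "schema": SCHEMA,
            "name": "post-healthspan",
            "elasticities": {"financial": 0.6, "physical": 0.4},
            "physical": {
                "alpha_min": 0.02,
                "alpha_max": 0.1,
                "tau": 0.2,
                "t0": 80.0,
                "p_bar_h": 0.5,
                "kappa": 0.03,
                "c0": 30.0,
            },
            "spans": common_spans | {"h_max": 30.0},
            "economy": {"y_max": 60.0, "eta": 1.0, "r": 0.04},
            "fin_index": fin,
            "initial": {"p": 0.4, "of": 400.0, "sf": 0.6},
            "start_age": 70.0,
            "horizon": 20,
        },
        "symmetric-static": {
            "schema": SCHEMA,
            "name": "symmetric-static",
            "elasticities": {"financial": 0.5, "physical": 0.5},
            "physical": {
                "alpha_min": 0.01,
                "alpha_max": 0.05,
                "tau": 0.1,
                "t0": 70.0,
                "p_bar_h": 0.3,
                "kappa": 0.08,
                "c0": 15.0,
            },
            "spans": common_spans,
            "economy": {"y_max": 50.0, "eta": 1.0, "r": 0.03},
            "fin_index": fin,
            "initial": {"p": 0.8, "of": 200.0, "sf": 0.8},
            "start_age": 40.0,
            "horizon": 30,
        },
    }
    return {name: scenario_from_dict(doc) for name, doc in scenarios.items()}


def _fmt(value: float) -> str:
    # 12 significant digits keeps round-trips lossless at the 1e-9 level.
    return format(value, ".12g")


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as comma-separated text with a stable header."""
    if not traj.records:
        raise InvalidScenarioError("refusing to write an empty trajectory")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TRAJECTORY_FIELDS) + "\n")
        for rec in traj.records:
            fh.write(",".join(_fmt(rec[name]) for name in TRAJECTORY_FIELDS) + "\n")


def read_trajectory(path: str | os.PathLike) -> Trajectory:
    """Read a trajectory written by ``write_trajectory``."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if tuple(header) != TRAJECTORY_FIELDS:
            raise InvalidScenarioError(
                f"unexpected trajectory header {header!r}; expected {list(TRAJECTORY_FIELDS)}"
            )
        records = []
        for line in fh:
            if not line.strip():
                continue
            values = [float(v) for v in line.strip().split(",")]
            records.append(dict(zip(TRAJECTORY_FIELDS, values)))
    return Trajectory(records=tuple(records))


def write_table(rows: list[dict], fields: tuple[str, ...], path: str | os.PathLike) -> None:
    """Write generic tabular results (e.g. a policy-search surface) as CSV."""
    if not rows:
        raise InvalidScenarioError("refusing to write an empty table")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(fields) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(row[name]) for name in fields) + "\n")


def write_report(report: PropositionReport, path: str | os.PathLike) -> None:
    """Write a proposition report as structured YAML text."""
    doc = {
        "proposition": report.proposition,
        "passed": report.passed,
        "narrative": report.narrative,
        "checks": [
            {"label": c.label, "passed": c.passed, "details": _plain(c.details)}
            for c in report.checks
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _plain(obj: Any) -> Any:
    """Coerce numpy scalars / tuples into YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
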