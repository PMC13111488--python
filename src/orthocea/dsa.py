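"""Deterministic (scenario) sensitivity analysis.

One parameter is varied at a time while all others are held at base case:

- ``c``   — treatment cost, increased by 10% or 50%;
- ``sf``  — long-term failure rate after initial success, varied by
  10%, 50% and 90% in both directions;
- ``psf`` — long-term failure rate after initial partial success, same grid.

Rate variations are multiplicative on the failure probability with the
paired success probability absorbing the complement, and are clamped to
[0, 1]; multiplicative changes keep the whole +/-90% grid feasible for
every arm. By default a cost scenario also scales the follow-up
fixed-appliance cost (resource-use inflation hits the rescue treatment too);
this co-variation can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .costing import DiscountSpec
from .errors import ValidationError
from .model import (
    EFFECT_INITIAL_SUCCESS,
    TreatmentArm,
    evaluate_arm,
    find_baseline,
    validate_arm,
)

PARAM_COST = "c"
PARAM_FAIL_AFTER_SUCCESS = "sf"
PARAM_FAIL_AFTER_PARTIAL = "psf"
PARAMETERS = (PARAM_COST, PARAM_FAIL_AFTER_SUCCESS, PARAM_FAIL_AFTER_PARTIAL)

#: Relative cost increases of the stated scenario grid.
DEFAULT_COST_CHANGES = (0.10, 0.50)
#: Relative failure-rate changes, both directions.
DEFAULT_RATE_CHANGES = (-0.90, -0.50, -0.10, 0.10, 0.50, 0.90)


@dataclass(frozen=True)
class Scenario:
    """One one-at-a-time parameter variation.

    ``arm_scope`` is ``"all"`` or a single arm name.
    """

    parameter: str
    relative_change: float
    arm_scope: str = "all"

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValidationError(
                f"unknown parameter code {self.parameter!r}; expected one of {PARAMETERS}"
            )

    @property
    def label(self) -> str:
        return f"{self.parameter}{self.relative_change * 100:+.0f}%"


def default_scenarios() -> list[Scenario]:
    """The stated grid: cost +10/+50%, failure rates +/-10/50/90%."""
    scenarios = [Scenario(PARAM_COST, change) for change in DEFAULT_COST_CHANGES]
    for parameter in (PARAM_FAIL_AFTER_SUCCESS, PARAM_FAIL_AFTER_PARTIAL):
        scenarios.extend(Scenario(parameter, change) for change in DEFAULT_RATE_CHANGES)
    return scenarios


def _in_scope(arm: TreatmentArm, scenario: Scenario) -> bool:
    return scenario.arm_scope == "all" or scenario.arm_scope == arm.name


def apply_scenario(arm: TreatmentArm, scenario: Scenario) -> TreatmentArm:
    """Return `arm` with the scenario's single parameter varied.

    The identity scenario (relative change 0) returns the arm unchanged so
    the null scenario reproduces the base case bit for bit. A baseline arm
    is invariant under ``sf``/``psf`` (its long-term failure rate is 0).
    """
    validate_arm(arm)
    if scenario.relative_change == 0 or not _in_scope(arm, scenario):
        return arm
    factor = 1.0 + scenario.relative_change
    if scenario.parameter == PARAM_COST:
        return replace(arm, initial_cost=arm.initial_cost * factor)
    if scenario.parameter == PARAM_FAIL_AFTER_SUCCESS:
        failure = min(max((1 - arm.long_term.q_success_after_success) * factor, 0.0), 1.0)
        long_term = replace(arm.long_term, q_success_after_success=1 - failure)
    else:
        failure = min(max((1 - arm.long_term.q_success_after_partial) * factor, 0.0), 1.0)
        long_term = replace(arm.long_term, q_success_after_partial=1 - failure)
    return replace(arm, long_term=long_term)


@dataclass
class DsaResult:
    """Per-scenario per-arm expected costs with deltas against base case."""

    base_case: pd.DataFrame  # columns: arm, expected_cost
    table: pd.DataFrame  # scenario, parameter, relative_change, arm, expected_cost, delta_vs_base


def run_dsa(
    arms: list[TreatmentArm],
    timing: DiscountSpec,
    scenarios: list[Scenario] | None = None,
    scale_follow_up_cost: bool = True,
    effect_definition: str = EFFECT_INITIAL_SUCCESS,
) -> DsaResult:
    """Evaluate expected cost per arm under each one-at-a-time scenario.

    Parameters
    ----------
    scenarios
        Scenario list (default: the stated grid). An empty list yields a
        result holding only the base-case reference.
    scale_follow_up_cost
        When True (default), cost scenarios also inflate the follow-up
        fixed-appliance cost used for rescue pathways.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    baseline = find_baseline(arms)
    base_fixed = baseline.initial_cost

    base_rows = [
        {
            "arm": arm.name,
            "expected_cost": evaluate_arm(arm, timing, base_fixed, effect_definition).expected_cost,
        }
        for arm in arms
    ]
    base_case = pd.DataFrame(base_rows)
    base_lookup = dict(zip(base_case["arm"], base_case["expected_cost"]))

    rows = []
    for scenario in scenarios:
        for arm in arms:
            # A cost scenario inflates the in-scope arm's rescue fixed-appliance
            # cost too (default), so resource-use inflation is arm-consistent.
            fixed_cost = base_fixed
            if (
                scenario.parameter == PARAM_COST
                and scale_follow_up_cost
                and scenario.relative_change != 0
                and _in_scope(arm, scenario)
            ):
                fixed_cost = base_fixed * (1.0 + scenario.relative_change)
            varied = apply_scenario(arm, scenario)
            cost = evaluate_arm(varied, timing, fixed_cost, effect_definition).expected_cost
            rows.append(
                {
                    "scenario": scenario.label,
                    "parameter": scenario.parameter,
                    "relative_change": scenario.relative_change,
                    "arm": arm.name,
                    "expected_cost": cost,
                    "delta_vs_base": cost - base_lookup[arm.name],
                }
            )
    columns = ["scenario", "parameter", "relative_change", "arm", "expected_cost", "delta_vs_base"]
    table = pd.DataFrame(rows, columns=columns)
    return DsaResult(base_case=base_case, table=table)
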