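"""Incremental cost-effectiveness analysis against the fixed-appliance baseline.

Computes incremental cost and effect, places each strategy on the
cost-effectiveness plane, and derives cost-neutrality thresholds: the
minimum success rate at which a cheaper strategy matches the baseline's
value for money, defined as the ratio of expected costs. Explicit ICERs are
deliberately not computed — the plane coordinates and the cost-neutrality
margins are the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .model import ExpectedOutcome

NORTHEAST = "northeast"
NORTHWEST = "northwest"
SOUTHEAST = "southeast"
SOUTHWEST = "southwest"
BOUNDARY = "boundary"


@dataclass(frozen=True)
class IncrementalResult:
    """A strategy's position on the cost-effectiveness plane."""

    arm_name: str
    delta_cost: float
    delta_effect: float
    quadrant: str


@dataclass(frozen=True)
class RequiredEffectiveness:
    """Cost-neutrality threshold and the margin to it, in percentage points."""

    arm_name: str
    required: float
    observed: float

    @property
    def margin_points(self) -> float:
        return effectiveness_margin(self.observed, self.required)


def classify_quadrant(delta_cost: float, delta_effect: float) -> str:
    """Strict-sign quadrant of the cost-effectiveness plane.

    Any zero component maps to ``"boundary"``. Southwest (cheaper but less
    effective) is where all interceptive strategies land in the base case.
    """
    if delta_cost == 0 or delta_effect == 0:
        return BOUNDARY
    if delta_cost > 0:
        return NORTHEAST if delta_effect > 0 else NORTHWEST
    return SOUTHEAST if delta_effect > 0 else SOUTHWEST


def incremental(arm: ExpectedOutcome, baseline: ExpectedOutcome) -> IncrementalResult:
    """Incremental cost and effect of `arm` versus `baseline`."""
    delta_cost = arm.expected_cost - baseline.expected_cost
    delta_effect = arm.expected_effect - baseline.expected_effect
    return IncrementalResult(
        arm.arm_name, delta_cost, delta_effect, classify_quadrant(delta_cost, delta_effect)
    )


def min_required_effectiveness(arm_cost: float, baseline_cost: float) -> float:
    """Minimum success rate for value-for-money parity: cost ratio to baseline."""
    if baseline_cost <= 0:
        raise ValidationError(f"baseline_cost must be positive, got {baseline_cost}")
    return arm_cost / baseline_cost


def effectiveness_margin(observed: float, required: float) -> float:
    """Margin to cost-neutrality, ``(observed - required) * 100`` points.

    Negative margins are the success-rate increase (in points) a strategy
    would need to reach cost-neutrality with the baseline.
    """
    return (observed - required) * 100.0


def cea_table(
    outcomes: list[ExpectedOutcome], baseline_name: str | None = None
) -> pd.DataFrame:
    """Full base-case CEA table for a set of arms containing one baseline.

    The baseline is the arm named `baseline_name`; when omitted it is
    detected as the arm with expected effect exactly 1 (ties broken by the
    larger expected cost).

    Returns one row per arm with raw (unrounded) values: expected cost and
    effect, incremental cost/effect vs baseline, quadrant, required
    effectiveness, and margin in percentage points.
    """
    if not outcomes:
        raise ValidationError("no outcomes supplied")
    if baseline_name is not None:
        matches = [o for o in outcomes if o.arm_name == baseline_name]
        if not matches:
            raise ValidationError(f"baseline arm {baseline_name!r} not in outcomes")
        baseline = matches[0]
    else:
        candidates = [o for o in outcomes if o.expected_effect == 1]
        if not candidates:
            raise ValidationError("no baseline arm (expected effect 1) present")
        baseline = max(candidates, key=lambda o: o.expected_cost)

    rows = []
    for o in outcomes:
        inc = incremental(o, baseline)
        required = min_required_effectiveness(o.expected_cost, baseline.expected_cost)
        rows.append(
            {
                "arm": o.arm_name,
                "expected_cost": o.expected_cost,
                "incremental_cost": inc.delta_cost,
                "expected_effect": o.expected_effect,
                "incremental_effect": inc.delta_effect,
                "quadrant": inc.quadrant,
                "required_effectiveness": required,
                "margin_points": effectiveness_margin(o.expected_effect, required),
            }
        )
    return pd.DataFrame(rows)


def round_cea_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the reporting rounding rules: whole euros, 2-decimal effects and
    thresholds, whole percentage points."""
    out = table.copy()
    out["expected_cost"] = out["expected_cost"].round(0).astype(int)
    out["incremental_cost"] = out["incremental_cost"].round(0).astype(int)
    out["expected_effect"] = out["expected_effect"].round(2)
    out["incremental_effect"] = out["incremental_effect"].round(2)
    out["required_effectiveness"] = out["required_effectiveness"].round(2)
    out["margin_points"] = out["margin_points"].round(0).astype(int)
    return out
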