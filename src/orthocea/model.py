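"""Decision-tree model of interceptive orthodontic treatment.

Each strategy (arm) is a chance node with three initial outcomes — success,
partial success, failure — followed by a long-term stage in which initially
successful or partially successful treatments either remain stable or fail
and are rescued with comprehensive fixed-appliance therapy (assumed certain
to succeed). The comparator arm is fixed-appliance therapy itself, modelled
as a single certain-success pathway.

Evaluation is by exhaustive pathway enumeration: every root-to-leaf route
carries a probability, a discounted cost, and a binary effect indicator, and
expected cost/effect are the probability-weighted sums over pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .costing import DiscountSpec
from .errors import (
    BaselineConsistencyError,
    NegativeCostError,
    ProbabilityRangeError,
    SimplexViolationError,
    ValidationError,
)

#: Tolerance for probability triples summing to one.
SIMPLEX_TOL = 1e-9

#: Effect = indicator of initial full success (default; matches the base-case
#: reading of the reported expected effects).
EFFECT_INITIAL_SUCCESS = "initial-success"
#: Effect = long-term success without fixed-appliance rescue (alternative).
EFFECT_LONG_TERM = "long-term"

EFFECT_DEFINITIONS = (EFFECT_INITIAL_SUCCESS, EFFECT_LONG_TERM)


@dataclass(frozen=True)
class OutcomeProbabilities:
    """Initial-outcome distribution (success, partial success, failure)."""

    p_success: float
    p_partial: float
    p_failure: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_success, self.p_partial, self.p_failure])

    def validate(self) -> "OutcomeProbabilities":
        for name in ("p_success", "p_partial", "p_failure"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ProbabilityRangeError(f"{name} must be in [0, 1], got {p}")
        total = self.p_success + self.p_partial + self.p_failure
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise SimplexViolationError(
                f"outcome probabilities must sum to 1, got {total!r}"
            )
        return self


@dataclass(frozen=True)
class LongTermAssumptions:
    """Expert-set long-term stability probabilities.

    ``q_success_after_success`` is the probability that an initially
    successful treatment remains stable (no relapse); the complement needs
    fixed-appliance rescue. Likewise after initial partial success.
    """

    q_success_after_success: float = 0.75
    q_success_after_partial: float = 0.5

    def validate(self) -> "LongTermAssumptions":
        for name in ("q_success_after_success", "q_success_after_partial"):
            q = getattr(self, name)
            if not 0 <= q <= 1:
                raise ProbabilityRangeError(f"{name} must be in [0, 1], got {q}")
        return self


@dataclass(frozen=True)
class TreatmentArm:
    """One strategy: its direct cost and the tree's chance-node parameters."""

    name: str
    initial_cost: float
    outcomes: OutcomeProbabilities
    long_term: LongTermAssumptions = field(default_factory=LongTermAssumptions)
    is_baseline: bool = False


@dataclass(frozen=True)
class Pathway:
    """One root-to-leaf route: probability, discounted cost, effect indicator."""

    label: str
    probability: float
    cost: float
    effect: int


@dataclass(frozen=True)
class ExpectedOutcome:
    """Per-arm expected cost (EUR, discounted) and expected effect."""

    arm_name: str
    expected_cost: float
    expected_effect: float


def validate_arm(arm: TreatmentArm) -> TreatmentArm:
    """Check all arm invariants; return the arm unchanged if valid.

    Raises
    ------
    SimplexViolationError, ProbabilityRangeError, NegativeCostError,
    BaselineConsistencyError
        Naming the offending field.
    """
    arm.outcomes.validate()
    arm.long_term.validate()
    if arm.initial_cost < 0:
        raise NegativeCostError(
            f"initial_cost of arm {arm.name!r} must be non-negative, got {arm.initial_cost}"
        )
    if arm.is_baseline:
        if arm.outcomes.p_success != 1:
            raise BaselineConsistencyError(
                f"baseline arm {arm.name!r} must have p_success = 1, "
                f"got {arm.outcomes.p_success}"
            )
        if arm.long_term.q_success_after_success != 1:
            raise BaselineConsistencyError(
                f"baseline arm {arm.name!r} must have q_success_after_success = 1, "
                f"got {arm.long_term.q_success_after_success}"
            )
    return arm


def enumerate_pathways(
    arm: TreatmentArm,
    timing: DiscountSpec,
    fixed_cost: float,
    effect_definition: str = EFFECT_INITIAL_SUCCESS,
) -> list[Pathway]:
    """Enumerate every root-to-leaf pathway of one arm.

    For an interceptive arm this yields exactly five pathways (probability-0
    pathways are retained so pathway counts are stable):

    1. success -> long-term stable
    2. success -> relapse -> fixed appliance
    3. partial -> long-term stable
    4. partial -> failure -> fixed appliance
    5. failure -> fixed appliance

    The baseline arm yields the single certain pathway. Rescue pathways carry
    the fixed-appliance cost discounted to its start year.

    Parameters
    ----------
    arm
        A validated treatment arm.
    timing
        Discounting/timing convention; the arm's own cost is booked at year 0.
    fixed_cost
        Undiscounted cost of follow-up fixed-appliance therapy.
    effect_definition
        ``"initial-success"`` (default): effect 1 iff the initial outcome is
        full success. ``"long-term"``: effect 1 iff the pathway ends in
        long-term stability without fixed-appliance rescue.
    """
    validate_arm(arm)
    if fixed_cost < 0:
        raise NegativeCostError(f"fixed_cost must be non-negative, got {fixed_cost}")
    if effect_definition not in EFFECT_DEFINITIONS:
        raise ValidationError(
            f"effect_definition must be one of {EFFECT_DEFINITIONS}, got {effect_definition!r}"
        )

    if arm.is_baseline:
        return [Pathway("fixed", 1.0, arm.initial_cost, 1)]

    c0 = arm.initial_cost
    rescue_relapse = fixed_cost * timing.relapse_factor()
    rescue_follow_up = fixed_cost * timing.follow_up_factor()
    o, lt = arm.outcomes, arm.long_term

    if effect_definition == EFFECT_INITIAL_SUCCESS:
        effects = (1, 1, 0, 0, 0)
    else:  # long-term: stability without rescue counts as the effect
        effects = (1, 0, 1, 0, 0)

    return [
        Pathway(
            "success->stable",
            o.p_success * lt.q_success_after_success,
            c0,
            effects[0],
        ),
        Pathway(
            "success->relapse->fixed",
            o.p_success * (1 - lt.q_success_after_success),
            c0 + rescue_relapse,
            effects[1],
        ),
        Pathway(
            "partial->stable",
            o.p_partial * lt.q_success_after_partial,
            c0,
            effects[2],
        ),
        Pathway(
            "partial->failure->fixed",
            o.p_partial * (1 - lt.q_success_after_partial),
            c0 + rescue_follow_up,
            effects[3],
        ),
        Pathway("failure->fixed", o.p_failure, c0 + rescue_follow_up, effects[4]),
    ]


def _check_pathways(pathways: list[Pathway]) -> None:
    if not pathways:
        raise ValidationError("pathway list is empty")
    total = sum(p.probability for p in pathways)
    if abs(total - 1.0) > SIMPLEX_TOL:
        raise SimplexViolationError(f"pathway probabilities must sum to 1, got {total!r}")


def expected_cost(pathways: list[Pathway]) -> float:
    """Probability-weighted sum of pathway costs."""
    _check_pathways(pathways)
    return sum(p.probability * p.cost for p in pathways)


def expected_effect(pathways: list[Pathway]) -> float:
    """Probability-weighted sum of pathway effect indicators.

    Under the default effect definition this equals the arm's initial
    full-success probability (1 for the baseline).
    """
    _check_pathways(pathways)
    return sum(p.probability * p.effect for p in pathways)


def evaluate_arm(
    arm: TreatmentArm,
    timing: DiscountSpec,
    fixed_cost: float,
    effect_definition: str = EFFECT_INITIAL_SUCCESS,
) -> ExpectedOutcome:
    """Expected cost and effect of one arm by pathway enumeration."""
    pathways = enumerate_pathways(arm, timing, fixed_cost, effect_definition)
    return ExpectedOutcome(arm.name, expected_cost(pathways), expected_effect(pathways))


def find_baseline(arms: list[TreatmentArm]) -> TreatmentArm:
    """Return the unique baseline arm of `arms`."""
    baselines = [a for a in arms if a.is_baseline]
    if len(baselines) != 1:
        raise ValidationError(
            f"expected exactly one baseline arm, found {len(baselines)}"
        )
    return baselines[0]


def evaluate_arms(
    arms: list[TreatmentArm],
    timing: DiscountSpec,
    effect_definition: str = EFFECT_INITIAL_SUCCESS,
) -> list[ExpectedOutcome]:
    """Evaluate every arm, using the baseline arm's cost as the rescue cost."""
    baseline = find_baseline(arms)
    return [
        evaluate_arm(arm, timing, baseline.initial_cost, effect_definition)
        for arm in arms
    ]


def with_outcomes(arm: TreatmentArm, outcomes: OutcomeProbabilities) -> TreatmentArm:
    """Copy of `arm` with a replaced initial-outcome distribution."""
    return replace(arm, outcomes=outcomes)
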