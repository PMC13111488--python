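import numpy as np
import pytest

from orthocea import (
    DiscountSpec,
    LongTermAssumptions,
    OutcomeProbabilities,
    TreatmentArm,
    load_arms,
)


@pytest.fixture(scope="session")
def arms():
    """The five packaged strategies (baseline fixed appliance + four interceptive)."""
    return load_arms()


@pytest.fixture(scope="session")
def timing():
    return DiscountSpec()


@pytest.fixture(scope="session")
def baseline(arms):
    return next(a for a in arms if a.is_baseline)


@pytest.fixture(scope="session")
def quad_helix(arms):
    return next(a for a in arms if a.name == "quad_helix")


def random_arm(rng: np.random.Generator, name: str = "random") -> TreatmentArm:
    """A valid random interceptive arm (uniform simplex outcomes, uniform costs)."""
    p = rng.dirichlet([1.0, 1.0, 1.0])
    return TreatmentArm(
        name=name,
        initial_cost=float(rng.uniform(0, 3000)),
        outcomes=OutcomeProbabilities(*p),
        long_term=LongTermAssumptions(float(rng.uniform(0, 1)), float(rng.uniform(0, 1))),
    )


def joint_distribution_cost(arm, timing, fixed_cost):
    """Independent oracle: expected cost by materialising the full joint
    distribution over (initial outcome x long-term outcome) and summing cost
    mass, without touching the pathway enumeration."""
    o, lt = arm.outcomes, arm.long_term
    if arm.is_baseline:
        return arm.initial_cost
    rescue_relapse = fixed_cost * (1 + timing.annual_rate) ** (-timing.relapse_start_year)
    rescue_follow = fixed_cost * (1 + timing.annual_rate) ** (-timing.follow_up_start_year)
    joint = {
        ("success", "stable"): (o.p_success * lt.q_success_after_success, arm.initial_cost),
        ("success", "fail"): (
            o.p_success * (1 - lt.q_success_after_success),
            arm.initial_cost + rescue_relapse,
        ),
        ("partial", "stable"): (o.p_partial * lt.q_success_after_partial, arm.initial_cost),
        ("partial", "fail"): (
            o.p_partial * (1 - lt.q_success_after_partial),
            arm.initial_cost + rescue_follow,
        ),
        ("failure", "fail"): (o.p_failure, arm.initial_cost + rescue_follow),
    }
    return sum(prob * cost for prob, cost in joint.values())
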