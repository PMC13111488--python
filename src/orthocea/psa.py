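"""Probabilistic sensitivity analysis with Dirichlet-distributed outcomes.

Each interceptive arm's initial-outcome triple (success, partial, failure)
is drawn from a Dirichlet distribution centred on the observed proportions.
The concentration is calibrated in closed form so that the marginal standard
deviation of the success component hits a target (default 0.05, i.e. about
95% of draws within +/-0.10 of the observed success rate): each Dirichlet
component is marginally Beta(a_i, a0 - a_i) with variance p_i (1 - p_i) /
(a0 + 1), so

    a0 = p (1 - p) / sd^2 - 1.

Draws are propagated through the decision tree; the baseline arm, assumed
to have a certain effect, is not varied. Long-term stability probabilities
are held fixed by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import classify_quadrant, min_required_effectiveness
from .costing import DiscountSpec
from .errors import CalibrationError, ValidationError
from .model import (
    EFFECT_INITIAL_SUCCESS,
    ExpectedOutcome,
    OutcomeProbabilities,
    TreatmentArm,
    enumerate_pathways,
    evaluate_arm,
    find_baseline,
    validate_arm,
)

_COMPONENTS = {"success": 0, "partial": 1, "failure": 2}


@dataclass(frozen=True)
class DirichletSpec:
    """Calibrated Dirichlet distribution over an outcome triple."""

    center: OutcomeProbabilities
    concentration: float
    alpha: tuple[float, float, float]
    calibrated_sd: float


def calibrate_dirichlet(
    center: OutcomeProbabilities,
    target_sd: float = 0.05,
    component: str = "success",
) -> DirichletSpec:
    """Choose the Dirichlet concentration hitting `target_sd` on one component.

    Raises
    ------
    CalibrationError
        If the centre component is degenerate (0 or 1; such an arm should be
        held fixed, not varied) or the dispersion target is infeasible
        (``target_sd**2 >= p * (1 - p)``).
    """
    center.validate()
    if component not in _COMPONENTS:
        raise ValidationError(f"component must be one of {tuple(_COMPONENTS)}")
    p = center.as_array()[_COMPONENTS[component]]
    if not 0 < p < 1:
        raise CalibrationError(
            f"centre {component} probability is degenerate ({p}); exclude this "
            "arm from probabilistic variation instead of calibrating it"
        )
    if target_sd <= 0:
        raise CalibrationError(f"target_sd must be positive, got {target_sd}")
    a0 = p * (1 - p) / target_sd**2 - 1
    # a0 -> 0 as target_sd approaches sqrt(p(1-p)); treat the boundary as
    # infeasible with a small guard against floating-point round-off
    if a0 <= 1e-9:
        raise CalibrationError(
            f"target_sd {target_sd} is infeasible for centre {p}: requires "
            f"target_sd < sqrt(p(1-p)) = {math.sqrt(p * (1 - p)):.4f}"
        )
    alpha = tuple(a0 * center.as_array())
    return DirichletSpec(center, a0, alpha, target_sd)


def sample_outcome_matrix(
    spec: DirichletSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` outcome triples, shape ``(n, 3)``, rows on the simplex."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    return rng.dirichlet(spec.alpha, size=n)


def sample_outcomes(spec: DirichletSpec, rng: np.random.Generator) -> OutcomeProbabilities:
    """Draw a single outcome triple."""
    s, p, f = sample_outcome_matrix(spec, 1, rng)[0]
    return OutcomeProbabilities(s, p, f)


@dataclass
class PsaResult:
    """Monte Carlo draws of (expected cost, expected effect) per arm.

    ``draws`` maps each varied (non-baseline) arm name to a DataFrame with
    columns ``cost``, ``effect``, ``p_success``, ``p_partial``, ``p_failure``,
    one row per iteration. The baseline is carried as its fixed base-case
    outcome.
    """

    n_iterations: int
    seed: int
    baseline: ExpectedOutcome
    base_case: dict[str, ExpectedOutcome]
    draws: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Per-arm mean cost/effect with Monte Carlo standard errors.

        The baseline row has zero standard error (it is not varied).
        """
        rows = [
            {
                "arm": self.baseline.arm_name,
                "mean_cost": self.baseline.expected_cost,
                "se_cost": 0.0,
                "mean_effect": self.baseline.expected_effect,
                "se_effect": 0.0,
            }
        ]
        for name, frame in self.draws.items():
            n = len(frame)
            rows.append(
                {
                    "arm": name,
                    "mean_cost": frame["cost"].mean(),
                    "se_cost": frame["cost"].std(ddof=1) / math.sqrt(n),
                    "mean_effect": frame["effect"].mean(),
                    "se_effect": frame["effect"].std(ddof=1) / math.sqrt(n),
                }
            )
        return pd.DataFrame(rows)


def _propagate(
    arm: TreatmentArm,
    triples: np.ndarray,
    timing: DiscountSpec,
    fixed_cost: float,
    effect_definition: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised tree evaluation for a matrix of outcome triples.

    Pathway costs and effect indicators are fixed by the arm's cost structure;
    only the pathway probabilities depend on the sampled triple, linearly. The
    map from (p_success, p_partial, p_failure) to the five pathway
    probabilities is taken from the enumerated tree itself so that the Monte
    Carlo propagation and the deterministic evaluation share one structure.
    """
    pathways = enumerate_pathways(arm, timing, fixed_cost, effect_definition)
    costs = np.array([p.cost for p in pathways])
    effects = np.array([float(p.effect) for p in pathways])
    q_ss = arm.long_term.q_success_after_success
    q_sp = arm.long_term.q_success_after_partial
    # rows: initial outcome; columns: the five pathways
    transfer = np.array(
        [
            [q_ss, 1 - q_ss, 0, 0, 0],
            [0, 0, q_sp, 1 - q_sp, 0],
            [0, 0, 0, 0, 1],
        ]
    )
    path_probs = triples @ transfer
    return path_probs @ costs, path_probs @ effects


def run_psa(
    arms: list[TreatmentArm],
    timing: DiscountSpec,
    n_iterations: int = 10_000,
    seed: int = 0,
    target_sd: float = 0.05,
    effect_definition: str = EFFECT_INITIAL_SUCCESS,
) -> PsaResult:
    """Monte Carlo propagation of outcome-probability uncertainty.

    Every non-baseline arm's outcome triple is redrawn `n_iterations` times
    from its calibrated Dirichlet distribution and pushed through the tree.
    Per-arm random substreams are derived from ``(seed, arm position)``, so
    appending an arm leaves earlier arms' draws unchanged, and identical
    seeds give bitwise-identical results.
    """
    if n_iterations < 1:
        raise ValidationError(f"n_iterations must be >= 1, got {n_iterations}")
    for arm in arms:
        validate_arm(arm)
    baseline_arm = find_baseline(arms)
    fixed_cost = baseline_arm.initial_cost

    base_case = {
        arm.name: evaluate_arm(arm, timing, fixed_cost, effect_definition)
        for arm in arms
    }
    result = PsaResult(
        n_iterations=n_iterations,
        seed=seed,
        baseline=base_case[baseline_arm.name],
        base_case=base_case,
    )
    for index, arm in enumerate(arms):
        if arm.is_baseline:
            continue
        spec = calibrate_dirichlet(arm.outcomes, target_sd)
        rng = np.random.default_rng([seed, index])
        triples = sample_outcome_matrix(spec, n_iterations, rng)
        costs, effects = _propagate(arm, triples, timing, fixed_cost, effect_definition)
        result.draws[arm.name] = pd.DataFrame(
            {
                "cost": costs,
                "effect": effects,
                "p_success": triples[:, 0],
                "p_partial": triples[:, 1],
                "p_failure": triples[:, 2],
            }
        )
    return result


def ce_scatter(result: PsaResult, baseline: ExpectedOutcome | None = None) -> pd.DataFrame:
    """Draw-level cost-effectiveness-plane coordinates.

    One row per draw per varied arm (the baseline, not being varied, is
    absent), with the per-arm means appended as flagged rows (``is_mean``,
    ``draw = -1``). ``mean_required_effectiveness`` is the per-arm mean of
    the draw-wise cost-neutrality threshold — the vertical reference line of
    the plane plot.
    """
    baseline = baseline or result.baseline
    frames = []
    for name, frame in result.draws.items():
        delta_cost = frame["cost"].to_numpy() - baseline.expected_cost
        delta_effect = frame["effect"].to_numpy() - baseline.expected_effect
        required = frame["cost"].to_numpy() / baseline.expected_cost
        mean_required = min_required_effectiveness(
            frame["cost"].mean(), baseline.expected_cost
        )
        per_arm = pd.DataFrame(
            {
                "arm": name,
                "draw": np.arange(len(frame)),
                "delta_cost": delta_cost,
                "delta_effect": delta_effect,
                "required_effectiveness": required,
                "mean_required_effectiveness": mean_required,
                "is_mean": False,
            }
        )
        mean_row = pd.DataFrame(
            {
                "arm": [name],
                "draw": [-1],
                "delta_cost": [delta_cost.mean()],
                "delta_effect": [delta_effect.mean()],
                "required_effectiveness": [mean_required],
                "mean_required_effectiveness": [mean_required],
                "is_mean": [True],
            }
        )
        frames.append(pd.concat([per_arm, mean_row], ignore_index=True))
    if not frames:
        return pd.DataFrame(
            columns=[
                "arm",
                "draw",
                "delta_cost",
                "delta_effect",
                "required_effectiveness",
                "mean_required_effectiveness",
                "is_mean",
            ]
        )
    scatter = pd.concat(frames, ignore_index=True)
    scatter["quadrant"] = [
        classify_quadrant(dc, de)
        for dc, de in zip(scatter["delta_cost"], scatter["delta_effect"])
    ]
    return scatter


def cost_draw_frame(result: PsaResult) -> pd.DataFrame:
    """Long-format expected-cost draws (arm, draw, cost), histogram-ready."""
    frames = [
        pd.DataFrame({"arm": name, "draw": np.arange(len(f)), "cost": f["cost"]})
        for name, f in result.draws.items()
    ]
    if not frames:
        return pd.DataFrame(columns=["arm", "draw", "cost"])
    return pd.concat(frames, ignore_index=True)
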