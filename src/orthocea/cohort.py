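"""Synthetic registry cohort: patient-level records with the statistical
structure the decision model assumes.

The real regional registry is access-restricted, so this module generates a
stand-in: per arm, each patient's initial outcome is an independent
multinomial draw at configurable true proportions, with visit counts from a
shifted Poisson distribution (minimum one visit) and treatment durations
from a log-normal. The visit and duration distributions are inventions of
the generator — the source registry reports only that durations and
appointment counts were extracted from it — and exist so that downstream
resource-use analyses have realistic-looking inputs; the decision model
itself consumes only the outcome proportions.

Cohorts are plain pandas DataFrames whose columns are the record schema
(`COHORT_COLUMNS`); `estimate_rates` recovers a Table-1-style summary with
Wilson confidence intervals, and `cohort_to_params` turns a summary plus a
cost table into model-ready treatment arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError
from .model import LongTermAssumptions, OutcomeProbabilities, TreatmentArm, validate_arm

OUTCOMES = ("success", "partial", "failure")
COHORT_COLUMNS = ("patient_id", "arm", "outcome", "n_visits", "duration_months")

#: Generator defaults: mean visits / mean+SD duration (months). Interceptive
#: appliances run about two years with sparse review visits; the comprehensive
#: fixed appliance is a two-year treatment with frequent adjustment visits.
DEFAULT_VISIT_MEAN = {"interceptive": 6.0, "baseline": 20.0}
DEFAULT_DURATION = {"interceptive": (18.0, 8.0), "baseline": (24.0, 6.0)}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a log-normal with the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def generate_cohort(
    arm_sizes: Mapping[str, int],
    true_probs: Mapping[str, OutcomeProbabilities],
    visit_params: Mapping[str, float] | None = None,
    duration_params: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    baseline_arms: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Draw a synthetic patient-level cohort.

    Parameters
    ----------
    arm_sizes
        Patients per arm (zero allowed).
    true_probs
        True outcome proportions per arm; every named arm must be present.
    visit_params
        Optional per-arm mean visit count (visits are ``1 + Poisson(mean-1)``).
    duration_params
        Optional per-arm ``(mean, sd)`` of log-normal duration in months.
    seed
        Master seed; the cohort is a deterministic function of it.
    baseline_arms
        Arm names that take the comprehensive-treatment resource-use defaults.
    """
    rng = np.random.default_rng(seed)
    visit_params = dict(visit_params or {})
    duration_params = dict(duration_params or {})

    frames = []
    for arm, size in arm_sizes.items():
        if size < 0:
            raise ValidationError(f"arm size must be non-negative, got {size} for {arm!r}")
        if arm not in true_probs:
            raise ValidationError(f"no outcome probabilities supplied for arm {arm!r}")
        probs = true_probs[arm].validate()
        kind = "baseline" if arm in baseline_arms else "interceptive"
        visit_mean = visit_params.get(arm, DEFAULT_VISIT_MEAN[kind])
        dur_mean, dur_sd = duration_params.get(arm, DEFAULT_DURATION[kind])
        if visit_mean < 1:
            raise ValidationError(f"mean visit count must be >= 1, got {visit_mean}")

        outcome_idx = rng.choice(3, size=size, p=probs.as_array())
        visits = 1 + rng.poisson(visit_mean - 1.0, size=size)
        mu, sigma = _lognormal_params(dur_mean, dur_sd)
        durations = rng.lognormal(mu, sigma, size=size)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"{arm}-{i:05d}" for i in range(size)],
                    "arm": arm,
                    "outcome": np.array(OUTCOMES)[outcome_idx],
                    "n_visits": visits,
                    "duration_months": durations,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))
    return pd.concat(frames, ignore_index=True)


@dataclass
class CohortSummary:
    """Per-arm outcome counts, proportions, and resource-use means.

    ``table`` is indexed by arm with columns ``n``, ``n_success``,
    ``n_partial``, ``n_failure``, ``p_success``, ``p_partial``, ``p_failure``,
    ``ci_low``/``ci_high`` (Wilson 95% interval on the success proportion),
    ``mean_visits``, ``mean_duration_months``.
    """

    table: pd.DataFrame = field(repr=False)

    def probs(self, arm: str) -> OutcomeProbabilities:
        row = self.table.loc[arm]
        return OutcomeProbabilities(row["p_success"], row["p_partial"], row["p_failure"])

    @property
    def arms(self) -> list[str]:
        return list(self.table.index)


def _summary_from_counts_frame(counts: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for _, row in counts.iterrows():
        n = int(row["n"])
        if n <= 0:
            raise ValidationError(f"arm {row['arm']!r} has no records")
        n_s, n_p, n_f = int(row["success"]), int(row["partial"]), int(row["failure"])
        if n_s + n_p + n_f != n:
            raise ValidationError(
                f"outcome counts for arm {row['arm']!r} sum to {n_s + n_p + n_f}, expected {n}"
            )
        low, high = proportion_confint(n_s, n, alpha=0.05, method="wilson")
        rows[row["arm"]] = {
            "n": n,
            "n_success": n_s,
            "n_partial": n_p,
            "n_failure": n_f,
            "p_success": n_s / n,
            "p_partial": n_p / n,
            "p_failure": n_f / n,
            "ci_low": low,
            "ci_high": high,
            "mean_visits": row.get("mean_visits", np.nan),
            "mean_duration_months": row.get("mean_duration_months", np.nan),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "arm"
    return table


def summary_from_counts(counts: pd.DataFrame) -> CohortSummary:
    """Build a summary directly from aggregated counts.

    `counts` needs columns ``arm``, ``n``, ``success``, ``partial``,
    ``failure`` — the shape of the published outcome table.
    """
    return CohortSummary(_summary_from_counts_frame(counts))


def estimate_rates(cohort: pd.DataFrame) -> CohortSummary:
    """Estimate per-arm outcome proportions from a patient-level cohort."""
    if cohort.empty:
        raise ValidationError("cohort is empty")
    records = []
    for arm, group in cohort.groupby("arm", sort=False):
        counts = group["outcome"].value_counts()
        records.append(
            {
                "arm": arm,
                "n": len(group),
                "success": int(counts.get("success", 0)),
                "partial": int(counts.get("partial", 0)),
                "failure": int(counts.get("failure", 0)),
                "mean_visits": group["n_visits"].mean(),
                "mean_duration_months": group["duration_months"].mean(),
            }
        )
    return CohortSummary(_summary_from_counts_frame(pd.DataFrame(records)))


def cohort_to_params(
    summary: CohortSummary,
    cost_table: pd.DataFrame,
    long_term: LongTermAssumptions | None = None,
) -> list[TreatmentArm]:
    """Turn estimated rates plus a cost table into model-ready arms.

    `cost_table` needs columns ``arm``, ``cost_eur`` and ``is_baseline``.
    Interceptive arms take `long_term` (default 0.75 / 0.5); baseline arms
    are modelled as certain long-term success.
    """
    long_term = long_term or LongTermAssumptions()
    costs = cost_table.set_index("arm")
    arms = []
    for arm_name in summary.arms:
        if arm_name not in costs.index:
            raise ValidationError(f"no cost entry for arm {arm_name!r}")
        row = costs.loc[arm_name]
        is_baseline = bool(row["is_baseline"])
        arm = TreatmentArm(
            name=arm_name,
            initial_cost=float(row["cost_eur"]),
            outcomes=summary.probs(arm_name),
            long_term=LongTermAssumptions(1.0, 0.0) if is_baseline else long_term,
            is_baseline=is_baseline,
        )
        arms.append(validate_arm(arm))
    return arms
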