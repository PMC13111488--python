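"""Reading the delimited parameter tables and packaged fixtures.

Three fixtures ship with the package, mirroring the published input tables:

- ``table1_counts.csv``   — per-arm outcome counts from the registry cohort
  (the removable-plate failure count is 135 = N - success - partial, the
  value consistent with the published percentages);
- ``table2_params.csv``   — per-arm costs and model probabilities;
- ``table3_expected.csv`` — the published expected costs/effects, used to
  validate the CEA layer independently of the cost-timing convention.
"""

from __future__ import annotations

from importlib.resources import as_file, files
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .model import (
    ExpectedOutcome,
    LongTermAssumptions,
    OutcomeProbabilities,
    TreatmentArm,
    validate_arm,
)

_FIXTURES = {
    "table1": "table1_counts.csv",
    "table2": "table2_params.csv",
    "table3": "table3_expected.csv",
}


def _read(path: str | Path | None, fixture: str) -> pd.DataFrame:
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"input table not found: {path}")
        return pd.read_csv(path)
    resource = files("orthocea").joinpath("data", _FIXTURES[fixture])
    with as_file(resource) as fixture_path:
        return pd.read_csv(fixture_path)


def load_arm_table(path: str | Path | None = None) -> pd.DataFrame:
    """Arm parameter table (columns of ``table2_params.csv``)."""
    table = _read(path, "table2")
    required = {
        "arm",
        "cost_eur",
        "p_success",
        "p_partial",
        "p_failure",
        "q_success_after_success",
        "q_success_after_partial",
        "is_baseline",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"arm table is missing columns: {sorted(missing)}")
    return table


def load_arms(path: str | Path | None = None) -> list[TreatmentArm]:
    """Validated treatment arms from a parameter table (default: fixture)."""
    table = load_arm_table(path)
    arms = []
    for _, row in table.iterrows():
        arm = TreatmentArm(
            name=str(row["arm"]),
            initial_cost=float(row["cost_eur"]),
            outcomes=OutcomeProbabilities(
                float(row["p_success"]), float(row["p_partial"]), float(row["p_failure"])
            ),
            long_term=LongTermAssumptions(
                float(row["q_success_after_success"]),
                float(row["q_success_after_partial"]),
            ),
            is_baseline=bool(row["is_baseline"]),
        )
        arms.append(validate_arm(arm))
    return arms


def load_expected_outcomes(path: str | Path | None = None) -> list[ExpectedOutcome]:
    """Externally supplied expected costs/effects (default: published values)."""
    table = _read(path, "table3")
    missing = {"arm", "expected_cost_eur", "expected_effect"} - set(table.columns)
    if missing:
        raise ValidationError(f"expected-outcome table is missing columns: {sorted(missing)}")
    return [
        ExpectedOutcome(str(r["arm"]), float(r["expected_cost_eur"]), float(r["expected_effect"]))
        for _, r in table.iterrows()
    ]


def load_cohort_counts(path: str | Path | None = None) -> pd.DataFrame:
    """Per-arm outcome counts (default: the registry-cohort fixture)."""
    table = _read(path, "table1")
    missing = {"arm", "n", "success", "partial", "failure"} - set(table.columns)
    if missing:
        raise ValidationError(f"counts table is missing columns: {sorted(missing)}")
    return table


def counts_to_probs(counts: pd.DataFrame) -> dict[str, OutcomeProbabilities]:
    """Exact per-arm outcome proportions from a counts table."""
    probs = {}
    for _, row in counts.iterrows():
        n = int(row["n"])
        if n <= 0:
            raise ValidationError(f"arm {row['arm']!r} has n = {n}")
        probs[str(row["arm"])] = OutcomeProbabilities(
            row["success"] / n, row["partial"] / n, row["failure"] / n
        )
    return probs
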