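"""Cost assembly, annual discounting, and currency conversion.

Costs are handled from a health-care payer perspective: direct costs only
(materials, professional fees, overhead, and chair time). Each treatment's
full cost is booked at its start year and discounted at a constant annual
rate; there is no within-treatment spreading because the model operates at
whole-year resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NegativeCostError, ValidationError

#: Average 2024 exchange rate, EUR per SEK.
DEFAULT_SEK_TO_EUR = 0.0875


def discount_factor(year: float, rate: float) -> float:
    """Present-value factor ``(1 + rate) ** -year`` for a cost incurred at `year`.

    Parameters
    ----------
    year
        Years after model start (non-negative; fractional years allowed).
    rate
        Annual discount rate as a proportion, ``0 <= rate < 1``.
    """
    if year < 0:
        raise ValidationError(f"year must be non-negative, got {year}")
    if not 0 <= rate < 1:
        raise ValidationError(f"annual_rate must be in [0, 1), got {rate}")
    return (1.0 + rate) ** (-year)


def present_value(amount: float, year: float, rate: float) -> float:
    """Discount `amount` incurred at `year` back to model start."""
    if amount < 0:
        raise NegativeCostError(f"amount must be non-negative, got {amount}")
    return amount * discount_factor(year, rate)


def sek_to_eur(amount_sek: float, rate: float = DEFAULT_SEK_TO_EUR) -> float:
    """Convert Swedish krona to euro at `rate` EUR per SEK (default 0.0875)."""
    if amount_sek < 0:
        raise NegativeCostError(f"amount_sek must be non-negative, got {amount_sek}")
    return amount_sek * rate


@dataclass(frozen=True)
class CostComponents:
    """Resource-use breakdown of one treatment's direct cost.

    Personnel cost is ``n_visits * chair_time_per_visit * personnel_rate``;
    the remaining fields are booked as-is.
    """

    materials: float = 0.0
    professional_fees: float = 0.0
    overhead: float = 0.0
    n_visits: int = 0
    chair_time_per_visit: float = 0.0  # minutes
    personnel_rate: float = 0.0  # EUR per minute

    def __post_init__(self) -> None:
        for field in (
            "materials",
            "professional_fees",
            "overhead",
            "n_visits",
            "chair_time_per_visit",
            "personnel_rate",
        ):
            value = getattr(self, field)
            if value < 0:
                raise NegativeCostError(f"{field} must be non-negative, got {value}")


def assemble_cost(components: CostComponents) -> float:
    """Total direct cost: fixed components plus chair-time personnel cost."""
    return (
        components.materials
        + components.professional_fees
        + components.overhead
        + components.n_visits * components.chair_time_per_visit * components.personnel_rate
    )


@dataclass(frozen=True)
class DiscountSpec:
    """Timing and discounting convention of the decision model.

    Attributes
    ----------
    annual_rate
        Annual discount rate (default 0.03).
    horizon_years
        Model horizon (default 8 years, covering interceptive treatment at
        roughly ages 8-10 and any follow-up fixed appliance at 14-16).
    follow_up_start_year
        Year at which follow-up fixed-appliance therapy starts for initial
        failures and for partial successes that later fail (default 5).
    relapse_start_year
        Year at which fixed-appliance therapy starts after relapse of an
        initially successful treatment (default: same as follow-up).
    """

    annual_rate: float = 0.03
    horizon_years: float = 8.0
    follow_up_start_year: float = 5.0
    relapse_start_year: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.annual_rate < 1:
            raise ValidationError(f"annual_rate must be in [0, 1), got {self.annual_rate}")
        if self.horizon_years < 0:
            raise ValidationError("horizon_years must be non-negative")
        if not 0 <= self.follow_up_start_year <= self.horizon_years:
            raise ValidationError(
                "follow_up_start_year must lie within [0, horizon_years], "
                f"got {self.follow_up_start_year}"
            )
        if not 0 <= self.relapse_start_year <= self.horizon_years:
            raise ValidationError(
                "relapse_start_year must lie within [0, horizon_years], "
                f"got {self.relapse_start_year}"
            )

    def follow_up_factor(self) -> float:
        return discount_factor(self.follow_up_start_year, self.annual_rate)

    def relapse_factor(self) -> float:
        return discount_factor(self.relapse_start_year, self.annual_rate)
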