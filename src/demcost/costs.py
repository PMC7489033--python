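"""Per-state annual cost schedule for outpatient dementia care.

Cost components per person and year, by severity state:

1. treatment  - flat outpatient treatment cost, independent of severity;
2. benefit    - the public long-term care benefit (a tiered, non-means-
                tested monthly allowance), annualized;
3. informal   - informal-care hours priced at an hourly wage: the average
                gross market wage including employer on-costs
                (opportunity-cost valuation) for mild and moderate
                dementia, a professional caregiver's wage (replacement-
                cost valuation) for severe dementia;
4. indirect   - informal minus benefit, so the part of informal care the
                public allowance already covers is not double-counted.

Total per-person cost is treatment + benefit + indirect, which equals
treatment + informal algebraically; both routes are computed and
cross-checked.  Schedule cells are exact decimals (cent precision);
floating point enters only in the projection stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Literal, Mapping, Union

import pandas as pd

from .errors import ConfigurationError, DomainError
from .ingest import STATES, SeverityState

__all__ = [
    "CostParameters",
    "WageLoadings",
    "CostSchedule",
    "hourly_rate_with_oncosts",
    "annual_benefit",
    "annual_informal",
    "annual_indirect",
    "build_cost_schedule",
]

logger = logging.getLogger(__name__)

Numeric = Union[int, float, str, Decimal]

CENT = Decimal("0.01")


def _dec(value: Numeric) -> Decimal:
    """Convert via str so float literals keep their printed value."""
    return value if isinstance(value, Decimal) else Decimal(str(value))


def _per_state(values: Mapping[Union[str, SeverityState], Numeric]) -> dict[SeverityState, Decimal]:
    out: dict[SeverityState, Decimal] = {}
    for key, value in values.items():
        state = key if isinstance(key, SeverityState) else SeverityState[str(key).upper()]
        out[state] = _dec(value)
    if set(out) != set(STATES):
        raise ConfigurationError("per-state values must cover mild, moderate and severe")
    return out


@dataclass(frozen=True)
class WageLoadings:
    """Employer on-costs loaded onto a gross hourly wage.

    Defaults are the 2017/18 Austrian figures: 25 vacation days, 11.2
    public holidays, 6.3 average sickness-leave days, and a 22.51% employer
    social-security contribution.
    """

    vacation_days: float = 25.0
    public_holiday_days: float = 11.2
    sickness_days: float = 6.3
    employer_social_security: float = 0.2251

    def __post_init__(self) -> None:
        if min(self.vacation_days, self.public_holiday_days, self.sickness_days) < 0:
            raise ConfigurationError("absence days must be non-negative")
        if not 0.0 <= self.employer_social_security < 1.0:
            raise ConfigurationError("employer social security must lie in [0, 1)")


@dataclass(frozen=True)
class CostParameters:
    """All cost inputs of the model (2018 price year, EUR).

    ``severe_valuation`` selects which hourly wage prices the informal-care
    hours of severe dementia; the default (replacement) reflects that severe
    care requires a registered nurse.
    """

    treatment_annual: Decimal = Decimal("3533.74")
    benefit_monthly: Mapping[SeverityState, Decimal] = field(
        default_factory=lambda: {
            SeverityState.MILD: Decimal("564.70"),
            SeverityState.MODERATE: Decimal("920.30"),
            SeverityState.SEVERE: Decimal("1487.50"),
        }
    )
    care_hours_monthly: Mapping[SeverityState, Decimal] = field(
        default_factory=lambda: {
            SeverityState.MILD: Decimal("140"),
            SeverityState.MODERATE: Decimal("180"),
            SeverityState.SEVERE: Decimal("180"),
        }
    )
    wage_opportunity: Decimal = Decimal("23.77")
    wage_replacement: Decimal = Decimal("32.29")
    severe_valuation: Literal["replacement", "opportunity"] = "replacement"
    discount_rate: float = 0.05
    clamp_negative_indirect: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment_annual", _dec(self.treatment_annual))
        object.__setattr__(self, "benefit_monthly", _per_state(self.benefit_monthly))
        object.__setattr__(self, "care_hours_monthly", _per_state(self.care_hours_monthly))
        object.__setattr__(self, "wage_opportunity", _dec(self.wage_opportunity))
        object.__setattr__(self, "wage_replacement", _dec(self.wage_replacement))
        if self.treatment_annual < 0 or self.wage_opportunity < 0 or self.wage_replacement < 0:
            raise ConfigurationError("monetary parameters must be non-negative")
        if any(v < 0 for v in self.benefit_monthly.values()):
            raise ConfigurationError("benefit_monthly must be non-negative")
        if any(v < 0 for v in self.care_hours_monthly.values()):
            raise ConfigurationError("care_hours_monthly must be non-negative")
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be non-negative")
        if self.severe_valuation not in ("replacement", "opportunity"):
            raise ConfigurationError(f"unknown severe_valuation {self.severe_valuation!r}")


@dataclass(frozen=True)
class CostSchedule:
    """Per-state annual cost components, EUR per person per year."""

    treatment: Mapping[SeverityState, Decimal]
    benefit: Mapping[SeverityState, Decimal]
    informal: Mapping[SeverityState, Decimal]
    indirect: Mapping[SeverityState, Decimal]
    total: Mapping[SeverityState, Decimal]

    def __post_init__(self) -> None:
        for s in STATES:
            if self.total[s] != self.treatment[s] + self.benefit[s] + self.indirect[s]:
                raise ValueError(f"total[{s.label}] inconsistent with components")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with components as rows and states as columns."""
        rows = {
            "treatment": self.treatment,
            "benefit": self.benefit,
            "informal": self.informal,
            "indirect": self.indirect,
            "total": self.total,
        }
        return pd.DataFrame(
            {s.label: {name: float(vals[s]) for name, vals in rows.items()} for s in STATES}
        )


def hourly_rate_with_oncosts(
    base_gross_hourly: Numeric,
    loadings: WageLoadings,
    contracted_days: float = 250.0,
) -> float:
    """Load employer on-costs and paid absence onto a gross hourly wage.

    The employer pays social security on top of the gross wage and pays for
    vacation, public holidays and sickness days during which no care work is
    delivered, so the effective cost per worked hour is

        base * (1 + ss) * contracted_days / (contracted_days - absences).
    """
    base = float(_dec(base_gross_hourly))
    if base <= 0:
        raise DomainError("base gross hourly wage must be positive")
    absences = loadings.vacation_days + loadings.public_holiday_days + loadings.sickness_days
    effective_days = contracted_days - absences
    if effective_days <= 0:
        raise DomainError("absence days leave no effective working days")
    return base * (1.0 + loadings.employer_social_security) * contracted_days / effective_days


def annual_benefit(state: SeverityState, params: CostParameters) -> Decimal:
    """Annualized long-term care benefit: monthly rate x 12."""
    return (params.benefit_monthly[state] * 12).quantize(CENT)


def _wage_for(state: SeverityState, params: CostParameters) -> Decimal:
    if state is SeverityState.SEVERE and params.severe_valuation == "replacement":
        return params.wage_replacement
    return params.wage_opportunity


def annual_informal(state: SeverityState, params: CostParameters) -> Decimal:
    """Informal-care cost: monthly hours x hourly wage x 12."""
    return (params.care_hours_monthly[state] * _wage_for(state, params) * 12).quantize(CENT)


def annual_indirect(state: SeverityState, params: CostParameters) -> Decimal:
    """Indirect cost: informal-care cost net of the care benefit.

    A negative difference (benefit exceeding informal-care value) is
    allowed with a warning by default; set
    ``params.clamp_negative_indirect`` to clamp it to zero.
    """
    value = annual_informal(state, params) - annual_benefit(state, params)
    if value < 0:
        logger.warning(
            "indirect cost for %s is negative (%s EUR); benefit exceeds informal care",
            state.label,
            value,
        )
        if params.clamp_negative_indirect:
            return Decimal("0.00")
    return value


def build_cost_schedule(params: CostParameters) -> CostSchedule:
    """Assemble the full per-state schedule and cross-check the identity
    total = treatment + informal (the benefit cancels)."""
    treatment = {s: params.treatment_annual.quantize(CENT) for s in STATES}
    benefit = {s: annual_benefit(s, params) for s in STATES}
    informal = {s: annual_informal(s, params) for s in STATES}
    indirect = {s: annual_indirect(s, params) for s in STATES}
    total = {s: treatment[s] + benefit[s] + indirect[s] for s in STATES}
    if not params.clamp_negative_indirect:
        for s in STATES:
            assert total[s] == treatment[s] + informal[s], "cost identity violated"
    return CostSchedule(
        treatment=treatment,
        benefit=benefit,
        informal=informal,
        indirect=indirect,
        total=total,
    )
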