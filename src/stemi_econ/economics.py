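"""Money-side primitives: average labour income, discounted present value of
future income, and cost annualization.

The average annual labour income is I = GDP * s / w, where s is the labour
share of GDP and w the total number of employed workers.  The present value
of the income a person with T expected working years would have earned is

    PV(I) = sum_{i=0}^{T} I_0 (1+g)^i / (1+r)^i

with g the annual real income growth rate (default 3%) and r the social
discount rate (default 6%), income credited at the start of each year so the
i = 0 term is undiscounted.  T_j is an expectation and generally fractional;
the fractional remainder f contributes f times the term at the next year, so
PV is continuous and monotone in T rather than a step function.

Program costs observed over a study window of ``period_days`` are converted
to an annual rate by amount * days_per_year / period_days (days_per_year
defaults to 365.25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._errors import ValidationError

DEFAULT_GROWTH_RATE = 0.03
DEFAULT_DISCOUNT_RATE = 0.06
DEFAULT_LIFE_EXPECTANCY = {"female": 72.7, "male": 68.6}
DEFAULT_DAYS_PER_YEAR = 365.25


@dataclass
class MacroInputs:
    """National accounts inputs for the average-income calculation.

    gdp in currency units (INR); labour_share in [0, 1]; employed_workers > 0.
    """

    gdp: float
    labour_share: float
    employed_workers: float

    def __post_init__(self) -> None:
        if self.gdp < 0:
            raise ValidationError("gdp must be non-negative")
        if not 0.0 <= self.labour_share <= 1.0:
            raise ValidationError("labour_share must lie in [0, 1]")
        if self.employed_workers <= 0:
            raise ValidationError("employed_workers must be positive")


@dataclass
class EconomicParams:
    """Valuation parameters: income level, growth/discount rates, horizons."""

    income_now: float
    growth_rate: float = DEFAULT_GROWTH_RATE
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    retirement_age: int = 70
    life_expectancy: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIFE_EXPECTANCY)
    )
    days_per_year: float = DEFAULT_DAYS_PER_YEAR

    def __post_init__(self) -> None:
        if self.income_now < 0:
            raise ValidationError("income_now must be non-negative")
        if self.growth_rate <= -1 or self.discount_rate <= -1:
            raise ValidationError("growth and discount rates must exceed -1")
        if self.days_per_year <= 0:
            raise ValidationError("days_per_year must be positive")

    def replace(self, **kwargs) -> "EconomicParams":
        """Copy with some fields overridden (life_expectancy is shared read-only)."""
        data = dict(
            income_now=self.income_now,
            growth_rate=self.growth_rate,
            discount_rate=self.discount_rate,
            retirement_age=self.retirement_age,
            life_expectancy=self.life_expectancy,
            days_per_year=self.days_per_year,
        )
        data.update(kwargs)
        return EconomicParams(**data)


@dataclass
class CostBreakdown:
    """Program cost components in INR millions over a study window.

    Six leaves under three phases; subtotals and the grand total are always
    computed from the leaves, never stored, so they cannot drift.
    """

    devices: float
    software_servers: float
    telecom_it: float
    operations: float
    logistics: float
    overheads: float
    period_days: int

    def __post_init__(self) -> None:
        leaves = [
            self.devices,
            self.software_servers,
            self.telecom_it,
            self.operations,
            self.logistics,
            self.overheads,
        ]
        if any(x < 0 for x in leaves):
            raise ValidationError("cost components must be non-negative")
        if self.period_days <= 0:
            raise ValidationError("period_days must be positive")

    @property
    def setting_up(self) -> float:
        return self.devices + self.software_servers

    @property
    def implementing(self) -> float:
        return self.telecom_it + self.operations

    @property
    def monitoring(self) -> float:
        return self.logistics + self.overheads

    @property
    def total(self) -> float:
        return self.setting_up + self.implementing + self.monitoring


def average_labor_income(macro: MacroInputs) -> float:
    """Average annual labour income I = GDP * s / w."""
    if macro.employed_workers <= 0:
        raise ValidationError("cannot compute average income with no employed workers")
    return macro.gdp * macro.labour_share / macro.employed_workers


def present_value_income(params: EconomicParams, working_years: float) -> float:
    """Present value of the income stream over ``working_years`` years.

    Full years i = 0..floor(T) contribute I_0 * ((1+g)/(1+r))^i; a fractional
    remainder f contributes f times the term at floor(T)+1.  At T = 0 this is
    exactly I_0 (the year of the index event, undiscounted).
    """
    if working_years < 0:
        raise ValidationError("working_years must be non-negative")
    i0 = params.income_now
    if i0 == 0:
        return 0.0
    ratio = (1.0 + params.growth_rate) / (1.0 + params.discount_rate)
    whole = math.floor(working_years)
    frac = working_years - whole
    if abs(ratio - 1.0) < 1e-12:
        pv = i0 * (whole + 1)
    else:
        pv = i0 * (1.0 - ratio ** (whole + 1)) / (1.0 - ratio)
    if frac > 0:
        pv += frac * i0 * ratio ** (whole + 1)
    return pv


def implied_working_years(params: EconomicParams, pv: float) -> float:
    """Invert :func:`present_value_income`: the duration T at which the PV of
    the income stream equals ``pv``.

    PV is continuous and strictly increasing in T (income and discounting
    positive), so the root is unique.  Useful for recovering the effective
    working-years duration behind a published aggregate PV.
    """
    if params.income_now <= 0:
        raise ValidationError("implied duration needs a positive income_now")
    if pv < params.income_now:
        raise ValidationError(
            "pv below the T = 0 value (one year's income); no duration attains it"
        )
    from scipy import optimize

    def gap(T: float) -> float:
        return present_value_income(params, T) - pv

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValidationError("pv not attainable at any finite duration")
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-10))


def annualize(amount: float, period_days: float, days_per_year: float = DEFAULT_DAYS_PER_YEAR) -> float:
    """Scale an amount observed over ``period_days`` to an annual rate."""
    if period_days <= 0:
        raise ValidationError("period_days must be positive")
    if days_per_year <= 0:
        raise ValidationError("days_per_year must be positive")
    return amount * days_per_year / period_days
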