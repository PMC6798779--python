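"""Synthetic cohorts, life tables and labour inputs for testing the pipeline,
plus a bundle of the published aggregate figures from the Tamil Nadu STEMI
quality-improvement program.

No patient-level data from the program are publicly deposited, so the
generators here produce cohorts with the same *structure*: two arms enrolled
over a shared window, arm-specific 1-year mortality, adult ages from a
truncated normal, a male-dominated sex mix typical of Indian STEMI
registries.  Life tables follow a Gompertz-like shape (mortality doubling
every fixed number of years), standing in for the official Sample
Registration System tables the published analysis drew on.  Employment by
age is hump-shaped in 5-year bins, as national labour-force surveys publish
it.

``tn_fixture`` carries only the program's published aggregates (cost
breakdown, arm sizes and mortality, the annualized patient base, life-years
and lost-income totals, national-accounts inputs).  It deliberately contains
no invented patient rows, so tests against published numbers never depend on
synthetic microdata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from ._errors import ValidationError
from .cohort_pipeline import Cohort
from .demography import LaborInputs, LifeTable

__all__ = [
    "CohortSpec",
    "LifeTableSpec",
    "generate_cohort",
    "generate_life_table",
    "generate_life_tables",
    "generate_labor_inputs",
    "tn_fixture",
    "TNFixture",
]


@dataclass
class CohortSpec:
    """Parameters of a synthetic pre/post cohort.

    Arm sizes, mortality rates and the enrollment window default to the
    Tamil Nadu program's published figures; the age/sex distribution
    (mean 56, SD 12, 78% male) is a package convention resembling published
    Indian STEMI registry demographics, not taken from that program.
    """

    n_pre: int = 898
    n_post: int = 1522
    enrollment_days: int = 319
    mortality_pre: float = 0.176
    mortality_post: float = 0.142
    age_mean: float = 56.0
    age_sd: float = 12.0
    age_range: tuple[int, int] = (25, 90)
    male_fraction: float = 0.78
    age_mortality_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mortality_pre", "mortality_post", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_pre < 0 or self.n_post < 0:
            raise ValidationError("arm sizes must be non-negative")
        if self.age_range[0] > self.age_range[1]:
            raise ValidationError("age_range must be ordered")
        if self.enrollment_days <= 0:
            raise ValidationError("enrollment_days must be positive")


@dataclass
class LifeTableSpec:
    """Gompertz-like mortality: rate doubles every ``doubling_years``.

    Defaults give roughly 0.08 deaths per 1,000 at age 0 rising to ~35 per
    1,000 at age 70 for males; the female schedule is the male schedule
    shifted ``sex_offset`` years older (females at age a die like males at
    age a - sex_offset).
    """

    max_age: int = 100
    base_rate_per_1000: float = 0.08
    doubling_years: float = 8.0
    sex_offset: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate_per_1000 < 0:
            raise ValidationError("base_rate_per_1000 must be non-negative")
        if self.doubling_years <= 0:
            raise ValidationError("doubling_years must be positive")
        if self.max_age < 0:
            raise ValidationError("max_age must be non-negative")


def _truncnorm_ages(rng: np.random.Generator, spec: CohortSpec, n: int) -> np.ndarray:
    lo, hi = spec.age_range
    a = (lo - spec.age_mean) / spec.age_sd
    b = (hi - spec.age_mean) / spec.age_sd
    draws = stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )
    return np.clip(np.round(draws).astype(int), lo, hi)


def _death_probs(ages: np.ndarray, marginal: float, slope: float, age_center: float) -> np.ndarray:
    """Per-patient death probabilities with a logistic age effect, with the
    intercept calibrated so the cohort's mean probability equals ``marginal``."""
    if slope == 0.0 or marginal in (0.0, 1.0) or ages.size == 0:
        return np.full(ages.shape, marginal)
    x = slope * (ages - age_center)

    def mean_gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + x))) - marginal

    alpha = optimize.brentq(mean_gap, -50.0, 50.0)
    return expit(alpha + x)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a two-arm cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for arm, n, mort in (
        ("pre", spec.n_pre, spec.mortality_pre),
        ("post", spec.n_post, spec.mortality_post),
    ):
        ages = _truncnorm_ages(rng, spec, n)
        sexes = np.where(rng.random(n) < spec.male_fraction, "male", "female")
        probs = _death_probs(ages, mort, spec.age_mortality_slope, spec.age_mean)
        died = rng.random(n) < probs
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{arm}-{i:05d}" for i in range(n)],
                    "age": ages,
                    "sex": sexes,
                    "arm": arm,
                    "died_1yr": died,
                }
            )
        )
    patients = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=Cohort.COLUMNS)
    if len(patients) == 0:
        patients = pd.DataFrame(columns=Cohort.COLUMNS)
    return Cohort(patients, spec.enrollment_days)


def generate_life_table(spec: LifeTableSpec, sex: str = "male") -> LifeTable:
    """Smooth exponential-in-age mortality, clamped at 1,000 per 1,000."""
    ages = np.arange(0, spec.max_age + 1)
    shift = spec.sex_offset if sex == "female" else 0.0
    eff_age = np.maximum(ages - shift, 0.0)
    rate = spec.base_rate_per_1000 * 2.0 ** (eff_age / spec.doubling_years)
    return LifeTable(sex=sex, ages=ages, deaths_per_1000=np.minimum(rate, 1000.0))


def generate_life_tables(spec: LifeTableSpec) -> dict[str, LifeTable]:
    return {sex: generate_life_table(spec, sex) for sex in ("male", "female")}


# Hump-shaped employment-by-age profile (per-1,000 weight for each 5-year bin
# starting at the given age); low before 20, peak 25-50, zero from 70.
_EMPLOYMENT_HUMP = {
    15: 20.0, 20: 80.0, 25: 120.0, 30: 130.0, 35: 130.0, 40: 125.0,
    45: 115.0, 50: 100.0, 55: 75.0, 60: 45.0, 65: 20.0,
}


def generate_labor_inputs(
    seed: int = 0,
    bins_shape: dict[int, float] | None = None,
    total_labour_force: dict[str, float] | None = None,
    max_age: int = 100,
) -> LaborInputs:
    """Binned employment shares with a consistent synthetic population.

    The population pyramid declines smoothly with age; bin shares follow a
    hump peaking in the prime working ages and vanishing by 70.  Small seeded
    perturbations keep distinct seeds distinguishable without changing the
    shape.
    """
    rng = np.random.default_rng(seed)
    shape = dict(bins_shape) if bins_shape is not None else dict(_EMPLOYMENT_HUMP)
    if total_labour_force is None:
        total_labour_force = {"male": 21_800_000.0, "female": 11_100_000.0}

    rows = []
    for sex in ("male", "female"):
        jitter = rng.uniform(0.97, 1.03, size=len(shape))
        vals = np.array(list(shape.values()), dtype=float) * jitter
        total = vals.sum()
        if total > 1000.0:
            vals *= 1000.0 / total
        for (lo, _), v in zip(shape.items(), vals):
            rows.append({"age_lo": lo, "age_hi": lo + 5, "sex": sex, "employed_per_1000": v})
    bins = pd.DataFrame(rows)

    ages = np.arange(0, max_age + 1)
    pop_rows = []
    for sex, base in (("male", 640_000.0), ("female", 630_000.0)):
        # gently declining pyramid, faster decline past 60
        decline = np.where(ages <= 60, 0.012, 0.06)
        pop = base * np.exp(-np.cumsum(decline) + decline[0])
        pop *= rng.uniform(0.99, 1.01, size=pop.size)
        for a, p in zip(ages, pop):
            pop_rows.append({"age": int(a), "sex": sex, "population": float(p)})
    population = pd.DataFrame(pop_rows)

    return LaborInputs(
        bins=bins,
        population_by_age=population,
        total_labour_force=total_labour_force,
        lfpr_per_1000=454.0,
    )


@dataclass
class TNFixture:
    """Published aggregate figures from the Tamil Nadu STEMI program.

    All money in 2013 INR.  The cost-breakdown leaves are annualized rates
    in millions (they sum to the annualization of the raw 13.2 million
    outlay over the 319-day window); lost-income PVs are annualized totals
    in INR.
    """

    n_pre: int = 898
    n_post: int = 1522
    enrollment_days: int = 319
    mortality_pre: float = 0.176
    mortality_post: float = 0.142
    annualized_n: float = 2265.0
    deaths_averted: int = 78

    # cost breakdown leaves, INR millions per year (annualized)
    cost_devices: float = 5.63
    cost_software_servers: float = 1.70
    cost_telecom_it: float = 1.68
    cost_operations: float = 4.11
    cost_logistics: float = 0.39
    cost_overheads: float = 1.59
    cost_raw_total_mn: float = 13.2

    life_years_lost_pre: float = 4381.0
    life_years_lost_post: float = 3273.0

    pv_lost_pre: float = 228.7e6
    pv_lost_post: float = 175.6e6

    gdp: float = 83_222e9
    labour_share: float = 0.496
    employed_workers: float = 481_832_540.0

    growth_rate: float = 0.03
    discount_rate: float = 0.06
    retirement_age: int = 70
    life_expectancy: dict[str, float] = field(
        default_factory=lambda: {"female": 72.7, "male": 68.6}
    )

    sensitivity_growth_rates: tuple[float, ...] = (0.03, 0.06, 0.08, 0.10, 0.12)
    sensitivity_discount_rates: tuple[float, ...] = (0.04, 0.06, 0.08, 0.10)


def tn_fixture() -> TNFixture:
    """The published-aggregates bundle feeding the headline-metric checks."""
    return TNFixture()
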