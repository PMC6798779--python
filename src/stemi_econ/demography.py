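"""Survival matrices, labour-force participation and expected working years.

The human-capital valuation of a premature death needs, for a person of age
``j``, the expected number of working years they had left:

    T_j = sum_{t=j}^{R} s_{j,t} * l_t

where ``s_{j,t}`` is the probability of surviving from age ``j`` to the end
of age ``t`` (built from a life table of deaths per 1,000 at each single year
of age), ``l_t`` is the labour-force participation rate at age ``t``, and
``R`` is the retirement age (default 70, beyond which ``l_t`` is forced to
zero so the upper summation limit is immaterial).

Survival is constructed by the cumulative-deaths rule

    s_{j,t} = 1 - min(1, sum_{u=j}^{t} d_u / 1000)

with ``d_u`` the tabulated deaths per 1,000 at age ``u``.  This treats the
per-1,000 death counts as additive hazards over the interval and is clamped
at zero once the accumulated count exceeds 1,000.  The standard actuarial
alternative, the product of conditional survival probabilities
``prod (1 - d_u/1000)``, is available via ``method="product"`` for
comparison; the cumulative rule is the default because it is the convention
the downstream cost-benefit arithmetic is built on.

Participation schedules are usually published per 1,000 employed in 5-year
age bins; :func:`disaggregate_participation` spreads each bin uniformly over
its single years, converts the per-1,000 shares into head counts using the
total labour force, and divides by single-age population counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import UndefinedRateError, ValidationError

SEXES = ("male", "female")
DEFAULT_RETIREMENT_AGE = 70


def _check_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ValidationError(f"unknown sex {sex!r}; expected one of {SEXES}")
    return sex


@dataclass
class LifeTable:
    """Deaths per 1,000 at each single year of age, for one sex.

    Ages must be contiguous integers; rates must lie in [0, 1000].
    """

    sex: str
    ages: np.ndarray
    deaths_per_1000: np.ndarray

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        self.ages = np.asarray(self.ages, dtype=int)
        self.deaths_per_1000 = np.asarray(self.deaths_per_1000, dtype=float)
        if self.ages.size == 0:
            raise ValidationError("life table is empty")
        if self.ages.size != self.deaths_per_1000.size:
            raise ValidationError("ages and deaths_per_1000 differ in length")
        if np.unique(self.ages).size != self.ages.size:
            raise ValidationError("life table has duplicate ages")
        order = np.argsort(self.ages)
        self.ages = self.ages[order]
        self.deaths_per_1000 = self.deaths_per_1000[order]
        gaps = np.where(np.diff(self.ages) != 1)[0]
        if gaps.size:
            missing = int(self.ages[gaps[0]]) + 1
            raise ValidationError(f"life table ages are not contiguous: missing age {missing}")
        if np.any(self.deaths_per_1000 < 0) or np.any(self.deaths_per_1000 > 1000):
            bad = int(self.ages[(self.deaths_per_1000 < 0) | (self.deaths_per_1000 > 1000)][0])
            raise ValidationError(f"deaths_per_1000 outside [0, 1000] at age {bad}")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "sex": self.sex, "deaths_per_1000": self.deaths_per_1000}
        )


@dataclass
class SurvivalMatrix:
    """Upper-triangular matrix of survival probabilities ``s[j][t]``.

    ``probability(j, t)`` is the chance that a person of age ``j`` survives
    to the end of age ``t``; defined for ``min_age <= j <= t <= max_age``.
    """

    sex: str
    min_age: int
    s: np.ndarray  # shape (n, n); valid where column >= row

    @property
    def max_age(self) -> int:
        return self.min_age + self.s.shape[0] - 1

    def probability(self, j: int, t: int) -> float:
        if not (self.min_age <= j <= t <= self.max_age):
            raise ValidationError(
                f"survival requested outside table range: j={j}, t={t}, "
                f"ages {self.min_age}..{self.max_age}"
            )
        return float(self.s[j - self.min_age, t - self.min_age])

    def row(self, j: int) -> np.ndarray:
        """Survival from age ``j`` to the end of each age ``t >= j``."""
        i = j - self.min_age
        return self.s[i, i:]


def build_survival_matrix(life_table: LifeTable, method: str = "cumulative") -> SurvivalMatrix:
    """Build ``s[j][t]`` for all ``j <= t`` covered by the life table.

    method="cumulative" (default): s = 1 - min(1, sum of deaths_per_1000/1000
    over ages j..t inclusive).  method="product": product of the single-age
    survival probabilities ``1 - d_u/1000``.
    """
    d = life_table.deaths_per_1000 / 1000.0
    n = d.size
    if method == "cumulative":
        c = np.concatenate([[0.0], np.cumsum(d)])
        # cumulative deaths over [j, t] = c[t+1] - c[j]
        cum = c[np.newaxis, 1:] - c[: n, np.newaxis]
        s = np.clip(1.0 - cum, 0.0, 1.0)
    elif method == "product":
        surv1 = np.clip(1.0 - d, 0.0, 1.0)
        s = np.zeros((n, n))
        for i in range(n):
            s[i, i:] = np.cumprod(surv1[i:])
    else:
        raise ValidationError(f"unknown survival method {method!r}")
    s = np.triu(s)
    return SurvivalMatrix(sex=life_table.sex, min_age=life_table.min_age, s=s)


@dataclass
class LaborInputs:
    """Binned employment shares plus the population needed to localise them.

    ``bins`` has columns age_lo, age_hi, sex, employed_per_1000 with half-open
    [age_lo, age_hi) bins; ``population_by_age`` has columns age, sex,
    population. ``total_labour_force`` maps sex -> persons in the labour
    force; ``lfpr_per_1000`` is the overall participation rate, kept for
    reporting.
    """

    bins: pd.DataFrame
    population_by_age: pd.DataFrame
    total_labour_force: dict[str, float]
    lfpr_per_1000: float = float("nan")

    def __post_init__(self) -> None:
        need = {"age_lo", "age_hi", "sex", "employed_per_1000"}
        if not need.issubset(self.bins.columns):
            raise ValidationError(f"bins table needs columns {sorted(need)}")
        needp = {"age", "sex", "population"}
        if not needp.issubset(self.population_by_age.columns):
            raise ValidationError(f"population table needs columns {sorted(needp)}")
        if (self.bins["employed_per_1000"] < 0).any():
            raise ValidationError("employed_per_1000 must be non-negative")
        if (self.population_by_age["population"] < 0).any():
            raise ValidationError("population counts must be non-negative")
        for sex, grp in self.bins.groupby("sex"):
            g = grp.sort_values("age_lo")
            if (g["age_hi"] <= g["age_lo"]).any():
                raise ValidationError(f"empty or inverted bin for sex {sex!r}")
            if (g["age_lo"].values[1:] < g["age_hi"].values[:-1]).any():
                raise ValidationError(f"overlapping bins for sex {sex!r}")
            if g["employed_per_1000"].sum() > 1000 + 1e-9:
                raise ValidationError(f"employed_per_1000 sums above 1000 for sex {sex!r}")


@dataclass
class ParticipationSchedule:
    """Single-age labour-force participation rates ``l[t]`` in [0, 1]."""

    sex: str
    ages: np.ndarray
    l: np.ndarray
    retirement_age: int = DEFAULT_RETIREMENT_AGE

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        self.ages = np.asarray(self.ages, dtype=int)
        self.l = np.asarray(self.l, dtype=float)
        if np.any(self.l < 0) or np.any(self.l > 1):
            raise ValidationError("participation rates must lie in [0, 1]")
        if np.any(self.l[self.ages >= self.retirement_age] != 0):
            raise ValidationError(
                f"participation must be zero at and beyond retirement age {self.retirement_age}"
            )

    def rate(self, t: int) -> float:
        if t >= self.retirement_age:
            return 0.0
        hit = np.where(self.ages == t)[0]
        return float(self.l[hit[0]]) if hit.size else 0.0


@dataclass
class WorkingYearsTable:
    """Expected remaining working years ``T[j]`` at each single age."""

    sex: str
    ages: np.ndarray
    T: np.ndarray
    retirement_age: int = DEFAULT_RETIREMENT_AGE

    def years(self, j: int) -> float:
        """T at age ``j``; zero at or beyond retirement or above table coverage."""
        if j >= self.retirement_age or j > int(self.ages[-1]):
            return 0.0
        hit = np.where(self.ages == j)[0]
        return float(self.T[hit[0]]) if hit.size else 0.0


def lfpr_from_counts(employed: float, unemployed: float, population: float) -> float:
    """Labour-force participation rate per 1,000: (employed + unemployed) / population * 1000."""
    if population <= 0:
        raise UndefinedRateError("LFPR undefined for zero or negative population")
    if employed < 0 or unemployed < 0:
        raise ValidationError("counts must be non-negative")
    if employed + unemployed > population:
        raise ValidationError("labour force exceeds population")
    return (employed + unemployed) / population * 1000.0


def disaggregate_participation(
    labor: LaborInputs,
    sex: str,
    retirement_age: int = DEFAULT_RETIREMENT_AGE,
    max_age: int | None = None,
) -> ParticipationSchedule:
    """Spread binned per-1,000 employment uniformly over single ages and
    divide by population to get ``l[t]``.

    Each bin's per-1,000 share is split evenly over its years; the head count
    employed at age t is (per-age share) * total_labour_force / 1000; the
    participation rate is that count over the population at t, clamped to
    [0, 1] and zeroed at ages >= retirement_age.
    """
    _check_sex(sex)
    bins = labor.bins[labor.bins["sex"] == sex].sort_values("age_lo")
    pop = labor.population_by_age[labor.population_by_age["sex"] == sex]
    pop_map = dict(zip(pop["age"].astype(int), pop["population"].astype(float)))
    total_lf = float(labor.total_labour_force[sex])

    if max_age is None:
        hi = int(bins["age_hi"].max()) if len(bins) else retirement_age
        max_age = max(hi - 1, retirement_age)
    ages = np.arange(0, max_age + 1)
    l = np.zeros_like(ages, dtype=float)

    for row in bins.itertuples(index=False):
        lo, hi = int(row.age_lo), int(row.age_hi)
        if float(row.age_lo) != lo or float(row.age_hi) != hi:
            raise ValidationError(f"bin boundaries must be integers: [{row.age_lo}, {row.age_hi})")
        per_age_share = float(row.employed_per_1000) / (hi - lo)
        for t in range(lo, hi):
            if t > max_age:
                continue
            employed_at_t = per_age_share * total_lf / 1000.0
            if employed_at_t == 0:
                continue
            p = pop_map.get(t)
            if p is None or p <= 0:
                raise ValidationError(
                    f"no population at age {t} (sex {sex!r}) but nonzero employment"
                )
            l[t] = min(employed_at_t / p, 1.0)

    l[ages >= retirement_age] = 0.0
    return ParticipationSchedule(sex=sex, ages=ages, l=l, retirement_age=retirement_age)


def expected_working_years(
    surv: SurvivalMatrix, sched: ParticipationSchedule, j: int
) -> float:
    """T_j = sum over t = j .. retirement_age of s[j][t] * l[t].

    Terms at t >= retirement_age vanish because l is zero there.  Ages above
    the life table's coverage are treated as having no working years left.
    """
    if j < 0:
        raise ValidationError("age must be non-negative")
    if surv.sex != sched.sex:
        raise ValidationError("survival matrix and participation schedule disagree on sex")
    R = sched.retirement_age
    if j >= R or j > surv.max_age:
        return 0.0
    j_eff = max(j, surv.min_age)
    t_hi = min(R - 1, surv.max_age)
    ts = np.arange(j_eff, t_hi + 1)
    s_row = surv.row(j_eff)[: ts.size]
    l_vals = np.array([sched.rate(int(t)) for t in ts])
    return float(np.sum(s_row * l_vals))


def working_years_table(
    surv: SurvivalMatrix, sched: ParticipationSchedule
) -> WorkingYearsTable:
    """Tabulate T_j for every age from the survival table's minimum to its maximum."""
    ages = np.arange(surv.min_age, surv.max_age + 1)
    T = np.array([expected_working_years(surv, sched, int(j)) for j in ages])
    return WorkingYearsTable(
        sex=surv.sex, ages=ages, T=T, retirement_age=sched.retirement_age
    )
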