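import numpy as np
import pandas as pd
import pytest

from stemi_econ import (
    Cohort,
    CohortSpec,
    LifeTable,
    LifeTableSpec,
    ParticipationSchedule,
    build_survival_matrix,
    build_working_years,
    generate_cohort,
    generate_labor_inputs,
    generate_life_tables,
    tn_fixture,
)


def flat_life_table(rate: float, sex: str = "male", max_age: int = 100) -> LifeTable:
    ages = np.arange(0, max_age + 1)
    return LifeTable(sex=sex, ages=ages, deaths_per_1000=np.full(ages.size, rate))


def flat_participation(rate: float, sex: str = "male", retirement_age: int = 70,
                       max_age: int = 100) -> ParticipationSchedule:
    ages = np.arange(0, max_age + 1)
    l = np.where(ages < retirement_age, rate, 0.0)
    return ParticipationSchedule(sex=sex, ages=ages, l=l, retirement_age=retirement_age)


def toy_cohort(rows, enrollment_days=365) -> Cohort:
    df = pd.DataFrame(rows, columns=["id", "age", "sex", "arm", "died_1yr"])
    return Cohort(df, enrollment_days)


@pytest.fixture(scope="session")
def fx():
    return tn_fixture()


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One seeded synthetic dataset shared by the slower end-to-end tests."""
    cohort = generate_cohort(CohortSpec(seed=7))
    tables = generate_life_tables(LifeTableSpec(seed=7))
    labor = generate_labor_inputs(seed=7)
    work_years = build_working_years(tables, labor)
    return {"cohort": cohort, "life_tables": tables, "labor": labor,
            "work_years": work_years}
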