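"""Synthetic inputs with known ground truth for the whole pipeline.

Everything the pipeline consumes can be generated here: baseline cohorts of
people recently diagnosed with type 2 diabetes, activity ledgers with the
delivery-cost category structure, small risk engines with documented
parameters for oracle tests, unit-cost and price-index tables, economic
parameters and a PSA distribution set.  All generators are bit-reproducible
under a fixed seed.

The default cohort moments (age 62 +/- 10, 55% male, HbA1c 7.0% +/- 1.2,
BMI 31 +/- 5, SBP 135 +/- 15, HDL 1.2 +/- 0.3, LDL 2.8 +/- 0.8) are
synthetic placeholders of realistic magnitude for a newly diagnosed English
T2DM population, not estimates from any particular study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .costing import (
    ActivityRecord,
    PriceIndexSeries,
    UnitCost,
    UnitCostTable,
    annuity_factor,
)
from .effects import hba1c_percent_to_mmol
from .microsim import EconomicParams
from .psa import ParameterDistribution
from .riskengine import ProgressionEquation, RiskEngineSpec, RiskEquation

# physiological truncation bounds applied to generated cohorts
COHORT_BOUNDS = {
    "age": (18.0, 99.0),
    "hba1c": (4.0, 16.0),
    "bmi": (15.0, 60.0),
    "sbp": (80.0, 220.0),
    "hdl": (0.4, 3.5),
    "ldl": (0.5, 8.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Moments and composition of a synthetic baseline cohort."""

    n: int
    age_mean: float = 62.0
    age_sd: float = 10.0
    male_fraction: float = 0.55
    minority_fraction: float = 0.25
    hba1c_mean: float = 7.0
    hba1c_sd: float = 1.2
    bmi_mean: float = 31.0
    bmi_sd: float = 5.0
    sbp_mean: float = 135.0
    sbp_sd: float = 15.0
    hdl_mean: float = 1.2
    hdl_sd: float = 0.3
    ldl_mean: float = 2.8
    ldl_sd: float = 0.8
    duration_years: float = 0.5  # diagnosed within the last 12 months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("age_sd", "hba1c_sd", "bmi_sd", "sbp_sd", "hdl_sd", "ldl_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("male_fraction", "minority_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a baseline cohort; reproducible given ``spec.seed``.

    Continuous risk factors are normal draws truncated (clipped) to
    physiological bounds.  HbA1c is carried in both DCCT % and IFCC mmol/mol.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    def trunc_normal(mean, sd, bounds):
        lo, hi = bounds
        return np.clip(rng.normal(mean, sd, n), lo, hi)

    df = pd.DataFrame(
        {
            "age": trunc_normal(spec.age_mean, spec.age_sd, COHORT_BOUNDS["age"]),
            "sex": np.where(rng.random(n) < spec.male_fraction, "male", "female"),
            "ethnicity": np.where(
                rng.random(n) < spec.minority_fraction, "minority", "white"
            ),
            "diabetes_duration": np.full(n, spec.duration_years),
            "hba1c": trunc_normal(spec.hba1c_mean, spec.hba1c_sd, COHORT_BOUNDS["hba1c"]),
            "bmi": trunc_normal(spec.bmi_mean, spec.bmi_sd, COHORT_BOUNDS["bmi"]),
            "sbp": trunc_normal(spec.sbp_mean, spec.sbp_sd, COHORT_BOUNDS["sbp"]),
            "hdl": trunc_normal(spec.hdl_mean, spec.hdl_sd, COHORT_BOUNDS["hdl"]),
            "ldl": trunc_normal(spec.ldl_mean, spec.ldl_sd, COHORT_BOUNDS["ldl"]),
        }
    )
    df["hba1c_mmol"] = hba1c_percent_to_mmol(df["hba1c"])
    return df


def default_cohort_generator(spec: CohortSpec | None = None):
    """A ``(n, seed) -> DataFrame`` callable for the PSA inner loop."""
    base = spec or CohortSpec(n=1)

    def generate(n: int, seed: int) -> pd.DataFrame:
        return gen_cohort(
            CohortSpec(**{**base.__dict__, "n": n, "seed": seed})
        )

    return generate


# ---------------------------------------------------------------------------
# Activity ledgers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LedgerSpec:
    """Counts and ranges for a random activity ledger."""

    records_per_cell: Mapping[tuple[str, str], int]  # (category, group) -> count
    minutes_range: tuple[float, float] = (30.0, 240.0)
    expense_range: tuple[float, float] = (20.0, 400.0)
    staff_role: str = "embedder"
    price_year: str = "2019/20"
    seed: int = 0

    def __post_init__(self) -> None:
        for cell, count in self.records_per_cell.items():
            if count < 0:
                raise ValueError(f"negative record count for cell {cell}")


_STAFF_CATEGORIES = ("embedder_direct", "practice_staff", "provider_staff")


def gen_ledger(spec: LedgerSpec) -> list[ActivityRecord]:
    """Random ledger with the delivery-cost category x site-group structure."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for (category, group), count in spec.records_per_cell.items():
        for k in range(count):
            if category in _STAFF_CATEGORIES:
                records.append(
                    ActivityRecord(
                        site_id=f"{group}_{k:03d}",
                        site_group=group,
                        category=category,
                        price_year=spec.price_year,
                        staff_role=spec.staff_role,
                        minutes=float(rng.uniform(*spec.minutes_range)),
                    )
                )
            else:
                records.append(
                    ActivityRecord(
                        site_id=f"{group}_{k:03d}",
                        site_group=group,
                        category=category,
                        price_year=spec.price_year,
                        expense_gbp=float(rng.uniform(*spec.expense_range)),
                    )
                )
    return records


#: Published-style delivery-cost table used to construct the bundled fixture
#: ledger.  Cells are pence-level so that half-up rounding reproduces the
#: printed whole-pound values, including the printed grand total (40 316),
#: which is one pound below the sum of the printed row totals because the
#: marketing and travel rows round upwards.
_FIXTURE_CELLS = {
    # (category, group): GBP at 2019/20 prices (toolkit = annual equivalent)
    ("embedder_direct", "waitlist"): 3650.0,
    ("embedder_direct", "immediate"): 7746.0,
    ("embedder_direct", "provider"): 17200.0,
    ("practice_staff", "waitlist"): 185.0,
    ("practice_staff", "immediate"): 1471.0,
    ("provider_staff", "provider"): 3358.0,
    ("travel", "waitlist"): 550.9,
    ("travel", "immediate"): 3826.8,
    ("marketing", "waitlist"): 600.2,
    ("marketing", "immediate"): 687.4,
    ("toolkit", "waitlist"): 504.0,
    ("toolkit", "immediate"): 537.0,
}

FIXTURE_HOURLY_RATES = {"embedder": 50.0, "practice_nurse": 40.0, "provider_staff": 40.0}

_FIXTURE_ROLES = {
    "embedder_direct": "embedder",
    "practice_staff": "practice_nurse",
    "provider_staff": "provider_staff",
}


def fixture_unit_costs(price_year: str = "2019/20") -> UnitCostTable:
    return UnitCostTable(
        {role: UnitCost(rate, price_year) for role, rate in FIXTURE_HOURLY_RATES.items()}
    )


def fixture_price_indices() -> PriceIndexSeries:
    """A plausible two-regime index series covering 2013/14 - 2019/20."""
    hchs = {"2013/14": 289.3, "2014/15": 292.3}
    nhscii = {
        "2014/15": 100.0,
        "2015/16": 101.1,
        "2016/17": 103.0,
        "2017/18": 105.1,
        "2018/19": 107.4,
        "2019/20": 110.2,
    }
    return PriceIndexSeries(hchs=hchs, nhscii=nhscii, boundary="2014/15")


def fixture_ledger(price_year: str = "2019/20") -> list[ActivityRecord]:
    """Deterministic ledger whose aggregate reproduces the published-style
    delivery-cost table cell for cell.

    Staff cells are expressed as minutes at the fixture hourly rates; toolkit
    cells are recorded as the one-off outlay whose 5-year 3.5% annuity-due
    equivalent is the tabulated annual figure.
    """
    factor = annuity_factor(5, 0.035, "advance")
    records = []
    for (category, group), cell in _FIXTURE_CELLS.items():
        site = f"{group}_fixture"
        if category in _FIXTURE_ROLES:
            role = _FIXTURE_ROLES[category]
            minutes = cell / FIXTURE_HOURLY_RATES[role] * 60.0
            records.append(
                ActivityRecord(
                    site_id=site,
                    site_group=group,
                    category=category,
                    price_year=price_year,
                    staff_role=role,
                    minutes=minutes,
                )
            )
        elif category == "toolkit":
            records.append(
                ActivityRecord(
                    site_id=site,
                    site_group=group,
                    category=category,
                    price_year=price_year,
                    expense_gbp=cell * factor,
                )
            )
        else:
            records.append(
                ActivityRecord(
                    site_id=site,
                    site_group=group,
                    category=category,
                    price_year=price_year,
                    expense_gbp=cell,
                )
            )
    return records


#: Synthetic per-group patient counts and follow-up lengths for the
#: per-patient cost calculation (the real counts were not published).
FIXTURE_GROUP_PATIENTS = {"waitlist": 16_709, "immediate": 29_000}
FIXTURE_FOLLOWUP_DAYS = {"waitlist": 134.0, "immediate": 204.0}


# ---------------------------------------------------------------------------
# Toy risk engines
# ---------------------------------------------------------------------------


def _persistence_progressions(residual_sd: float = 0.0) -> dict[str, ProgressionEquation]:
    floors = {"hba1c": 4.0, "bmi": 15.0}
    return {
        name: ProgressionEquation(
            name=name,
            intercept=0.0,
            coefficients={name: 1.0},
            residual_sd=residual_sd,
            floor=floors.get(name),
        )
        for name in ("hba1c", "bmi", "sbp", "hdl", "ldl")
    }


def toy_engine(hazard_level: str = "low") -> RiskEngineSpec:
    """Small engine with documented parameters for oracle tests.

    ``"low"``: two complication events (a macrovascular Weibull equation on
    diabetes duration driven by HbA1c, and a microvascular exponential
    equation driven by HbA1c and SBP), Gompertz mortality on age, and mildly
    drifting autoregressive progression equations.  All annual event
    probabilities are below 5% for the default mean person.

    ``"calibration"``: every complication switched off (logistic intercept
    -30) and mortality a constant 0.5/year (logistic intercept 0), with
    pure-persistence noiseless progression - lifetimes are geometric with
    known mean, for closed-form checks.
    """
    if hazard_level == "calibration":
        off = RiskEquation(name="mi", form="logistic", intercept=-30.0)
        off2 = RiskEquation(name="micro", form="logistic", intercept=-30.0)
        coin = dict(form="logistic", intercept=0.0, time_covariate="age")
        return RiskEngineSpec(
            events={"mi": off, "micro": off2},
            mortality_event_year=RiskEquation(name="mortality_event_year", **coin),
            mortality_no_event=RiskEquation(name="mortality_no_event", **coin),
            progressions=_persistence_progressions(0.0),
        )
    if hazard_level != "low":
        raise ValueError(f"unknown hazard_level {hazard_level!r}")
    events = {
        "mi": RiskEquation(
            name="mi",
            form="weibull_ph",
            intercept=-7.2,
            coefficients={"hba1c": 0.12, "male": 0.3},
            shape=1.4,
            time_covariate="diabetes_duration",
        ),
        "micro": RiskEquation(
            name="micro",
            form="exponential_ph",
            intercept=-6.8,
            coefficients={"hba1c": 0.18, "sbp": 0.005},
            time_covariate="diabetes_duration",
        ),
    }
    mortality_no_event = RiskEquation(
        name="mortality_no_event",
        form="gompertz_ph",
        intercept=-10.6,
        coefficients={"hba1c": 0.03},
        shape=0.09,
        time_covariate="age",
    )
    mortality_event_year = RiskEquation(
        name="mortality_event_year",
        form="gompertz_ph",
        intercept=-9.9,
        coefficients={"hba1c": 0.03},
        shape=0.09,
        time_covariate="age",
    )
    progressions = {
        "hba1c": ProgressionEquation(
            name="hba1c",
            intercept=0.25,
            coefficients={"hba1c": 0.92, "hba1c_baseline": 0.05},
            residual_sd=0.25,
            floor=4.0,
        ),
        "bmi": ProgressionEquation(
            name="bmi",
            intercept=0.6,
            coefficients={"bmi": 0.98},
            residual_sd=0.4,
            floor=15.0,
        ),
        "sbp": ProgressionEquation(
            name="sbp",
            intercept=4.0,
            coefficients={"sbp": 0.97},
            residual_sd=4.0,
        ),
        "hdl": ProgressionEquation(
            name="hdl",
            intercept=0.025,
            coefficients={"hdl": 0.98},
            residual_sd=0.05,
        ),
        "ldl": ProgressionEquation(
            name="ldl",
            intercept=0.06,
            coefficients={"ldl": 0.98},
            residual_sd=0.15,
        ),
    }
    return RiskEngineSpec(
        events=events,
        mortality_event_year=mortality_event_year,
        mortality_no_event=mortality_no_event,
        progressions=progressions,
    )


def toy_econ() -> EconomicParams:
    """Synthetic economic parameters of realistic magnitude (GBP 2019/20)."""
    return EconomicParams(
        complication_first_year_cost={"mi": 7000.0, "micro": 3000.0},
        complication_subsequent_cost={"mi": 1500.0, "micro": 800.0},
        management_cost=500.0,
        utility_intercept=0.85,
        utility_age_slope=-0.003,
        utility_male_offset=0.02,
        utility_decrements={"mi": -0.06, "micro": -0.04},
        discount_rate=0.035,
        utility_floor=-0.594,
    )


#: Trial-derived base-case effect inputs: year-1 and year-2 HbA1c arm
#: differences (percentage points) and SSME attendance odds ratios (18%
#: lower at 1 year, 15% higher at 2 years), log-transformed.
BASE_EFFECT_INPUTS = {
    "hba1c_year1": -0.01,
    "hba1c_year2": -0.05,
    "bmi_year1": 0.0,
    "sbp_year1": 0.0,
    "hdl_year1": 0.0,
    "ldl_year1": 0.0,
    "attendance_lor1": math.log(0.82),
    "attendance_lor2": math.log(1.15),
}


def gen_psa_spec() -> list[ParameterDistribution]:
    """A PSA distribution set spanning all seven parameter-group tags.

    Effectiveness means equal the base-case effect inputs; engine and
    economics hyper-parameters centre on the toy defaults with modest
    spread.  Standard errors are synthetic.
    """
    engine = toy_engine("low")
    econ = toy_econ()
    spec = [
        ParameterDistribution(
            "hba1c_year1", "normal",
            {"mean": BASE_EFFECT_INPUTS["hba1c_year1"], "sd": 0.03},
            "effectiveness", "effects.hba1c_year1",
        ),
        ParameterDistribution(
            "hba1c_year2", "normal",
            {"mean": BASE_EFFECT_INPUTS["hba1c_year2"], "sd": 0.03},
            "effectiveness", "effects.hba1c_year2",
        ),
        ParameterDistribution(
            "attendance_lor1", "normal",
            {"mean": BASE_EFFECT_INPUTS["attendance_lor1"], "sd": 0.15},
            "effectiveness", "effects.attendance_lor1",
        ),
        ParameterDistribution(
            "attendance_lor2", "normal",
            {"mean": BASE_EFFECT_INPUTS["attendance_lor2"], "sd": 0.15},
            "effectiveness", "effects.attendance_lor2",
        ),
        ParameterDistribution(
            "management_cost", "gamma",
            {"shape": 100.0, "scale": econ.management_cost / 100.0},
            "cost", "econ.management_cost",
        ),
        ParameterDistribution(
            "mi_first_year_cost", "gamma",
            {"shape": 49.0, "scale": econ.complication_first_year_cost["mi"] / 49.0},
            "cost", "econ.first_cost.mi",
        ),
        ParameterDistribution(
            "micro_first_year_cost", "gamma",
            {"shape": 49.0, "scale": econ.complication_first_year_cost["micro"] / 49.0},
            "cost", "econ.first_cost.micro",
        ),
        ParameterDistribution(
            "utility_intercept", "beta", {"a": 170.0, "b": 30.0},
            "utility", "econ.utility_intercept",
        ),
        ParameterDistribution(
            "mi_decrement", "normal", {"mean": econ.utility_decrements["mi"], "sd": 0.01},
            "utility", "econ.decrement.mi",
        ),
        ParameterDistribution(
            "micro_intercept", "normal",
            {"mean": engine.events["micro"].intercept, "sd": 0.15},
            "risk_micro", "engine.event.micro.intercept",
        ),
        ParameterDistribution(
            "mi_intercept", "normal",
            {"mean": engine.events["mi"].intercept, "sd": 0.15},
            "risk_macro", "engine.event.mi.intercept",
        ),
        ParameterDistribution(
            "mortality_intercept", "normal",
            {"mean": engine.mortality_no_event.intercept, "sd": 0.1},
            "mortality", "engine.mortality.no_event.intercept",
        ),
        ParameterDistribution(
            "hba1c_drift", "normal",
            {"mean": engine.progressions["hba1c"].intercept, "sd": 0.03},
            "progression", "engine.progression.hba1c.intercept",
        ),
    ]
    return spec


def psa_groups(spec: Sequence[ParameterDistribution]) -> dict[str, list[str]]:
    """Group-tag -> parameter-name mapping for the VOI table."""
    groups: dict[str, list[str]] = {}
    for dist in spec:
        groups.setdefault(dist.group, []).extend(dist.column_names)
    return groups
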