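"""Individual-level annual-cycle simulation of diabetes outcomes.

Each simulated person carries demographic covariates, continuous risk
factors (HbA1c, BMI, SBP, HDL, LDL) and absorbing complication-history
flags.  Every annual cycle the simulator (in this fixed order):

1. progresses the risk factors through the engine's progression equations,
2. adds the intervention's effect offsets for that cycle,
3. draws each non-fatal complication with one uniform per event,
4. draws mortality (an event-year equation in cycles with a new
   complication, a no-event equation otherwise),
5. accrues costs (annual management cost, first-year cost for new
   complications, subsequent-year cost for established ones) and utility
   (baseline by age/sex plus additive decrements; a death mid-cycle credits
   half a cycle of utility and life-years, costs are not half-cycled),
6. discounts at ``(1+r)^-(cycle-1)`` so cycle-1 amounts are undiscounted.

Randomness comes from one substream per purpose (each progression equation,
each event, mortality), derived from the master seed.  Because both arms of
a comparison consume the same substreams for the same persons, outcome
differences between arms reflect only the intervention (common random
numbers): identical effect profiles give bitwise-identical results.

The implementation is vectorised across persons; :func:`simulate_person` is
the single-person view with a full per-cycle trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .effects import BIOMARKERS, EffectProfile
from .riskengine import RiskEngineSpec, annual_event_probability, linear_predictor

COHORT_COLUMNS = [
    "age",
    "sex",
    "ethnicity",
    "diabetes_duration",
    "hba1c",
    "bmi",
    "sbp",
    "hdl",
    "ldl",
]


@dataclass
class EconomicParams:
    """Costs, utilities and the discount rate for the economic bookkeeping.

    Complication costs distinguish the first year after the event from
    subsequent years.  Baseline utility is linear in age with a sex offset;
    complication decrements combine additively (or multiplicatively via
    ``utility_combination``) and the total is clamped to
    ``[utility_floor, 1]``.
    """

    complication_first_year_cost: Mapping[str, float] = field(default_factory=dict)
    complication_subsequent_cost: Mapping[str, float] = field(default_factory=dict)
    management_cost: float = 0.0
    utility_intercept: float = 0.85
    utility_age_slope: float = 0.0
    utility_male_offset: float = 0.0
    utility_decrements: Mapping[str, float] = field(default_factory=dict)
    utility_combination: str = "additive"  # or "multiplicative"
    discount_rate: float = 0.035
    utility_floor: float = -0.594

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount_rate must lie in [0, 1)")
        if self.utility_combination not in ("additive", "multiplicative"):
            raise ValueError("utility_combination must be 'additive' or 'multiplicative'")
        for name, value in {
            **dict(self.complication_first_year_cost),
            **dict(self.complication_subsequent_cost),
        }.items():
            if value < 0:
                raise ValueError(f"complication cost for {name!r} must be >= 0")
        for name, value in dict(self.utility_decrements).items():
            if value > 0:
                raise ValueError(f"utility decrement for {name!r} must be <= 0")


def discount_factor(cycle: int, rate: float) -> float:
    """Discount weight for annual ``cycle`` (1-based); cycle 1 is undiscounted."""
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    return (1.0 + rate) ** -(cycle - 1)


def baseline_utility(age, male, params: EconomicParams):
    return (
        params.utility_intercept
        + params.utility_age_slope * (np.asarray(age, dtype=float) - 60.0)
        + params.utility_male_offset * np.asarray(male, dtype=float)
    )


def cycle_utility(state: Mapping[str, object], params: EconomicParams):
    """QALY weight for one cycle given current age/sex and complication history."""
    base = baseline_utility(state["age"], state["male"], params)
    if params.utility_combination == "additive":
        total = np.asarray(base, dtype=float).copy()
        for event, dec in params.utility_decrements.items():
            flag = state.get(f"hist_{event}")
            if flag is not None:
                total = total + dec * np.asarray(flag, dtype=float)
    else:
        total = np.asarray(base, dtype=float).copy()
        for event, dec in params.utility_decrements.items():
            flag = state.get(f"hist_{event}")
            if flag is not None:
                total = total * (1.0 + dec) ** np.asarray(flag, dtype=float)
    total = np.clip(total, params.utility_floor, 1.0)
    return total if np.shape(total) else float(total)


def _purpose_rngs(seed: int, engine: RiskEngineSpec) -> dict[str, np.random.Generator]:
    """One independent generator per randomness purpose, derived from the seed.

    The purpose list (and hence the substream assignment) depends only on the
    engine structure, so two arms simulated with the same seed and engine
    structure share every stream.
    """
    purposes = (
        [f"progression:{name}" for name in engine.progressions]
        + [f"event:{name}" for name in engine.events]
        + ["mortality"]
    )
    return {
        purpose: np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        for i, purpose in enumerate(purposes)
    }


def _state_arrays(cohort: pd.DataFrame, engine: RiskEngineSpec) -> dict[str, np.ndarray]:
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing columns: {sorted(missing)}")
    n = len(cohort)
    state = {
        "age": cohort["age"].to_numpy(dtype=float).copy(),
        "male": (cohort["sex"].to_numpy() == "male").astype(float),
        "minority": (cohort["ethnicity"].to_numpy() == "minority").astype(float),
        "diabetes_duration": cohort["diabetes_duration"].to_numpy(dtype=float).copy(),
    }
    for b in BIOMARKERS:
        state[b] = cohort[b].to_numpy(dtype=float).copy()
        state[f"{b}_baseline"] = cohort[b].to_numpy(dtype=float).copy()
    for event in engine.events:
        state[f"hist_{event}"] = np.zeros(n)
    return state


@dataclass
class CohortResult:
    """Per-person lifetime outcomes from one simulated arm."""

    discounted_cost: np.ndarray
    discounted_qalys: np.ndarray
    life_years: np.ndarray
    undiscounted_cost: np.ndarray
    event_counts: dict[str, int]
    trajectory: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.discounted_cost)

    def means(self) -> dict[str, float]:
        return {
            "discounted_cost": float(self.discounted_cost.mean()),
            "discounted_qalys": float(self.discounted_qalys.mean()),
            "life_years": float(self.life_years.mean()),
        }


def simulate_cohort(
    cohort: pd.DataFrame,
    engine: RiskEngineSpec,
    effects: EffectProfile,
    econ: EconomicParams,
    *,
    seed: int,
    horizon: int | None = None,
    max_age: float = 100.0,
    intervention_cost_per_patient: float = 0.0,
    collect_trajectory: bool = False,
) -> CohortResult:
    """Simulate every person in ``cohort`` under one effect profile.

    ``horizon`` caps the number of annual cycles; by default people are
    simulated until death or ``max_age`` (lifetime horizon).  The
    intervention's per-patient cost, if any, is charged undiscounted in
    cycle 1.
    """
    if seed is None:
        raise ValueError("a seed is required (unseeded streams break reproducibility)")
    if horizon is not None and horizon < 1:
        raise ValueError("horizon must be >= 1")
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")

    state = _state_arrays(cohort, engine)
    rngs = _purpose_rngs(seed, engine)
    max_cycles = int(np.ceil(max_age - state["age"].min()))
    n_cycles = max(1, max_cycles if horizon is None else min(horizon, max_cycles))

    alive = np.ones(n, dtype=bool)
    disc_cost = np.zeros(n)
    undisc_cost = np.zeros(n)
    disc_qaly = np.zeros(n)
    life_years = np.zeros(n)
    event_counts = {e: 0 for e in engine.events}
    trajectory_rows = [] if collect_trajectory else None
    if collect_trajectory and n != 1:
        raise ValueError("trajectories are only collected for single-person cohorts")

    for cycle in range(1, n_cycles + 1):
        active = alive & (state["age"] < max_age)
        if not active.any():
            break

        # 1. natural risk-factor progression (noise drawn even for inactive
        # persons so the streams stay aligned across arms)
        for name, eq in engine.progressions.items():
            noise = rngs[f"progression:{name}"].standard_normal(n) * eq.residual_sd
            lp = np.asarray(linear_predictor(eq, state), dtype=float)
            new = lp + noise
            if eq.floor is not None:
                new = np.maximum(new, eq.floor)
            state[name] = np.where(active, new, state[name])

        # 2. intervention offsets for this cycle
        for b in BIOMARKERS:
            off = effects.offset_at(b, cycle)
            if off:
                updated = state[b] + off
                eq = engine.progressions.get(b)
                if eq is not None and eq.floor is not None:
                    updated = np.maximum(updated, eq.floor)
                state[b] = np.where(active, updated, state[b])

        # 3. non-fatal events, fixed order, one uniform per event per cycle
        new_events = {}
        any_event = np.zeros(n, dtype=bool)
        for name, eq in engine.events.items():
            u = rngs[f"event:{name}"].random(n)
            t = state["age"] if eq.time_covariate == "age" else state["diabetes_duration"]
            p = np.asarray(annual_event_probability(eq, state, t), dtype=float)
            at_risk = active & (state[f"hist_{name}"] == 0.0)
            occurred = at_risk & (u < p)
            new_events[name] = occurred
            any_event |= occurred
        prior_history = {name: state[f"hist_{name}"].copy() for name in engine.events}
        for name, occurred in new_events.items():
            state[f"hist_{name}"] = np.maximum(state[f"hist_{name}"], occurred.astype(float))
            event_counts[name] += int(occurred.sum())

        # 4. mortality
        u_death = rngs["mortality"].random(n)
        t_ev = (
            state["age"]
            if engine.mortality_event_year.time_covariate == "age"
            else state["diabetes_duration"]
        )
        t_ne = (
            state["age"]
            if engine.mortality_no_event.time_covariate == "age"
            else state["diabetes_duration"]
        )
        p_event = np.asarray(
            annual_event_probability(engine.mortality_event_year, state, t_ev), dtype=float
        )
        p_no_event = np.asarray(
            annual_event_probability(engine.mortality_no_event, state, t_ne), dtype=float
        )
        p_death = np.where(any_event, p_event, p_no_event)
        died = active & (u_death < p_death)

        # 5. costs and utility
        cost = np.full(n, econ.management_cost)
        for name in engine.events:
            first = econ.complication_first_year_cost.get(name, 0.0)
            subseq = econ.complication_subsequent_cost.get(name, 0.0)
            cost += first * new_events[name] + subseq * prior_history[name]
        if cycle == 1:
            cost = cost + intervention_cost_per_patient
        utility = np.asarray(cycle_utility(state, econ), dtype=float)
        utility = np.where(died, 0.5 * utility, utility)

        df = discount_factor(cycle, econ.discount_rate)
        disc_cost += np.where(active, df * cost, 0.0)
        undisc_cost += np.where(active, cost, 0.0)
        disc_qaly += np.where(active, df * utility, 0.0)
        life_years += np.where(active, np.where(died, 0.5, 1.0), 0.0)

        if collect_trajectory:
            trajectory_rows.append(
                {
                    "cycle": cycle,
                    "age": float(state["age"][0]),
                    **{b: float(state[b][0]) for b in BIOMARKERS},
                    "events": ",".join(sorted(e for e, occ in new_events.items() if occ[0])),
                    "died": bool(died[0]),
                    "cost_gbp": float(cost[0]) if active[0] else 0.0,
                    "utility": float(utility[0]) if active[0] else 0.0,
                    "discount": df,
                }
            )

        alive &= ~died
        state["age"] = np.where(active, state["age"] + 1.0, state["age"])
        state["diabetes_duration"] = np.where(
            active, state["diabetes_duration"] + 1.0, state["diabetes_duration"]
        )

    trajectory = pd.DataFrame(trajectory_rows) if collect_trajectory else None
    return CohortResult(
        discounted_cost=disc_cost,
        discounted_qalys=disc_qaly,
        life_years=life_years,
        undiscounted_cost=undisc_cost,
        event_counts=event_counts,
        trajectory=trajectory,
    )


@dataclass
class Trajectory:
    """One person's per-cycle record plus lifetime summaries."""

    cycles: pd.DataFrame
    discounted_cost: float
    discounted_qalys: float
    life_years: float


def simulate_person(
    initial: pd.Series | Mapping[str, object],
    engine: RiskEngineSpec,
    effects: EffectProfile,
    econ: EconomicParams,
    *,
    horizon: int | None = None,
    seed: int,
    max_age: float = 100.0,
) -> Trajectory:
    """Simulate a single person, returning the full cycle-level trajectory."""
    cohort = pd.DataFrame([dict(initial)])
    result = simulate_cohort(
        cohort,
        engine,
        effects,
        econ,
        seed=seed,
        horizon=horizon,
        max_age=max_age,
        collect_trajectory=True,
    )
    return Trajectory(
        cycles=result.trajectory,
        discounted_cost=float(result.discounted_cost[0]),
        discounted_qalys=float(result.discounted_qalys[0]),
        life_years=float(result.life_years[0]),
    )


def icer_and_label(delta_cost: float, delta_qalys: float) -> tuple[float | None, str]:
    """Incremental cost-effectiveness ratio and its dominance label.

    The ICER is only meaningful in the NE (costlier, more effective) and SW
    (cheaper, less effective) quadrants; elsewhere a dominance label is
    returned instead.
    """
    if delta_qalys == 0.0:
        if delta_cost > 0:
            return None, "intervention costlier, equal QALYs"
        if delta_cost < 0:
            return None, "intervention cheaper, equal QALYs"
        return None, "equivalent"
    if delta_qalys > 0 and delta_cost <= 0:
        return None, "intervention dominates"
    if delta_qalys < 0 and delta_cost >= 0:
        return None, "control dominates"
    return delta_cost / delta_qalys, "ICER"


@dataclass
class ArmComparison:
    """Mean per-person outcomes in each arm and their increments."""

    control: dict[str, float]
    intervention: dict[str, float]
    delta_cost: float
    delta_qalys: float
    delta_life_years: float
    icer: float | None
    label: str
    n: int
    control_result: CohortResult | None = None
    intervention_result: CohortResult | None = None


def simulate_arms(
    cohort: pd.DataFrame,
    engine: RiskEngineSpec,
    control_effects: EffectProfile,
    intervention_effects: EffectProfile,
    econ: EconomicParams,
    *,
    intervention_cost_per_patient: float = 0.0,
    horizon: int | None = None,
    seed: int,
    max_age: float = 100.0,
    keep_person_results: bool = False,
) -> ArmComparison:
    """Simulate both arms on the same cohort with common random numbers.

    The intervention arm is charged ``intervention_cost_per_patient`` in
    cycle 1 (undiscounted), so with identical effect profiles the cost
    increment equals that charge exactly and the QALY increment is zero.
    """
    control = simulate_cohort(
        cohort, engine, control_effects, econ, seed=seed, horizon=horizon, max_age=max_age
    )
    intervention = simulate_cohort(
        cohort,
        engine,
        intervention_effects,
        econ,
        seed=seed,
        horizon=horizon,
        max_age=max_age,
        intervention_cost_per_patient=intervention_cost_per_patient,
    )
    c, i = control.means(), intervention.means()
    delta_cost = i["discounted_cost"] - c["discounted_cost"]
    delta_qalys = i["discounted_qalys"] - c["discounted_qalys"]
    icer, label = icer_and_label(delta_cost, delta_qalys)
    return ArmComparison(
        control=c,
        intervention=i,
        delta_cost=delta_cost,
        delta_qalys=delta_qalys,
        delta_life_years=i["life_years"] - c["life_years"],
        icer=icer,
        label=label,
        n=len(cohort),
        control_result=control if keep_person_results else None,
        intervention_result=intervention if keep_person_results else None,
    )
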