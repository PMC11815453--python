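"""Probabilistic sensitivity analysis and cost-effectiveness statistics.

The outer loop draws every uncertain model parameter from its assigned
distribution; the inner loop simulates a fresh cohort per draw under both
arms with common random numbers and records the per-arm mean discounted cost
and QALYs.  Decision statistics follow the standard net-monetary-benefit
rules: the ICER is computed from the expected increments across draws (never
a mean of per-draw ratios), and the cost-effectiveness acceptability curve
(CEAC) reports, for each willingness-to-pay threshold, the fraction of draws
in which the intervention's net monetary benefit strictly exceeds the
comparator's (ties count as not cost-effective).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .effects import EffectProfile, build_base_profile
from .microsim import EconomicParams, icer_and_label, simulate_arms
from .riskengine import RiskEngineSpec, engine_from_dict

DISTRIBUTION_FAMILIES = ("normal", "lognormal", "gamma", "beta", "multivariate_normal")

PARAMETER_GROUPS = (
    "effectiveness",
    "cost",
    "utility",
    "risk_micro",
    "risk_macro",
    "mortality",
    "progression",
)

DEFAULT_THRESHOLD = 20_000.0


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain parameter (or multivariate block) in the PSA.

    ``target`` is a dotted address naming the model quantity the draw
    replaces, e.g. ``effects.hba1c_year1``, ``econ.management_cost``,
    ``econ.first_cost.mi``, ``engine.event.mi.intercept`` or
    ``engine.progression.hba1c.coef.hba1c``.  Multivariate-normal blocks
    carry parallel ``names``/``targets`` lists in ``params``.
    """

    name: str
    family: str
    params: Mapping[str, object]
    group: str
    target: str | None = None

    def __post_init__(self) -> None:
        if self.family not in DISTRIBUTION_FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if self.group not in PARAMETER_GROUPS:
            raise ValueError(f"{self.name}: unknown group tag {self.group!r}")
        p = self.params
        if self.family == "normal":
            if p["sd"] < 0:
                raise ValueError(f"{self.name}: normal sd must be >= 0")
        elif self.family == "lognormal":
            if p["sigma"] < 0:
                raise ValueError(f"{self.name}: lognormal sigma must be >= 0")
        elif self.family == "gamma":
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise ValueError(f"{self.name}: gamma shape and scale must be > 0")
        elif self.family == "beta":
            if p["a"] <= 0 or p["b"] <= 0:
                raise ValueError(f"{self.name}: beta a and b must be > 0")
        elif self.family == "multivariate_normal":
            mean = np.asarray(p["mean"], dtype=float)
            cov = np.asarray(p["cov"], dtype=float)
            names = list(p["names"])
            if cov.shape != (len(mean), len(mean)) or len(names) != len(mean):
                raise ValueError(f"{self.name}: inconsistent multivariate block shapes")
            eigvals = np.linalg.eigvalsh((cov + cov.T) / 2.0)
            if eigvals.min() < -1e-10:
                raise ValueError(f"{self.name}: covariance is not positive semidefinite")

    @property
    def column_names(self) -> list[str]:
        if self.family == "multivariate_normal":
            return list(self.params["names"])
        return [self.name]

    def targets(self) -> list[tuple[str, str]]:
        """(column name, target address) pairs for applying draws to the model."""
        if self.family == "multivariate_normal":
            return list(zip(self.params["names"], self.params["targets"]))
        return [(self.name, self.target)] if self.target else []


def sample_parameters(
    spec: Sequence[ParameterDistribution], n_draws: int, seed: int
) -> pd.DataFrame:
    """Draw ``n_draws`` joint parameter samples; reproducible given ``seed``."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    for dist in spec:
        p = dist.params
        if dist.family == "normal":
            columns[dist.name] = rng.normal(p["mean"], p["sd"], n_draws)
        elif dist.family == "lognormal":
            columns[dist.name] = rng.lognormal(p["mu"], p["sigma"], n_draws)
        elif dist.family == "gamma":
            columns[dist.name] = rng.gamma(p["shape"], p["scale"], n_draws)
        elif dist.family == "beta":
            columns[dist.name] = rng.beta(p["a"], p["b"], n_draws)
        elif dist.family == "multivariate_normal":
            block = rng.multivariate_normal(
                np.asarray(p["mean"], dtype=float),
                np.asarray(p["cov"], dtype=float),
                size=n_draws,
                method="svd",
            )
            for j, name in enumerate(p["names"]):
                columns[name] = block[:, j]
    df = pd.DataFrame(columns)
    df.insert(0, "draw", np.arange(n_draws))
    return df


def _apply_target(
    target: str,
    value: float,
    engine_doc: dict,
    econ: EconomicParams,
    effect_inputs: dict,
) -> None:
    parts = target.split(".")
    root = parts[0]
    if root == "effects":
        effect_inputs[parts[1]] = value
    elif root == "econ":
        if parts[1] == "first_cost":
            econ.complication_first_year_cost[parts[2]] = value
        elif parts[1] == "subsequent_cost":
            econ.complication_subsequent_cost[parts[2]] = value
        elif parts[1] == "decrement":
            econ.utility_decrements[parts[2]] = value
        elif hasattr(econ, parts[1]):
            setattr(econ, parts[1], value)
        else:
            raise KeyError(f"unknown econ target {target!r}")
    elif root == "engine":
        if parts[1] == "event":
            eq = engine_doc["events"][parts[2]]
            rest = parts[3:]
        elif parts[1] == "mortality":
            eq = engine_doc["mortality"][parts[2]]
            rest = parts[3:]
        elif parts[1] == "progression":
            eq = engine_doc["progressions"][parts[2]]
            rest = parts[3:]
        else:
            raise KeyError(f"unknown engine target {target!r}")
        if rest[0] == "coef":
            eq["coefficients"][rest[1]] = value
        elif rest[0] in ("intercept", "shape", "residual_sd"):
            eq[rest[0]] = value
        else:
            raise KeyError(f"unknown engine target {target!r}")
    else:
        raise KeyError(f"unknown target root in {target!r}")


def instantiate_draw(
    row: Mapping[str, float],
    spec: Sequence[ParameterDistribution],
    engine: RiskEngineSpec,
    econ: EconomicParams,
    effect_inputs: Mapping[str, object],
) -> tuple[RiskEngineSpec, EconomicParams, dict]:
    """Build the draw-specific engine, economics and effect inputs."""
    engine_doc = engine.to_dict()
    econ_d = copy.deepcopy(econ)
    econ_d.complication_first_year_cost = dict(econ_d.complication_first_year_cost)
    econ_d.complication_subsequent_cost = dict(econ_d.complication_subsequent_cost)
    econ_d.utility_decrements = dict(econ_d.utility_decrements)
    eff = copy.deepcopy(dict(effect_inputs))
    for dist in spec:
        for column, target in dist.targets():
            _apply_target(target, float(row[column]), engine_doc, econ_d, eff)
    return engine_from_dict(engine_doc), econ_d, eff


def _profile_from_inputs(eff: Mapping[str, object], n_cycles: int) -> EffectProfile:
    year1 = {
        "hba1c": eff.get("hba1c_year1", 0.0),
        "bmi": eff.get("bmi_year1", 0.0),
        "sbp": eff.get("sbp_year1", 0.0),
        "hdl": eff.get("hdl_year1", 0.0),
        "ldl": eff.get("ldl_year1", 0.0),
    }
    return build_base_profile(
        year1,
        eff.get("hba1c_year2", year1["hba1c"]),
        (eff.get("attendance_lor1", 0.0), eff.get("attendance_lor2", 0.0)),
        n_cycles=n_cycles,
    )


def _sub_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_psa(
    spec: Sequence[ParameterDistribution],
    cohort_generator: Callable[[int, int], pd.DataFrame],
    engine: RiskEngineSpec,
    effect_inputs: Mapping[str, object],
    econ: EconomicParams,
    *,
    intervention_cost_per_patient: float = 0.0,
    n_outer: int = 200,
    n_inner: int = 500,
    seed: int,
    horizon: int | None = None,
    profile_builder: Callable[[Mapping[str, object], int], EffectProfile] | None = None,
    n_cycles: int = 40,
) -> pd.DataFrame:
    """Outer-loop parameter draws around inner-loop cohort simulations.

    ``cohort_generator(n, seed)`` supplies a fresh baseline cohort per outer
    draw.  Returns one row per draw with the sampled parameter values and the
    per-arm mean discounted cost and QALYs (plus their increments).
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must be >= 1")
    params = sample_parameters(spec, n_outer, seed)
    build = profile_builder or _profile_from_inputs
    rows = []
    for d in range(n_outer):
        row = params.iloc[d]
        try:
            engine_d, econ_d, eff_d = instantiate_draw(row, spec, engine, econ, effect_inputs)
            cohort = cohort_generator(n_inner, _sub_seed(seed, 1, d))
            intervention_profile = build(eff_d, n_cycles)
            control_profile = EffectProfile.zero(intervention_profile.n_cycles)
            comparison = simulate_arms(
                cohort,
                engine_d,
                control_profile,
                intervention_profile,
                econ_d,
                intervention_cost_per_patient=intervention_cost_per_patient,
                horizon=horizon,
                seed=_sub_seed(seed, 2, d),
            )
        except Exception as exc:
            raise RuntimeError(f"PSA outer draw {d} failed: {exc}") from exc
        record = dict(row)
        record.update(
            {
                "cost_control": comparison.control["discounted_cost"],
                "qalys_control": comparison.control["discounted_qalys"],
                "cost_intervention": comparison.intervention["discounted_cost"],
                "qalys_intervention": comparison.intervention["discounted_qalys"],
                "delta_cost": comparison.delta_cost,
                "delta_qalys": comparison.delta_qalys,
            }
        )
        rows.append(record)
    out = pd.DataFrame(rows)
    out["draw"] = out["draw"].astype(int)
    return out


def ceac(samples: pd.DataFrame, thresholds: Iterable[float]) -> pd.DataFrame:
    """Probability the intervention is cost-effective at each threshold.

    A draw counts as cost-effective when ``threshold * dQ - dC > 0``; ties at
    zero net benefit count against the intervention.
    """
    if samples.empty:
        raise ValueError("no PSA samples")
    dc = samples["delta_cost"].to_numpy()
    dq = samples["delta_qalys"].to_numpy()
    rows = [
        {"threshold": float(lam), "probability": float(np.mean(lam * dq - dc > 0.0))}
        for lam in thresholds
    ]
    return pd.DataFrame(rows)


@dataclass
class CEResult:
    """Headline cost-effectiveness statistics from a PSA sample."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: str
    threshold: float
    probability_cost_effective: float
    n_draws: int
    ceac_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer": self.icer,
            "label": self.label,
            "threshold": self.threshold,
            "probability_cost_effective": self.probability_cost_effective,
            "n_draws": self.n_draws,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def summarise_ce(
    samples: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    ceac_thresholds: Iterable[float] | None = None,
) -> CEResult:
    """Expected increments, ICER from expected increments, and P(cost-effective)."""
    if samples.empty:
        raise ValueError("no PSA samples")
    dc = float(samples["delta_cost"].mean())
    dq = float(samples["delta_qalys"].mean())
    icer, label = icer_and_label(dc, dq)
    prob = float(ceac(samples, [threshold])["probability"].iloc[0])
    table = None
    if ceac_thresholds is not None:
        table = ceac(samples, ceac_thresholds)
    return CEResult(
        delta_cost=dc,
        delta_qalys=dq,
        icer=icer,
        label=label,
        threshold=threshold,
        probability_cost_effective=prob,
        n_draws=len(samples),
        ceac_table=table,
    )


def plane_export(
    samples: pd.DataFrame, path, scenario_points: Mapping[str, tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Write the cost-effectiveness plane scatter (dQ, dC) to CSV.

    Optional deterministic scenario points are appended with their labels.
    """
    if samples.empty:
        raise ValueError("no PSA samples")
    out = pd.DataFrame(
        {
            "label": "psa_draw",
            "delta_qalys": samples["delta_qalys"].to_numpy(),
            "delta_cost": samples["delta_cost"].to_numpy(),
        }
    )
    if scenario_points:
        extra = pd.DataFrame(
            [
                {"label": name, "delta_qalys": dq, "delta_cost": dc}
                for name, (dq, dc) in scenario_points.items()
            ]
        )
        out = pd.concat([out, extra], ignore_index=True)
    out.to_csv(path, index=False)
    return out
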