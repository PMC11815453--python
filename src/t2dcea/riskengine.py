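"""Pluggable annual risk equations and risk-factor progression.

Event and mortality equations follow the functional forms of the UKPDS
Outcomes Model family: logistic, and proportional-hazards forms with
exponential, Weibull or Gompertz baseline hazards discretised to annual
cycles via the hazard increment over [t, t+1).  Risk-factor progression
follows the UKPDS 90 pattern: a linear predictor on the current value, the
baseline value and demographics, plus a normal residual.

Coefficients are data, not code: published coefficient tables can be dropped
in as JSON, and the bundled toy engines (see :mod:`t2dcea.synthdata`) carry
known parameters for oracle tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

EQUATION_FORMS = ("logistic", "exponential_ph", "weibull_ph", "gompertz_ph")
TIME_COVARIATES = ("age", "diabetes_duration")


class EngineSpecError(ValueError):
    """Raised when an engine document violates the schema; message carries the field path."""


@dataclass(frozen=True)
class RiskEquation:
    """One annual event (or mortality) equation.

    ``shape`` is the Weibull rho or Gompertz phi and must be present exactly
    when the form requires it.  ``time_covariate`` names the clock the
    baseline hazard runs on (diabetes duration for complications, age for
    mortality, by convention).
    """

    name: str
    form: str
    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)
    shape: float | None = None
    time_covariate: str = "diabetes_duration"

    def __post_init__(self) -> None:
        if self.form not in EQUATION_FORMS:
            raise EngineSpecError(f"{self.name}.form: unknown form {self.form!r}")
        needs_shape = self.form in ("weibull_ph", "gompertz_ph")
        if needs_shape and self.shape is None:
            raise EngineSpecError(f"{self.name}.shape: required for form {self.form!r}")
        if not needs_shape and self.shape is not None:
            raise EngineSpecError(f"{self.name}.shape: not allowed for form {self.form!r}")
        if self.time_covariate not in TIME_COVARIATES:
            raise EngineSpecError(
                f"{self.name}.time_covariate: unknown clock {self.time_covariate!r}"
            )

    def to_dict(self) -> dict:
        out = {
            "form": self.form,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "time_covariate": self.time_covariate,
        }
        if self.shape is not None:
            out["shape"] = self.shape
        return out


@dataclass(frozen=True)
class ProgressionEquation:
    """Annual update equation for one continuous risk factor."""

    name: str
    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)
    residual_sd: float = 0.0
    floor: float | None = None

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise EngineSpecError(f"{self.name}.residual_sd: must be >= 0")

    def to_dict(self) -> dict:
        out = {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "residual_sd": self.residual_sd,
        }
        if self.floor is not None:
            out["floor"] = self.floor
        return out


def linear_predictor(eq: RiskEquation | ProgressionEquation, state: Mapping[str, object]):
    """Intercept plus the coefficient-weighted sum of state covariates.

    ``state`` maps covariate names to scalars or aligned numpy arrays.  A
    coefficient on a covariate the state does not expose is an error, never a
    silent zero.
    """
    lp = eq.intercept
    for cov, coef in eq.coefficients.items():
        if cov not in state:
            raise KeyError(f"equation {eq.name!r} references unknown covariate {cov!r}")
        lp = lp + coef * np.asarray(state[cov], dtype=float)
    return lp


def annual_event_probability(eq: RiskEquation, state: Mapping[str, object], t):
    """Probability of the event during annual cycle [t, t+1).

    PH forms integrate the baseline hazard over the cycle:
    exponential H' = exp(LP); Weibull increment exp(LP)((t+1)^rho - t^rho);
    Gompertz increment exp(LP)(e^{phi(t+1)} - e^{phi t})/phi.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lp = np.asarray(linear_predictor(eq, state), dtype=float)
    if not np.all(np.isfinite(lp)):
        raise FloatingPointError(f"non-finite linear predictor in equation {eq.name!r}")
    if eq.form == "logistic":
        p = 1.0 / (1.0 + np.exp(-lp))
    elif eq.form == "exponential_ph":
        p = 1.0 - np.exp(-np.exp(lp) * np.ones_like(t))
    elif eq.form == "weibull_ph":
        rho = eq.shape
        increment = (t + 1.0) ** rho - t**rho
        p = 1.0 - np.exp(-np.exp(lp) * increment)
    elif eq.form == "gompertz_ph":
        phi = eq.shape
        increment = (np.exp(phi * (t + 1.0)) - np.exp(phi * t)) / phi
        p = 1.0 - np.exp(-np.exp(lp) * increment)
    else:  # pragma: no cover - validated in __post_init__
        raise EngineSpecError(f"unknown form {eq.form!r}")
    return p if p.shape else float(p)


def progress_risk_factor(eq: ProgressionEquation, state: Mapping[str, object], noise):
    """Next-cycle value of a risk factor: linear predictor plus external noise.

    The residual draw is supplied by the caller (mean 0, SD ``residual_sd``)
    so the operation itself is deterministic.  Values are clamped at the
    equation's physiological floor when one is set.
    """
    value = np.asarray(linear_predictor(eq, state), dtype=float) + np.asarray(noise, dtype=float)
    if eq.floor is not None:
        value = np.maximum(value, eq.floor)
    return value if value.shape else float(value)


@dataclass(frozen=True)
class RiskEngineSpec:
    """The full equation layer: events, mortality, progression.

    ``events`` preserves insertion order, which fixes the within-cycle event
    draw order in the simulator.  Mortality has two equations: one applying
    in cycles with a new complication event, one otherwise.
    """

    events: Mapping[str, RiskEquation]
    mortality_event_year: RiskEquation
    mortality_no_event: RiskEquation
    progressions: Mapping[str, ProgressionEquation]

    def __post_init__(self) -> None:
        for name, eq in self.events.items():
            if eq.name != name:
                raise EngineSpecError(f"events.{name}: equation name mismatch ({eq.name!r})")
        for name, eq in self.progressions.items():
            if eq.name != name:
                raise EngineSpecError(f"progressions.{name}: equation name mismatch ({eq.name!r})")

    def to_dict(self) -> dict:
        return {
            "events": {n: eq.to_dict() for n, eq in self.events.items()},
            "mortality": {
                "event_year": self.mortality_event_year.to_dict(),
                "no_event": self.mortality_no_event.to_dict(),
            },
            "progressions": {n: eq.to_dict() for n, eq in self.progressions.items()},
        }


def _build_risk_equation(name: str, doc: dict, path: str) -> RiskEquation:
    if not isinstance(doc, dict):
        raise EngineSpecError(f"{path}: expected an object")
    unknown = set(doc) - {"form", "intercept", "coefficients", "shape", "time_covariate"}
    if unknown:
        raise EngineSpecError(f"{path}: unknown fields {sorted(unknown)}")
    if "form" not in doc:
        raise EngineSpecError(f"{path}.form: required")
    return RiskEquation(
        name=name,
        form=doc["form"],
        intercept=float(doc.get("intercept", 0.0)),
        coefficients={k: float(v) for k, v in doc.get("coefficients", {}).items()},
        shape=None if doc.get("shape") is None else float(doc["shape"]),
        time_covariate=doc.get("time_covariate", "diabetes_duration"),
    )


def _build_progression(name: str, doc: dict, path: str) -> ProgressionEquation:
    if not isinstance(doc, dict):
        raise EngineSpecError(f"{path}: expected an object")
    unknown = set(doc) - {"intercept", "coefficients", "residual_sd", "floor"}
    if unknown:
        raise EngineSpecError(f"{path}: unknown fields {sorted(unknown)}")
    if "intercept" not in doc:
        raise EngineSpecError(f"{path}.intercept: required")
    return ProgressionEquation(
        name=name,
        intercept=float(doc["intercept"]),
        coefficients={k: float(v) for k, v in doc.get("coefficients", {}).items()},
        residual_sd=float(doc.get("residual_sd", 0.0)),
        floor=None if doc.get("floor") is None else float(doc["floor"]),
    )


def engine_from_dict(doc: dict) -> RiskEngineSpec:
    for section in ("events", "mortality", "progressions"):
        if section not in doc:
            raise EngineSpecError(f"{section}: required section missing")
    events = {
        name: _build_risk_equation(name, spec, f"events.{name}")
        for name, spec in doc["events"].items()
    }
    mortality = doc["mortality"]
    for key in ("event_year", "no_event"):
        if key not in mortality:
            raise EngineSpecError(f"mortality.{key}: required")
    progressions = {
        name: _build_progression(name, spec, f"progressions.{name}")
        for name, spec in doc["progressions"].items()
    }
    return RiskEngineSpec(
        events=events,
        mortality_event_year=_build_risk_equation(
            "mortality_event_year", mortality["event_year"], "mortality.event_year"
        ),
        mortality_no_event=_build_risk_equation(
            "mortality_no_event", mortality["no_event"], "mortality.no_event"
        ),
        progressions=progressions,
    )


def load_engine(path) -> RiskEngineSpec:
    """Load and validate a JSON engine specification."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise EngineSpecError(f"malformed JSON in {path}: {exc}") from None
    return engine_from_dict(doc)


def save_engine(spec: RiskEngineSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2)
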