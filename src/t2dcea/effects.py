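"""Treatment-effect profiles, waning schedules and scenario analyses.

An :class:`EffectProfile` holds, for every simulated annual cycle, the
additive offsets the intervention applies to each biomarker (HbA1c in
percentage points, BMI in kg/m2, SBP in mmHg, HDL and LDL in mmol/L) and the
log odds ratio it applies to the probability of attending structured
self-management education (SSME).

The base case encodes the trial read-outs: year-1 offsets for all five
biomarkers, a year-2 HbA1c offset from observational follow-up (other
biomarkers carried forward from year 1), the year-2 level maintained for one
further year, then waning entirely by the end of year 4.  With annual cycles
the waning year is sampled at its midpoint, so the cycle-4 offset is half the
plateau value.

Scenario families (S1-S8) re-parameterise that schedule: dropping
non-significant effects, using 12-month read-outs, substituting
literature-based SSME effectiveness mediated by attendance changes, extending
effect durations, swapping the year-1 HbA1c source, and restricting the
simulated population to subgroups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

BIOMARKERS = ("hba1c", "bmi", "sbp", "hdl", "ldl")

WANE_MODES = ("base_case", "fixed_duration", "plateau_linear", "lifetime")

#: Fraction of people with newly diagnosed T2DM recorded as attending SSME
#: within 12 months under usual care.
DEFAULT_BASELINE_ATTENDANCE = 0.056


def plateau_wane_curve(
    plateau_years: float, zero_year: float, n_cycles: int, lifetime: bool = False
) -> np.ndarray:
    """Fractional effect by year since onset: full for ``plateau_years``, then
    declining linearly to zero at the end of year ``zero_year``.

    Annual cycles sample the declining segment at its midpoint (a cycle
    entirely inside the ramp carries the ramp's mid-year value), so a one-year
    ramp contributes half the plateau level.  ``zero_year == plateau_years``
    means a hard stop with no ramp; ``lifetime`` holds the full effect for
    every cycle.
    """
    if plateau_years < 0 or zero_year < plateau_years:
        raise ValueError("need 0 <= plateau_years <= zero_year")
    years = np.arange(1, n_cycles + 1, dtype=float)
    if lifetime:
        return np.ones(n_cycles)
    curve = np.zeros(n_cycles)
    full = years <= plateau_years
    curve[full] = 1.0
    ramp_len = zero_year - plateau_years
    if ramp_len > 0:
        in_ramp = (~full) & (years <= zero_year)
        midpoints = years[in_ramp] - 0.5
        curve[in_ramp] = 1.0 - (midpoints - plateau_years) / ramp_len
    return curve


@dataclass(frozen=True)
class EffectProfile:
    """Per-cycle intervention offsets for biomarkers and attendance log-OR."""

    offsets: Mapping[str, np.ndarray]  # biomarker -> length-n_cycles array
    attendance_log_or: np.ndarray
    wane_mode: str = "base_case"

    def __post_init__(self) -> None:
        if self.wane_mode not in WANE_MODES:
            raise ValueError(f"unknown wane_mode {self.wane_mode!r}")
        n = len(self.attendance_log_or)
        for name in BIOMARKERS:
            if name not in self.offsets:
                raise ValueError(f"missing biomarker offsets for {name!r}")
            if len(self.offsets[name]) != n:
                raise ValueError(f"offset length mismatch for {name!r}")

    @property
    def n_cycles(self) -> int:
        return len(self.attendance_log_or)

    def offset_at(self, biomarker: str, cycle: int) -> float:
        """Offset applied during annual ``cycle`` (1-based); zero beyond the schedule."""
        if cycle < 1:
            raise ValueError("cycle must be >= 1")
        arr = self.offsets[biomarker]
        return float(arr[cycle - 1]) if cycle <= len(arr) else 0.0

    @classmethod
    def zero(cls, n_cycles: int) -> "EffectProfile":
        return cls(
            offsets={b: np.zeros(n_cycles) for b in BIOMARKERS},
            attendance_log_or=np.zeros(n_cycles),
        )

    def is_zero(self) -> bool:
        return all(not np.any(v) for v in self.offsets.values()) and not np.any(
            self.attendance_log_or
        )

    def to_frame(self) -> pd.DataFrame:
        data = {b: self.offsets[b] for b in BIOMARKERS}
        data["attendance_log_or"] = self.attendance_log_or
        return pd.DataFrame(data, index=pd.RangeIndex(1, self.n_cycles + 1, name="cycle"))


def build_base_profile(
    year1_effects: Mapping[str, float],
    year2_hba1c: float,
    attendance_log_ors: Sequence[float],
    *,
    n_cycles: int = 40,
    carry_sbp_forward: bool = True,
    plateau_years: float = 3.0,
    zero_year: float = 4.0,
) -> EffectProfile:
    """Base-case effect schedule from year-1 and year-2 trial estimates.

    Cycle 1 carries the year-1 estimates; cycle 2 the year-2 HbA1c estimate
    with the other biomarkers carried forward from year 1 (SBP carried too
    unless ``carry_sbp_forward`` is false, in which case its year-2 offset is
    zero); the year-2 level holds through year ``plateau_years`` and wanes
    linearly to zero at the end of year ``zero_year``.
    """
    missing = [b for b in BIOMARKERS if b not in year1_effects]
    if missing:
        raise ValueError(f"year-1 effects missing for: {missing}")
    if len(attendance_log_ors) != 2:
        raise ValueError("attendance_log_ors must supply (year 1, year 2) values")

    wane = plateau_wane_curve(plateau_years, zero_year, n_cycles)
    offsets = {}
    for b in BIOMARKERS:
        y1 = float(year1_effects[b])
        if b == "hba1c":
            y2 = float(year2_hba1c)
        elif b == "sbp" and not carry_sbp_forward:
            y2 = 0.0
        else:
            y2 = y1
        sched = y2 * wane
        if n_cycles >= 1:
            sched[0] = y1
        offsets[b] = sched
    lor1, lor2 = (float(v) for v in attendance_log_ors)
    att = lor2 * wane
    if n_cycles >= 1:
        att[0] = lor1
    return EffectProfile(offsets=offsets, attendance_log_or=att)


def attendance_probability(baseline_rate: float, log_or: float) -> float:
    """Attendance probability after shifting the baseline odds by ``log_or``."""
    if not 0.0 < baseline_rate < 1.0:
        raise ValueError("baseline_rate must lie strictly between 0 and 1")
    return float(expit(logit(baseline_rate) + log_or))


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

SCENARIO_IDS = (
    "base",
    "S1",
    "S2",
    "S3",
    "S4",
    "S5a",
    "S5b",
    "S6a",
    "S6b",
    "S7a",
    "S7b",
    "S7c",
    "S7d",
    "S7e",
    "S7f",
    "S7g",
    "S8a",
    "S8b",
    "S8c",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameterisation of one scenario analysis.

    ``hba1c_year1``/``hba1c_year2`` override the base-case HbA1c offsets (S2,
    S7x, S8x); ``attendance_log_ors`` overrides the attendance schedule (S2);
    ``literature_effect`` is the mean HbA1c change (percentage points) among
    SSME attenders from external evidence, delivered to the extra attenders
    the intervention generates (S3, S4, S6); ``population_filter`` restricts
    the simulated cohort (S8 only).
    """

    scenario_id: str = "base"
    hba1c_year1: float | None = None
    hba1c_year2: float | None = None
    attendance_log_ors: tuple[float, float] | None = None
    literature_effect: float = -0.30
    literature_plateau_years: float = 6.0
    literature_zero_year: float = 10.0
    literature_lifetime: bool = False
    apply_literature_to: str = "attenders"  # or "referrals"
    referral_multiplier: float = 1.0  # referrals per extra attender, if applied to referrals
    baseline_attendance: float = DEFAULT_BASELINE_ATTENDANCE
    duration_years: float | None = None  # S5 fixed-duration override
    population_filter: tuple[str, object] | None = None

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario_id {self.scenario_id!r}")
        if self.population_filter is not None and not self.scenario_id.startswith("S8"):
            raise ValueError("population filters are only defined for S8 scenarios")
        if not 0.0 < self.baseline_attendance < 1.0:
            raise ValueError("baseline_attendance must lie strictly in (0, 1)")
        if self.apply_literature_to not in ("attenders", "referrals"):
            raise ValueError("apply_literature_to must be 'attenders' or 'referrals'")


def _literature_offsets(
    attendance_log_or: np.ndarray, config: ScenarioConfig, n_cycles: int
) -> np.ndarray:
    """HbA1c offsets from external SSME effectiveness mediated by attendance.

    Each cycle's change in attendance probability (intervention minus usual
    care) launches the literature effect for the extra attenders, which then
    follows its own plateau/wane curve.  Contributions from successive
    attendance cohorts are summed (a discrete convolution).
    """
    curve = plateau_wane_curve(
        config.literature_plateau_years,
        config.literature_zero_year,
        n_cycles,
        lifetime=config.literature_lifetime,
    )
    scale = config.referral_multiplier if config.apply_literature_to == "referrals" else 1.0
    offsets = np.zeros(n_cycles)
    for s, lor in enumerate(attendance_log_or):
        if lor == 0.0:
            continue
        delta_p = attendance_probability(config.baseline_attendance, lor) - config.baseline_attendance
        contribution = delta_p * scale * config.literature_effect
        length = n_cycles - s
        offsets[s:] += contribution * curve[:length]
    return offsets


def apply_scenario(
    base: EffectProfile, config: ScenarioConfig
) -> tuple[EffectProfile, tuple[str, object] | None]:
    """Derive a scenario's effect profile (and population filter) from the base case."""
    sid = config.scenario_id
    n = base.n_cycles
    offsets = {b: base.offsets[b].copy() for b in BIOMARKERS}
    att = base.attendance_log_or.copy()

    def rebuilt(year1_hba1c=None, year2_hba1c=None, attendance=None, plateau=3.0, zero=4.0):
        y1 = {b: float(offsets[b][0]) if n else 0.0 for b in BIOMARKERS}
        if year1_hba1c is not None:
            y1["hba1c"] = year1_hba1c
        y2 = year2_hba1c if year2_hba1c is not None else (offsets["hba1c"][1] if n > 1 else 0.0)
        lors = attendance if attendance is not None else (att[0] if n else 0.0, att[1] if n > 1 else 0.0)
        return build_base_profile(y1, y2, tuple(lors), n_cycles=n, plateau_years=plateau, zero_year=zero)

    if sid == "base":
        profile = EffectProfile(offsets=offsets, attendance_log_or=att, wane_mode=base.wane_mode)
    elif sid == "S1":
        # non-significant secondary outcomes treated as zero change
        for b in ("bmi", "sbp", "hdl", "ldl"):
            offsets[b] = np.zeros(n)
        profile = EffectProfile(offsets=offsets, attendance_log_or=att, wane_mode=base.wane_mode)
    elif sid == "S2":
        # 12-month read-outs only: year-2 values collapse onto year 1
        y1 = config.hba1c_year1 if config.hba1c_year1 is not None else float(offsets["hba1c"][0])
        lor1 = config.attendance_log_ors[0] if config.attendance_log_ors else float(att[0])
        profile = rebuilt(year1_hba1c=y1, year2_hba1c=y1, attendance=(lor1, lor1))
    elif sid in ("S3", "S6a", "S6b"):
        cfg = config
        if sid == "S6a":
            cfg = replace(config, literature_plateau_years=10.0, literature_zero_year=15.0)
        elif sid == "S6b":
            cfg = replace(config, literature_lifetime=True)
        hba1c = _literature_offsets(att, cfg, n)
        offsets = {b: np.zeros(n) for b in BIOMARKERS}
        offsets["hba1c"] = hba1c
        profile = EffectProfile(offsets=offsets, attendance_log_or=att, wane_mode="plateau_linear")
    elif sid == "S4":
        # 12-month attendance (reduced uptake) with literature effectiveness
        lor1 = config.attendance_log_ors[0] if config.attendance_log_ors else float(att[0])
        att12 = plateau_wane_curve(3.0, 4.0, n) * lor1
        hba1c = _literature_offsets(att12, config, n)
        offsets = {b: np.zeros(n) for b in BIOMARKERS}
        offsets["hba1c"] = hba1c
        profile = EffectProfile(offsets=offsets, attendance_log_or=att12, wane_mode="plateau_linear")
    elif sid in ("S5a", "S5b"):
        duration = config.duration_years or (5.0 if sid == "S5a" else 10.0)
        curve = plateau_wane_curve(duration, duration, n)
        for b in BIOMARKERS:
            plateau_value = offsets[b][1] if n > 1 else (offsets[b][0] if n else 0.0)
            sched = plateau_value * curve
            if n:
                sched[0] = offsets[b][0]
            offsets[b] = sched
        att_plateau = att[1] if n > 1 else (att[0] if n else 0.0)
        att_sched = att_plateau * curve
        if n:
            att_sched[0] = att[0]
        profile = EffectProfile(offsets=offsets, attendance_log_or=att_sched, wane_mode="fixed_duration")
    elif sid.startswith("S7") or sid.startswith("S8"):
        if config.hba1c_year1 is None:
            raise ValueError(f"{sid} requires an alternative year-1 HbA1c estimate")
        profile = rebuilt(year1_hba1c=config.hba1c_year1, year2_hba1c=config.hba1c_year2)
    else:  # pragma: no cover - SCENARIO_IDS is exhaustive
        raise ValueError(f"unknown scenario_id {sid!r}")

    return profile, config.population_filter


def filter_cohort(cohort: pd.DataFrame, population_filter: tuple[str, object] | None) -> pd.DataFrame:
    """Restrict a cohort to a scenario's subgroup (S8 family)."""
    if population_filter is None:
        return cohort
    kind, value = population_filter
    if kind == "ethnicity":
        return cohort[cohort["ethnicity"] == value].reset_index(drop=True)
    if kind == "hba1c_ge_mmol":
        threshold = float(value)
        mmol = cohort.get("hba1c_mmol")
        if mmol is None:
            mmol = hba1c_percent_to_mmol(cohort["hba1c"])
        return cohort[mmol >= threshold].reset_index(drop=True)
    raise ValueError(f"unknown population filter kind {kind!r}")


def hba1c_percent_to_mmol(percent):
    """IFCC conversion: mmol/mol = 10.929 x (DCCT % - 2.15)."""
    return 10.929 * (np.asarray(percent, dtype=float) - 2.15)


def default_scenarios() -> dict[str, ScenarioConfig]:
    """A configured scenario set runnable on synthetic inputs.

    The alternative HbA1c point estimates (S2, S7a-g, S8a-c) come from trial
    sensitivity analyses whose values are not published; the numbers below
    are synthetic placeholders of plausible sign and magnitude so the full
    scenario grid can be exercised end to end.  Replace them with real
    estimates via configuration for substantive use.
    """
    return {
        "base": ScenarioConfig("base"),
        "S1": ScenarioConfig("S1"),
        "S2": ScenarioConfig("S2", hba1c_year1=-0.01, attendance_log_ors=(math.log(0.82), math.log(0.82))),
        "S3": ScenarioConfig("S3"),
        "S4": ScenarioConfig("S4", attendance_log_ors=(math.log(0.82), math.log(0.82))),
        "S5a": ScenarioConfig("S5a"),
        "S5b": ScenarioConfig("S5b"),
        "S6a": ScenarioConfig("S6a"),
        "S6b": ScenarioConfig("S6b"),
        "S7a": ScenarioConfig("S7a", hba1c_year1=-0.02),
        "S7b": ScenarioConfig("S7b", hba1c_year1=-0.018),
        "S7c": ScenarioConfig("S7c", hba1c_year1=-0.004),
        "S7d": ScenarioConfig("S7d", hba1c_year1=-0.019),
        "S7e": ScenarioConfig("S7e", hba1c_year1=0.012),
        "S7f": ScenarioConfig("S7f", hba1c_year1=-0.011),
        "S7g": ScenarioConfig("S7g", hba1c_year1=0.005),
        "S8a": ScenarioConfig("S8a", hba1c_year1=-0.009, population_filter=("ethnicity", "white")),
        "S8b": ScenarioConfig("S8b", hba1c_year1=-0.030, population_filter=("ethnicity", "minority")),
        "S8c": ScenarioConfig("S8c", hba1c_year1=-0.011, population_filter=("hba1c_ge_mmol", 47.5)),
    }
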