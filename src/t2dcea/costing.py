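"""Micro-costing of an implementation package from activity ledgers.

Staff time and direct expenses recorded during delivery of an implementation
package are priced with national unit-cost tables, inflated to a common price
year with a chain-linked price index (Hospital and Community Health Services
pay & prices index handed over to the NHS Cost Inflation Index at fiscal year
2014/15), aggregated into a cost-category x site-group summary table, and
converted to a per-patient cost adjusted for differential follow-up length.

All monetary values are GBP.  Pence are retained internally; summary exports
round to whole pounds and whole percentages (half-up).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SITE_GROUPS = ("waitlist", "immediate", "provider")

COST_CATEGORIES = (
    "embedder_direct",
    "practice_staff",
    "provider_staff",
    "travel",
    "marketing",
    "toolkit",
)

CATEGORY_LABELS = {
    "embedder_direct": "Embedder direct costs",
    "practice_staff": "Practice costs (staff)",
    "provider_staff": "Provider costs (staff)",
    "travel": "Travel and subsistence",
    "marketing": "Marketing materials costs",
    "toolkit": "Toolkit costs",
}

#: Follow-up length (days) of the group observed for the full delivery
#: period; per-patient costs are scaled to this common duration.
DEFAULT_REFERENCE_DAYS = 204.0

_FISCAL_RE = re.compile(r"^(\d{4})/(\d{2})$")


def fiscal_year_start(label: str) -> int:
    """Return the calendar start year of a fiscal-year label like ``2018/19``."""
    m = _FISCAL_RE.match(str(label))
    if not m:
        raise ValueError(f"not a fiscal-year label: {label!r} (expected e.g. '2018/19')")
    start, end = int(m.group(1)), int(m.group(2))
    if (start + 1) % 100 != end:
        raise ValueError(f"fiscal-year label {label!r} does not span consecutive years")
    return start


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used in the exports)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ActivityRecord:
    """One ledger row: either priced staff time or a direct expense.

    Exactly one of (``staff_role`` + ``minutes``) or ``expense_gbp`` must be
    populated.  ``price_year`` is the fiscal year the money value (or the
    activity, for staff time) belongs to.
    """

    site_id: str
    site_group: str
    category: str
    price_year: str
    staff_role: str | None = None
    minutes: float | None = None
    expense_gbp: float | None = None

    def __post_init__(self) -> None:
        if self.site_group not in SITE_GROUPS:
            raise ValueError(f"unknown site_group {self.site_group!r}")
        if self.category not in COST_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "provider_staff" and self.site_group != "provider":
            raise ValueError("category 'provider_staff' only valid for site_group 'provider'")
        staff = self.staff_role is not None and self.minutes is not None
        expense = self.expense_gbp is not None
        if staff == expense:
            raise ValueError(
                "exactly one of (staff_role + minutes) or expense_gbp must be populated"
            )
        if staff and self.minutes < 0:
            raise ValueError("minutes must be non-negative")
        if expense and self.expense_gbp < 0:
            raise ValueError("expense_gbp must be non-negative")
        fiscal_year_start(self.price_year)  # validates the label

    @property
    def is_staff(self) -> bool:
        return self.staff_role is not None


LEDGER_COLUMNS = [
    "site_id",
    "site_group",
    "category",
    "staff_role",
    "minutes",
    "expense_gbp",
    "price_year",
]


def read_ledger(path) -> list[ActivityRecord]:
    """Read an activity ledger CSV into validated records."""
    df = pd.read_csv(path, dtype={"site_id": str, "price_year": str})
    missing = set(LEDGER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ledger missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ActivityRecord(
                site_id=row.site_id,
                site_group=row.site_group,
                category=row.category,
                price_year=row.price_year,
                staff_role=None if pd.isna(row.staff_role) else str(row.staff_role),
                minutes=None if pd.isna(row.minutes) else float(row.minutes),
                expense_gbp=None if pd.isna(row.expense_gbp) else float(row.expense_gbp),
            )
        )
    return records


def write_ledger(records: Iterable[ActivityRecord], path) -> None:
    rows = [
        {
            "site_id": r.site_id,
            "site_group": r.site_group,
            "category": r.category,
            "staff_role": r.staff_role,
            "minutes": r.minutes,
            "expense_gbp": r.expense_gbp,
            "price_year": r.price_year,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=LEDGER_COLUMNS).to_csv(path, index=False)


@dataclass(frozen=True)
class UnitCost:
    hourly_gbp: float
    price_year: str

    def __post_init__(self) -> None:
        if self.hourly_gbp <= 0:
            raise ValueError("hourly cost must be > 0")
        fiscal_year_start(self.price_year)


@dataclass(frozen=True)
class UnitCostTable:
    """Hourly staff costs by role, each with the price year of its source."""

    rates: Mapping[str, UnitCost]

    def __getitem__(self, role: str) -> UnitCost:
        try:
            return self.rates[role]
        except KeyError:
            raise KeyError(f"unknown staff role {role!r}; known: {sorted(self.rates)}") from None

    @classmethod
    def from_json(cls, path) -> "UnitCostTable":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({role: UnitCost(**spec) for role, spec in raw.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {r: {"hourly_gbp": u.hourly_gbp, "price_year": u.price_year} for r, u in self.rates.items()},
                fh,
                indent=2,
            )


@dataclass(frozen=True)
class PriceIndexSeries:
    """Two price-index regimes chain-linked at a boundary fiscal year.

    ``hchs`` covers fiscal years up to and including the boundary; ``nhscii``
    covers the boundary year onwards.  Both must cover the boundary year so
    the regimes can be spliced into one continuous series.
    """

    hchs: Mapping[str, float]
    nhscii: Mapping[str, float]
    boundary: str = "2014/15"

    def __post_init__(self) -> None:
        for name, series in (("hchs", self.hchs), ("nhscii", self.nhscii)):
            for year, value in series.items():
                fiscal_year_start(year)
                if value <= 0:
                    raise ValueError(f"{name}[{year!r}] must be strictly positive, got {value}")
        if self.boundary not in self.hchs or self.boundary not in self.nhscii:
            raise ValueError(f"both regimes must cover the boundary year {self.boundary!r}")

    def chained_index(self, year: str) -> float:
        """Value of the spliced series at ``year`` (HCHS levels, NHSCII-grown)."""
        ys = fiscal_year_start(year)
        if ys <= fiscal_year_start(self.boundary):
            if year not in self.hchs:
                raise KeyError(f"fiscal year {year!r} missing from the HCHS index")
            return float(self.hchs[year])
        if year not in self.nhscii:
            raise KeyError(f"fiscal year {year!r} missing from the NHSCII index")
        return float(self.hchs[self.boundary]) * float(self.nhscii[year]) / float(
            self.nhscii[self.boundary]
        )

    @classmethod
    def from_json(cls, path) -> "PriceIndexSeries":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            hchs=raw["hchs"], nhscii=raw["nhscii"], boundary=raw.get("boundary", "2014/15")
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"hchs": dict(self.hchs), "nhscii": dict(self.nhscii), "boundary": self.boundary},
                fh,
                indent=2,
            )


def inflate_cost(amount: float, from_year: str, to_year: str, indices: PriceIndexSeries) -> float:
    """Re-express ``amount`` from one fiscal year's prices in another's.

    Multiplies by the ratio of the chain-linked index, switching regime at the
    boundary year.
    """
    if from_year == to_year:
        return float(amount)
    return float(amount) * indices.chained_index(to_year) / indices.chained_index(from_year)


def annuitize(one_off_cost: float, n_years: int, rate: float, timing: str = "advance") -> float:
    """Equivalent annual cost of a one-off outlay spread over ``n_years``.

    Divides by the annuity factor ``A = (1 - (1+r)^-n) / r`` (payments in
    arrears), multiplied by ``(1+r)`` for payments in advance (annuity-due).
    With ``r = 0`` the factor degenerates to ``n``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if timing not in ("advance", "arrears"):
        raise ValueError(f"timing must be 'advance' or 'arrears', got {timing!r}")
    factor = annuity_factor(n_years, rate, timing)
    return float(one_off_cost) / factor


def annuity_factor(n_years: int, rate: float, timing: str = "advance") -> float:
    if rate == 0:
        return float(n_years)
    a = (1.0 - (1.0 + rate) ** -n_years) / rate
    if timing == "advance":
        a *= 1.0 + rate
    return a


def price_activities(
    records: Iterable[ActivityRecord],
    unit_costs: UnitCostTable,
    indices: PriceIndexSeries,
    target_year: str,
    *,
    annuitize_toolkit: bool = True,
    annuity_years: int = 5,
    annuity_rate: float = 0.035,
) -> pd.DataFrame:
    """Price every ledger row in target-year GBP.

    Staff rows are ``minutes / 60 x hourly rate``, inflated from the unit-cost
    source year; expense rows pass through, inflated from the recorded price
    year.  One-off toolkit outlays are annuitized in advance (default 5 years
    at 3.5%) so the toolkit line reflects the annual equivalent for the
    delivery period.
    """
    rows = []
    for rec in records:
        if rec.is_staff:
            unit = unit_costs[rec.staff_role]
            cost = rec.minutes / 60.0 * unit.hourly_gbp
            cost = inflate_cost(cost, unit.price_year, target_year, indices)
        else:
            cost = inflate_cost(rec.expense_gbp, rec.price_year, target_year, indices)
        if annuitize_toolkit and rec.category == "toolkit":
            cost = annuitize(cost, annuity_years, annuity_rate, "advance")
        rows.append(
            {
                "site_id": rec.site_id,
                "site_group": rec.site_group,
                "category": rec.category,
                "cost_gbp": cost,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["site_id", "site_group", "category", "cost_gbp"])
    return pd.DataFrame(rows)


@dataclass
class CostSummary:
    """Cost-category x site-group totals with margins and share percentages.

    ``table`` holds GBP at full precision (categories as rows, site groups as
    columns).  ``formatted()`` renders the publication-style view: whole
    pounds with each cell's share of its category row, totals with shares of
    the grand total.
    """

    table: pd.DataFrame  # index: COST_CATEGORIES, columns: SITE_GROUPS

    @property
    def row_totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.table.to_numpy().sum())

    def cell_percentages(self) -> pd.DataFrame:
        """Each cell's share of its category row (percent)."""
        totals = self.row_totals.replace(0.0, np.nan)
        return self.table.div(totals, axis=0) * 100.0

    def row_total_percentages(self) -> pd.Series:
        """Each category total's share of the grand total (percent)."""
        return self.row_totals / self.grand_total * 100.0

    def column_total_percentages(self) -> pd.Series:
        """Each site group total's share of the grand total (percent)."""
        return self.column_totals / self.grand_total * 100.0

    def formatted(self) -> pd.DataFrame:
        """Whole-pound / whole-percent view mirroring the published layout."""
        out = pd.DataFrame(index=list(self.table.index) + ["total"], dtype=object)
        pct = self.cell_percentages()
        for group in self.table.columns:
            col = []
            for cat in self.table.index:
                value = round_half_up(self.table.loc[cat, group])
                share = pct.loc[cat, group]
                col.append(f"{value:.0f} ({round_half_up(share):.0f}%)" if not np.isnan(share) else "0")
            col.append(
                f"{round_half_up(self.column_totals[group]):.0f} "
                f"({round_half_up(self.column_total_percentages()[group]):.0f}%)"
            )
            out[group] = col
        total_col = [
            f"{round_half_up(self.row_totals[cat]):.0f} "
            f"({round_half_up(self.row_total_percentages()[cat]):.0f}%)"
            for cat in self.table.index
        ]
        total_col.append(f"{round_half_up(self.grand_total):.0f} (100%)")
        out["total"] = total_col
        return out

    def rounded_cells(self) -> pd.DataFrame:
        """Whole-pound cell values (half-up)."""
        return self.table.map(round_half_up)

    def to_json(self, path) -> None:
        payload = {
            "table_gbp": {c: self.table[c].to_dict() for c in self.table.columns},
            "row_totals": self.row_totals.to_dict(),
            "column_totals": self.column_totals.to_dict(),
            "grand_total": self.grand_total,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def aggregate_costs(priced: pd.DataFrame) -> CostSummary:
    """Aggregate priced ledger rows into the category x site-group summary."""
    if priced.empty:
        raise ValueError("cannot aggregate an empty set of priced records")
    pivot = priced.pivot_table(
        index="category", columns="site_group", values="cost_gbp", aggfunc="sum", fill_value=0.0
    )
    pivot = pivot.reindex(index=COST_CATEGORIES, columns=SITE_GROUPS, fill_value=0.0)
    return CostSummary(table=pivot.astype(float))


def per_patient_cost(
    group_cost: float,
    followup_days: float,
    n_patients: int,
    reference_days: float = DEFAULT_REFERENCE_DAYS,
) -> float:
    """Mean cost per patient, scaled to a common follow-up duration.

    Groups observed for a shorter delivery window have their cost scaled up
    by ``reference_days / followup_days`` before dividing by the number of
    patients, so per-patient figures are comparable across groups.
    """
    if followup_days <= 0:
        raise ValueError("followup_days must be > 0")
    if n_patients <= 0:
        raise ValueError("n_patients must be > 0")
    return float(group_cost) * (reference_days / followup_days) / n_patients
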