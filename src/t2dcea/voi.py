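"""Expected value of perfect (partial) information from PSA output.

EVPI is the expected gain from resolving all parameter uncertainty before
choosing between decisions: ``E[max_d NMB_d] - max_d E[NMB_d]`` over the PSA
draws.  EVPPI for a parameter subset replaces the inner conditional
expectation with a flexible regression surrogate: each decision's net
monetary benefit is regressed on the subset's sampled values with penalised
splines (the Sheffield accelerated value of information approach), and the
fitted values stand in for the conditional mean.  Standard errors for both
quantities come from a bootstrap over draws, refitting the (reduced-basis)
regression in each resample.

Raw EVPPI estimates can be slightly negative through estimation noise; the
exported value is clamped at zero with the raw value retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.preprocessing import SplineTransformer

from .costing import round_half_up
from .psa import DEFAULT_THRESHOLD


@dataclass
class NetBenefitMatrix:
    """Net monetary benefit per draw and decision, aligned with the parameter draws."""

    nb: np.ndarray  # (n_draws, n_decisions)
    parameters: pd.DataFrame  # n_draws rows, one column per parameter
    threshold: float
    decision_names: tuple[str, ...] = ("control", "intervention")

    def __post_init__(self) -> None:
        self.nb = np.asarray(self.nb, dtype=float)
        if self.nb.ndim != 2:
            raise ValueError("nb must be a draws x decisions matrix")
        if len(self.parameters) != self.nb.shape[0]:
            raise ValueError("parameter table and NMB matrix disagree on draw count")
        if self.nb.shape[1] != len(self.decision_names):
            raise ValueError("decision_names length must match the NMB columns")

    @property
    def n_draws(self) -> int:
        return self.nb.shape[0]

    @property
    def n_decisions(self) -> int:
        return self.nb.shape[1]

    @classmethod
    def from_psa(
        cls,
        samples: pd.DataFrame,
        parameter_names: Sequence[str],
        threshold: float = DEFAULT_THRESHOLD,
    ) -> "NetBenefitMatrix":
        """Build the two-decision NMB matrix from a PSA sample table."""
        nb_control = threshold * samples["qalys_control"] - samples["cost_control"]
        nb_int = threshold * samples["qalys_intervention"] - samples["cost_intervention"]
        return cls(
            nb=np.column_stack([nb_control.to_numpy(), nb_int.to_numpy()]),
            parameters=samples[list(parameter_names)].reset_index(drop=True),
            threshold=threshold,
        )


@dataclass
class VoiEstimate:
    """One row of a value-of-information table."""

    quantity: str  # "EVPI" or "EVPPI"
    group: str
    value: float  # clamped at 0 in exports
    raw_value: float
    se: float | None
    index_to_evpi: float | None = None


def _evpi_value(nb: np.ndarray) -> float:
    return float(nb.max(axis=1).mean() - nb.mean(axis=0).max())


def evpi(nb: NetBenefitMatrix, *, n_boot: int = 1000, seed: int = 0) -> VoiEstimate:
    """Overall EVPI with a draw-level bootstrap standard error."""
    if nb.n_decisions < 2:
        raise ValueError("EVPI needs at least two decisions")
    value = _evpi_value(nb.nb)
    se = None
    if n_boot:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, nb.n_draws, size=(n_boot, nb.n_draws))
        reps = np.array([_evpi_value(nb.nb[i]) for i in idx])
        se = float(reps.std(ddof=1))
    return VoiEstimate("EVPI", "overall", max(value, 0.0), value, se)


def _spline_design(X: np.ndarray, n_knots: int) -> np.ndarray:
    """Additive B-spline basis per parameter, plus pairwise linear
    interactions when the group is small (<= 4 parameters)."""
    parts = [
        SplineTransformer(n_knots=n_knots, degree=3, include_bias=False).fit_transform(
            X[:, [j]]
        )
        for j in range(X.shape[1])
    ]
    if 2 <= X.shape[1] <= 4:
        centred = X - X.mean(axis=0)
        for a in range(X.shape[1]):
            for b in range(a + 1, X.shape[1]):
                parts.append((centred[:, a] * centred[:, b])[:, None])
    return np.hstack(parts)


def _fitted_conditional_nb(
    nb: np.ndarray, X: np.ndarray, n_knots: int, alpha: float
) -> np.ndarray:
    """Fitted E[NMB_d | group] per decision via penalised spline regression."""
    design = _spline_design(X, n_knots)
    fitted = np.empty_like(nb)
    for d in range(nb.shape[1]):
        y = nb[:, d]
        if np.ptp(y) == 0.0:  # constant decision, nothing to fit
            fitted[:, d] = y
            continue
        model = Ridge(alpha=alpha)
        model.fit(design, y)
        fitted[:, d] = model.predict(design)
    return fitted


def _evppi_value(nb: np.ndarray, X: np.ndarray, n_knots: int, alpha: float) -> float:
    fitted = _fitted_conditional_nb(nb, X, n_knots, alpha)
    return float(fitted.max(axis=1).mean() - nb.mean(axis=0).max())


def evppi_regression(
    nb: NetBenefitMatrix,
    group: Sequence[str],
    *,
    n_boot: int = 200,
    seed: int = 0,
    n_knots: int = 5,
    alpha: float = 1.0,
    group_name: str | None = None,
) -> VoiEstimate:
    """Regression-based EVPPI for a named parameter subset.

    The bootstrap refits on each resample with a reduced basis (one knot
    fewer) to keep the resampling cheap and stable.
    """
    missing = [p for p in group if p not in nb.parameters.columns]
    if missing:
        raise KeyError(f"parameters not in the PSA table: {missing}")
    if not group:
        raise ValueError("parameter group is empty")
    X = nb.parameters[list(group)].to_numpy(dtype=float)
    raw = _evppi_value(nb.nb, X, n_knots, alpha)
    se = None
    if n_boot:
        rng = np.random.default_rng(seed)
        boot_knots = max(4, n_knots - 1)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, nb.n_draws, size=nb.n_draws)
            reps[b] = _evppi_value(nb.nb[idx], X[idx], boot_knots, alpha)
        se = float(reps.std(ddof=1))
    return VoiEstimate("EVPPI", group_name or "+".join(group), max(raw, 0.0), raw, se)


def voi_table(
    nb: NetBenefitMatrix,
    groups: Mapping[str, Sequence[str]],
    *,
    n_boot: int = 200,
    seed: int = 0,
    n_knots: int = 5,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Overall EVPI plus per-group EVPPI with index ratios to the EVPI.

    The export mirrors the conventional per-person table: value, approximate
    standard error, and the group value indexed to the overall EVPI (half-up
    rounded to 2 decimal places).
    """
    overall = evpi(nb, n_boot=max(n_boot, 1000) if n_boot else 0, seed=seed)
    rows = [
        {
            "parameters": "Overall EVPI",
            "per_person_value": overall.value,
            "approx_se": overall.se,
            "index_to_evpi": 1.0,
        }
    ]
    for i, (name, members) in enumerate(groups.items()):
        est = evppi_regression(
            nb, members, n_boot=n_boot, seed=seed + 1 + i, n_knots=n_knots, alpha=alpha,
            group_name=name,
        )
        rows.append(
            {
                "parameters": name,
                "per_person_value": est.value,
                "approx_se": est.se,
                "index_to_evpi": index_ratio(est.value, overall.value),
            }
        )
    return pd.DataFrame(rows)


def index_ratio(value: float, evpi_value: float) -> float:
    """Group value indexed to overall EVPI, half-up rounded to 2 dp."""
    if evpi_value == 0.0:
        return float("nan")
    return round_half_up(value / evpi_value, 2)
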