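"""Log-logistic dose-response toxicology submodel.

The effect of an application rate ``r`` on a species is the two-parameter
log-logistic

    effect(r) = r^b / (ER50^b + r^b),

the fractional reduction of biomass at rate ``r``; ``ER50`` is the rate
producing a 50% reduction and ``b`` the slope.  Parameters are estimated per
species x herbicide from monoculture greenhouse effects by bounded nonlinear
least squares, with standard errors from the Gauss-Newton approximation to
the Hessian at the optimum.  In the simulation the herbicide acts as a
constant weekly multiplier ``1 - effect`` on biomass gain from the
application week onward (no dissipation over the 6-week horizon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponse",
    "DoseResponseFitError",
    "effect_at_rate",
    "fit_dose_response",
    "build_effect_schedule",
    "read_dose_response_table",
    "write_dose_response_table",
    "default_dose_responses",
]


class DoseResponseFitError(RuntimeError):
    """Raised when a dose-response curve cannot be estimated."""


@dataclass
class DoseResponse:
    """Fitted log-logistic parameters for one species x herbicide pair."""

    species: str
    herbicide: str
    er50: float
    slope_b: float
    er50_se: float | None = None
    slope_se: float | None = None
    hessian_ok: bool = True

    def __post_init__(self):
        if self.er50 <= 0:
            raise ValueError("er50 must be positive")


def effect_at_rate(rate: float, dr: DoseResponse) -> float:
    """Fractional biomass reduction at an application rate; in [0, 1].

    Strictly increasing in rate for b > 0, equal to 0.5 at rate = ER50 for
    any nonzero slope, and 0 at rate 0 (limit 1 for negative slopes).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    b = dr.slope_b
    if rate == 0.0:
        if b > 0:
            return 0.0
        if b < 0:
            return 1.0
        return 0.5
    # exp/log form avoids overflow for extreme rate/er50 ratios
    logit = b * (math.log(rate) - math.log(dr.er50))
    if logit > 700:
        return 1.0
    if logit < -700:
        return 0.0
    x = math.exp(logit)
    return x / (1.0 + x)


def _model(rates: np.ndarray, er50: float, b: float) -> np.ndarray:
    logit = np.clip(b * (np.log(rates) - math.log(er50)), -700, 700)
    x = np.exp(logit)
    return x / (1.0 + x)


def fit_dose_response(
    rates: Sequence[float],
    effects: Sequence[float],
    species: str = "",
    herbicide: str = "",
) -> DoseResponse:
    """Least-squares estimate of (ER50, b) from observed fractional effects.

    Requires at least 3 distinct positive rates.  Effects may stray outside
    [0, 1] (empirical noise).  The optimizer starts at
    (ER50 = median rate, b = 1) with bounds ER50 in (0, 100 * max rate] and
    b in [-10, 10]; negative slopes are permitted.  If the Gauss-Newton
    Hessian at the optimum is singular or ill-conditioned the estimates are
    still returned but ``hessian_ok`` is False and the standard errors are
    undefined.

    Raises
    ------
    DoseResponseFitError
        Fewer than 3 distinct positive rates, or all effects identical
        (no dose-response information).
    """
    r = np.asarray(rates, dtype=float)
    e = np.asarray(effects, dtype=float)
    if r.shape != e.shape:
        raise ValueError("rates and effects must have equal length")
    if np.any(r <= 0):
        raise DoseResponseFitError("all rates must be positive for fitting")
    if len(np.unique(r)) < 3:
        raise DoseResponseFitError(
            "need at least 3 distinct positive rates to fit a dose-response"
        )
    if np.ptp(e) == 0.0:
        raise DoseResponseFitError(
            "all observed effects are identical; no dose-response information"
        )
    if np.any(e < -0.5) or np.any(e > 1.5):
        raise ValueError("effects outside the plausible range [-0.5, 1.5]")

    x0 = np.array([float(np.median(r)), 1.0])
    bounds = ([1e-9, -10.0], [100.0 * float(r.max()), 10.0])
    res = least_squares(
        lambda p: _model(r, p[0], p[1]) - e, x0, bounds=bounds, method="trf"
    )
    er50_hat, b_hat = float(res.x[0]), float(res.x[1])

    er50_se = slope_se = None
    hessian_ok = False
    n, p = len(r), 2
    if n > p:
        jtj = res.jac.T @ res.jac
        s2 = 2.0 * res.cost / (n - p)
        try:
            if np.linalg.cond(jtj) < 1e12:
                cov = s2 * np.linalg.inv(jtj)
                d = np.diag(cov)
                if np.all(np.isfinite(d)) and np.all(d >= 0):
                    er50_se, slope_se = float(np.sqrt(d[0])), float(np.sqrt(d[1]))
                    hessian_ok = True
        except np.linalg.LinAlgError:
            pass
    return DoseResponse(
        species=species,
        herbicide=herbicide,
        er50=er50_hat,
        slope_b=b_hat,
        er50_se=er50_se,
        slope_se=slope_se,
        hessian_ok=hessian_ok,
    )


def build_effect_schedule(
    dr: DoseResponse,
    rate: float,
    application_week: int,
    horizon: int,
) -> list[float]:
    """Per-week gain multipliers for one treated PFT.

    The multiplier is 1 before the application week and ``1 - effect(rate)``
    from the application week to the horizon (the herbicide does not
    dissipate).  The returned list has ``horizon + 1`` entries indexed by
    simulation week.
    """
    if not 0 <= application_week <= horizon:
        raise ValueError("need horizon >= application_week >= 0")
    if rate == 0:
        return [1.0] * (horizon + 1)
    mult = 1.0 - effect_at_rate(rate, dr)
    return [1.0] * application_week + [mult] * (horizon + 1 - application_week)


_TABLE_COLUMNS = ["herbicide", "species", "er50", "er50_se", "slope_b", "slope_se"]


def read_dose_response_table(path: str | Path) -> dict[tuple[str, str], DoseResponse]:
    """Read a delimited dose-response table keyed by (herbicide, species)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response table missing columns: {missing}")
    out = {}
    for _, row in df.iterrows():
        er50_se = None if pd.isna(row["er50_se"]) else float(row["er50_se"])
        slope_se = None if pd.isna(row["slope_se"]) else float(row["slope_se"])
        out[(str(row["herbicide"]), str(row["species"]))] = DoseResponse(
            species=str(row["species"]),
            herbicide=str(row["herbicide"]),
            er50=float(row["er50"]),
            slope_b=float(row["slope_b"]),
            er50_se=er50_se,
            slope_se=slope_se,
            hessian_ok=er50_se is not None,
        )
    return out


def write_dose_response_table(
    doses: dict[tuple[str, str], DoseResponse] | Sequence[DoseResponse],
    path: str | Path,
) -> pd.DataFrame:
    items = doses.values() if isinstance(doses, dict) else doses
    df = pd.DataFrame(
        [
            {
                "herbicide": d.herbicide,
                "species": d.species,
                "er50": d.er50,
                "er50_se": d.er50_se,
                "slope_b": d.slope_b,
                "slope_se": d.slope_se,
            }
            for d in items
        ],
        columns=_TABLE_COLUMNS,
    )
    df.to_csv(path, index=False)
    return df


def default_dose_responses() -> dict[tuple[str, str], DoseResponse]:
    """Packaged reference dose-response table for the six test species and
    the broad-spectrum (RoundUp) and selective (Monitor) herbicides."""
    import importlib.resources

    ref = importlib.resources.files("grasstox.data") / "dose_response_default.csv"
    with importlib.resources.as_file(ref) as p:
        return read_dose_response_table(p)


def effects_from_measurements(
    records: pd.DataFrame,
    week: int = 4,
    baseline_week: int | None = 2,
) -> pd.DataFrame:
    """Per-replicate fractional effects from monoculture measurement records.

    With the default growth endpoint, the effect of a treated replicate is
    the reduction of the shoot-mass *increment* between the baseline
    assessment and the target week relative to the control increment,

        effect = 1 - (treated(week) - mean treated(baseline))
                     / (mean control(week) - mean control(baseline)),

    matching the model's reading of the dose-response as a reduction in
    growth and removing the dilution by pre-treatment biomass.  With
    ``baseline_week=None`` the endpoint is the plain shoot-mass ratio
    ``1 - treated / mean control`` at the target week.  Fresh or dry basis
    does not matter as long as it is consistent: the static conversion
    factor cancels.

    Raises
    ------
    ValueError
        If the chosen weeks, controls or treatments are missing.
    """
    at = records[records["week"] == week]
    if at.empty:
        raise ValueError(f"no measurements for week {week}")

    def ctrl_mean(species: str, w: int) -> float:
        ctrl = records[
            (records["week"] == w)
            & (records["species"] == species)
            & (records["rate"] == 0)
        ]["shoot_mass_mg"]
        if ctrl.empty:
            raise ValueError(f"no week-{w} controls for species {species!r}")
        return float(ctrl.mean())

    rows = []
    for herbicide in sorted(at["herbicide"].unique()):
        h = at[at["herbicide"] == herbicide]
        rates = sorted(r for r in h["rate"].unique() if r > 0)
        if not rates:
            continue
        for species in sorted(h["species"].unique()):
            c_w = ctrl_mean(species, week)
            c_b = (
                ctrl_mean(species, baseline_week)
                if baseline_week is not None else 0.0
            )
            denom = c_w - c_b
            if denom <= 0:
                raise ValueError(
                    f"control growth increment is not positive for {species!r}"
                )
            for rate in rates:
                treated = h[(h["species"] == species) & (h["rate"] == rate)]
                if treated.empty:
                    continue
                if baseline_week is not None:
                    t_b = records[
                        (records["week"] == baseline_week)
                        & (records["species"] == species)
                        & (records["herbicide"] == herbicide)
                        & (records["rate"] == rate)
                    ]["shoot_mass_mg"]
                    if t_b.empty:
                        raise ValueError(
                            f"no week-{baseline_week} treated records for "
                            f"{species!r} at rate {rate}"
                        )
                    base = float(t_b.mean())
                else:
                    base = 0.0
                for _, r in treated.iterrows():
                    rows.append((
                        herbicide, species, rate, r["replicate"],
                        1.0 - (float(r["shoot_mass_mg"]) - base) / denom,
                    ))
    if not rows:
        raise ValueError("no treated measurements found")
    return pd.DataFrame(
        rows, columns=["herbicide", "species", "rate", "replicate", "effect"]
    )


def fit_dose_responses_from_measurements(
    records: pd.DataFrame,
    week: int = 4,
    baseline_week: int | None = 2,
) -> dict[tuple[str, str], DoseResponse]:
    """Fit one dose-response per herbicide x species from measurement records."""
    eff = effects_from_measurements(records, week=week, baseline_week=baseline_week)
    out: dict[tuple[str, str], DoseResponse] = {}
    for (herbicide, species), grp in eff.groupby(["herbicide", "species"]):
        e = np.clip(grp["effect"].to_numpy(), -0.5, 1.5)
        out[(herbicide, species)] = fit_dose_response(
            grp["rate"].to_numpy(), e, species=species, herbicide=herbicide
        )
    return out
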