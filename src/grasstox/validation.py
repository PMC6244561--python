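"""Model-validation statistics: interval-overlap adequacy and reliability.

For each assessment week the modeled prediction envelope is the band between
the 2.5th and 97.5th percentile of the simulated shoot masses, and the
observed envelope is the min-max range of the measurements.  Summing the
band widths over the three assessment weeks gives the modeled area ``M``,
the observed area ``O`` and their intersection ``I`` (per-week overlap,
clamped at zero for disjoint intervals).  Model *adequacy* ``I/O`` is the
fraction of the observed variability the model covers; model *reliability*
``I/M`` is the fraction of the model's predictions that were actually
observed.  Both lie in [0, 1]; 1/1 means complete overlap.

The module also houses the static fresh-to-dry weight conversion, the
treatment/control effect ratios, and the Welch two-sample t-test used for
per-week model/data comparisons (no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntervalSeries",
    "FitMetrics",
    "fresh_to_dry",
    "percentile_band",
    "compute_MOI",
    "effect_ratio",
    "welch_t_test",
    "metrics_report",
    "welch_table",
]


@dataclass(frozen=True)
class IntervalSeries:
    """Per-week (lower, upper) shoot-mass bounds for one envelope."""

    weeks: tuple[int, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    source: str  # "modeled" (2.5th/97.5th percentile) | "observed" (min/max)

    def __post_init__(self):
        if not (len(self.weeks) == len(self.lower) == len(self.upper)):
            raise ValueError("weeks, lower, upper must have equal length")
        for lo, hi in zip(self.lower, self.upper):
            if lo > hi:
                raise ValueError("interval lower bound exceeds upper bound")


@dataclass(frozen=True)
class FitMetrics:
    """Interval-area sums and the derived adequacy/reliability ratios."""

    M: float
    O: float
    I: float
    adequacy: float  # I/O; nan when O == 0
    reliability: float  # I/M; nan when M == 0
    m_t: tuple[float, ...] = ()
    o_t: tuple[float, ...] = ()
    i_t: tuple[float, ...] = ()


def fresh_to_dry(fresh: float, factor: float) -> float:
    """Static species-specific fresh-to-dry weight conversion (mg)."""
    if not 0.0 < factor < 1.0:
        raise ValueError("conversion factor must be in (0, 1)")
    arr = np.asarray(fresh, dtype=float)
    if np.any(arr < 0):
        raise ValueError("fresh weight must be non-negative")
    out = arr * factor
    return float(out) if np.isscalar(fresh) else out


def percentile_band(
    values_per_week: Mapping[int, Sequence[float]],
    source: str = "modeled",
) -> IntervalSeries:
    """Envelope of shoot masses per week.

    ``modeled`` bands span the 2.5th to 97.5th percentile (need >= 2 values
    per week); ``observed`` bands span the min-max (>= 1 value).
    """
    weeks = tuple(sorted(values_per_week))
    lower, upper = [], []
    for w in weeks:
        vals = np.asarray(values_per_week[w], dtype=float)
        if vals.size == 0:
            raise ValueError(f"no values for week {w}")
        if source == "modeled":
            if vals.size < 2:
                raise ValueError("modeled band needs >= 2 values per week")
            lo, hi = np.percentile(vals, [2.5, 97.5])
        elif source == "observed":
            lo, hi = float(vals.min()), float(vals.max())
        else:
            raise ValueError(f"unknown source {source!r}")
        lower.append(float(lo))
        upper.append(float(hi))
    return IntervalSeries(weeks, tuple(lower), tuple(upper), source)


def compute_MOI(modeled: IntervalSeries, observed: IntervalSeries) -> FitMetrics:
    """Interval-overlap fit metrics over matched assessment weeks.

    ``M`` and ``O`` sum the weekly widths of the modeled and observed
    envelopes; ``I`` sums the weekly overlaps, clamped at zero when the
    intervals are disjoint (a literal signed-gap reading would count the gap
    between disjoint intervals as overlap, contradicting the meaning of an
    intersection).  ``adequacy = I/O`` and ``reliability = I/M``; a zero
    denominator yields nan.
    """
    if modeled.weeks != observed.weeks:
        raise ValueError(
            f"week sets differ: {modeled.weeks} vs {observed.weeks}"
        )
    m_t, o_t, i_t = [], [], []
    for (ml, mu, ol, ou) in zip(
        modeled.lower, modeled.upper, observed.lower, observed.upper
    ):
        m_t.append(mu - ml)
        o_t.append(ou - ol)
        i_t.append(max(0.0, min(mu, ou) - max(ml, ol)))
    M, O, I = sum(m_t), sum(o_t), sum(i_t)
    adequacy = I / O if O > 0 else float("nan")
    reliability = I / M if M > 0 else float("nan")
    return FitMetrics(M, O, I, adequacy, reliability,
                      tuple(m_t), tuple(o_t), tuple(i_t))


def effect_ratio(
    treatment: Mapping[int, Sequence[float]],
    control: Mapping[int, Sequence[float]],
    summary: str = "median",
) -> pd.Series:
    """Per-week treatment/control shoot-mass ratio of a summary statistic."""
    if set(treatment) != set(control):
        raise ValueError("treatment and control must cover the same weeks")
    ratios = {}
    for w in sorted(treatment):
        t = np.asarray(treatment[w], dtype=float)
        c = np.asarray(control[w], dtype=float)
        if summary == "median":
            ts, cs = float(np.median(t)), float(np.median(c))
        elif summary == "mean":
            ts, cs = float(t.mean()), float(c.mean())
        else:
            raise ValueError(f"unknown summary {summary!r}")
        if cs == 0:
            raise ValueError(f"zero control mass in week {w}")
        ratios[w] = ts / cs
    return pd.Series(ratios, name=f"{summary}_ratio")


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Welch's unequal-variance two-sample t-test (two-sided).

    Uses the Welch-Satterthwaite degrees of freedom; samples are unpaired
    and no multiple-comparison correction is applied.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _nanmean(values) -> float:
    vals = [v for v in values if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _band_from_records(records: pd.DataFrame, weeks, source: str) -> IntervalSeries:
    per_week = {
        int(w): records.loc[records["week"] == w, "shoot_mass_mg"].to_numpy()
        for w in weeks
    }
    return percentile_band(per_week, source=source)


def metrics_report(
    modeled: pd.DataFrame,
    observed: pd.DataFrame,
    mode: str = "area",
) -> pd.DataFrame:
    """Adequacy/reliability table per species (plus an "All" row).

    Both inputs are dry-basis measurement-record tables (columns
    ``herbicide, rate, week, species, shoot_mass_mg``).  For every species x
    herbicide x rate the modeled percentile band and the observed min-max
    band are overlapped per assessment week.  ``mode="area"`` forms one
    adequacy/reliability ratio per rate from the week-summed areas and then
    averages over rates; ``mode="weekly"`` averages the per-week ratios
    first.  The "All" row is the mean over the species rows computed on the
    same path, so the aggregation is internally consistent.
    """
    if mode not in ("area", "weekly"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for herbicide in sorted(observed["herbicide"].unique()):
        obs_h = observed[observed["herbicide"] == herbicide]
        mod_h = modeled[
            (modeled["herbicide"] == herbicide)
            | (~modeled["herbicide"].isin(observed["herbicide"].unique()))
        ]
        rates = sorted(obs_h["rate"].unique())
        species = sorted(obs_h["species"].unique())
        per_species = {}
        for sp in species:
            vals = []
            for rate in rates:
                obs = obs_h[(obs_h["species"] == sp) & (obs_h["rate"] == rate)]
                mod = mod_h[(mod_h["species"] == sp) & (mod_h["rate"] == rate)]
                if obs.empty or mod.empty:
                    continue
                weeks = sorted(obs["week"].unique())
                fm = compute_MOI(
                    _band_from_records(mod, weeks, "modeled"),
                    _band_from_records(obs, weeks, "observed"),
                )
                if mode == "area":
                    vals.append((fm.adequacy, fm.reliability))
                else:
                    ad = _nanmean(
                        i / o if o > 0 else float("nan")
                        for i, o in zip(fm.i_t, fm.o_t)
                    )
                    re = _nanmean(
                        i / m if m > 0 else float("nan")
                        for i, m in zip(fm.i_t, fm.m_t)
                    )
                    vals.append((ad, re))
            if vals:
                per_species[sp] = (
                    _nanmean(v[0] for v in vals),
                    _nanmean(v[1] for v in vals),
                )
        for sp, (ad, re) in per_species.items():
            rows.append((sp, herbicide, ad, re))
        if per_species:
            rows.append((
                "All", herbicide,
                _nanmean(v[0] for v in per_species.values()),
                _nanmean(v[1] for v in per_species.values()),
            ))
    return pd.DataFrame(
        rows, columns=["species", "herbicide", "adequacy", "reliability"]
    )


def welch_table(modeled: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    """Welch t-test per species x week between modeled and observed masses."""
    rows = []
    keys = observed[["species", "week"]].drop_duplicates()
    for _, k in keys.iterrows():
        sp, w = k["species"], k["week"]
        a = modeled[
            (modeled["species"] == sp) & (modeled["week"] == w)
        ]["shoot_mass_mg"].to_numpy()
        b = observed[
            (observed["species"] == sp) & (observed["week"] == w)
        ]["shoot_mass_mg"].to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = welch_t_test(a, b)
        rows.append((sp, int(w), t, p, p < 0.05))
    return pd.DataFrame(
        rows, columns=["species", "week", "t", "p", "significant"]
    )
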