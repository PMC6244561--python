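"""Pseudo-empirical greenhouse measurement tables.

The empirical dataset the community model was originally benchmarked against
is not public, so this module generates measurement tables with the same
design and statistical structure: six grassland species, monoculture pots
(4 plants, 4 replicates per assessment date) and community pots (49 plants,
3 replicates per date), assessment weeks 2/4/6 after application, five
application rates plus a control per herbicide (3-25% of 3 L/ha for the
broad-spectrum product, 5-55% of 25 g/ha for the selective one), and fresh
shoot weights with multiplicative lognormal replicate noise.

Latent trajectories are produced by the simulation engine itself (optionally
with perturbed per-species growth rates), so the community records carry an
honest competitive-release structure: when a sensitive species is suppressed
its neighbours really do acquire the freed resources.  A truth manifest
records every generating parameter for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import DEFAULT_PARAMS, EngineParams, Grid, run_simulation
from .experiments import (
    DEFAULT_TIMING,
    MEASUREMENT_COLUMNS,
    TimingTable,
    init_community,
    init_monoculture,
    monoculture_transplant_masses,
)
from .herbicide import (
    DoseResponse,
    build_effect_schedule,
    default_dose_responses,
    effect_at_rate,
)
from .traits import PFTraits, default_pfts

__all__ = [
    "SyntheticConfig",
    "HERBICIDE_RATES",
    "MAX_APPLICATION_RATE",
    "RATE_FRACTIONS",
    "DEFAULT_DRY_FRESH",
    "gen_control_measurements",
    "gen_treatment_measurements",
    "gen_conversion_ratios",
    "truth_manifest",
]

#: Maximal field application rates: mL/ha (broad-spectrum) and g/ha (selective).
MAX_APPLICATION_RATE = {"RoundUp": 3000.0, "Monitor": 25.0}

#: Tested fractions of the maximal rate.
RATE_FRACTIONS = {
    "RoundUp": (0.03, 0.05, 0.09, 0.15, 0.25),
    "Monitor": (0.05, 0.09, 0.17, 0.31, 0.55),
}

#: Tested application rates (90-750 mL/ha and 1.25-13.75 g/ha).
HERBICIDE_RATES = {
    h: tuple(round(f * MAX_APPLICATION_RATE[h], 4) for f in RATE_FRACTIONS[h])
    for h in MAX_APPLICATION_RATE
}

#: Latent dry:fresh mass ratios; leaf-succulence differences between the
#: grasses, forbs and the legume give a modest spread around 0.2.
DEFAULT_DRY_FRESH = {
    "B. erectus": 0.25,
    "C. cristatus": 0.22,
    "G. mollugo": 0.18,
    "L. hispidus": 0.15,
    "S. nutans": 0.20,
    "T. pratense": 0.17,
}


def _default_true_dr() -> dict[tuple[str, str], DoseResponse]:
    return default_dose_responses()


@dataclass
class SyntheticConfig:
    """Generating parameters of the pseudo-empirical dataset."""

    pfts: Sequence[PFTraits] = field(default_factory=default_pfts)
    below: float = 90.0
    above: float = 75.0
    sigma: float = 0.15  # lognormal sd of the replicate noise
    mono_reps: int = 4  # pots per assessment date, monoculture
    comm_reps: int = 3  # pots per assessment date, community
    weeks: tuple[int, ...] = (2, 4, 6)
    herbicides: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(HERBICIDE_RATES)
    )
    dry_fresh: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRY_FRESH)
    )
    true_dr: Mapping[tuple[str, str], DoseResponse] = field(
        default_factory=_default_true_dr
    )
    growth_multipliers: Mapping[str, float] = field(default_factory=dict)
    timing: TimingTable = DEFAULT_TIMING
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.mono_reps < 1 or self.comm_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        for h, rates in self.herbicides.items():
            if any(r <= 0 for r in rates):
                raise ValueError(f"non-positive rate for {h}")

    def engine_params(self) -> EngineParams:
        return replace(DEFAULT_PARAMS, growth_multipliers=dict(self.growth_multipliers))

    def species(self) -> list[str]:
        return [p.name for p in self.pfts]


def _rng(cfg: SyntheticConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *stream]))


_STREAM_MONO, _STREAM_COMM, _STREAM_RATIO, _STREAM_LAYOUT = 1, 2, 3, 4


def _noise(rng: np.random.Generator, sigma: float) -> float:
    return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0


def _latent_mono(
    cfg: SyntheticConfig,
    pft: PFTraits,
    herbicide: str | None = None,
    rate: float = 0.0,
) -> dict[int, float]:
    """Mean dry shoot mass per assessment week of the latent monoculture.

    The control trajectory comes from an engine run.  A treated trajectory
    scales the latent control's weekly shoot gains after the application
    week by ``1 - effect`` (constant, no dissipation):
    ``m_t(a + w) = m(a) + (1 - effect) * (m(a + w) - m(a))``.  The week-4
    shoot-mass effect of the generated data therefore equals the generating
    dose-response up to the small pre-application biomass fraction, which
    is what the downstream fitting step assumes of greenhouse effect data.
    """
    age = cfg.timing.age_at_potting(pft.name)
    horizon = age + max(cfg.weeks)
    grid = Grid(7, 7, above_resource=cfg.above, below_resource=cfg.below)
    state = init_monoculture(pft, grid)
    traj = run_simulation(state, horizon, None, cfg.engine_params())

    def mean_at(week: int) -> float:
        return float(traj.loc[traj["week"] == week, "shoot_mass_mg"].mean())

    if rate <= 0:
        return {w: mean_at(age + w) for w in cfg.weeks}
    dr = cfg.true_dr[(herbicide, pft.name)]
    keep = 1.0 - effect_at_rate(rate, dr)
    m_a = mean_at(age)
    return {
        w: m_a + keep * (mean_at(age + w) - m_a) for w in cfg.weeks
    }


def _latent_community(
    cfg: SyntheticConfig,
    layout_seed: int,
    herbicide: str | None = None,
    rate: float = 0.0,
) -> dict[tuple[str, int], float]:
    """Per-species mean dry shoot mass per week from one community run."""
    params = cfg.engine_params()
    masses = monoculture_transplant_masses(
        cfg.pfts, (cfg.below, cfg.above), cfg.timing, params
    )
    grid = Grid(20, 20, above_resource=cfg.above, below_resource=cfg.below)
    state = init_community(cfg.pfts, grid, masses, seed=layout_seed,
                           timing=cfg.timing)
    horizon = max(cfg.weeks)
    schedule = None
    if rate > 0:
        schedule = {
            p.name: build_effect_schedule(
                cfg.true_dr[(herbicide, p.name)], rate, 0, horizon
            )
            for p in cfg.pfts
        }
    traj = run_simulation(state, horizon, schedule, params)
    out = {}
    for w in cfg.weeks:
        at = traj[traj["week"] == w]
        for sp, grp in at.groupby("pft"):
            out[(str(sp), w)] = float(grp["shoot_mass_mg"].mean())
    return out


def _layout_seed(cfg: SyntheticConfig, batch: int, rep: int) -> int:
    return int(_rng(cfg, _STREAM_LAYOUT, batch, rep).integers(2**31))


def gen_control_measurements(cfg: SyntheticConfig, setup: str) -> pd.DataFrame:
    """Fresh-weight control records for one setup.

    Monoculture controls are generated for both herbicide batches, so
    pooling them gives N = mono_reps * 2 (= 8 by default) control values
    per species-week.  Community controls come from engine runs whose
    layout seeds are shared with the matching treatment replicates.
    """
    rows = []
    batches = list(cfg.herbicides) or ["control"]
    if setup == "monoculture":
        rng = _rng(cfg, _STREAM_MONO, 0)
        for b, herbicide in enumerate(batches):
            for pft in cfg.pfts:
                latent = _latent_mono(cfg, pft)
                for w in cfg.weeks:
                    fresh = latent[w] / cfg.dry_fresh[pft.name]
                    for rep in range(cfg.mono_reps):
                        rows.append((
                            setup, herbicide, 0.0, rep, w, pft.name, -1,
                            fresh * _noise(rng, cfg.sigma), "fresh",
                        ))
    elif setup == "community":
        rng = _rng(cfg, _STREAM_COMM, 0)
        for b, herbicide in enumerate(batches):
            for rep in range(cfg.comm_reps):
                latent = _latent_community(cfg, _layout_seed(cfg, b, rep))
                for (sp, w), dry in sorted(latent.items()):
                    fresh = dry / cfg.dry_fresh[sp]
                    rows.append((
                        setup, herbicide, 0.0, rep, w, sp, -1,
                        fresh * _noise(rng, cfg.sigma), "fresh",
                    ))
    else:
        raise ValueError(f"unknown setup {setup!r}")
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def gen_treatment_measurements(
    cfg: SyntheticConfig, setup: str, herbicide: str
) -> pd.DataFrame:
    """Fresh-weight treated records for one setup and herbicide.

    The true dose-response scales the weekly biomass gain in the generating
    engine run from the application week onward; community replicates reuse
    the control layouts, so treatment effects (including competitive
    release of the less sensitive species) are paired with the controls.
    """
    if herbicide not in cfg.herbicides:
        raise ValueError(f"unknown herbicide {herbicide!r}")
    batch = list(cfg.herbicides).index(herbicide)
    rows = []
    if setup == "monoculture":
        rng = _rng(cfg, _STREAM_MONO, 1, batch)
        for pft in cfg.pfts:
            if (herbicide, pft.name) not in cfg.true_dr:
                raise ValueError(f"no true dose-response for {pft.name}")
            for rate in cfg.herbicides[herbicide]:
                latent = _latent_mono(cfg, pft, herbicide, rate)
                for w in cfg.weeks:
                    fresh = latent[w] / cfg.dry_fresh[pft.name]
                    for rep in range(cfg.mono_reps):
                        rows.append((
                            setup, herbicide, rate, rep, w, pft.name, -1,
                            fresh * _noise(rng, cfg.sigma), "fresh",
                        ))
    elif setup == "community":
        rng = _rng(cfg, _STREAM_COMM, 1, batch)
        for rate in cfg.herbicides[herbicide]:
            for rep in range(cfg.comm_reps):
                latent = _latent_community(
                    cfg, _layout_seed(cfg, batch, rep), herbicide, rate
                )
                for (sp, w), dry in sorted(latent.items()):
                    fresh = dry / cfg.dry_fresh[sp]
                    rows.append((
                        setup, herbicide, rate, rep, w, sp, -1,
                        fresh * _noise(rng, cfg.sigma), "fresh",
                    ))
    else:
        raise ValueError(f"unknown setup {setup!r}")
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def gen_conversion_ratios(
    cfg: SyntheticConfig, n_reps: int = 5, noise_sd: float = 0.02
) -> pd.DataFrame:
    """Per-species dry:fresh conversion factors from a repeated control
    experiment: the mean of ``n_reps`` noisy draws around the latent ratio,
    clamped to (0, 1)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = _rng(cfg, _STREAM_RATIO)
    rows = []
    for sp in cfg.species():
        latent = cfg.dry_fresh[sp]
        draws = np.clip(
            latent + rng.normal(0.0, noise_sd, size=n_reps), 1e-6, 1 - 1e-6
        )
        rows.append((sp, float(draws.mean()), n_reps))
    return pd.DataFrame(rows, columns=["species", "dry_fresh_ratio", "n_reps"])


def truth_manifest(cfg: SyntheticConfig) -> dict:
    """The generating parameters, for parameter-recovery tests."""
    return {
        "seed": cfg.seed,
        "below": cfg.below,
        "above": cfg.above,
        "sigma": cfg.sigma,
        "mono_reps": cfg.mono_reps,
        "comm_reps": cfg.comm_reps,
        "weeks": list(cfg.weeks),
        "herbicides": {h: list(r) for h, r in cfg.herbicides.items()},
        "dry_fresh": dict(cfg.dry_fresh),
        "growth_multipliers": dict(cfg.growth_multipliers),
        "true_dose_responses": {
            f"{h}|{sp}": {"er50": d.er50, "slope_b": d.slope_b}
            for (h, sp), d in cfg.true_dr.items()
        },
    }
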