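"""Pattern-oriented calibration of the abstract resource levels.

The model does not represent concrete nutrients or light; all resources are
pooled into abstract above- and belowground resource units.  The levels that
reproduce the observed growth are found by a Latin-Hypercube sweep over
belowground units in [60, 120] and aboveground units in [50, 100] (90
combinations by default, each repeated 10 times), followed by
pattern-oriented selection: a resource combination is accepted when its
simulated mean control-monoculture shoot mass falls inside the observed
min-max envelope for every species and every assessment week.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .engine import DEFAULT_PARAMS, EngineParams, Grid, run_simulation
from .experiments import DEFAULT_TIMING, TimingTable, init_monoculture
from .traits import PFTraits

__all__ = [
    "ResourceSample",
    "DEFAULT_BOUNDS",
    "lhs_sample",
    "sweep_manifest",
    "run_sweep",
    "observed_envelope",
    "select_resource_levels",
]

#: (below, above) resource-unit sweep bounds: medium-to-high levels.
DEFAULT_BOUNDS = ((60.0, 120.0), (50.0, 100.0))


@dataclass(frozen=True)
class ResourceSample:
    sample_id: int
    below: float
    above: float
    seeds: tuple[int, ...]


def lhs_sample(
    n: int,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    seed: int = 0,
    reps: int = 10,
) -> list[ResourceSample]:
    """Latin-Hypercube sample of resource combinations.

    Per dimension each of the ``n`` equal-width strata contains exactly one
    point (uniform within its stratum).  Each sample carries ``reps``
    replicate seeds derived deterministically from the master seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for lo, hi in bounds:
        if lo >= hi:
            raise ValueError(f"degenerate bounds ({lo}, {hi})")
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    unit = sampler.random(n)
    lows = np.array([lo for lo, _ in bounds])
    highs = np.array([hi for _, hi in bounds])
    points = qmc.scale(unit, lows, highs)
    seed_pool = np.random.SeedSequence(seed).generate_state(n * reps) % (2**31)
    return [
        ResourceSample(
            sample_id=i,
            below=float(points[i, 0]),
            above=float(points[i, 1]),
            seeds=tuple(int(s) for s in seed_pool[i * reps:(i + 1) * reps]),
        )
        for i in range(n)
    ]


def sweep_manifest(samples: Sequence[ResourceSample]) -> pd.DataFrame:
    """One manifest row per simulation run (sample x replicate)."""
    rows = [
        (s.sample_id, rep, s.below, s.above, seed)
        for s in samples
        for rep, seed in enumerate(s.seeds)
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "rep", "below", "above", "seed"]
    )


def run_sweep(
    samples: Sequence[ResourceSample],
    pfts: Sequence[PFTraits],
    params: EngineParams = DEFAULT_PARAMS,
    timing: TimingTable = DEFAULT_TIMING,
    weeks: Sequence[int] = (2, 4, 6),
) -> pd.DataFrame:
    """Control-monoculture runs for every sample x replicate x species.

    Returns the ensemble of per-run mean shoot masses with columns
    ``sample_id, rep, below, above, species, week, shoot_mass_mg`` (week is
    the assessment week after application).  Monoculture runs carry no
    stochastic process, so replicates are identical by construction; they
    are executed nonetheless to keep the run count of the protocol.
    """
    rows = []
    for s in samples:
        for rep, seed in enumerate(s.seeds):
            for pft in pfts:
                age = timing.age_at_potting(pft.name)
                grid = Grid(7, 7, above_resource=s.above, below_resource=s.below)
                state = init_monoculture(pft, grid, seed=seed)
                traj = run_simulation(state, age + max(weeks), params=params)
                for w in weeks:
                    at = traj[traj["week"] == age + w]
                    rows.append((
                        s.sample_id, rep, s.below, s.above,
                        pft.name, w, float(at["shoot_mass_mg"].mean()),
                    ))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "rep", "below", "above",
                 "species", "week", "shoot_mass_mg"],
    )


def observed_envelope(observed: pd.DataFrame) -> pd.DataFrame:
    """Per species-week [min, max] of observed dry shoot masses.

    Expects a measurement-record table (columns ``species``, ``week``,
    ``shoot_mass_mg``); controls should be filtered by the caller.
    """
    env = (
        observed.groupby(["species", "week"])["shoot_mass_mg"]
        .agg(["min", "max"])
        .reset_index()
    )
    return env


def select_resource_levels(
    ensemble: pd.DataFrame,
    observed: pd.DataFrame,
    per_run: bool = False,
) -> tuple[list[int], pd.DataFrame]:
    """Pattern-oriented acceptance of resource combinations.

    A sample is accepted iff its simulated shoot mass lies inside the
    observed [min, max] envelope for *every* species and *every* assessment
    week.  By default the per-sample mean over the replicate runs is
    compared; ``per_run=True`` requires every individual run to match.

    Returns the accepted sample ids and a manifest frame with an
    ``accepted`` flag per sample.  An empty accepted set triggers a warning,
    not an error; a species-week present in the ensemble but absent from the
    observed table is an error.
    """
    env = observed_envelope(observed)
    env_idx = {(r["species"], r["week"]): (r["min"], r["max"])
               for _, r in env.iterrows()}
    needed = set(map(tuple, ensemble[["species", "week"]].drop_duplicates().values))
    missing = needed - set(env_idx)
    if missing:
        raise ValueError(f"observed table missing species-weeks: {sorted(missing)}")

    group_cols = ["sample_id", "species", "week"]
    if per_run:
        sim = ensemble.rename(columns={"shoot_mass_mg": "value"})
        per = sim.groupby(group_cols)["value"].agg(["min", "max"]).reset_index()

        def inside(row):
            lo, hi = env_idx[(row["species"], row["week"])]
            return lo <= row["min"] and row["max"] <= hi
    else:
        per = (
            ensemble.groupby(group_cols)["shoot_mass_mg"].mean().reset_index()
        )

        def inside(row):
            lo, hi = env_idx[(row["species"], row["week"])]
            return lo <= row["shoot_mass_mg"] <= hi

    per["inside"] = per.apply(inside, axis=1)
    ok = per.groupby("sample_id")["inside"].all()
    accepted = sorted(int(i) for i in ok[ok].index)
    if not accepted:
        warnings.warn(
            "no resource combination matched the observed envelopes",
            stacklevel=2,
        )
    manifest = (
        ensemble[["sample_id", "below", "above"]]
        .drop_duplicates()
        .sort_values("sample_id")
        .reset_index(drop=True)
    )
    manifest["accepted"] = manifest["sample_id"].map(ok).fillna(False).astype(bool)
    return accepted, manifest
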