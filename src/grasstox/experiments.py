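"""Virtual greenhouse pots: monoculture and community designs.

Two spatial setups mirror the greenhouse study the model is bench-marked
against: a 7x7-cell monoculture pot with 4 individuals of one species at
2-cell spacing, and a 20x20-cell community pot with 8 individuals of each of
the six species plus one randomly chosen individual on the centre cell
(49 plants total).  Species are transplanted at different ages (weeks since
germination) because of their different germination and early growth speeds;
in the monoculture the herbicide is applied at the transplant age and
simulated measurement weeks map to assessment weeks 2, 4 and 6 after
application.  Community pots start from the per-species monoculture biomass
at transplant age and are treated at community week 0.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import (
    DEFAULT_PARAMS,
    EngineParams,
    Grid,
    PlantIndividual,
    SimulationState,
    run_simulation,
)
from .herbicide import DoseResponse, build_effect_schedule
from .traits import PFTraits

__all__ = [
    "SpeciesTiming",
    "TimingTable",
    "DEFAULT_TIMING",
    "ExperimentDesign",
    "default_design",
    "PlacementError",
    "init_monoculture",
    "init_community",
    "monoculture_transplant_masses",
    "run_design",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = [
    "setup", "herbicide", "rate", "replicate", "week",
    "species", "plant_id", "shoot_mass_mg", "basis",
]

#: Initial seedling mass at germination (mg dry weight, shoot + root).
DEFAULT_SEEDLING_MASS = 1.0


@dataclass(frozen=True)
class SpeciesTiming:
    week_emergence: int
    week_bbch12_14: int
    age_at_potting: int

    def __post_init__(self):
        if self.age_at_potting < 0:
            raise ValueError("age_at_potting must be >= 0")


@dataclass(frozen=True)
class TimingTable:
    """Per-species germination/transplant timing (weeks)."""

    rows: Mapping[str, SpeciesTiming]

    def age_at_potting(self, species: str) -> int:
        return self.rows[species].age_at_potting


#: Week of >75% emergence, week of reaching growth stage BBCH 12-14 (2-4 true
#: leaves) and the resulting age at transplanting.  C. cristatus is tabled
#: with transplant age 0 (its BBCH 12-14 window starts at 2-3 weeks).
DEFAULT_TIMING = TimingTable(
    rows={
        "B. erectus": SpeciesTiming(2, 4, 2),
        "C. cristatus": SpeciesTiming(2, 2, 0),
        "G. mollugo": SpeciesTiming(2, 3, 1),
        "L. hispidus": SpeciesTiming(2, 3, 1),
        "S. nutans": SpeciesTiming(3, 4, 1),
        "T. pratense": SpeciesTiming(1, 3, 2),
    }
)


class PlacementError(RuntimeError):
    """Random placement failed to satisfy the minimum-spacing constraint."""


@dataclass
class ExperimentDesign:
    """One replicated treatment x assessment-date design."""

    setup: str  # "monoculture" | "community"
    pfts: Sequence[PFTraits]
    herbicides: Mapping[str, Sequence[float]]  # rates excluding the control
    replicates: int
    measurement_weeks: Sequence[int] = (2, 4, 6)
    grid_shape: tuple[int, int] = (7, 7)
    n_per_species: int = 4
    spacing: float = 2.0

    def __post_init__(self):
        if self.setup not in ("monoculture", "community"):
            raise ValueError(f"unknown setup {self.setup!r}")
        if self.setup == "monoculture":
            if self.grid_shape != (7, 7) or self.n_per_species != 4:
                raise ValueError("monoculture design is 4 plants on a 7x7 grid")
        else:
            if self.grid_shape != (20, 20):
                raise ValueError("community design uses a 20x20 grid")
            if len(self.pfts) * self.n_per_species + 1 != 49:
                raise ValueError(
                    "community design totals 49 individuals "
                    "(8 per species x 6 species + 1 centre plant)"
                )


def default_design(
    setup: str,
    pfts: Sequence[PFTraits],
    herbicides: Mapping[str, Sequence[float]] | None = None,
) -> ExperimentDesign:
    """Default replication: 4 monoculture pots or 3 community pots per date."""
    herbicides = herbicides if herbicides is not None else {}
    if setup == "monoculture":
        return ExperimentDesign(
            setup, pfts, herbicides, replicates=4,
            grid_shape=(7, 7), n_per_species=4,
        )
    return ExperimentDesign(
        setup, pfts, herbicides, replicates=3,
        grid_shape=(20, 20), n_per_species=8,
    )


def init_monoculture(
    pft: PFTraits,
    grid: Grid,
    seed: int = 0,
    m0: float = DEFAULT_SEEDLING_MASS,
    spacing: int = 2,
) -> SimulationState:
    """Four seedlings of one PFT at 2-cell spacing on a 7x7 pot.

    Germination probability is 100%, so the state holds exactly four plants
    of mass ``m0`` (split evenly between shoot and root) arranged evenly
    around the pot centre.  Deterministic; the seed is recorded only for
    provenance.
    """
    cx, cy = grid.width // 2, grid.height // 2
    half = spacing // 2 if spacing >= 2 else 1
    positions = [
        (cx - half, cy - half), (cx - half, cy + half),
        (cx + half, cy - half), (cx + half, cy + half),
    ]
    for (x, y) in positions:
        if not grid.contains(x, y):
            raise ValueError("grid too small for the 4-plant spacing")
    plants = [
        PlantIndividual(pft, x, y, m0 / 2.0, m0 / 2.0, age=0, plant_id=i)
        for i, (x, y) in enumerate(positions)
    ]
    return SimulationState(grid=grid, plants=plants, week=0, rng_seed=seed)


def init_community(
    pfts: Sequence[PFTraits],
    grid: Grid,
    transplant_masses: Mapping[str, tuple[float, float]],
    seed: int = 0,
    timing: TimingTable = DEFAULT_TIMING,
    n_per_species: int = 8,
    spacing: float = 2.0,
    max_tries: int = 2000,
    max_restarts: int = 20,
) -> SimulationState:
    """Randomly place 8 individuals per species plus one centre individual.

    All pairwise distances (Euclidean, in cells) must be at least
    ``spacing``; the centre cell of the 20x20 grid, index (10, 10), carries
    one extra individual of a uniformly drawn species.  Initial shoot/root
    masses come from the monoculture state at each species' transplant age.
    Reproducible under the seed.

    Raises
    ------
    PlacementError
        If no layout satisfying the spacing is found within the retry budget.
    """
    rng = np.random.default_rng(seed)
    names = [p.name for p in pfts]
    by_name = {p.name: p for p in pfts}
    center = (grid.width // 2, grid.height // 2)
    center_species = names[int(rng.integers(len(names)))]
    sp2 = spacing * spacing

    for _ in range(max_restarts):
        placed: list[tuple[str, int, int]] = [(center_species, *center)]
        ok = True
        for name in names:
            for _k in range(n_per_species):
                for _try in range(max_tries):
                    x = int(rng.integers(grid.width))
                    y = int(rng.integers(grid.height))
                    if all(
                        (x - px) ** 2 + (y - py) ** 2 >= sp2
                        for (_, px, py) in placed
                    ):
                        placed.append((name, x, y))
                        break
                else:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            plants = []
            for i, (name, x, y) in enumerate(placed):
                shoot, root = transplant_masses[name]
                plants.append(
                    PlantIndividual(
                        by_name[name], x, y, shoot, root,
                        age=timing.age_at_potting(name), plant_id=i,
                    )
                )
            return SimulationState(grid=grid, plants=plants, week=0, rng_seed=seed)
    raise PlacementError(
        "could not place the community with the required minimum spacing"
    )


def monoculture_transplant_masses(
    pfts: Sequence[PFTraits],
    resources: tuple[float, float],
    timing: TimingTable = DEFAULT_TIMING,
    params: EngineParams = DEFAULT_PARAMS,
    m0: float = DEFAULT_SEEDLING_MASS,
) -> dict[str, tuple[float, float]]:
    """Per-species (shoot, root) mass at transplant age, from the control
    monoculture run at the given (below, above) resource levels, averaged
    over the four pot mates."""
    below, above = resources
    out = {}
    for pft in pfts:
        age = timing.age_at_potting(pft.name)
        grid = Grid(7, 7, above_resource=above, below_resource=below)
        state = init_monoculture(pft, grid)
        traj = run_simulation(state, age, schedule=None, params=params)
        at_age = traj[traj["week"] == age]
        out[pft.name] = (
            float(at_age["shoot_mass_mg"].mean()),
            float(at_age["root_mass_mg"].mean()),
        )
    return out


def _mono_records(
    pft: PFTraits,
    herbicide: str,
    rate: float,
    dr: DoseResponse | None,
    resources: tuple[float, float],
    replicates: int,
    measurement_weeks: Sequence[int],
    timing: TimingTable,
    params: EngineParams,
) -> list[tuple]:
    below, above = resources
    age = timing.age_at_potting(pft.name)
    horizon = age + max(measurement_weeks)
    schedule = None
    if rate > 0:
        if dr is None:
            raise ValueError(
                f"no dose-response for {herbicide}/{pft.name} at rate {rate}"
            )
        schedule = {pft.name: build_effect_schedule(dr, rate, age, horizon)}
    grid = Grid(7, 7, above_resource=above, below_resource=below)
    state = init_monoculture(pft, grid)
    traj = run_simulation(state, horizon, schedule=schedule, params=params)
    rows = []
    for w in measurement_weeks:
        at = traj[traj["week"] == age + w]
        for rep in range(replicates):
            for _, r in at.iterrows():
                rows.append((
                    "monoculture", herbicide, rate, rep, w,
                    pft.name, int(r["plant_id"]), float(r["shoot_mass_mg"]), "dry",
                ))
    return rows


def run_design(
    design: ExperimentDesign,
    dose_responses: Mapping[tuple[str, str], DoseResponse],
    resources: tuple[float, float],
    seed: int = 0,
    params: EngineParams = DEFAULT_PARAMS,
    timing: TimingTable = DEFAULT_TIMING,
) -> pd.DataFrame:
    """Run the full treatment x replicate x assessment-date design.

    Returns one record per plant and measurement week with simulated dry
    shoot mass (``MEASUREMENT_COLUMNS`` schema; rate 0 is the control).
    Monoculture runs are deterministic, so replicates coincide; community
    replicates differ through the random placement and centre-species draw.
    Treatment and control arms of a community replicate share the same
    layout seed, so treated/control contrasts are paired.
    """
    below, above = resources
    rows: list[tuple] = []
    rep_seeds = np.random.SeedSequence(seed).generate_state(design.replicates)

    if design.setup == "monoculture":
        for herbicide, rates in _with_control(design.herbicides):
            for rate in rates:
                for pft in design.pfts:
                    dr = dose_responses.get((herbicide, pft.name))
                    rows.extend(_mono_records(
                        pft, herbicide, rate, dr, resources,
                        design.replicates, design.measurement_weeks,
                        timing, params,
                    ))
    else:
        masses = monoculture_transplant_masses(
            design.pfts, resources, timing, params
        )
        horizon = max(design.measurement_weeks)
        for herbicide, rates in _with_control(design.herbicides):
            for rate in rates:
                for rep in range(design.replicates):
                    grid = Grid(design.grid_shape[0], design.grid_shape[1],
                                above_resource=above, below_resource=below)
                    state = init_community(
                        design.pfts, grid, masses, seed=int(rep_seeds[rep]),
                        timing=timing, n_per_species=design.n_per_species,
                        spacing=design.spacing,
                    )
                    schedule = None
                    if rate > 0:
                        schedule = {}
                        for pft in design.pfts:
                            dr = dose_responses.get((herbicide, pft.name))
                            if dr is None:
                                raise ValueError(
                                    f"no dose-response for {herbicide}/{pft.name}"
                                )
                            schedule[pft.name] = build_effect_schedule(
                                dr, rate, 0, horizon
                            )
                    traj = run_simulation(state, horizon, schedule, params)
                    for w in design.measurement_weeks:
                        at = traj[traj["week"] == w]
                        for _, r in at.iterrows():
                            rows.append((
                                "community", herbicide, rate, rep, w,
                                str(r["pft"]), int(r["plant_id"]),
                                float(r["shoot_mass_mg"]), "dry",
                            ))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def _with_control(herbicides: Mapping[str, Sequence[float]]):
    """Prepend the rate-0 control to each herbicide's rate list; a design
    with no herbicides still yields one control series."""
    if not herbicides:
        return [("control", [0.0])]
    return [(h, [0.0] + list(rates)) for h, rates in herbicides.items()]
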