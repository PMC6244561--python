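"""Weekly-step spatial simulation: grid, zones of influence, competition, growth.

The world is a rectangular grid of 1 cm^2 cells.  Above- and belowground
resources are supplied homogeneously in space and constant in time (units per
cell per week).  Each plant individual acquires resources within a circular
zone of influence (ZOI) around its stem; the belowground ZOI area scales with
root mass only (similar root geometries across PFTs), the aboveground area
with shoot mass and growth form.  Where ZOIs overlap, the cell's supply is
divided between claimants: size-symmetrically belowground, partially
size-asymmetrically (weights proportional to shoot mass) aboveground, and
with intraspecific competition stronger than interspecific competition.

Growth is co-limited by the two layers (Liebig's law of the minimum): the
smaller of the above- and belowground uptakes forms the plant's usable
resource pool, which is split evenly between shoot and root before the
PFT's allocation shift.  Each compartment then gains
``dm = c * resources * (1 - m / m_cap)``; combined with the ZOI area growing
as ``m^(2/3)`` this yields sigmoid growth of an uncrowded plant.  One time
step is one week.  Mortality, senescence, seed production and biotic
disturbances are excluded in this short-term model version, so biomass never
decreases; herbicide exposure enters only as a per-PFT multiplier on the
weekly biomass gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .traits import PFTraits, apply_allocation

__all__ = [
    "EngineParams",
    "DEFAULT_PARAMS",
    "Grid",
    "PlantIndividual",
    "SimulationState",
    "zoi_cells",
    "distribute_cell_resource",
    "grow",
    "weekly_step",
    "run_simulation",
    "LAYER_ABOVE",
    "LAYER_BELOW",
]

LAYER_ABOVE = "above"
LAYER_BELOW = "below"


@dataclass(frozen=True)
class EngineParams:
    """Tunable constants of the competition/growth engine.

    conversion_rate
        mg dry mass gained per resource unit.  Sized so that a control
        monoculture traverses the rising limb of its sigmoid over the
        8-week horizon instead of saturating within 2-3 weeks, which keeps
        the growth trajectories responsive to the resource level.
    theta
        Exponent on shoot mass in the aboveground competition weight.
        0 = fully size-symmetric, 1 (default) = partial size asymmetry
        (shading by taller plants).
    kappa
        Discount (< 1) on heterospecific competitor weights: conspecific
        neighbours depress a focal plant's share more than heterospecific
        ones.  Cell shares are renormalised so a cell never hands out more
        than its supply.
    k_form
        Aboveground ZOI area per mg^(2/3) of shoot mass, by growth form;
        rosettes spread over the ground, erect forms stack height.
    k_below
        Single belowground area coefficient (similar root geometries).
    shoot_mass_fraction
        Fraction of a PFT's maximal plant mass available to the shoot
        compartment; the remainder caps the root.
    shoot_only_effect
        If True the herbicide gain multiplier acts on shoot gain only;
        default applies it to both compartments.
    growth_multipliers
        Optional per-PFT multiplier on the conversion rate (used by the
        synthetic-data generator to perturb latent growth rates).
    """

    conversion_rate: float = 0.1
    theta: float = 1.0
    kappa: float = 0.8
    k_form: Mapping[str, float] = field(
        default_factory=lambda: {"rosette": 1.5, "semi-rosette": 1.0, "erect": 0.5}
    )
    k_below: float = 0.6
    shoot_mass_fraction: float = 0.5
    shoot_only_effect: bool = False
    growth_multipliers: Mapping[str, float] = field(default_factory=dict)


DEFAULT_PARAMS = EngineParams()


@dataclass
class Grid:
    """Homogeneous resource arena; one cell is 1 cm^2."""

    width: int
    height: int
    above_resource: float
    below_resource: float

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must be at least 1x1")
        if self.above_resource < 0 or self.below_resource < 0:
            raise ValueError("resources must be non-negative")

    def contains(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height


@dataclass
class PlantIndividual:
    pft: PFTraits
    x: int
    y: int
    shoot_mass: float
    root_mass: float
    age: int = 0
    plant_id: int = 0

    def __post_init__(self):
        if self.shoot_mass < 0 or self.root_mass < 0:
            raise ValueError("masses must be non-negative")


@dataclass
class SimulationState:
    grid: Grid
    plants: list[PlantIndividual]
    week: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        for p in self.plants:
            if not self.grid.contains(p.x, p.y):
                raise ValueError(
                    f"plant {p.plant_id} at ({p.x},{p.y}) outside grid"
                )


def _zoi_area(plant: PlantIndividual, layer: str, params: EngineParams) -> float:
    if layer == LAYER_BELOW:
        return params.k_below * plant.root_mass ** (2.0 / 3.0)
    if layer == LAYER_ABOVE:
        return params.k_form[plant.pft.growth_form] * plant.shoot_mass ** (2.0 / 3.0)
    raise ValueError(f"unknown layer {layer!r}")


def zoi_cells(
    plant: PlantIndividual,
    layer: str,
    grid: Grid,
    params: EngineParams = DEFAULT_PARAMS,
) -> set[tuple[int, int]]:
    """Grid cells covered by the plant's zone of influence in one layer.

    A cell belongs to the ZOI when its centre lies within radius
    ``r = sqrt(A / pi)`` of the plant's cell centre, with area
    ``A = k * m^(2/3)``.  Cells beyond the grid edge are discarded (plants
    cannot grow past the plot), and the home cell is always included.
    """
    area = _zoi_area(plant, layer, params)
    r = math.sqrt(area / math.pi)
    cells = set()
    if grid.contains(plant.x, plant.y):
        cells.add((plant.x, plant.y))
    rint = int(r)
    r2 = r * r
    for dx in range(-rint, rint + 1):
        for dy in range(-rint, rint + 1):
            if dx * dx + dy * dy <= r2:
                cx, cy = plant.x + dx, plant.y + dy
                if grid.contains(cx, cy):
                    cells.add((cx, cy))
    return cells


def distribute_cell_resource(
    cell_claimants: Sequence[tuple[PlantIndividual, float]],
    cell_supply: float,
    layer: str = LAYER_BELOW,
    params: EngineParams = DEFAULT_PARAMS,
) -> list[float]:
    """Divide one cell's supply among the plants claiming it.

    Each claimant ``i`` with weight ``w_i`` receives
    ``supply * w_i / D_i`` where the focal denominator
    ``D_i = sum_j w_j * s_ij`` discounts heterospecific competitors by
    ``kappa < 1`` (``s_ij = 1`` for conspecifics).  In mixed cells the
    focal-specific denominators can nominally allocate more than the supply;
    shares are then rescaled so that their sum never exceeds the cell supply
    (exact partition when kappa = 1 or all claimants are conspecific).
    """
    if cell_supply < 0:
        raise ValueError("cell_supply must be non-negative")
    if not cell_claimants:
        return []
    shares = []
    for pi, wi in cell_claimants:
        if wi <= 0:
            shares.append(0.0)
            continue
        denom = 0.0
        for pj, wj in cell_claimants:
            if wj <= 0:
                continue
            same = pj.pft.name == pi.pft.name
            denom += wj if same else params.kappa * wj
        shares.append(cell_supply * wi / denom)
    total = sum(shares)
    if total > cell_supply > 0:
        scale = cell_supply / total
        shares = [s * scale for s in shares]
    return shares


def grow(
    plant: PlantIndividual,
    shoot_uptake: float,
    root_uptake: float,
    gain_multiplier: float = 1.0,
    params: EngineParams = DEFAULT_PARAMS,
) -> PlantIndividual:
    """Convert one week's resource uptake into biomass.

    The PFT's allocation shift is applied to the uptake pair first; each
    compartment then gains ``c * resources * (1 - m / m_cap)``, multiplied by
    the herbicide gain multiplier (1 = untreated, 0 = full suppression).
    Masses never decrease and are capped at the compartment maxima.
    """
    if shoot_uptake < 0 or root_uptake < 0:
        raise ValueError("uptake must be non-negative")
    if not 0.0 <= gain_multiplier <= 1.0:
        raise ValueError("gain_multiplier must be in [0, 1]")
    shoot_res, root_res = apply_allocation(shoot_uptake, root_uptake, plant.pft)
    c = params.conversion_rate * params.growth_multipliers.get(plant.pft.name, 1.0)
    shoot_cap = plant.pft.max_mass * params.shoot_mass_fraction
    root_cap = plant.pft.max_mass * (1.0 - params.shoot_mass_fraction)
    root_multiplier = 1.0 if params.shoot_only_effect else gain_multiplier
    d_shoot = c * shoot_res * max(0.0, 1.0 - plant.shoot_mass / shoot_cap)
    d_root = c * root_res * max(0.0, 1.0 - plant.root_mass / root_cap)
    plant.shoot_mass = min(plant.shoot_mass + d_shoot * gain_multiplier, shoot_cap)
    plant.root_mass = min(plant.root_mass + d_root * root_multiplier, root_cap)
    return plant


def _layer_weight(plant: PlantIndividual, layer: str, params: EngineParams) -> float:
    if layer == LAYER_BELOW:
        return plant.pft.comp_ability_below
    return plant.pft.comp_ability_above * plant.shoot_mass ** params.theta


def weekly_step(
    state: SimulationState,
    effects: Mapping[str, float] | None = None,
    params: EngineParams = DEFAULT_PARAMS,
) -> SimulationState:
    """Advance the community by one week.

    For each layer every plant's ZOI is computed, every cell's supply is
    divided among its claimants and per-plant uptake is summed (capped at
    the PFT's maximal uptake per ZOI area).  The limiting layer's uptake
    (law of the minimum) is the plant's usable resource pool; it is split
    evenly between the shoot and root compartments and converted into
    growth with the plant's current herbicide gain multiplier.
    Deterministic given the state and effect map.
    """
    effects = effects or {}
    uptake = {LAYER_ABOVE: [0.0] * len(state.plants),
              LAYER_BELOW: [0.0] * len(state.plants)}
    for layer in (LAYER_ABOVE, LAYER_BELOW):
        supply = (state.grid.above_resource if layer == LAYER_ABOVE
                  else state.grid.below_resource)
        cell_map: dict[tuple[int, int], list[tuple[int, float]]] = {}
        n_cells = [0] * len(state.plants)
        for i, p in enumerate(state.plants):
            cells = zoi_cells(p, layer, state.grid, params)
            n_cells[i] = len(cells)
            w = _layer_weight(p, layer, params)
            for cell in cells:
                cell_map.setdefault(cell, []).append((i, w))
        for cell, claimants in cell_map.items():
            shares = distribute_cell_resource(
                [(state.plants[i], w) for i, w in claimants],
                supply, layer, params,
            )
            for (i, _), s in zip(claimants, shares):
                uptake[layer][i] += s
        for i, p in enumerate(state.plants):
            cap = p.pft.max_uptake_per_area * n_cells[i]
            uptake[layer][i] = min(uptake[layer][i], cap)
    for i, p in enumerate(state.plants):
        gm = float(effects.get(p.pft.name, 1.0))
        pool = min(uptake[LAYER_ABOVE][i], uptake[LAYER_BELOW][i])
        grow(p, pool / 2.0, pool / 2.0, gm, params)
        p.age += 1
    state.week += 1
    return state


def run_simulation(
    initial: SimulationState,
    weeks: int,
    schedule: Mapping[str, Sequence[float]] | None = None,
    params: EngineParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Run ``weeks`` weekly steps and return a tidy mass trajectory.

    ``schedule`` maps PFT name to a per-week sequence of gain multipliers,
    indexed by the simulation week at the start of each step; missing PFTs
    or a ``None`` schedule mean untreated.  The returned frame has one row
    per (week, plant), starting with the initial state, with columns
    ``week, plant_id, pft, shoot_mass_mg, root_mass_mg``.
    """
    if weeks < 0:
        raise ValueError("weeks must be >= 0")
    rows = []

    def snapshot():
        for p in initial.plants:
            rows.append((initial.week, p.plant_id, p.pft.name,
                         p.shoot_mass, p.root_mass))

    snapshot()
    for _ in range(weeks):
        if schedule:
            effects = {
                name: seq[initial.week] if initial.week < len(seq) else seq[-1]
                for name, seq in schedule.items()
            }
        else:
            effects = None
        weekly_step(initial, effects, params)
        snapshot()
    return pd.DataFrame(
        rows, columns=["week", "plant_id", "pft", "shoot_mass_mg", "root_mass_mg"]
    )
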