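"""Plant functional types (PFTs) and the root/shoot allocation shift.

The community model abstracts species into plant functional types: bundles of
trait values (plant size class, growth form, resource response, grazing
response) that determine maximal plant mass, the geometry of the zone of
influence and competitive ability.  Two of the six default grassland species
additionally carry an allocation shift: after resources have been divided
between the shoot and root compartments, a fixed fraction is moved to the
favoured compartment (shoot for *Trifolium pratense*, root for *Silene
nutans*), reflecting the root/shoot ratios reported for these species in
trait databases.

The default trait table ships with the package and covers the six mesic
grassland species of the greenhouse community design: *Bromus erectus*,
*Cynosurus cristatus*, *Galium mollugo*, *Leontodon hispidus*, *Silene
nutans* and *Trifolium pratense*.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "PFTraits",
    "load_pft_table",
    "default_pfts",
    "pft_map",
    "apply_allocation",
    "SIZE_CLASSES",
    "GROWTH_FORMS",
    "RESOURCE_RESPONSES",
    "GRAZING_RESPONSES",
    "DEFAULT_MAX_MASS",
    "DEFAULT_COMP_ABILITY",
    "DEFAULT_MAX_UPTAKE_PER_AREA",
]

SIZE_CLASSES = ("small", "medium", "large")
GROWTH_FORMS = ("rosette", "semi-rosette", "erect")
RESOURCE_RESPONSES = ("competitor", "intermediate", "stress-tolerator")
GRAZING_RESPONSES = ("avoider", "tolerator", "intermediate")

#: Maximal plant mass (mg dry weight) per size class.  The classification only
#: constrains the ordering small < medium < large; the absolute numbers are
#: package defaults and can be overridden per species in the trait table.
DEFAULT_MAX_MASS = {"small": 1000.0, "medium": 3000.0, "large": 5000.0}

#: Competitive-ability weight derived from the resource-response trade-off
#: (competitors acquire contested resources more effectively than
#: stress-tolerators).  Applied in both the above- and belowground layer.
DEFAULT_COMP_ABILITY = {
    "competitor": 1.0,
    "intermediate": 0.75,
    "stress-tolerator": 0.5,
}

#: Physiological ceiling on resource uptake (resource units per cm^2 of zone
#: of influence per week).  At the default it is above the per-cell supply
#: used in the calibration sweep, so uptake is normally supply-limited.
DEFAULT_MAX_UPTAKE_PER_AREA = 200.0

_REQUIRED_COLUMNS = (
    "species",
    "size_class",
    "growth_form",
    "resource_response",
    "grazing_response",
    "alloc_shoot",
    "alloc_root",
)


@dataclass(frozen=True)
class PFTraits:
    """Trait syndrome of one plant functional type.

    Parameters
    ----------
    name:
        Species / PFT label.
    size_class:
        One of ``small``, ``medium``, ``large``; sets ``max_mass`` unless an
        explicit value is given.
    max_mass:
        Maximal plant mass in mg dry weight (shoot + root).
    growth_form:
        ``rosette``, ``semi-rosette`` or ``erect``; controls how much ground
        area a given shoot mass covers.
    resource_response:
        Position on the competition/stress-tolerance trade-off; sets the
        competitive-ability weights unless given explicitly.
    grazing_response:
        Recorded for completeness; unused in the herbicide-exposure model
        version (grazing is switched off).
    alloc_shoot, alloc_root:
        Allocation-shift fractions in [0, 1].  At most one may be nonzero:
        a PFT either shifts root resources to the shoot, shoot resources to
        the root, or neither.
    comp_ability_above, comp_ability_below:
        Dimensionless competition weights (> 0) for the two resource layers.
    max_uptake_per_area:
        Resource units a plant can take up per cm^2 of its zone of influence
        per week.
    """

    name: str
    size_class: str
    growth_form: str
    resource_response: str
    grazing_response: str = "intermediate"
    alloc_shoot: float = 0.0
    alloc_root: float = 0.0
    max_mass: float = 0.0
    comp_ability_above: float = 0.0
    comp_ability_below: float = 0.0
    max_uptake_per_area: float = DEFAULT_MAX_UPTAKE_PER_AREA

    def __post_init__(self):
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size_class {self.size_class!r}")
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(f"unknown growth_form {self.growth_form!r}")
        if self.resource_response not in RESOURCE_RESPONSES:
            raise ValueError(
                f"unknown resource_response {self.resource_response!r}"
            )
        if self.grazing_response not in GRAZING_RESPONSES:
            raise ValueError(
                f"unknown grazing_response {self.grazing_response!r}"
            )
        for attr in ("alloc_shoot", "alloc_root"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.alloc_shoot > 0 and self.alloc_root > 0:
            raise ValueError(
                "at most one of alloc_shoot/alloc_root may be nonzero "
                f"for PFT {self.name!r}"
            )
        # Fill derived defaults on the frozen instance.
        if self.max_mass <= 0:
            object.__setattr__(self, "max_mass", DEFAULT_MAX_MASS[self.size_class])
        if self.comp_ability_above <= 0:
            object.__setattr__(
                self,
                "comp_ability_above",
                DEFAULT_COMP_ABILITY[self.resource_response],
            )
        if self.comp_ability_below <= 0:
            object.__setattr__(
                self,
                "comp_ability_below",
                DEFAULT_COMP_ABILITY[self.resource_response],
            )
        if self.max_uptake_per_area <= 0:
            raise ValueError("max_uptake_per_area must be > 0")


def load_pft_table(path: str | Path | None = None) -> list[PFTraits]:
    """Read a trait table (comma- or tab-delimited, header row).

    ``path=None`` loads the packaged default table with the six grassland
    species of the greenhouse design.  Optional columns ``max_mass``,
    ``comp_ability_above``, ``comp_ability_below`` and ``max_uptake_per_area``
    override the size-class / resource-response defaults.

    Raises
    ------
    ValueError
        On missing columns, duplicate species, allocation values outside
        [0, 1], unknown categorical values, or a ``max_mass`` assignment that
        breaks the strict small < medium < large ordering.
    """
    if path is None:
        ref = importlib.resources.files("grasstox.data") / "pft_default.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=None, engine="python")

    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in trait table: {dups}")

    optional = ("max_mass", "comp_ability_above", "comp_ability_below",
                "max_uptake_per_area")
    pfts = []
    for _, row in df.iterrows():
        kwargs = dict(
            name=str(row["species"]),
            size_class=str(row["size_class"]).strip().lower(),
            growth_form=str(row["growth_form"]).strip().lower(),
            resource_response=str(row["resource_response"]).strip().lower(),
            grazing_response=str(row["grazing_response"]).strip().lower(),
            alloc_shoot=float(row["alloc_shoot"]),
            alloc_root=float(row["alloc_root"]),
        )
        for col in optional:
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        pfts.append(PFTraits(**kwargs))

    _check_mass_ordering(pfts)
    return pfts


def _check_mass_ordering(pfts: Iterable[PFTraits]) -> None:
    """max_mass must strictly increase with size-class rank."""
    by_class: dict[str, list[float]] = {}
    for p in pfts:
        by_class.setdefault(p.size_class, []).append(p.max_mass)
    present = [c for c in SIZE_CLASSES if c in by_class]
    for lo, hi in zip(present, present[1:]):
        if max(by_class[lo]) >= min(by_class[hi]):
            raise ValueError(
                f"max_mass ordering violated: {lo} plants must be strictly "
                f"lighter than {hi} plants"
            )


def default_pfts() -> list[PFTraits]:
    """The packaged six-species trait table."""
    return load_pft_table(None)


def pft_map(pfts: Iterable[PFTraits]) -> dict[str, PFTraits]:
    return {p.name: p for p in pfts}


def apply_allocation(
    shoot_res: float, root_res: float, pft: PFTraits
) -> tuple[float, float]:
    """Apply the PFT's allocation shift to a (shoot, root) resource pair.

    Shift-to-shoot PFTs move ``alloc_shoot`` of the root resources into the
    shoot pool; shift-to-root PFTs move ``alloc_root`` of the shoot resources
    into the root pool; neutral PFTs return the inputs unchanged.  The total
    is conserved exactly.
    """
    if shoot_res < 0 or root_res < 0:
        raise ValueError("resource inputs must be non-negative")
    if pft.alloc_shoot > 0:
        return (
            shoot_res + root_res * pft.alloc_shoot,
            root_res * (1.0 - pft.alloc_shoot),
        )
    if pft.alloc_root > 0:
        return (
            shoot_res * (1.0 - pft.alloc_root),
            root_res + shoot_res * pft.alloc_root,
        )
    return shoot_res, root_res
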