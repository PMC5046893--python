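"""Shared data model: functional groups, cohorts, autotroph stocks, landscapes,
treatments, and run summaries.

Conventions used throughout the package:

* masses in kg, areas in km², time in months, temperature in °C,
  productivity in kg km⁻² month⁻¹; unit conversions happen only at I/O
  boundaries;
* grid coordinates are 0-based ``(row, col)``, row-major, with cell (0, 0)
  in the north-west corner;
* cohort abundance is a non-negative real number of individuals — cohorts
  stand for many organisms, so deterministic sub-individual dynamics are
  accepted in exchange for avoiding demographic rounding artifacts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrophicGroup",
    "Thermoregulation",
    "ReproductiveStrategy",
    "LeafStrategy",
    "Configuration",
    "FunctionalGroupDef",
    "Cohort",
    "CohortTable",
    "AutotrophStock",
    "Landscape",
    "Treatment",
    "EcosystemSummary",
    "ModelState",
    "validate_state",
    "state_to_frames",
    "frames_to_state",
]

EARTH_RADIUS_KM = 6371.0

#: Relative tolerance used when checking additive biomass identities.
SUM_RTOL = 1e-9


class TrophicGroup(enum.IntEnum):
    """Feeding guild of a heterotroph cohort."""

    CARNIVORE = 0
    OMNIVORE = 1
    HERBIVORE = 2

    @property
    def label(self) -> str:
        return self.name.lower()


class Thermoregulation(enum.IntEnum):
    ENDOTHERM = 0
    ECTOTHERM = 1

    @property
    def label(self) -> str:
        return self.name.lower()


class ReproductiveStrategy(enum.IntEnum):
    SEMELPAROUS = 0
    ITEROPAROUS = 1

    @property
    def label(self) -> str:
        return self.name.lower()


class LeafStrategy(enum.IntEnum):
    DECIDUOUS = 0
    EVERGREEN = 1

    @property
    def label(self) -> str:
        return self.name.lower()


class Configuration(str, enum.Enum):
    """Spatial arrangement of impacted cells in a land-use treatment."""

    RANDOM = "random"
    CONTINUOUS = "continuous"
    PRISTINE = "pristine"


@dataclass(frozen=True)
class FunctionalGroupDef:
    """A combination of categorical traits defining a functional group.

    Organisms carry no taxonomic identity; a functional group is the full
    trait combination (trophic group × thermoregulation × reproductive
    strategy) plus the admissible mass ranges for newly seeded cohorts.

    Parameters
    ----------
    trophic_group, thermoregulation, reproductive_strategy
        Categorical traits.
    juvenile_mass_range, adult_mass_range
        Inclusive ``(low, high)`` intervals in kg constraining the birth
        mass and maturity mass of seeded cohorts.
    """

    trophic_group: TrophicGroup
    thermoregulation: Thermoregulation
    reproductive_strategy: ReproductiveStrategy
    juvenile_mass_range: tuple[float, float] = (4e-7, 50.0)
    adult_mass_range: tuple[float, float] = (4e-7, 5000.0)

    def __post_init__(self) -> None:
        jlo, jhi = self.juvenile_mass_range
        alo, ahi = self.adult_mass_range
        if not (jlo > 0 and jlo <= jhi):
            raise ValueError(f"invalid juvenile mass range {self.juvenile_mass_range}")
        if not (alo >= jlo and alo <= ahi):
            raise ValueError(f"invalid adult mass range {self.adult_mass_range}")
        # coerce to enums so string/int input fails loudly
        object.__setattr__(self, "trophic_group", TrophicGroup(self.trophic_group))
        object.__setattr__(self, "thermoregulation", Thermoregulation(self.thermoregulation))
        object.__setattr__(
            self, "reproductive_strategy", ReproductiveStrategy(self.reproductive_strategy)
        )


def all_functional_groups(
    exclude: Iterable[tuple[TrophicGroup, Thermoregulation, ReproductiveStrategy]] = (),
    juvenile_mass_range: tuple[float, float] = (4e-7, 50.0),
    adult_mass_range: tuple[float, float] = (4e-7, 5000.0),
) -> list[FunctionalGroupDef]:
    """The full 3 × 2 × 2 factorial of categorical trait combinations.

    ``exclude`` lists trait triples to drop (e.g. combinations considered
    non-viable in a given configuration).
    """
    excluded = {tuple(e) for e in exclude}
    groups = []
    for tg in TrophicGroup:
        for th in Thermoregulation:
            for rs in ReproductiveStrategy:
                if (tg, th, rs) in excluded:
                    continue
                groups.append(
                    FunctionalGroupDef(
                        tg, th, rs,
                        juvenile_mass_range=juvenile_mass_range,
                        adult_mass_range=adult_mass_range,
                    )
                )
    return groups


@dataclass
class Cohort:
    """A group of identical heterotroph individuals — the simulator's unit
    of agency.

    Attributes
    ----------
    trophic_group, thermoregulation, reproductive_strategy
        Categorical traits shared by every individual in the cohort.
    current_mass : float
        Body mass per individual, kg.
    birth_mass, maturity_mass : float
        Mass at birth and at reproductive maturity, kg.
    abundance : float
        Number of individuals (non-negative real).
    reproductive_pool : float
        Mass accumulated toward reproduction, kg per individual.
    cell_index : int
        Flat row-major grid index of the occupied cell.
    age : float
        Cohort age in months.
    """

    trophic_group: TrophicGroup
    thermoregulation: Thermoregulation
    reproductive_strategy: ReproductiveStrategy
    current_mass: float
    birth_mass: float
    maturity_mass: float
    abundance: float
    cell_index: int = 0
    reproductive_pool: float = 0.0
    age: float = 0.0

    def __post_init__(self) -> None:
        if self.birth_mass > self.maturity_mass:
            raise ValueError("birth_mass must not exceed maturity_mass")
        if self.current_mass <= 0:
            raise ValueError("current_mass must be positive")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


_COHORT_FIELDS = (
    ("cell", np.int64),
    ("trophic", np.int8),
    ("thermo", np.int8),
    ("repro", np.int8),
    ("mass", np.float64),
    ("birth_mass", np.float64),
    ("maturity_mass", np.float64),
    ("abundance", np.float64),
    ("repro_pool", np.float64),
    ("age", np.float64),
    ("newborn", np.bool_),
    ("hunger", np.float64),
    ("starving", np.bool_),
)


class CohortTable:
    """Struct-of-arrays container for all live cohorts.

    Each field is a flat numpy array aligned across cohorts. ``hunger`` is
    the realized intake/requirement ratio from the most recent feeding
    step (used by responsive dispersal), ``newborn`` marks cohorts spawned
    in the current step (used by natal dispersal), and ``starving`` is the
    starvation flag set by metabolism/feeding.
    """

    __slots__ = tuple(name for name, _ in _COHORT_FIELDS)

    def __init__(self, **arrays: np.ndarray) -> None:
        n = None
        for name, dtype in _COHORT_FIELDS:
            arr = arrays.get(name)
            if arr is None:
                if name == "hunger":
                    arr = np.ones(0 if n is None else n)
                else:
                    arr = np.zeros(0 if n is None else n, dtype=dtype)
            arr = np.asarray(arr, dtype=dtype)
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError(f"field {name!r} has length {arr.shape[0]}, expected {n}")
            setattr(self, name, arr)

    # -- construction ----------------------------------------------------
    @classmethod
    def empty(cls) -> "CohortTable":
        return cls()

    @classmethod
    def from_cohorts(cls, cohorts: Sequence[Cohort]) -> "CohortTable":
        return cls(
            cell=[c.cell_index for c in cohorts],
            trophic=[int(c.trophic_group) for c in cohorts],
            thermo=[int(c.thermoregulation) for c in cohorts],
            repro=[int(c.reproductive_strategy) for c in cohorts],
            mass=[c.current_mass for c in cohorts],
            birth_mass=[c.birth_mass for c in cohorts],
            maturity_mass=[c.maturity_mass for c in cohorts],
            abundance=[c.abundance for c in cohorts],
            repro_pool=[c.reproductive_pool for c in cohorts],
            age=[c.age for c in cohorts],
            hunger=np.ones(len(cohorts)),
        )

    def to_cohorts(self) -> list[Cohort]:
        return [
            Cohort(
                trophic_group=TrophicGroup(int(self.trophic[i])),
                thermoregulation=Thermoregulation(int(self.thermo[i])),
                reproductive_strategy=ReproductiveStrategy(int(self.repro[i])),
                current_mass=float(self.mass[i]),
                birth_mass=float(self.birth_mass[i]),
                maturity_mass=float(self.maturity_mass[i]),
                abundance=float(self.abundance[i]),
                cell_index=int(self.cell[i]),
                reproductive_pool=float(self.repro_pool[i]),
                age=float(self.age[i]),
            )
            for i in range(len(self))
        ]

    # -- basic protocol --------------------------------------------------
    def __len__(self) -> int:
        return int(self.cell.shape[0])

    def copy(self) -> "CohortTable":
        return CohortTable(**{name: getattr(self, name).copy() for name, _ in _COHORT_FIELDS})

    def select(self, idx) -> "CohortTable":
        """Row subset (boolean mask or index array) as a new table."""
        return CohortTable(**{name: getattr(self, name)[idx] for name, _ in _COHORT_FIELDS})

    def concat(self, other: "CohortTable") -> "CohortTable":
        return CohortTable(
            **{
                name: np.concatenate([getattr(self, name), getattr(other, name)])
                for name, _ in _COHORT_FIELDS
            }
        )

    @property
    def biomass(self) -> np.ndarray:
        """Per-cohort total biomass, kg: (body + reproductive pool) × abundance."""
        return (self.mass + self.repro_pool) * self.abundance

    def total_biomass(self) -> float:
        return float(self.biomass.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: getattr(self, name) for name, _ in _COHORT_FIELDS}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        return cls(**{name: df[name].to_numpy() for name, _ in _COHORT_FIELDS if name in df})


@dataclass
class AutotrophStock:
    """Per-cell plant biomass, split into edible leaf and inedible
    structural pools. Only ``leaf_biomass`` is ever debited by herbivory."""

    leaf_biomass: float
    structural_biomass: float
    leaf_strategy: LeafStrategy = LeafStrategy.DECIDUOUS

    def __post_init__(self) -> None:
        if self.leaf_biomass < 0 or self.structural_biomass < 0:
            raise ValueError("autotroph biomass pools must be non-negative")

    @property
    def total(self) -> float:
        return self.leaf_biomass + self.structural_biomass


@dataclass(frozen=True)
class Landscape:
    """Bounded rectangular grid of habitat cells.

    The boundary is closed: no dispersal into or out of the grid. Cell
    areas come from spherical-Earth geometry (mean radius 6371 km) and are
    stored flat in row-major order; row 0 is the northern edge.
    """

    n_rows: int
    n_cols: int
    cell_size_deg: float
    centre_lat: float
    centre_lon: float
    cell_areas: np.ndarray  # km², flat row-major
    cell_lats: np.ndarray  # cell-centre latitudes, degrees
    cell_lons: np.ndarray  # cell-centre longitudes, degrees

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def total_area(self) -> float:
        """Total landscape area, km²."""
        return float(self.cell_areas.sum())

    def cell_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside {self.n_rows}×{self.n_cols} grid")
        return row * self.n_cols + col

    def rowcol(self, index: int) -> tuple[int, int]:
        return divmod(int(index), self.n_cols)

    def pairwise_distances_km(self) -> np.ndarray:
        """Great-circle-free planar distances between cell centres, km.

        At the sub-degree scales simulated here an equirectangular
        approximation (longitude scaled by cos latitude) is accurate to
        well under 0.1%.
        """
        km_per_deg = 2 * np.pi * EARTH_RADIUS_KM / 360.0
        lat = self.cell_lats
        lon = self.cell_lons
        coslat = np.cos(np.deg2rad(self.centre_lat))
        y = lat * km_per_deg
        x = lon * km_per_deg * coslat
        dy = y[:, None] - y[None, :]
        dx = x[:, None] - x[None, :]
        return np.hypot(dx, dy)


@dataclass(frozen=True)
class Treatment:
    """One land-use scenario: spatial configuration, extent and intensity,
    with its realized impacted-cell mask.

    ``extent`` is the fraction of grid cells impacted; ``intensity`` the
    fraction of autotroph biomass removed from each impacted cell at every
    monthly step. The pristine control has extent 0 and an empty mask.
    """

    configuration: Configuration
    extent: float
    intensity: float
    impacted_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.extent <= 1.0):
            raise ValueError("extent must be in [0, 1]")
        if not (0.0 <= self.intensity <= 1.0):
            raise ValueError("intensity must be in [0, 1]")
        if self.configuration == Configuration.PRISTINE and self.extent != 0.0:
            raise ValueError("pristine treatment must have extent 0")
        if self.extent == 0.0 and self.configuration != Configuration.PRISTINE:
            raise ValueError("extent 0 is reserved for the pristine control")
        if self.impacted_mask is not None:
            mask = np.asarray(self.impacted_mask, dtype=bool)
            object.__setattr__(self, "impacted_mask", mask)

    @property
    def label(self) -> str:
        if self.configuration == Configuration.PRISTINE:
            return "pristine"
        return (
            f"{self.configuration.value}"
            f"_e{int(round(self.extent * 100))}"
            f"_i{int(round(self.intensity * 100))}"
        )

    def with_mask(self, mask: np.ndarray) -> "Treatment":
        mask = np.asarray(mask, dtype=bool)
        expected = self.extent * mask.size
        if abs(mask.sum() - round(expected)) > 0.5:
            raise ValueError(
                f"mask cardinality {mask.sum()} inconsistent with extent {self.extent}"
            )
        return replace(self, impacted_mask=mask)


@dataclass
class EcosystemSummary:
    """Per-run trophic-group biomass totals (kg) averaged over the recorded
    window of landscape totals — the input to every response metric."""

    carnivore_biomass: float
    omnivore_biomass: float
    herbivore_biomass: float
    autotroph_biomass: float
    configuration: str = "pristine"
    extent: float = 0.0
    intensity: float = 0.0
    scale: str = ""
    replicate: int = 0
    seed: int = 0

    @property
    def total_biomass(self) -> float:
        return (
            self.carnivore_biomass
            + self.omnivore_biomass
            + self.herbivore_biomass
            + self.autotroph_biomass
        )

    def shares(self) -> np.ndarray:
        """Biomass shares (C, O, H, A) of the total; requires total > 0."""
        t = self.total_biomass
        if t <= 0:
            raise ValueError("total biomass must be positive to form shares")
        return (
            np.array(
                [
                    self.carnivore_biomass,
                    self.omnivore_biomass,
                    self.herbivore_biomass,
                    self.autotroph_biomass,
                ]
            )
            / t
        )


@dataclass
class ModelState:
    """Full simulator state: all cohorts plus per-cell autotroph pools."""

    cohorts: CohortTable
    leaf: np.ndarray  # kg per cell, flat row-major
    structural: np.ndarray  # kg per cell
    leaf_strategy: np.ndarray  # LeafStrategy codes per cell
    month: int = 0

    def copy(self) -> "ModelState":
        return ModelState(
            cohorts=self.cohorts.copy(),
            leaf=self.leaf.copy(),
            structural=self.structural.copy(),
            leaf_strategy=self.leaf_strategy.copy(),
            month=self.month,
        )

    @property
    def n_cells(self) -> int:
        return int(self.leaf.shape[0])

    def autotroph_total(self) -> float:
        return float(self.leaf.sum() + self.structural.sum())

    def heterotroph_total(self) -> float:
        return self.cohorts.total_biomass()

    def total_biomass(self) -> float:
        return self.autotroph_total() + self.heterotroph_total()

    def trophic_totals(self) -> dict[str, float]:
        """Landscape biomass totals keyed by trophic group plus autotrophs."""
        b = self.cohorts.biomass
        out = {}
        for tg in TrophicGroup:
            out[tg.label] = float(b[self.cohorts.trophic == int(tg)].sum())
        out["autotroph"] = self.autotroph_total()
        return out


def validate_state(state) -> list[str]:
    """Check every domain invariant; return a list of violation messages.

    Accepts a :class:`ModelState` or an :class:`EcosystemSummary`. Never
    mutates its argument; an empty list means the state is valid.
    """
    violations: list[str] = []
    if isinstance(state, EcosystemSummary):
        comps = {
            "carnivore": state.carnivore_biomass,
            "omnivore": state.omnivore_biomass,
            "herbivore": state.herbivore_biomass,
            "autotroph": state.autotroph_biomass,
        }
        for name, v in comps.items():
            if v < 0 or not np.isfinite(v):
                violations.append(f"summary component {name} is negative or non-finite: {v}")
        total = sum(comps.values())
        stored = state.total_biomass
        if not np.isclose(stored, total, rtol=SUM_RTOL, atol=1e-30):
            violations.append(
                f"summary total {stored} differs from component sum {total}"
            )
        return violations

    c = state.cohorts
    if np.any(c.abundance < 0):
        for i in np.flatnonzero(c.abundance < 0):
            violations.append(f"cohort {i} has negative abundance {c.abundance[i]}")
    if np.any(c.mass <= 0):
        for i in np.flatnonzero(c.mass <= 0):
            violations.append(f"cohort {i} has non-positive mass {c.mass[i]}")
    bad = c.birth_mass > c.maturity_mass
    for i in np.flatnonzero(bad):
        violations.append(
            f"cohort {i} has birth_mass {c.birth_mass[i]} > maturity_mass {c.maturity_mass[i]}"
        )
    n_cells = state.n_cells
    out_of_grid = (c.cell < 0) | (c.cell >= n_cells)
    for i in np.flatnonzero(out_of_grid):
        violations.append(f"cohort {i} occupies out-of-grid cell {c.cell[i]}")
    if np.any(state.leaf < 0):
        violations.append("negative leaf biomass in cells "
                          f"{np.flatnonzero(state.leaf < 0).tolist()}")
    if np.any(state.structural < 0):
        violations.append("negative structural biomass in cells "
                          f"{np.flatnonzero(state.structural < 0).tolist()}")
    for name, arr in (("leaf", state.leaf), ("structural", state.structural),
                      ("mass", c.mass), ("abundance", c.abundance)):
        if not np.all(np.isfinite(arr)):
            violations.append(f"non-finite values in {name}")
    return violations


# -- serialization -------------------------------------------------------

def state_to_frames(state: ModelState) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy frames: one row per cohort, one row per cell stock."""
    cohorts = state.cohorts.to_dataframe()
    stocks = pd.DataFrame(
        {
            "cell": np.arange(state.n_cells),
            "leaf": state.leaf,
            "structural": state.structural,
            "leaf_strategy": state.leaf_strategy,
        }
    )
    return cohorts, stocks


def frames_to_state(
    cohorts: pd.DataFrame, stocks: pd.DataFrame, month: int = 0
) -> ModelState:
    stocks = stocks.sort_values("cell")
    return ModelState(
        cohorts=CohortTable.from_dataframe(cohorts),
        leaf=stocks["leaf"].to_numpy(dtype=float),
        structural=stocks["structural"].to_numpy(dtype=float),
        leaf_strategy=stocks["leaf_strategy"].to_numpy(dtype=np.int8),
        month=month,
    )
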