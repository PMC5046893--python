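"""Monthly-time-step ecosystem dynamics.

One simulated month applies, in fixed order:

1. autotroph growth (NPP input with logistic damping, climate mortality,
   deciduous leaf shedding in dry-season months);
2. eating — herbivory on leaf biomass and size-structured predation with a
   log-normal prey-preference kernel, both per cell, with proportional
   rationing so no pool can go negative;
3. metabolism — allometric mass loss, temperature-scaled for ectotherms;
4. growth and reproduction — assimilated surplus builds body mass to
   maturity, then a reproductive pool that spawns offspring cohorts;
5. mortality — background, senescence and starvation hazards acting on
   abundance, plus an extinction cutoff;
6. dispersal — natal and hunger-triggered movement with mass-dependent
   radii on the closed grid;
7. cohort merging against a per-cell cap.

Every kilogram entering or leaving the system is itemized in a per-step
mass ledger; the step is deterministic given (state, environment, params,
rng state).

The process functional forms here are deliberately simple allometric
stand-ins for a full general ecosystem model: the traits that drive each
process (body mass, thermoregulation, trophic group, reproductive
strategy) and the trophic structure are preserved, while every constant is
exposed in :class:`ProcessParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from fragsim.domain import (
    AutotrophStock,
    CohortTable,
    LeafStrategy,
    ModelState,
    TrophicGroup,
)
from fragsim.environment import EnvironmentGrid

__all__ = [
    "ProcessParams",
    "step_month",
    "autotroph_growth",
    "eat",
    "metabolise",
    "grow_and_reproduce",
    "apply_mortality",
    "disperse",
    "merge_cohorts",
    "new_ledger",
    "LEDGER_KEYS",
]


@dataclass(frozen=True)
class ProcessParams:
    """All tunable process constants, with units.

    Metabolism
    ----------
    metabolic_coeff_endotherm, metabolic_coeff_ectotherm : float
        Monthly mass loss per kg^exponent of body mass, kg·kg^(−b)·month⁻¹.
        The endotherm coefficient must exceed the ectotherm baseline.
    metabolic_exponent : float
        Allometric exponent b of metabolic loss (default 3/4).
    q10, reference_temperature : float
        Q10 factor and reference temperature (°C) scaling ectotherm
        metabolism; endotherms are temperature-independent.

    Feeding
    -------
    assimilation_herbivory, assimilation_predation : float
        Fraction of eaten biomass credited to the consumer, in (0, 1].
    herbivory_attack : float
        Maximum per-individual leaf intake, kg·kg^(−b)·month⁻¹.
    herbivory_half_saturation : float
        Leaf biomass density at half-maximal intake, kg km⁻².
    predation_attack, predation_half_saturation : float
        Same pair for predation; half-saturation applies to the
        kernel-weighted prey biomass density, kg km⁻².
    optimal_prey_ratio : float
        φ — optimal prey:predator body-mass ratio of the log-normal
        preference kernel.
    kernel_sigma : float
        Kernel width on the natural-log mass-ratio scale.
    omnivore_herbivory_weight : float
        Fraction of an omnivore's attack budget spent on herbivory; the
        rest goes to predation.
    omnivore_efficiency : float
        Jack-of-all-trades penalty: omnivore attack rates in both
        channels are scaled by this factor, keeping the generalist
        strategy viable but inferior to specialists on either channel.
    ectotherm_activity_fraction : float
        Fraction of the month an ectotherm can forage (thermal activity
        window); scales ectotherm attack rates. The default makes
        resource-exploitation efficiency (intake-to-cost ratio at a given
        resource density) comparable across thermoregulation classes, so
        neither class structurally excludes the other.

    Mortality
    ---------
    mortality_background : float
        Baseline hazard, month⁻¹.
    mortality_senescence, senescence_timescale : float
        Senescence hazard ramps linearly as rate × age/timescale (months).
    mortality_starvation : float
        Additional hazard while the starvation flag is set, month⁻¹.
    starvation_mass_fraction : float
        A cohort is starving when body mass falls below this fraction of
        its maturity mass.
    mass_floor_fraction : float
        Metabolic losses cannot push body mass below this fraction of
        birth mass (the remainder is an unrealized deficit).
    extinction_abundance : float
        Cohorts whose abundance falls below this many individuals go
        extinct (removed, biomass ledgered as mortality).

    Reproduction
    ------------
    reproductive_allocation : float
        Fraction of post-maintenance surplus routed to the reproductive
        pool once body mass has reached maturity.

    Dispersal
    ---------
    dispersal_d0, dispersal_exponent : float
        Movement radius d = d0 · m^exponent, km per month.
    natal_dispersal_prob : float
        Probability a newly spawned cohort disperses.
    hunger_threshold : float
        Responsive dispersal triggers when realized intake/requirement
        falls below this ratio.

    Autotrophs
    ----------
    leaf_allocation : float
        Fraction of new growth allocated to the edible leaf pool.
    climate_mortality : float
        Monthly hazard on both plant pools, month⁻¹.
    carrying_capacity_density : float
        Logistic ceiling on total plant biomass, kg km⁻².
    regeneration_half_saturation : float
        Plant biomass density (kg km⁻²) at which regrowth reaches half
        its NPP-driven rate: regrowth is propagule-limited at low
        standing biomass, so a cell stripped bare cannot regreen within
        a month and a cell at exactly zero stays bare.
    deciduous_shed_fraction : float
        Leaf fraction shed per dry-season month by deciduous stocks.

    Bookkeeping
    -----------
    cohort_cap : int
        Maximum cohorts per cell before merging.
    """

    metabolic_coeff_endotherm: float = 1.5
    metabolic_coeff_ectotherm: float = 0.15
    metabolic_exponent: float = 0.75
    q10: float = 2.0
    reference_temperature: float = 25.0

    assimilation_herbivory: float = 0.5
    assimilation_predation: float = 0.64
    herbivory_attack: float = 10.0
    herbivory_half_saturation: float = 4.0e5
    predation_attack: float = 5.0
    predation_half_saturation: float = 2.0e3
    optimal_prey_ratio: float = 0.05
    kernel_sigma: float = 2.0
    omnivore_herbivory_weight: float = 0.5
    omnivore_efficiency: float = 0.6
    ectotherm_activity_fraction: float = 0.1

    mortality_background: float = 0.01
    mortality_senescence: float = 0.05
    senescence_timescale: float = 240.0
    mortality_starvation: float = 0.1
    starvation_mass_fraction: float = 0.1
    mass_floor_fraction: float = 0.5
    extinction_abundance: float = 0.5

    reproductive_allocation: float = 0.6

    dispersal_d0: float = 5.0
    dispersal_exponent: float = 0.25
    natal_dispersal_prob: float = 1.0
    hunger_threshold: float = 0.5

    leaf_allocation: float = 0.98
    climate_mortality: float = 0.1
    carrying_capacity_density: float = 1.0e6
    regeneration_half_saturation: float = 5.0e3
    deciduous_shed_fraction: float = 0.1

    cohort_cap: int = 64

    def __post_init__(self) -> None:
        for name in (
            "assimilation_herbivory",
            "assimilation_predation",
            "natal_dispersal_prob",
            "leaf_allocation",
            "omnivore_herbivory_weight",
            "omnivore_efficiency",
            "ectotherm_activity_fraction",
            "deciduous_shed_fraction",
            "mass_floor_fraction",
            "starvation_mass_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.metabolic_coeff_endotherm <= self.metabolic_coeff_ectotherm:
            raise ValueError("endotherm metabolic coefficient must exceed ectotherm")
        if self.cohort_cap < 1:
            raise ValueError("cohort_cap must be at least 1")


LEDGER_KEYS = (
    "npp_input",
    "autotroph_climate_loss",
    "autotroph_shed_loss",
    "herbivory_leaf_debit",
    "herbivory_assimilated",
    "herbivory_waste",
    "predation_prey_debit",
    "predation_assimilated",
    "predation_waste",
    "intake_lapsed",
    "metabolic_loss",
    "mortality_loss",
    "merge_cull_loss",
    "removal",
)


def new_ledger() -> dict[str, float]:
    """Fresh all-zero per-step mass ledger (all entries kg)."""
    return {k: 0.0 for k in LEDGER_KEYS}


def _check_finite(arrays: dict[str, np.ndarray], process: str) -> None:
    for name, arr in arrays.items():
        if not np.all(np.isfinite(arr)):
            bad = np.flatnonzero(~np.isfinite(np.atleast_1d(arr)))
            raise FloatingPointError(
                f"non-finite {name} after process {process!r} at indices {bad[:5].tolist()}"
            )


# ----------------------------------------------------------------------
# 1. autotroph growth
# ----------------------------------------------------------------------

def _autotroph_growth_vec(
    leaf: np.ndarray,
    structural: np.ndarray,
    strategy: np.ndarray,
    npp: np.ndarray,
    dry_season: bool,
    areas: np.ndarray,
    params: ProcessParams,
    ledger: dict[str, float],
) -> None:
    capacity = params.carrying_capacity_density * areas
    total = leaf + structural
    damping = np.clip(1.0 - total / capacity, 0.0, 1.0)
    regen = total / (total + params.regeneration_half_saturation * areas)
    added = npp * areas * damping * regen
    leaf += params.leaf_allocation * added
    structural += (1.0 - params.leaf_allocation) * added
    ledger["npp_input"] += float(added.sum())

    survive = np.exp(-params.climate_mortality)
    loss = (leaf + structural) * (1.0 - survive)
    leaf *= survive
    structural *= survive
    ledger["autotroph_climate_loss"] += float(loss.sum())

    if dry_season and params.deciduous_shed_fraction > 0:
        deciduous = strategy == int(LeafStrategy.DECIDUOUS)
        shed = leaf[deciduous] * params.deciduous_shed_fraction
        leaf[deciduous] -= shed
        ledger["autotroph_shed_loss"] += float(shed.sum())


def autotroph_growth(
    stock: AutotrophStock,
    npp: float,
    area: float,
    params: ProcessParams,
    dry_season: bool = False,
) -> AutotrophStock:
    """Single-cell autotroph update (growth, climate mortality, shedding).

    Adds NPP × area for one month, split between leaf and structural pools
    by the allocation fraction and damped logistically toward the cell
    carrying capacity; then applies climate mortality and, in dry-season
    months, deciduous leaf shedding.
    """
    leaf = np.array([stock.leaf_biomass])
    structural = np.array([stock.structural_biomass])
    strategy = np.array([int(stock.leaf_strategy)], dtype=np.int8)
    _autotroph_growth_vec(
        leaf, structural, strategy, np.array([npp]), dry_season,
        np.array([area]), params, new_ledger(),
    )
    return AutotrophStock(float(leaf[0]), float(structural[0]), stock.leaf_strategy)


# ----------------------------------------------------------------------
# 2. eating
# ----------------------------------------------------------------------

def _eat_cell(
    c: CohortTable,
    idx: np.ndarray,
    leaf: np.ndarray,
    cell: int,
    area: float,
    params: ProcessParams,
    assimilated: np.ndarray,
    ledger: dict[str, float],
    temperature: float | None = None,
) -> None:
    """Herbivory and predation among the cohorts of one cell.

    Mutates leaf biomass and prey abundances; accumulates assimilated
    intake (kg per cohort) into ``assimilated``.
    """
    mass = c.mass[idx]
    abundance = c.abundance[idx]
    trophic = c.trophic[idx]
    alive = abundance > 0
    if not np.any(alive):
        return

    is_omni = trophic == int(TrophicGroup.OMNIVORE)
    w_herb = np.where(
        trophic == int(TrophicGroup.HERBIVORE),
        1.0,
        np.where(is_omni, params.omnivore_efficiency * params.omnivore_herbivory_weight, 0.0),
    )
    w_pred = np.where(
        trophic == int(TrophicGroup.CARNIVORE),
        1.0,
        np.where(
            is_omni,
            params.omnivore_efficiency * (1.0 - params.omnivore_herbivory_weight),
            0.0,
        ),
    )
    # ectotherm attack rates are limited by the thermal activity window
    # and scale with temperature exactly as their metabolism does
    if temperature is None:
        temperature = params.reference_temperature
    q = params.q10 ** ((temperature - params.reference_temperature) / 10.0)
    activity = np.where(
        c.thermo[idx] == 1, params.ectotherm_activity_fraction * q, 1.0
    )
    w_herb = w_herb * activity
    w_pred = w_pred * activity
    mb = mass**params.metabolic_exponent

    # herbivory: saturating intake on the shared leaf pool, rationed
    L = float(leaf[cell])
    if L > 0:
        sat = L / (L + params.herbivory_half_saturation * area)
        demand_i = w_herb * params.herbivory_attack * mb * sat  # kg per individual
        demand = demand_i * abundance
        total_demand = float(demand.sum())
        if total_demand > 0:
            ration = min(1.0, L / total_demand)
            take = demand * ration
            taken = float(take.sum())
            leaf[cell] = max(L - taken, 0.0)
            assimilated[idx] += params.assimilation_herbivory * take
            ledger["herbivory_leaf_debit"] += taken
            ledger["herbivory_assimilated"] += params.assimilation_herbivory * taken
            ledger["herbivory_waste"] += (1.0 - params.assimilation_herbivory) * taken

    # predation: log-normal size preference, demand distributed over prey
    pred = np.flatnonzero((w_pred > 0) & alive)
    if pred.size == 0:
        return
    prey_b_ind = mass + c.repro_pool[idx]  # killed individuals take their pool along
    prey_B = prey_b_ind * abundance
    candidates = np.flatnonzero(alive & (prey_B > 0))
    if candidates.size == 0:
        return

    log_ratio = np.log(
        mass[candidates][None, :]
        / (params.optimal_prey_ratio * mass[pred][:, None])
    )
    kernel = np.exp(-(log_ratio**2) / (2.0 * params.kernel_sigma**2))
    # no cannibalism within a cohort
    same = pred[:, None] == candidates[None, :]
    kernel[same] = 0.0

    weighted = kernel * prey_B[candidates][None, :]  # (n_pred, n_prey)
    P = weighted.sum(axis=1)
    sat = P / (P + params.predation_half_saturation * area)
    demand_ind = w_pred[pred] * params.predation_attack * mb[pred] * sat
    demand_tot = demand_ind * abundance[pred]  # kg per predator cohort
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(P[:, None] > 0, weighted / P[:, None], 0.0)
    demand_on_prey = (demand_tot[:, None] * share).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ration = np.where(
            demand_on_prey > prey_B[candidates],
            prey_B[candidates] / np.where(demand_on_prey > 0, demand_on_prey, 1.0),
            1.0,
        )
    kill = demand_tot[:, None] * share * ration[None, :]  # kg, (n_pred, n_prey)
    killed_per_prey = kill.sum(axis=0)
    eaten_per_pred = kill.sum(axis=1)
    total_kill = float(killed_per_prey.sum())
    if total_kill <= 0:
        return

    # debit prey abundance
    dN = killed_per_prey / prey_b_ind[candidates]
    gidx = idx[candidates]
    c.abundance[gidx] = np.maximum(c.abundance[gidx] - dN, 0.0)

    gpred = idx[pred]
    assimilated[gpred] += params.assimilation_predation * eaten_per_pred
    ledger["predation_prey_debit"] += total_kill
    ledger["predation_assimilated"] += params.assimilation_predation * total_kill
    ledger["predation_waste"] += (1.0 - params.assimilation_predation) * total_kill


def eat(
    cell_cohorts: CohortTable,
    stock: AutotrophStock,
    area: float,
    params: ProcessParams,
    temperature: float | None = None,
) -> tuple[CohortTable, AutotrophStock, np.ndarray, dict[str, float]]:
    """Feeding among the cohorts of a single cell.

    Herbivores (and omnivores, weighted) draw on the cell's leaf pool with
    a saturating per-individual intake; carnivores (and omnivores) kill
    prey cohorts with demand weighted by a log-normal preference kernel
    centred on φ × predator mass. When demand exceeds a pool it is
    rationed proportionally, so nothing goes negative.

    Returns the updated cohorts and stock, the assimilated intake per
    individual (kg; intake of cohorts eaten to extinction within the step
    is dropped), and the feeding ledger.
    """
    c = cell_cohorts.copy()
    leaf = np.array([stock.leaf_biomass])
    assimilated = np.zeros(len(c))
    ledger = new_ledger()
    _eat_cell(c, np.arange(len(c)), leaf, 0, area, params, assimilated, ledger,
              temperature=temperature)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_ind = np.where(c.abundance > 0, assimilated / c.abundance, 0.0)
    new_stock = AutotrophStock(float(leaf[0]), stock.structural_biomass, stock.leaf_strategy)
    return c, new_stock, per_ind, ledger


# ----------------------------------------------------------------------
# 3. metabolism
# ----------------------------------------------------------------------

def metabolic_requirement(
    cohorts: CohortTable, temperature: np.ndarray, params: ProcessParams
) -> np.ndarray:
    """Nominal monthly metabolic loss per individual, kg.

    Endotherms: k_endo · m^b; ectotherms: k_ecto · m^b · Q10^((T−T_ref)/10).
    """
    mb = cohorts.mass**params.metabolic_exponent
    q = params.q10 ** ((np.asarray(temperature) - params.reference_temperature) / 10.0)
    k = np.where(
        cohorts.thermo == 0,  # endotherm
        params.metabolic_coeff_endotherm,
        params.metabolic_coeff_ectotherm * q,
    )
    return k * mb


def metabolise(
    cohorts: CohortTable, temperature: np.ndarray, params: ProcessParams
) -> np.ndarray:
    """Debit metabolic costs from body mass, in place.

    Mass cannot fall below the floor (``mass_floor_fraction`` × birth
    mass); hitting the floor, or dropping below the starvation fraction of
    maturity mass, sets the starvation flag. Returns the realized loss per
    individual (kg), which may be below the nominal requirement when the
    floor binds.
    """
    lam = metabolic_requirement(cohorts, temperature, params)
    floor = params.mass_floor_fraction * cohorts.birth_mass
    new_mass = np.maximum(cohorts.mass - lam, floor)
    realized = cohorts.mass - new_mass
    clipped = realized < lam - 1e-300
    cohorts.mass = new_mass
    cohorts.starving = clipped | (
        new_mass < params.starvation_mass_fraction * cohorts.maturity_mass
    )
    return realized


# ----------------------------------------------------------------------
# 4. growth and reproduction
# ----------------------------------------------------------------------

def grow_and_reproduce(
    cohorts: CohortTable,
    assimilated: np.ndarray,
    params: ProcessParams,
    ledger: dict[str, float] | None = None,
) -> CohortTable:
    """Allocate assimilated intake and spawn offspring cohorts, in place.

    Intake first rebuilds body mass up to maturity; surplus beyond
    maturity is split — ``reproductive_allocation`` to the per-individual
    reproductive pool, the rest to continued (self-limiting) body growth.
    When the pool reaches birth mass, an offspring cohort is spawned with
    abundance = parent abundance × pool/birth mass, inheriting all
    categorical traits and mass traits; semelparous parents die on
    spawning. Returns the offspring table (possibly empty).
    """
    a = np.asarray(assimilated, dtype=float)
    if np.any(a < 0):
        raise ValueError("assimilated intake must be non-negative")
    base = np.clip(cohorts.maturity_mass - cohorts.mass, 0.0, None)
    to_body = np.minimum(a, base)
    surplus = a - to_body
    rho = params.reproductive_allocation
    cohorts.mass = cohorts.mass + to_body + (1.0 - rho) * surplus
    cohorts.repro_pool = cohorts.repro_pool + rho * surplus

    spawn = np.flatnonzero(
        (cohorts.repro_pool >= cohorts.birth_mass) & (cohorts.abundance > 0)
    )
    if spawn.size == 0:
        return CohortTable.empty()

    pool = cohorts.repro_pool[spawn]
    birth = cohorts.birth_mass[spawn]
    n_off = cohorts.abundance[spawn] * pool / birth
    offspring = CohortTable(
        cell=cohorts.cell[spawn],
        trophic=cohorts.trophic[spawn],
        thermo=cohorts.thermo[spawn],
        repro=cohorts.repro[spawn],
        mass=birth.copy(),
        birth_mass=birth.copy(),
        maturity_mass=cohorts.maturity_mass[spawn],
        abundance=n_off,
        repro_pool=np.zeros(spawn.size),
        age=np.zeros(spawn.size),
        newborn=np.ones(spawn.size, dtype=bool),
        hunger=np.ones(spawn.size),
    )
    cohorts.repro_pool[spawn] = 0.0

    semel = spawn[cohorts.repro[spawn] == 0]
    if semel.size:
        died = float((cohorts.mass[semel] * cohorts.abundance[semel]).sum())
        cohorts.abundance[semel] = 0.0
        if ledger is not None:
            ledger["mortality_loss"] += died
    return offspring


# ----------------------------------------------------------------------
# 5. mortality
# ----------------------------------------------------------------------

def apply_mortality(
    cohorts: CohortTable,
    params: ProcessParams,
    rng: np.random.Generator | None = None,
    ledger: dict[str, float] | None = None,
) -> float:
    """Exponential survival under additive hazards, in place.

    Abundance is multiplied by exp(−(μ_bg + μ_sen(age) + μ_starv·starving))
    for one month; cohorts falling below the extinction abundance are
    zeroed. Returns the biomass lost (kg). Deterministic — ``rng`` is
    accepted for interface symmetry but unused.
    """
    mu = (
        params.mortality_background
        + params.mortality_senescence * cohorts.age / params.senescence_timescale
        + params.mortality_starvation * cohorts.starving
    )
    f = np.exp(-mu)
    per_ind = cohorts.mass + cohorts.repro_pool
    before = per_ind * cohorts.abundance
    cohorts.abundance = cohorts.abundance * f
    extinct = cohorts.abundance < params.extinction_abundance
    cohorts.abundance[extinct] = 0.0
    loss = float((before - per_ind * cohorts.abundance).sum())
    if ledger is not None:
        ledger["mortality_loss"] += loss
    return loss


# ----------------------------------------------------------------------
# 6. dispersal
# ----------------------------------------------------------------------

def disperse(
    state: ModelState,
    landscape,
    params: ProcessParams,
    rng: np.random.Generator,
) -> ModelState:
    """Natal and responsive (hunger-triggered) dispersal, in place.

    Radius d = d0 · m^exponent km; the destination is drawn uniformly
    among grid cells whose centre lies within d of the current cell's
    centre (the current cell included, so d below one cell width means
    the cohort stays). The grid boundary is closed: only in-grid cells
    are candidates. Cohorts relocate wholesale.
    """
    c = state.cohorts
    n = len(c)
    if n == 0:
        return state
    natal = c.newborn & (rng.random(n) < params.natal_dispersal_prob)
    responsive = (~c.newborn) & (c.hunger < params.hunger_threshold)
    movers = np.flatnonzero((natal | responsive) & (c.abundance > 0))
    if movers.size == 0:
        c.newborn[:] = False
        return state
    dist = landscape.pairwise_distances_km()
    # per-cell neighbours presorted by distance: a radius maps to a prefix
    order = np.argsort(dist, axis=1, kind="stable")
    dist_sorted = np.take_along_axis(dist, order, axis=1)
    radii = params.dispersal_d0 * c.mass[movers] ** params.dispersal_exponent
    cells = c.cell[movers]
    n_candidates = np.array(
        [np.searchsorted(dist_sorted[cell], r, side="right") for cell, r in zip(cells, radii)]
    )
    picks = rng.integers(n_candidates)  # uniform in [0, k) per mover
    c.cell[movers] = order[cells, picks]
    c.newborn[:] = False
    return state


# ----------------------------------------------------------------------
# 7. merging
# ----------------------------------------------------------------------

def _merge_pair(c: CohortTable, a: int, b: int) -> None:
    """Merge cohort b into a, conserving abundance and total biomass."""
    na, nb = c.abundance[a], c.abundance[b]
    n = na + nb
    if n > 0:
        c.mass[a] = (c.mass[a] * na + c.mass[b] * nb) / n
        c.repro_pool[a] = (c.repro_pool[a] * na + c.repro_pool[b] * nb) / n
        c.birth_mass[a] = np.exp(
            (np.log(c.birth_mass[a]) * na + np.log(c.birth_mass[b]) * nb) / n
        )
        c.maturity_mass[a] = np.exp(
            (np.log(c.maturity_mass[a]) * na + np.log(c.maturity_mass[b]) * nb) / n
        )
        c.age[a] = (c.age[a] * na + c.age[b] * nb) / n
        c.hunger[a] = (c.hunger[a] * na + c.hunger[b] * nb) / n
    c.abundance[a] = n
    c.newborn[a] = bool(c.newborn[a] or c.newborn[b])
    c.starving[a] = bool(c.starving[a] and c.starving[b])
    c.abundance[b] = 0.0


def _merge_cell(
    c: CohortTable, idx: np.ndarray, cap: int, ledger: dict[str, float] | None
) -> None:
    """Merge the cohorts of one cell down to ``cap``, in place.

    Repeatedly merges the identical-trait pair with the smallest absolute
    log body-mass difference. Per-trait-class member lists are kept sorted
    by mass incrementally: the merged mass is the abundance-weighted mean
    of an adjacent pair, so order is preserved without re-sorting.
    """
    count = len(idx)
    if count <= cap:
        return
    key = (c.trophic[idx].astype(np.int64) * 4
           + c.thermo[idx].astype(np.int64) * 2
           + c.repro[idx].astype(np.int64))
    logm = dict(zip((int(i) for i in idx), np.log(c.mass[idx]).tolist()))
    classes: dict[int, list[int]] = {}
    for i, k in zip(idx, key):
        classes.setdefault(int(k), []).append(int(i))
    for members in classes.values():
        members.sort(key=logm.__getitem__)

    def class_best(members: list[int]):
        best = None
        prev = members[0]
        lp = logm[prev]
        for b in members[1:]:
            lb = logm[b]
            d = lb - lp  # sorted ascending, so non-negative
            if best is None or d < best[0]:
                best = (d, prev, b)
            prev, lp = b, lb
        return best

    bests = {k: class_best(m) for k, m in classes.items() if len(m) > 1}
    while count > cap:
        if bests:
            k, (_, a, b) = min(bests.items(), key=lambda kv: kv[1][0])
            _merge_pair(c, a, b)
            logm[a] = float(np.log(c.mass[a]))
            members = classes[k]
            members.remove(b)
            if len(members) > 1:
                bests[k] = class_best(members)
            else:
                del bests[k]
        else:
            # no identical-trait pair anywhere: cull lowest-biomass cohort
            flat = [i for m in classes.values() for i in m]
            worst = min(flat, key=lambda i: (c.mass[i] + c.repro_pool[i]) * c.abundance[i])
            if ledger is not None:
                ledger["merge_cull_loss"] += float(
                    (c.mass[worst] + c.repro_pool[worst]) * c.abundance[worst]
                )
            c.abundance[worst] = 0.0
            for m in classes.values():
                if worst in m:
                    m.remove(worst)
                    break
        count -= 1


def merge_cohorts(
    cell_cohorts: CohortTable, cap: int, ledger: dict[str, float] | None = None
) -> CohortTable:
    """Reduce one cell's cohort count to ``cap`` by pairwise merging.

    Repeatedly merges the identical-trait pair with the smallest log body
    mass difference, conserving total abundance and total biomass (the
    merged mass is the abundance-weighted mean). If no identical-trait
    pair exists, the lowest-total-biomass cohort is removed and ledgered.
    """
    if cap < 1:
        raise ValueError("cap must be at least 1")
    c = cell_cohorts.copy()
    _merge_cell(c, np.arange(len(c)), cap, ledger)
    return c.select(c.abundance > 0)


# ----------------------------------------------------------------------
# the full step
# ----------------------------------------------------------------------

def _cells_of(c: CohortTable, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Stable sort of cohort indices by cell, with cell boundaries."""
    order = np.argsort(c.cell, kind="stable")
    bounds = np.searchsorted(c.cell[order], np.arange(n_cells + 1))
    return order, bounds


def step_month(
    state: ModelState,
    env: EnvironmentGrid,
    params: ProcessParams,
    rng: np.random.Generator,
) -> tuple[ModelState, dict[str, float]]:
    """Advance the ecosystem by one month.

    Applies, in fixed order: autotroph growth, eating, metabolism, growth
    and reproduction, mortality, dispersal, and cohort merging. Returns
    the new state (the input is not mutated) and the per-process mass
    ledger for the step. Any non-finite biomass raises
    :class:`FloatingPointError` naming the offending process.
    """
    landscape = env.landscape
    areas = landscape.cell_areas
    state = state.copy()
    ledger = new_ledger()
    temp, npp, dry = env.month(state.month)

    _autotroph_growth_vec(
        state.leaf, state.structural, state.leaf_strategy, npp, dry, areas, params, ledger
    )
    _check_finite({"leaf": state.leaf, "structural": state.structural}, "autotroph_growth")

    c = state.cohorts
    n = len(c)
    assimilated = np.zeros(n)
    if n:
        order, bounds = _cells_of(c, landscape.n_cells)
        for cell in range(landscape.n_cells):
            idx = order[bounds[cell] : bounds[cell + 1]]
            if idx.size == 0:
                continue
            _eat_cell(c, idx, state.leaf, cell, areas[cell], params, assimilated,
                      ledger, temperature=float(temp[cell]))
        _check_finite(
            {"leaf": state.leaf, "abundance": c.abundance, "assimilated": assimilated}, "eat"
        )
        # intake of cohorts eaten to extinction during feeding never gets
        # credited; itemize it so the mass ledger closes exactly
        alive = c.abundance > 0
        ledger["intake_lapsed"] += float(assimilated[~alive].sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            assimilated = np.where(alive, assimilated / np.where(alive, c.abundance, 1.0), 0.0)

        lam_nominal = metabolic_requirement(c, temp[c.cell], params)
        realized = metabolise(c, temp[c.cell], params)
        ledger["metabolic_loss"] += float((realized * c.abundance).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            c.hunger = np.where(lam_nominal > 0, assimilated / lam_nominal, 1.0)
        _check_finite({"mass": c.mass}, "metabolise")

        offspring = grow_and_reproduce(c, assimilated, params, ledger)
        if len(offspring):
            state.cohorts = c = c.concat(offspring)
        _check_finite({"mass": c.mass, "repro_pool": c.repro_pool}, "grow_and_reproduce")

        apply_mortality(c, params, rng, ledger)
        alive = c.abundance > 0
        if not alive.all():
            state.cohorts = c = c.select(alive)
        _check_finite({"abundance": c.abundance}, "apply_mortality")

        disperse(state, landscape, params, rng)

        if len(c):
            order, bounds = _cells_of(c, landscape.n_cells)
            changed = False
            for cell in range(landscape.n_cells):
                idx = order[bounds[cell] : bounds[cell + 1]]
                if idx.size > params.cohort_cap:
                    _merge_cell(c, idx, params.cohort_cap, ledger)
                    changed = True
            if changed:
                state.cohorts = c = c.select(c.abundance > 0)
        c.age = c.age + 1.0

    state.month += 1
    return state, ledger
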