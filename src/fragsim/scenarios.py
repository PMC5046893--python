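"""Factorial land-use experiment: treatments, impacts, and orchestration.

A treatment combines a spatial *configuration* of impacted cells (random —
fragmenting — or continuous whole rows), an *extent* (fraction of cells
impacted) and an *intensity* (fraction of autotroph biomass removed from
each impacted cell at every monthly step). The full default factorial is
4 intensities × (3 extents × 2 configurations + the deduplicated
full-extent case) + 1 pristine control = 29 treatments; at 10 replicates
and two landscape scales that is 580 simulations.

Every run shares its burn-in with the pristine control of the same
replicate, so pristine references are paired: the impacted and pristine
trajectories are identical up to the moment impact begins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fragsim.domain import (
    Configuration,
    EcosystemSummary,
    Landscape,
    ModelState,
    Treatment,
    TrophicGroup,
    all_functional_groups,
)
from fragsim.engine import ProcessParams, step_month
from fragsim.environment import (
    SeasonalityParams,
    generate_environment,
    make_landscape,
    seed_cohorts,
)

__all__ = [
    "ScaleSpec",
    "ExperimentPlan",
    "ExperimentResult",
    "RemovalLedger",
    "enumerate_treatments",
    "select_impacted_cells",
    "apply_impact",
    "burn_in",
    "run_experiment",
    "run_replicate",
    "desk_plan",
    "paper_plan",
]


@dataclass(frozen=True)
class ScaleSpec:
    """One landscape scale: grid dimensions, cell size and centre."""

    name: str
    n_rows: int = 10
    n_cols: int = 10
    cell_size_deg: float = 0.1
    centre_lat: float = 0.05
    centre_lon: float = 38.0

    def make(self) -> Landscape:
        return make_landscape(
            self.n_rows, self.n_cols, self.cell_size_deg, self.centre_lat, self.centre_lon
        )


LARGE_SCALE = ScaleSpec("large", 10, 10, 0.1)
SMALL_SCALE = ScaleSpec("small", 10, 10, 0.01)


@dataclass(frozen=True)
class ExperimentPlan:
    """Full specification of a factorial habitat-loss experiment.

    Durations are months; the summary window is the final
    ``record_window_months`` of the impact phase. ``removal_pools``
    selects whether impact debits total plant biomass proportionally from
    both pools ("total") or the leaf pool only ("leaf").
    """

    extents: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    intensities: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    configurations: tuple[Configuration, ...] = (
        Configuration.RANDOM,
        Configuration.CONTINUOUS,
    )
    replicates: int = 10
    scales: tuple[ScaleSpec, ...] = (LARGE_SCALE, SMALL_SCALE)
    burn_in_months: int = 1200
    impact_months: int = 1200
    record_window_months: int = 120
    base_seed: int = 0
    seasonality: SeasonalityParams = field(default_factory=SeasonalityParams)
    process: ProcessParams = field(default_factory=ProcessParams)
    n_cohorts_per_cell: int = 3
    mass_range: tuple[float, float] = (4e-7, 5000.0)
    removal_pools: str = "total"
    record_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.record_window_months > self.impact_months:
            raise ValueError("record window cannot exceed the impact phase")
        for f in itertools.chain(self.extents, self.intensities):
            if not (0.0 < f <= 1.0):
                raise ValueError(f"extents/intensities must lie in (0, 1], got {f}")
        if self.removal_pools not in ("total", "leaf"):
            raise ValueError("removal_pools must be 'total' or 'leaf'")

    @property
    def treatments(self) -> list[Treatment]:
        return enumerate_treatments(self.extents, self.intensities, self.configurations)

    @property
    def n_runs(self) -> int:
        return len(self.scales) * len(self.treatments) * self.replicates

    def with_seed(self, base_seed: int) -> "ExperimentPlan":
        return replace(self, base_seed=int(base_seed))


def desk_plan(base_seed: int = 0, **overrides) -> ExperimentPlan:
    """Desk-scale preset: 5×5 grid at the large cell size, 240 + 240
    months, 36-month summary window, 3 replicates, one scale.

    The full-scale design (10×10, 100 + 100 years, 10 replicates, two
    scales) takes hours; this preset preserves the factorial structure and
    runs in minutes."""
    defaults = dict(
        replicates=3,
        scales=(ScaleSpec("large", 5, 5, 0.1),),
        burn_in_months=240,
        impact_months=240,
        record_window_months=36,
        base_seed=int(base_seed),
    )
    defaults.update(overrides)
    return ExperimentPlan(**defaults)


def paper_plan(base_seed: int = 0, **overrides) -> ExperimentPlan:
    """The full factorial design: 10 replicates × 29 treatments × 2 scales
    with 100-year burn-in and impact phases (580 runs)."""
    defaults = dict(base_seed=int(base_seed))
    defaults.update(overrides)
    return ExperimentPlan(**defaults)


def enumerate_treatments(
    extents,
    intensities,
    configurations=(Configuration.RANDOM, Configuration.CONTINUOUS),
) -> list[Treatment]:
    """The full factorial of (configuration × extent × intensity).

    At extent 1.0 the two configurations give the identical all-cells
    mask, so they are deduplicated into a single treatment; exactly one
    pristine control is appended first. Ordering is canonical: pristine,
    then sorted by (configuration, extent, intensity).
    """
    extents = sorted(set(float(e) for e in extents))
    intensities = sorted(set(float(i) for i in intensities))
    configurations = [Configuration(c) for c in configurations]
    if not extents or not intensities or not configurations:
        raise ValueError("extents, intensities and configurations must be non-empty")
    for f in itertools.chain(extents, intensities):
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fractions must lie in (0, 1], got {f}")

    seen_full = set()
    treatments = [Treatment(Configuration.PRISTINE, 0.0, 0.0)]
    for cfg in sorted(configurations, key=lambda c: c.value):
        for e in extents:
            for i in intensities:
                if e == 1.0:
                    if i in seen_full:
                        continue
                    seen_full.add(i)
                    treatments.append(Treatment(Configuration.CONTINUOUS, 1.0, i))
                else:
                    treatments.append(Treatment(cfg, e, i))
    return treatments


def select_impacted_cells(
    landscape: Landscape,
    extent: float,
    configuration: Configuration,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean impacted-cell mask of exact cardinality round(extent × n).

    Random configuration: a uniform sample of cells without replacement.
    Continuous configuration: cells filled row-major from row 0 downward,
    keeping impacted and pristine areas unbroken. Non-integral quotas are
    rounded half up.
    """
    if not (0.0 <= extent <= 1.0):
        raise ValueError("extent must lie in [0, 1]")
    n = landscape.n_cells
    quota = int(np.floor(extent * n + 0.5))
    mask = np.zeros(n, dtype=bool)
    if quota == 0:
        return mask
    configuration = Configuration(configuration)
    if configuration == Configuration.RANDOM:
        mask[rng.choice(n, size=quota, replace=False)] = True
    elif configuration == Configuration.CONTINUOUS:
        mask[:quota] = True
    else:
        raise ValueError("pristine treatments have no impacted cells")
    return mask


class RemovalLedger:
    """Accumulates removed autotroph biomass per month (kg)."""

    def __init__(self) -> None:
        self.monthly: list[float] = []

    def record(self, removed: float) -> None:
        self.monthly.append(float(removed))

    @property
    def total(self) -> float:
        return float(np.sum(self.monthly)) if self.monthly else 0.0


def apply_impact(
    state: ModelState,
    mask: np.ndarray,
    intensity: float,
    pools: str = "total",
) -> tuple[ModelState, np.ndarray]:
    """Remove ``intensity`` × autotroph biomass from every masked cell.

    With ``pools="total"`` the debit falls proportionally on the leaf and
    structural pools; with ``pools="leaf"`` it falls on the leaf pool
    only. Heterotrophs are never touched directly. The state is modified
    in place; the per-cell removed biomass (kg) is returned alongside it.
    """
    if not (0.0 <= intensity <= 1.0):
        raise ValueError("intensity must lie in [0, 1]")
    mask = np.asarray(mask, dtype=bool)
    removed = np.zeros(state.n_cells)
    if intensity == 0.0 or not mask.any():
        return state, removed
    if pools == "total":
        removed[mask] = intensity * (state.leaf[mask] + state.structural[mask])
        state.leaf[mask] *= 1.0 - intensity
        state.structural[mask] *= 1.0 - intensity
    elif pools == "leaf":
        removed[mask] = intensity * state.leaf[mask]
        state.leaf[mask] *= 1.0 - intensity
    else:
        raise ValueError("pools must be 'total' or 'leaf'")
    return state, removed


@dataclass
class ExperimentResult:
    """Tidy outputs of an experiment.

    ``summaries`` has one row per run with window-mean biomass totals by
    trophic group; ``occupancy`` holds per-trait-class patch occupancy for
    the 100%-intensity runs; ``removal`` the total biomass removed per
    run; ``trajectories`` (optional) monthly landscape totals.
    """

    summaries: pd.DataFrame
    occupancy: pd.DataFrame
    removal: pd.DataFrame
    occupancy_trophic: pd.DataFrame | None = None
    occupancy_mass: pd.DataFrame | None = None
    trajectories: pd.DataFrame | None = None

    def summary_objects(self) -> list[EcosystemSummary]:
        out = []
        for _, r in self.summaries.iterrows():
            out.append(
                EcosystemSummary(
                    carnivore_biomass=r["carnivore"],
                    omnivore_biomass=r["omnivore"],
                    herbivore_biomass=r["herbivore"],
                    autotroph_biomass=r["autotroph"],
                    configuration=r["configuration"],
                    extent=r["extent"],
                    intensity=r["intensity"],
                    scale=r["scale"],
                    replicate=int(r["replicate"]),
                )
            )
        return out


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def _mass_bin_edges(mass_range: tuple[float, float]) -> np.ndarray:
    lo, hi = mass_range
    k0 = int(np.floor(np.log10(lo)))
    k1 = int(np.ceil(np.log10(hi)))
    return 10.0 ** np.arange(k0, k1 + 1)


def burn_in(plan: ExperimentPlan, scale_index: int, replicate: int):
    """Seed and spin up one replicate's unimpacted ecosystem.

    Every treatment of this (scale, replicate) pair starts from the state
    returned here, so the pristine control is a paired reference. Returns
    ``(state, environment, landscape)``.
    """
    scale = plan.scales[scale_index]
    landscape = scale.make()
    env_seed = int(
        np.random.SeedSequence([plan.base_seed, scale_index]).generate_state(1)[0] % (2**31)
    )
    env = generate_environment(landscape, plan.seasonality, seed=env_seed)

    burn_seq = np.random.SeedSequence([plan.base_seed, scale_index, replicate])
    seed_int = int(burn_seq.generate_state(1)[0] % (2**31))
    state = seed_cohorts(
        landscape,
        all_functional_groups(),
        n_cohorts_per_cell=plan.n_cohorts_per_cell,
        mass_range=plan.mass_range,
        seed=seed_int,
    )
    burn_rng = np.random.default_rng(burn_seq)
    for _ in range(plan.burn_in_months):
        state, _ = step_month(state, env, plan.process, burn_rng)
    return state, env, landscape


def run_replicate(
    plan: ExperimentPlan, scale_index: int, replicate: int
) -> ExperimentResult:
    """Run one replicate at one scale: a shared burn-in, then every
    treatment's impact phase from the identical post-burn-in state."""
    from fragsim.metrics import occupancy as compute_occupancy  # local: avoid cycle

    scale = plan.scales[scale_index]
    state_burned, env, landscape = burn_in(plan, scale_index, replicate)

    treatments = plan.treatments
    bin_edges = _mass_bin_edges(plan.mass_range)
    summary_rows, occupancy_rows, removal_rows, traj_rows = [], [], [], []
    occ_trophic_rows, occ_mass_rows = [], []

    for t_idx, tr in enumerate(treatments):
        run_seq = np.random.SeedSequence(
            [plan.base_seed, scale_index, replicate, 1 + t_idx]
        )
        rng = np.random.default_rng(run_seq)
        seed_id = int(run_seq.generate_state(1)[0] % (2**31))
        if tr.configuration == Configuration.PRISTINE:
            mask = np.zeros(landscape.n_cells, dtype=bool)
        else:
            mask = select_impacted_cells(landscape, tr.extent, tr.configuration, rng)

        st = state_burned.copy()
        ledger = RemovalLedger()
        window_start = plan.impact_months - plan.record_window_months
        acc = {g.label: 0.0 for g in TrophicGroup}
        acc["autotroph"] = 0.0
        n_rec = 0
        for m in range(plan.impact_months):
            if mask.any() and tr.intensity > 0:
                st, removed = apply_impact(st, mask, tr.intensity, plan.removal_pools)
                ledger.record(removed.sum())
            st, _ = step_month(st, env, plan.process, rng)
            if m >= window_start:
                totals = st.trophic_totals()
                for k, v in totals.items():
                    acc[k] += v
                n_rec += 1
            if plan.record_trajectories:
                totals = st.trophic_totals()
                traj_rows.append(
                    dict(
                        scale=scale.name,
                        replicate=replicate,
                        treatment=tr.label,
                        month=m,
                        **totals,
                    )
                )

        summary_rows.append(
            dict(
                scale=scale.name,
                configuration=tr.configuration.value,
                extent=tr.extent,
                intensity=tr.intensity,
                replicate=replicate,
                seed=seed_id,
                carnivore=acc["carnivore"] / n_rec,
                omnivore=acc["omnivore"] / n_rec,
                herbivore=acc["herbivore"] / n_rec,
                autotroph=acc["autotroph"] / n_rec,
            )
        )
        removal_rows.append(
            dict(
                scale=scale.name,
                configuration=tr.configuration.value,
                extent=tr.extent,
                intensity=tr.intensity,
                replicate=replicate,
                removed_total=ledger.total,
            )
        )
        if tr.intensity == 1.0 and 0.0 < tr.extent < 1.0:
            meta = dict(
                scale=scale.name,
                configuration=tr.configuration.value,
                extent=tr.extent,
                intensity=tr.intensity,
                replicate=replicate,
            )
            occ = compute_occupancy(st, ~mask, bin_edges=bin_edges)
            for _, row in occ.iterrows():
                occupancy_rows.append(
                    dict(
                        **meta,
                        trophic_group=row["trophic_group"],
                        mass_bin_low=row["mass_bin_low"],
                        mass_bin_high=row["mass_bin_high"],
                        occupancy=row["occupancy"],
                    )
                )
            occ_t = compute_occupancy(st, ~mask, by="trophic")
            for _, row in occ_t.iterrows():
                occ_trophic_rows.append(
                    dict(**meta, trophic_group=row["trophic_group"],
                         occupancy=row["occupancy"])
                )
            occ_m = compute_occupancy(st, ~mask, bin_edges=bin_edges, by="mass")
            for _, row in occ_m.iterrows():
                occ_mass_rows.append(
                    dict(**meta, mass_bin_low=row["mass_bin_low"],
                         mass_bin_high=row["mass_bin_high"],
                         occupancy=row["occupancy"])
                )

    return ExperimentResult(
        summaries=pd.DataFrame(summary_rows),
        occupancy=pd.DataFrame(occupancy_rows),
        removal=pd.DataFrame(removal_rows),
        occupancy_trophic=pd.DataFrame(occ_trophic_rows),
        occupancy_mass=pd.DataFrame(occ_mass_rows),
        trajectories=pd.DataFrame(traj_rows) if plan.record_trajectories else None,
    )


def run_experiment(plan: ExperimentPlan, progress: bool = False) -> ExperimentResult:
    """Execute the full plan: every scale × replicate × treatment.

    Within a replicate all treatments share the burn-in state, so the
    pristine run is a paired reference. Deterministic under
    ``plan.base_seed``. Failures in a single replicate are logged and the
    remaining replicates continue.
    """
    import logging

    log = logging.getLogger(__name__)
    parts: list[ExperimentResult] = []
    for s_idx in range(len(plan.scales)):
        for rep in range(plan.replicates):
            try:
                parts.append(run_replicate(plan, s_idx, rep))
            except Exception:  # noqa: BLE001 — continue the plan, per contract
                log.exception(
                    "replicate failed (scale=%s, replicate=%d); continuing",
                    plan.scales[s_idx].name,
                    rep,
                )
            if progress:
                print(f"scale {plan.scales[s_idx].name} replicate {rep} done", flush=True)
    if not parts:
        raise RuntimeError("every replicate failed")
    return ExperimentResult(
        summaries=pd.concat([p.summaries for p in parts], ignore_index=True),
        occupancy=pd.concat([p.occupancy for p in parts], ignore_index=True),
        removal=pd.concat([p.removal for p in parts], ignore_index=True),
        occupancy_trophic=pd.concat(
            [p.occupancy_trophic for p in parts], ignore_index=True
        ),
        occupancy_mass=pd.concat([p.occupancy_mass for p in parts], ignore_index=True),
        trajectories=(
            pd.concat([p.trajectories for p in parts], ignore_index=True)
            if plan.record_trajectories
            else None
        ),
    )
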