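"""Synthetic abiotic environment and initial conditions.

The study design needs, for each grid cell, a monthly temperature and a
monthly net primary productivity (NPP). Here those come from a parametric
tropical-savanna generator — a sinusoidal annual cycle plus smooth spatial
noise — rather than from observed climate rasters, so the whole experiment
is self-contained and deterministic under a seed. The landscape geometry
itself (cell areas, distances) uses real spherical-Earth arithmetic so
that landscape sizes are physically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from fragsim.domain import (
    EARTH_RADIUS_KM,
    CohortTable,
    FunctionalGroupDef,
    Landscape,
    LeafStrategy,
    ModelState,
    TrophicGroup,
)

__all__ = [
    "make_landscape",
    "SeasonalityParams",
    "EnvironmentGrid",
    "generate_environment",
    "seed_cohorts",
]


def make_landscape(
    n_rows: int,
    n_cols: int,
    cell_size_deg: float,
    centre_lat: float = 0.05,
    centre_lon: float = 38.0,
) -> Landscape:
    """Build a bounded rectangular grid of cells centred on a coordinate.

    Cell areas follow the exact spherical quadrilateral formula
    ``A = R² · Δλ · (sin φ_top − sin φ_bottom)`` with R = 6371 km, so all
    cells in one row share an area and areas shrink slightly with
    latitude. Row 0 is the northern edge; cells are indexed row-major.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions (both ≥ 1).
    cell_size_deg : float
        Cell edge length in degrees (square cells).
    centre_lat, centre_lon : float
        Latitude/longitude of the grid centre, degrees. Defaults place the
        grid on the equator in East Africa.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    if cell_size_deg <= 0:
        raise ValueError("cell size must be positive")
    if abs(centre_lat) >= 90:
        raise ValueError("centre latitude must satisfy |lat| < 90")

    half_h = n_rows * cell_size_deg / 2.0
    # northern edge of row i: centre_lat + half_h - i*cell_size
    row_top = centre_lat + half_h - np.arange(n_rows) * cell_size_deg
    row_bot = row_top - cell_size_deg
    dlam = np.deg2rad(cell_size_deg)
    row_area = (
        EARTH_RADIUS_KM**2
        * dlam
        * (np.sin(np.deg2rad(row_top)) - np.sin(np.deg2rad(row_bot)))
    )
    areas = np.repeat(row_area, n_cols)

    lat_centres = np.repeat(row_top - cell_size_deg / 2.0, n_cols)
    half_w = n_cols * cell_size_deg / 2.0
    col_centres = centre_lon - half_w + (np.arange(n_cols) + 0.5) * cell_size_deg
    lon_centres = np.tile(col_centres, n_rows)

    return Landscape(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_deg=cell_size_deg,
        centre_lat=centre_lat,
        centre_lon=centre_lon,
        cell_areas=areas,
        cell_lats=lat_centres,
        cell_lons=lon_centres,
    )


@dataclass(frozen=True)
class SeasonalityParams:
    """Parameters of the synthetic savanna climate.

    Defaults describe an equatorial savanna: warm with a mild annual
    temperature cycle, and productivity concentrated in a wet season. NPP
    is expressed as dry-matter production in kg km⁻² month⁻¹; the default
    annual mean of 1.2 × 10⁶ kg km⁻² yr⁻¹ (≈ 1.2 kg m⁻² yr⁻¹) sits in the
    range reported for tropical grassy biomes.

    Attributes
    ----------
    mean_temperature : float
        Annual mean air temperature, °C.
    temperature_amplitude : float
        Half-amplitude of the annual temperature sinusoid, °C.
    mean_npp : float
        Annual-mean monthly NPP, kg km⁻² month⁻¹.
    npp_amplitude : float
        Relative amplitude of the annual NPP cycle in [0, 1); months whose
        seasonal multiplier falls below 1 are "dry season" months.
    season_period_months : float
        Period of the seasonal cycle in months. The default of 6 emulates
        the bimodal (two wet seasons per year) rainfall regime of
        equatorial East Africa.
    phase_month : float
        Calendar month at which the seasonal cycle peaks.
    spatial_noise : float
        Relative standard deviation of the smooth spatial field modulating
        NPP and (scaled to °C) temperature across cells.
    noise_correlation_cells : float
        Gaussian smoothing radius of the spatial field, in cells.
    """

    mean_temperature: float = 25.0
    temperature_amplitude: float = 3.0
    mean_npp: float = 1.0e5
    npp_amplitude: float = 0.6
    season_period_months: float = 6.0
    phase_month: float = 3.0
    spatial_noise: float = 0.10
    noise_correlation_cells: float = 2.0

    def annual_npp_band(self) -> tuple[float, float]:
        """[min, max] admissible per-cell annual NPP, kg km⁻² yr⁻¹.

        The spatial field is clipped to ±3 relative standard deviations,
        so per-cell annual NPP stays within this band by construction.
        """
        lo = 12.0 * self.mean_npp * max(0.0, 1.0 - 3.0 * self.spatial_noise)
        hi = 12.0 * self.mean_npp * (1.0 + 3.0 * self.spatial_noise)
        return lo, hi


@dataclass
class EnvironmentGrid:
    """Monthly abiotic drivers for every cell, recycled annually.

    ``temperature`` and ``npp`` are (12, n_cells) arrays; calendar month m
    of simulation month t is ``t % 12``.
    """

    temperature: np.ndarray  # °C, shape (12, n_cells)
    npp: np.ndarray  # kg km⁻² month⁻¹, shape (12, n_cells)
    dry_season: np.ndarray  # bool, shape (12,)
    params: SeasonalityParams
    seed: int
    landscape: Landscape | None = None

    def month(self, t: int) -> tuple[np.ndarray, np.ndarray, bool]:
        m = int(t) % 12
        return self.temperature[m], self.npp[m], bool(self.dry_season[m])


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized smooth Gaussian field on the grid (mean 0, sd 1)."""
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = noise.std()
    if sd > 0:
        noise = (noise - noise.mean()) / sd
    return noise


def generate_environment(
    landscape: Landscape,
    params: SeasonalityParams | None = None,
    seed: int = 0,
) -> EnvironmentGrid:
    """Generate the 12-month cyclic environment for a landscape.

    The seasonal cycle is a cosine peaking at ``phase_month``; one smooth
    spatial field (clipped at ±3 sd) modulates NPP multiplicatively and
    temperature additively, so neighbouring cells differ smoothly. Purely
    deterministic given (landscape, params, seed).
    """
    params = params or SeasonalityParams()
    if params.mean_npp < 0:
        raise ValueError("mean NPP must be non-negative")
    rng = np.random.default_rng(seed)

    months = np.arange(12)
    season = np.cos(
        2 * np.pi * (months - params.phase_month) / params.season_period_months
    )

    spatial = _smooth_field(
        (landscape.n_rows, landscape.n_cols), params.noise_correlation_cells, rng
    ).ravel()
    spatial = np.clip(spatial, -3.0, 3.0)

    temp_season = params.mean_temperature + params.temperature_amplitude * season
    temperature = temp_season[:, None] + (params.spatial_noise * 10.0) * spatial[None, :]

    npp_season = params.mean_npp * (1.0 + params.npp_amplitude * season)
    npp_field = 1.0 + params.spatial_noise * spatial
    npp = np.clip(npp_season[:, None] * np.clip(npp_field, 0.0, None)[None, :], 0.0, None)

    dry = season < 0.0
    return EnvironmentGrid(
        temperature=temperature,
        npp=npp,
        dry_season=dry,
        params=params,
        seed=int(seed),
        landscape=landscape,
    )


# -- initial heterotroph seeding ----------------------------------------

#: Default initial standing biomass density per trophic group, kg km⁻².
#: A bottom-heavy start: herbivores outweigh omnivores outweigh carnivores.
DEFAULT_INITIAL_DENSITY = {
    TrophicGroup.HERBIVORE: 2000.0,
    TrophicGroup.OMNIVORE: 400.0,
    TrophicGroup.CARNIVORE: 100.0,
}

#: Default initial plant pools, kg km⁻² (leaf, structural).
DEFAULT_INITIAL_LEAF_DENSITY = 2.0e5
DEFAULT_INITIAL_STRUCTURAL_DENSITY = 3.0e4


def seed_cohorts(
    landscape: Landscape,
    group_table: list[FunctionalGroupDef],
    n_cohorts_per_cell: int = 3,
    mass_range: tuple[float, float] = (4e-7, 5000.0),
    seed: int = 0,
    initial_density: dict | None = None,
    initial_leaf_density: float = DEFAULT_INITIAL_LEAF_DENSITY,
    initial_structural_density: float = DEFAULT_INITIAL_STRUCTURAL_DENSITY,
    leaf_strategy: LeafStrategy = LeafStrategy.DECIDUOUS,
) -> ModelState:
    """Seed every cell with cohorts spanning the admissible trait space.

    Each cell receives ``n_cohorts_per_cell`` cohorts per functional group.
    Maturity masses are drawn log-uniformly from the intersection of
    ``mass_range`` with the group's adult range; birth mass is a
    log-uniform fraction (2–50%) of maturity, floored to the group's
    juvenile range; cohorts start at their maturity mass. Initial
    abundance follows a Damuth-like allometry N ∝ m^(−0.75), rescaled so
    each trophic group starts at a configured biomass density per cell.

    Parameters
    ----------
    n_cohorts_per_cell : int
        Cohorts per functional group per cell; 0 yields a state with
        autotroph stocks only.
    mass_range : (float, float)
        Global admissible maturity-mass interval, kg.
    initial_density : dict, optional
        Initial biomass density per :class:`TrophicGroup`, kg km⁻².
    """
    if not group_table:
        raise ValueError("group table must not be empty")
    if n_cohorts_per_cell < 0:
        raise ValueError("n_cohorts_per_cell must be non-negative")
    lo, hi = mass_range
    if not (0 < lo <= hi):
        raise ValueError("mass_range must be a positive interval")
    density = dict(DEFAULT_INITIAL_DENSITY)
    if initial_density:
        density.update(initial_density)

    rng = np.random.default_rng(seed)
    n_cells = landscape.n_cells

    cells, trophic, thermo, repro = [], [], [], []
    mass, birth, maturity, abundance = [], [], [], []

    for cell in range(n_cells):
        area = landscape.cell_areas[cell]
        # draw all cohorts for the cell, then rescale abundance per guild
        cell_slices: dict[int, list[int]] = {}
        for g in group_table:
            glo = max(lo, g.adult_mass_range[0])
            ghi = min(hi, g.adult_mass_range[1])
            if glo > ghi:
                continue
            for _ in range(n_cohorts_per_cell):
                m_mat = np.exp(rng.uniform(np.log(glo), np.log(ghi)))
                frac = np.exp(rng.uniform(np.log(0.02), np.log(0.5)))
                m_birth = m_mat * frac
                jlo, jhi = g.juvenile_mass_range
                m_birth = float(np.clip(m_birth, jlo, min(jhi, m_mat)))
                idx = len(mass)
                cells.append(cell)
                trophic.append(int(g.trophic_group))
                thermo.append(int(g.thermoregulation))
                repro.append(int(g.reproductive_strategy))
                mass.append(m_mat)
                birth.append(m_birth)
                maturity.append(m_mat)
                abundance.append(m_mat ** (-0.75))  # placeholder, rescaled below
                cell_slices.setdefault(int(g.trophic_group), []).append(idx)
        for tg, idxs in cell_slices.items():
            idxs = np.asarray(idxs)
            m = np.asarray([mass[i] for i in idxs])
            target = density[TrophicGroup(tg)] * area
            # N_k = c·m_k^-0.75 with Σ m_k N_k = target
            c = target / np.sum(m**0.25)
            for i, mi in zip(idxs, m):
                abundance[i] = c * mi ** (-0.75)

    cohorts = CohortTable(
        cell=cells,
        trophic=trophic,
        thermo=thermo,
        repro=repro,
        mass=mass,
        birth_mass=birth,
        maturity_mass=maturity,
        abundance=abundance,
        repro_pool=np.zeros(len(mass)),
        age=np.zeros(len(mass)),
        hunger=np.ones(len(mass)),
    )
    leaf = initial_leaf_density * landscape.cell_areas
    structural = initial_structural_density * landscape.cell_areas
    strategy = np.full(n_cells, int(leaf_strategy), dtype=np.int8)
    return ModelState(
        cohorts=cohorts, leaf=leaf, structural=structural, leaf_strategy=strategy, month=0
    )
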