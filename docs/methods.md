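# Methods

`fragsim` simulates how habitat loss, habitat degradation and habitat
fragmentation interact to reshape a multi-trophic terrestrial ecosystem.
It couples a trait-based, cohort-based, spatially explicit ecosystem
engine to a factorial land-use experiment, and reads the outcome through
three response measures: trophic skew, top-down mitigation of autotroph
biomass loss, and patch occupancy by trait class.

## The model world

The landscape is a bounded rectangular grid (default 10 × 10; the desk
preset uses 5 × 5) of square cells, with per-cell areas from exact
spherical-Earth geometry (mean radius 6 371 km). Cells of 0.1° at the
default equatorial East-African centre are ≈ 123 km²; the two default
scales therefore total ≈ 12 300 km² and ≈ 123 km². The boundary is
closed: nothing disperses in or out.

Each cell holds one autotroph stock — a leaf pool (edible) and a
structural pool (inedible) — and a set of heterotroph cohorts. A cohort
is a group of identical individuals defined by categorical traits
(trophic group × thermoregulation × reproductive strategy) and
quantitative traits (current, birth and maturity body mass), with a
real-valued abundance. There is no taxonomy and no trait evolution:
trait combinations that go extinct do not return.

### Abiotic drivers

Real climate inputs are replaced by a parametric savanna generator:
monthly temperature and NPP per cell, built from a seasonal cosine plus
one smooth spatial field (Gaussian-filtered noise, clipped at ±3 sd).
The default seasonal cycle has a 6-month period, emulating the bimodal
(two wet seasons) rainfall of equatorial East Africa; mean NPP is
1.2 kg m⁻² yr⁻¹ of dry matter with relative amplitude 0.6. Months below
the seasonal mean are "dry season" months, in which deciduous stocks
shed a fraction of leaf. The generator is pure: identical seed and
parameters give identical grids. What it does **not** emulate: weather
(no interannual variability — the 12 monthly fields recycle every
year), soil moisture, fire, or climate trends. A green test against
this world shows the *mechanisms* behave directionally as expected, not
that any real landscape would.

### Monthly processes

Each month applies, in fixed order:

1. **Autotroph growth** — adds `NPP × area × (1 − B/K) × B/(B + r_h·area)`,
   split between leaf and structural pools by an allocation fraction
   (default 0.98 leaf: a grass-dominated system), then climate mortality
   (0.1 month⁻¹) and dry-season shedding. The second factor is a
   regeneration limitation (half-saturation r_h = 5 × 10³ kg km⁻²):
   regrowth is propagule-limited at very low standing biomass, so a cell
   stripped completely bare stays bare. Patches under total monthly
   removal therefore stay empty, while partially vegetated cells are
   essentially unconstrained.
2. **Eating** — herbivores (and omnivores, weighted 0.5, with a 0.6
   generalist penalty) take leaf biomass at a saturating per-individual
   rate `a_h · m^0.75 · L/(L + h·area)`; carnivores (and omnivores) kill
   prey cohorts with demand weighted by a log-normal kernel centred on
   φ·m_predator (φ = 0.05, σ = 2 ln-units — predators mostly 0.5–4
   orders of magnitude heavier than their prey). Demand above a pool's
   content is rationed proportionally; nothing goes negative. Ectotherm
   attack rates carry a thermal activity factor (0.1, Q10-scaled), which
   keeps the intake-to-cost ratio comparable across thermoregulation
   classes so neither structurally excludes the other.
3. **Metabolism** — per-individual mass loss `k · m^0.75`, with
   k = 1.5 kg·kg^(−3/4)·month⁻¹ for endotherms (field metabolic rate
   converted at tissue energy density) and 0.15 × Q10^((T−25)/10) for
   ectotherms. Mass cannot fall below half the birth mass; hitting the
   floor or dropping below 10% of maturity mass flags starvation.
4. **Growth and reproduction** — assimilated intake first rebuilds body
   mass to maturity; surplus splits 0.6 to a per-individual reproductive
   pool. A pool reaching birth mass spawns an offspring cohort
   (abundance = parent abundance × pool/birth mass) inheriting all
   traits; semelparous parents die on spawning.
5. **Mortality** — exponential survival under additive hazards:
   background 0.01, senescence ramping with age, starvation +0.1
   month⁻¹. Cohorts below 0.5 individuals go extinct.
6. **Dispersal** — newly spawned cohorts always disperse (natal
   dispersal is obligatory, as in the full general ecosystem model this
   engine abbreviates); cohorts whose intake/requirement ratio fell
   below 0.5 also move. Destinations are quality-blind, so in heavily
   impacted landscapes the offspring of mobile (large) animals are lost
   to stripped cells — the model's only coupling between population
   persistence and total habitat area. The
   destination is uniform among cells within `d = 5·m^0.25` km (current
   cell included), so animals below ~1 kg cannot leave a 0.1° cell while
   megafauna cross several. Whole cohorts relocate.
7. **Merging** — cells are capped at 64 cohorts; the identical-trait
   pair closest in log body mass merges (abundance-weighted), conserving
   abundance and biomass exactly.

Every kilogram is itemized in a per-step mass ledger (NPP input, climate
loss, shedding, herbivory/predation waste, metabolic loss, mortality,
merge culls, impact removal, plus a `intake_lapsed` line for intake of
cohorts that were themselves eaten to extinction in the same step); the
ledger closes the biomass balance to 10⁻⁹ relative per step, and the
trajectory is fully deterministic given the seed.

## Why these defaults

The process constants are not fitted to data; they were chosen from
allometric first principles and then calibrated — before any acceptance
evaluation of the land-use experiment — so that the *unimpacted* system
shows the qualitative behaviours expected of the class of full general
ecosystem models this engine abbreviates:

* a dynamic steady state within the burn-in (total-biomass CV < 0.2 over
  the last fifth of an unimpacted run);
* a bottom-heavy biomass pyramid (A > H ≥ O + C);
* persistence of all three trophic groups across essentially all cells,
  with endothermic herbivores of several hundred to a few thousand kg
  the largest survivors;
* grazing as the dominant loss term of the leaf pool (top-down control),
  which is the mechanism behind the mitigation response.

Three lessons from that calibration are worth recording. First, with a
single shared leaf resource, the thermoregulation class with the lower
intake-to-cost break-even always competitively excludes the other by
depressing the resource; the ectotherm activity window is the minimal
trait-faithful way to avoid a structurally predetermined outcome.
Second, with φ = 0.01 every predator ontogeny must pass through prey two
orders of magnitude below the adult optimum — a region of the size
spectrum that predation itself empties — and carnivore recruitment
collapses; φ = 0.05 resolves this while staying inside the stated
predator–prey size range. Third, unpenalized omnivores (0.5 herbivory +
0.5 predation at specialist rates) become dominant generalists that
backfill the grazing niche in impacted cells, erasing the herbivory
release; the 0.6 efficiency penalty restores them to the minor guild
they are in real savannas.

## The experiment

A treatment is (configuration, extent, intensity): random or continuous
(whole rows from the northern edge) masks covering 25/50/75/100% of
cells, with 25/50/75/100% of autotroph biomass removed from each masked
cell at the start of every month (proportionally from both pools by
default; a leaf-only mode exists). The factorial, with full-extent
configurations deduplicated and one pristine control, is 29 treatments;
the full design is 10 replicates × 29 × 2 scales = 580 runs of
100 burn-in + 100 impact years. The desk preset (5 × 5 grid, 240 + 240
months, 36-month summary window, 3 replicates, one scale) preserves the
design while running in minutes.

Within a replicate, every treatment branches from the identical
post-burn-in state, so the pristine run is a *paired* reference; seeds
derive deterministically from (base seed, scale, replicate, treatment).
Summaries average the final window's monthly landscape totals per
trophic group.

## Metrics

* **Trophic skew** — half the L1 distance between the impacted and
  pristine (C, O, H, A) biomass-share vectors: zero iff every group lost
  the same proportion, bounded by 1, and readable as the fraction of
  total biomass redistributed between groups. Complete-collapse
  scenarios (both extent and intensity 100%) are excluded.
* **Mitigation** — `M = A_I / ((1 − E·i)·A_P) − 1`: the proportional
  excess of impacted autotroph biomass over a naive expectation with no
  trophic effects. Positive means release from herbivory; negative means
  added herbivore pressure or failure to regenerate. Excluded at
  E·i = 1.
* **Occupancy** — for 100%-intensity scenarios (where impacted patches
  are unambiguously unsuitable), the proportion of remaining pristine
  patches holding ≥ 1 individual-equivalent of a trait class, with
  classes at three granularities: trophic group × log10 mass-decade bin,
  trophic group alone, and mass bin alone.

## Statistics

Skew and mitigation are arcsine-square-root transformed (values above 1
— mitigation can exceed 1 — are clipped with a logged count, since the
source analysis does not state its handling). The interpretable reading
is via subsets: OLS of transformed skew on intensity within each extent
level and vice versa (β, R², df, p per subset), plus paired t-tests
matching otherwise-equivalent scenarios across configurations and
scales, and mean pairwise percentage differences. Full-extent runs are
duplicated into both configuration series before subsetting, restoring
the balanced 4 × 2 × replicates shape (df = 78 per subset at 10
replicates; 120 pairs, df = 119, for the configuration contrast). No
multiple-testing correction is applied — the subset tests interpret
established differences and the emphasis is on effect sizes.

## Numerical and degenerate-case choices

* Rationing resolves any demand-over-supply proportionally; pools and
  abundances are clamped at 0 and checked after every sub-process.
* Merging picks the smallest log-mass gap within identical-trait
  classes; with no such pair, the lowest-biomass cohort is culled and
  ledgered. Merged masses are abundance-weighted arithmetic means (mass,
  pool, age) and geometric means (birth/maturity mass).
* Non-integral mask quotas round half up. Cell (0,0) is the north-west
  corner; row 0 is the northern edge; continuous masks fill from row 0.
* A dispersal radius below one cell width leaves the cohort in place
  (the current cell is always a candidate destination).
* Paired tests with zero difference variance return the mean of
  differences with a degenerate flag rather than an undefined t.
* Subset regressions drop subsets with < 3 points or a constant
  predictor, with a logged warning.

## Known limitations

* Process constants are an order-of-magnitude parameterization of a
  deliberately simplified engine; quantitative outputs (mean skew and
  mitigation levels, regression coefficients) characterize this desk-scale
  world only and are not comparable to full-scale ensemble results.
* Life histories are compressed — generation times of large animals are
  months rather than years — which compresses trophic biomass ratios:
  predator standing biomass is 1–2 orders of magnitude above field
  values. Per-cell populations of large classes therefore sit far above
  the extinction cutoff, and size-selective occupancy declines (the
  hardest trait signal) are weak at desk scale.
* Without home ranges, the local dynamics are nearly scale-invariant:
  the subsystem on the remaining pristine cells is a miniature of the
  pristine landscape. Consequently trophic skew responds strongly to
  extent but *falls* at 100% intensity (bare cells lose plants and
  animals in equal proportion), and top-down mitigation engages fully
  only at severe intensities, where removal actually starves the
  grazers. Obtaining a skew increase with intensity and
  mitigation at mild degradation appears to require the area-dependent
  demography of the full model at full scale.
* Each replicate assembles its own community from the same trait pool;
  which size classes persist varies between replicates, so trait-class
  analyses are noisier than guild-level ones.
* The environment recycles a single climatological year; there is no
  interannual variability, so "steady state" is a limit cycle plus
  demographic noise.
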