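"""Response metrics: trophic skew, biomass-loss mitigation, occupancy.

*Trophic skew* summarizes how far the relative biomass composition
(carnivore/omnivore/herbivore/autotroph) of an impacted ecosystem departs
from its paired pristine reference. It is implemented in total-variation
form,

    skew = ½ Σ_g | g_I / T_I − g_P / T_P |,   g ∈ {C, O, H, A},

which is 0 when each trophic group loses the same proportion of its
biomass, is bounded by 1, and reads directly as "the fraction of total
ecosystem biomass redistributed between trophic groups".

*Mitigation* compares the observed impacted autotroph biomass with a
naive no-trophic-effects expectation (1 − extent × intensity) of the
pristine autotroph biomass:

    M = A_I / ((1 − E·i) · A_P) − 1.

Positive values indicate release from herbivory (more plant biomass than
naively predicted); negative values indicate increased herbivore pressure
or failure to regenerate before further removal.

*Occupancy* is, per trait class (trophic group × body-mass decade), the
proportion of remaining pristine patches containing a population; it is
used for 100%-intensity scenarios, where impacted patches are
unambiguously unsuitable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fragsim.domain import EcosystemSummary, ModelState, TrophicGroup

__all__ = [
    "ExcludedScenarioError",
    "SkewResult",
    "MitigationResult",
    "trophic_skew",
    "biomass_mitigation",
    "occupancy",
    "metric_table",
]


class ExcludedScenarioError(ValueError):
    """Raised for scenarios a metric is undefined on (e.g. total collapse)."""


@dataclass(frozen=True)
class SkewResult:
    """Trophic skew with the share vectors it was computed from."""

    skew: float
    impacted_shares: np.ndarray  # (C, O, H, A) fractions
    pristine_shares: np.ndarray
    excluded: bool = False


@dataclass(frozen=True)
class MitigationResult:
    """Mitigation M with its naive-expectation intermediate."""

    mitigation: float
    naive_expected_biomass: float
    extent: float
    intensity: float


def trophic_skew(impacted: EcosystemSummary, pristine: EcosystemSummary) -> SkewResult:
    """Half the L1 distance between impacted and pristine biomass shares.

    Both totals must be positive: complete ecosystem collapse is excluded
    upstream and raises :class:`ExcludedScenarioError` here.
    """
    if pristine.total_biomass <= 0:
        raise ExcludedScenarioError("pristine total biomass must be positive")
    if impacted.total_biomass <= 0:
        raise ExcludedScenarioError(
            "impacted ecosystem has collapsed entirely; skew is excluded"
        )
    s_i = impacted.shares()
    s_p = pristine.shares()
    skew = 0.5 * float(np.abs(s_i - s_p).sum())
    return SkewResult(skew=skew, impacted_shares=s_i, pristine_shares=s_p)


def biomass_mitigation(
    a_impacted: float,
    a_pristine: float,
    extent: float,
    intensity: float,
) -> MitigationResult:
    """Proportional excess of impacted autotroph biomass over the naive
    expectation (1 − extent × intensity) × pristine biomass.

    Undefined when extent × intensity = 1 (the naive expectation is zero);
    requires positive pristine biomass.
    """
    if a_pristine <= 0:
        raise ValueError("pristine autotroph biomass must be positive")
    if a_impacted < 0:
        raise ValueError("impacted autotroph biomass must be non-negative")
    removal = extent * intensity
    if removal >= 1.0:
        raise ExcludedScenarioError(
            "extent × intensity = 1 removes everything; mitigation is excluded"
        )
    naive = (1.0 - removal) * a_pristine
    return MitigationResult(
        mitigation=a_impacted / naive - 1.0,
        naive_expected_biomass=naive,
        extent=extent,
        intensity=intensity,
    )


def occupancy(
    final_state: ModelState,
    pristine_mask: np.ndarray,
    bin_edges: np.ndarray | None = None,
    presence_threshold: float = 1.0,
    by: str = "trophic_x_mass",
) -> pd.DataFrame:
    """Patch occupancy by trait class over the remaining pristine cells.

    A trait class is, by default, a trophic group × maturity-mass bin
    (log10-decade bins by default, spanning the masses present); with
    ``by="trophic"`` classes are trophic groups alone, and with
    ``by="mass"`` mass bins alone (pooled across trophic groups). A
    pristine cell counts as occupied by a class when it holds at least
    one cohort of the class with abundance at or above
    ``presence_threshold`` individuals.

    Returns a frame with one row per class: trophic_group and/or
    mass_bin_low/mass_bin_high, n_occupied, n_pristine, occupancy ∈ [0, 1].
    """
    if by not in ("trophic_x_mass", "trophic", "mass"):
        raise ValueError("by must be 'trophic_x_mass', 'trophic' or 'mass'")
    pristine_mask = np.asarray(pristine_mask, dtype=bool)
    n_pristine = int(pristine_mask.sum())
    if n_pristine == 0:
        raise ExcludedScenarioError("no pristine cells remain (extent = 100%)")

    c = final_state.cohorts
    if bin_edges is None:
        if len(c) == 0:
            bin_edges = np.array([1e-7, 1e4])
        else:
            k0 = int(np.floor(np.log10(c.maturity_mass.min())))
            k1 = int(np.ceil(np.log10(c.maturity_mass.max())))
            bin_edges = 10.0 ** np.arange(k0, max(k1, k0 + 1) + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)

    present = (c.abundance >= presence_threshold) & pristine_mask[c.cell]
    bins = np.clip(np.digitize(c.maturity_mass, bin_edges) - 1, 0, len(bin_edges) - 2)

    trophic_classes = list(TrophicGroup) if by != "mass" else [None]
    mass_classes = range(len(bin_edges) - 1) if by != "trophic" else [None]

    rows = []
    for tg in trophic_classes:
        for b in mass_classes:
            sel = present
            row: dict = {}
            if tg is not None:
                sel = sel & (c.trophic == int(tg))
                row["trophic_group"] = tg.label
            if b is not None:
                sel = sel & (bins == b)
                row["mass_bin_low"] = bin_edges[b]
                row["mass_bin_high"] = bin_edges[b + 1]
            occupied_cells = np.unique(c.cell[sel])
            row.update(
                n_occupied=int(occupied_cells.size),
                n_pristine=n_pristine,
                occupancy=occupied_cells.size / n_pristine,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def metric_table(summaries: pd.DataFrame, pairing: str = "paired") -> pd.DataFrame:
    """Assemble the per-run metric table from an experiment's summaries.

    Each impacted run is paired with a pristine reference: its own
    replicate's pristine run (``pairing="paired"``, the default) or the
    mean of all pristine runs at the same scale (``pairing="pooled"``).
    Trophic skew is excluded (NaN, ``skew_excluded=True``) for the
    complete-collapse design cell (extent and intensity both 100%), and
    mitigation for extent × intensity = 1.

    Returns one row per impacted run keyed by (scale, configuration,
    extent, intensity, replicate) with columns ``skew`` and ``mitigation``.
    """
    if pairing not in ("paired", "pooled"):
        raise ValueError("pairing must be 'paired' or 'pooled'")
    pristine = summaries[summaries["configuration"] == "pristine"]
    impacted = summaries[summaries["configuration"] != "pristine"]
    if pristine.empty:
        raise ValueError("summaries contain no pristine reference runs")

    rows = []
    for _, r in impacted.iterrows():
        if pairing == "paired":
            ref = pristine[
                (pristine["scale"] == r["scale"])
                & (pristine["replicate"] == r["replicate"])
            ]
            if ref.empty:
                raise ValueError(
                    f"no pristine reference for scale={r['scale']} "
                    f"replicate={r['replicate']}"
                )
            ref = ref.iloc[0]
        else:
            ref = pristine[pristine["scale"] == r["scale"]].mean(numeric_only=True)

        p_sum = EcosystemSummary(
            ref["carnivore"], ref["omnivore"], ref["herbivore"], ref["autotroph"]
        )
        i_sum = EcosystemSummary(
            r["carnivore"], r["omnivore"], r["herbivore"], r["autotroph"]
        )
        collapse_cell = r["extent"] == 1.0 and r["intensity"] == 1.0
        if collapse_cell or i_sum.total_biomass <= 0:
            skew, skew_excluded = np.nan, True
        else:
            skew, skew_excluded = trophic_skew(i_sum, p_sum).skew, False
        if r["extent"] * r["intensity"] >= 1.0 or ref["autotroph"] <= 0:
            mitigation = np.nan
        else:
            mitigation = biomass_mitigation(
                r["autotroph"], ref["autotroph"], r["extent"], r["intensity"]
            ).mitigation
        rows.append(
            dict(
                scale=r["scale"],
                configuration=r["configuration"],
                extent=r["extent"],
                intensity=r["intensity"],
                replicate=r["replicate"],
                skew=skew,
                skew_excluded=skew_excluded,
                mitigation=mitigation,
            )
        )
    return pd.DataFrame(rows)
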