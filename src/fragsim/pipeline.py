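"""End-to-end orchestration: configs in, simulations run, tables out.

The pipeline reads a plan (JSON) and optionally a scenario table (CSV),
runs the factorial experiment with per-replicate caching so interrupted
runs resume where they stopped, then computes the metric table, the
subset-regression table and the paired contrasts, and writes everything
as tidy CSV plus a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from fragsim import __version__
from fragsim.domain import Configuration, Treatment
from fragsim.engine import ProcessParams
from fragsim.environment import SeasonalityParams
from fragsim.metrics import metric_table
from fragsim.scenarios import (
    ExperimentPlan,
    ExperimentResult,
    ScaleSpec,
    desk_plan,
    paper_plan,
    run_replicate,
)
from fragsim.stats import (
    expand_full_extent,
    paired_comparison,
    percentage_contrast,
    subset_regressions,
)

log = logging.getLogger(__name__)

__all__ = [
    "plan_to_dict",
    "plan_from_dict",
    "load_plan",
    "read_scenarios",
    "write_scenarios",
    "run_pipeline",
    "compute_metrics",
    "compute_stats",
    "make_fixtures",
]


# -- configuration I/O ---------------------------------------------------

def plan_to_dict(plan: ExperimentPlan) -> dict:
    d = dataclasses.asdict(plan)
    d["configurations"] = [c.value for c in plan.configurations]
    return d


def plan_from_dict(d: dict) -> ExperimentPlan:
    d = dict(d)
    if "scales" in d:
        d["scales"] = tuple(ScaleSpec(**s) for s in d["scales"])
    if "seasonality" in d and isinstance(d["seasonality"], dict):
        d["seasonality"] = SeasonalityParams(**d["seasonality"])
    if "process" in d and isinstance(d["process"], dict):
        d["process"] = ProcessParams(**d["process"])
    if "configurations" in d:
        d["configurations"] = tuple(Configuration(c) for c in d["configurations"])
    for key in ("extents", "intensities", "mass_range"):
        if key in d:
            d[key] = tuple(d[key])
    return ExperimentPlan(**d)


def load_plan(path: str | Path | None, preset: str = "desk", seed: int = 0) -> ExperimentPlan:
    """Load a plan from JSON, or build a preset ('desk' or 'paper')."""
    if path is not None:
        with open(path) as fh:
            plan = plan_from_dict(json.load(fh))
        return plan.with_seed(seed)
    if preset == "desk":
        return desk_plan(base_seed=seed)
    if preset == "paper":
        return paper_plan(base_seed=seed)
    raise ValueError(f"unknown preset {preset!r}")


def write_scenarios(plan: ExperimentPlan, path: str | Path) -> None:
    """Write the treatment table as a scenario CSV."""
    rows = [
        dict(
            label=t.label,
            configuration=t.configuration.value,
            extent_percent=int(round(t.extent * 100)),
            intensity_percent=int(round(t.intensity * 100)),
            replicates=plan.replicates,
        )
        for t in plan.treatments
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scenarios(path: str | Path) -> dict:
    """Parse a scenario CSV back into factorial plan fields."""
    df = pd.read_csv(path)
    impacted = df[df["configuration"] != "pristine"]
    return dict(
        extents=tuple(sorted(set(impacted["extent_percent"] / 100.0))),
        intensities=tuple(sorted(set(impacted["intensity_percent"] / 100.0))),
        configurations=tuple(
            Configuration(c)
            for c in sorted(set(impacted["configuration"]))
            if c != "pristine"
        ),
        replicates=int(df["replicates"].iloc[0]),
    )


def _config_hash(plan: ExperimentPlan) -> str:
    blob = json.dumps(plan_to_dict(plan), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- pipeline ------------------------------------------------------------

def run_pipeline(
    plan: ExperimentPlan,
    out_dir: str | Path,
    resume: bool = True,
    make_plots: bool = True,
    progress: bool = False,
) -> dict:
    """Run the whole experiment and analysis; return the manifest.

    Per-replicate results are cached under ``out/runs/``; with
    ``resume=True`` cached parts are loaded instead of recomputed, and
    the final outputs are identical to an uninterrupted execution.
    """
    out = Path(out_dir)
    runs_dir = out / "runs"
    runs_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(plan)
    manifest_path = out / "manifest.json"
    manifest = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "base_seed": plan.base_seed,
        "n_runs_planned": plan.n_runs,
        "parts": {},
        "outputs": [],
        "wall_time_s": {},
    }
    if resume and manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == cfg_hash:
                manifest["parts"] = old.get("parts", {})
        except json.JSONDecodeError:
            log.warning("corrupt manifest; starting fresh")

    parts: list[ExperimentResult] = []
    for s_idx, scale in enumerate(plan.scales):
        for rep in range(plan.replicates):
            part_id = f"{scale.name}-r{rep}"
            paths = {
                kind: runs_dir / f"part-{part_id}-{kind}.csv"
                for kind in (
                    "summaries", "occupancy", "removal",
                    "occupancy_trophic", "occupancy_mass",
                )
            }
            cached = (
                resume
                and manifest["parts"].get(part_id, {}).get("status") == "done"
                and all(p.exists() for p in paths.values())
            )
            t0 = time.time()
            if cached:
                part = ExperimentResult(
                    summaries=pd.read_csv(
                        paths["summaries"], float_precision="round_trip"
                    ),
                    occupancy=_read_maybe_empty(paths["occupancy"]),
                    removal=pd.read_csv(paths["removal"], float_precision="round_trip"),
                    occupancy_trophic=_read_maybe_empty(paths["occupancy_trophic"]),
                    occupancy_mass=_read_maybe_empty(paths["occupancy_mass"]),
                )
                log.info("loaded cached part %s", part_id)
            else:
                part = run_replicate(plan, s_idx, rep)
                part.summaries.to_csv(paths["summaries"], index=False)
                part.occupancy.to_csv(paths["occupancy"], index=False)
                part.removal.to_csv(paths["removal"], index=False)
                part.occupancy_trophic.to_csv(paths["occupancy_trophic"], index=False)
                part.occupancy_mass.to_csv(paths["occupancy_mass"], index=False)
                manifest["parts"][part_id] = {
                    "status": "done",
                    "files": [str(p) for p in paths.values()],
                    "n_runs": len(part.summaries),
                }
                manifest_path.write_text(json.dumps(manifest, indent=2))
            manifest["wall_time_s"][part_id] = round(time.time() - t0, 2)
            if progress:
                print(f"part {part_id} done in {manifest['wall_time_s'][part_id]}s",
                      flush=True)
            parts.append(part)

    def _concat(frames):
        frames = [f for f in frames if f is not None and not f.empty]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    result = ExperimentResult(
        summaries=pd.concat([p.summaries for p in parts], ignore_index=True),
        occupancy=_concat([p.occupancy for p in parts]),
        removal=pd.concat([p.removal for p in parts], ignore_index=True),
        occupancy_trophic=_concat([p.occupancy_trophic for p in parts]),
        occupancy_mass=_concat([p.occupancy_mass for p in parts]),
    )

    outputs = compute_metrics(result, out)
    outputs += compute_stats(out)
    if make_plots:
        outputs += make_figures(out)
    manifest["outputs"] = [str(p) for p in outputs]
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _read_maybe_empty(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, FileNotFoundError):
        return pd.DataFrame()


def compute_metrics(result: ExperimentResult, out_dir: str | Path) -> list[Path]:
    """Write summaries, the per-run metric table and occupancy curves."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    result.summaries.to_csv(out / "summaries.csv", index=False)
    written.append(out / "summaries.csv")
    metrics = metric_table(result.summaries)
    metrics.to_csv(out / "metrics.csv", index=False)
    written.append(out / "metrics.csv")
    result.occupancy.to_csv(out / "occupancy.csv", index=False)
    written.append(out / "occupancy.csv")
    if result.occupancy_trophic is not None:
        result.occupancy_trophic.to_csv(out / "occupancy_trophic.csv", index=False)
        written.append(out / "occupancy_trophic.csv")
    if result.occupancy_mass is not None:
        result.occupancy_mass.to_csv(out / "occupancy_mass.csv", index=False)
        written.append(out / "occupancy_mass.csv")
    result.removal.to_csv(out / "removal.csv", index=False)
    written.append(out / "removal.csv")
    return written


def compute_stats(out_dir: str | Path) -> list[Path]:
    """Regression table and paired contrasts from the metric CSVs."""
    out = Path(out_dir)
    metrics = pd.read_csv(out / "metrics.csv")
    written = []

    reg_rows = []
    for scale, sub in metrics.groupby("scale"):
        expanded = expand_full_extent(sub)
        for row in subset_regressions(expanded, response="skew"):
            reg_rows.append(dict(scale=scale, **dataclasses.asdict(row)))
    table1 = pd.DataFrame(reg_rows)
    table1.to_csv(out / "regressions.csv", index=False)
    written.append(out / "regressions.csv")

    contrasts = {}
    for scale, sub in metrics.groupby("scale"):
        comparable = sub[(sub["extent"] < 1.0)].dropna(subset=["skew"])
        piv = comparable.pivot_table(
            index=["extent", "intensity", "replicate"],
            columns="configuration",
            values="skew",
        ).dropna()
        if {"random", "continuous"} <= set(piv.columns) and len(piv) >= 2:
            res = paired_comparison(piv["random"], piv["continuous"])
            pct = percentage_contrast(piv["random"], piv["continuous"])
            contrasts[f"configuration_skew_{scale}"] = dict(
                t=res.t, df=res.df, p=res.p,
                mean_of_differences=res.mean_of_differences,
                n_pairs=res.n_pairs, percent_difference=pct,
            )
    scales = sorted(metrics["scale"].unique())
    if len(scales) == 2:
        piv = (
            metrics.dropna(subset=["skew"])
            .pivot_table(
                index=["configuration", "extent", "intensity", "replicate"],
                columns="scale",
                values="skew",
            )
            .dropna()
        )
        if len(piv) >= 2:
            res = paired_comparison(piv[scales[1]], piv[scales[0]])
            contrasts["scale_skew"] = dict(
                t=res.t, df=res.df, p=res.p,
                mean_of_differences=res.mean_of_differences, n_pairs=res.n_pairs,
            )
    (out / "contrasts.json").write_text(json.dumps(contrasts, indent=2))
    written.append(out / "contrasts.json")
    return written


def make_figures(out_dir: str | Path) -> list[Path]:
    """Simple figure analogues: skew grid, mitigation grid, occupancy."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    metrics = pd.read_csv(out / "metrics.csv")
    written = []

    for value, fname in (("skew", "skew_grid.png"), ("mitigation", "mitigation_grid.png")):
        groups = list(metrics.groupby(["scale", "configuration"]))
        fig, axes = plt.subplots(
            1, max(len(groups), 1), figsize=(4 * max(len(groups), 1), 3.5), squeeze=False
        )
        for ax, ((scale, cfg), sub) in zip(axes[0], groups):
            grid = sub.pivot_table(index="intensity", columns="extent", values=value)
            im = ax.imshow(grid.to_numpy(), origin="lower", cmap="viridis", aspect="auto")
            ax.set_xticks(range(len(grid.columns)), [f"{c:.0%}" for c in grid.columns])
            ax.set_yticks(range(len(grid.index)), [f"{i:.0%}" for i in grid.index])
            ax.set_xlabel("extent")
            ax.set_ylabel("intensity")
            ax.set_title(f"{scale} / {cfg}")
            fig.colorbar(im, ax=ax, label=value)
        fig.tight_layout()
        fig.savefig(out / fname, dpi=120)
        plt.close(fig)
        written.append(out / fname)

    occ_path = out / "occupancy.csv"
    if occ_path.exists():
        occ = _read_maybe_empty(occ_path)
        if not occ.empty:
            fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
            for ax, tg in zip(axes, ("carnivore", "omnivore", "herbivore")):
                sub = occ[occ["trophic_group"] == tg]
                for (lo, hi), binsub in sub.groupby(["mass_bin_low", "mass_bin_high"]):
                    curve = binsub.groupby("extent")["occupancy"].mean()
                    if curve.max() > 0:
                        ax.plot(curve.index, curve.values, marker="o",
                                label=f"{lo:g}–{hi:g} kg")
                ax.set_title(tg)
                ax.set_xlabel("extent")
            axes[0].set_ylabel("occupancy of pristine cells")
            axes[-1].legend(fontsize=6)
            fig.tight_layout()
            fig.savefig(out / "occupancy_curves.png", dpi=120)
            plt.close(fig)
            written.append(out / "occupancy_curves.png")
    return written


# -- fixtures ------------------------------------------------------------

def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write tiny deterministic inputs used by tests and docs.

    Contents: a 3×3 landscape table, a two-cohort state, a hand-checkable
    pristine/impacted summary pair (skew exactly 0.10), a continuous
    one-row mask and a seeded random three-cell mask.
    """
    from fragsim.domain import Cohort, CohortTable, ModelState, TrophicGroup
    from fragsim.domain import state_to_frames
    from fragsim.environment import make_landscape
    from fragsim.scenarios import select_impacted_cells

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory = {}

    landscape = make_landscape(3, 3, 0.1)
    pd.DataFrame(
        dict(
            cell=np.arange(9),
            lat=landscape.cell_lats,
            lon=landscape.cell_lons,
            area_km2=landscape.cell_areas,
        )
    ).to_csv(out / "landscape_3x3.csv", index=False)
    inventory["landscape"] = out / "landscape_3x3.csv"

    cohorts = CohortTable.from_cohorts(
        [
            Cohort(TrophicGroup.HERBIVORE, 0, 1, current_mass=10.0, birth_mass=1.0,
                   maturity_mass=10.0, abundance=100.0, cell_index=0),
            Cohort(TrophicGroup.CARNIVORE, 0, 1, current_mass=50.0, birth_mass=5.0,
                   maturity_mass=50.0, abundance=5.0, cell_index=0),
        ]
    )
    state = ModelState(
        cohorts=cohorts,
        leaf=np.full(9, 1e5),
        structural=np.full(9, 2e5),
        leaf_strategy=np.zeros(9, dtype=np.int8),
    )
    cdf, sdf = state_to_frames(state)
    cdf.to_csv(out / "state_cohorts.csv", index=False)
    sdf.to_csv(out / "state_stocks.csv", index=False)
    inventory["state"] = [out / "state_cohorts.csv", out / "state_stocks.csv"]

    # share vectors (A, H, O, C): pristine (0.70, 0.20, 0.07, 0.03),
    # impacted (0.80, 0.10, 0.07, 0.03) → skew 0.10 at total 1000 kg
    summary_pair = {
        "pristine": dict(autotroph=700.0, herbivore=200.0, omnivore=70.0, carnivore=30.0),
        "impacted": dict(autotroph=800.0, herbivore=100.0, omnivore=70.0, carnivore=30.0),
        "expected_skew": 0.10,
    }
    (out / "summary_pair.json").write_text(json.dumps(summary_pair, indent=2))
    inventory["summary_pair"] = out / "summary_pair.json"

    masks = pd.DataFrame(
        dict(
            cell=np.arange(9),
            continuous_row=select_impacted_cells(
                landscape, 3 / 9, Configuration.CONTINUOUS, np.random.default_rng(seed)
            ),
            random_3=select_impacted_cells(
                landscape, 3 / 9, Configuration.RANDOM, np.random.default_rng(seed)
            ),
        )
    )
    masks.to_csv(out / "masks_3x3.csv", index=False)
    inventory["masks"] = out / "masks_3x3.csv"
    return inventory
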