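"""Analysis layer: arcsine transform, subset regressions, paired tests.

The factorial design produces strong interactions between extent,
intensity, configuration and scale; the interpretable reading is via
subsets — ordinary least squares of (arcsine-transformed) trophic skew on
intensity within each extent level and vice versa, plus paired t-tests
matching otherwise-equivalent scenarios across configurations or scales.
No multiple-testing correction is applied: the subset tests interpret
established differences, and effect sizes (β, R², mean of differences)
carry the interpretation rather than p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "RegressionRow",
    "PairedTestResult",
    "arcsine_transform",
    "expand_full_extent",
    "subset_regressions",
    "paired_comparison",
    "percentage_contrast",
]


def arcsine_transform(x, clip_above_one: bool = True) -> np.ndarray:
    """Arcsine square-root transform, arcsin(√x), radians in [0, π/2].

    Proportions outside [0, 1] are clipped with a logged warning (values
    above 1 can arise for mitigation, which is a ratio, not a true
    proportion)."""
    x = np.asarray(x, dtype=float)
    out_of_range = (x < 0) | (x > 1)
    n_bad = int(np.count_nonzero(out_of_range & np.isfinite(x)))
    if n_bad:
        log.warning("arcsine transform clipped %d value(s) outside [0, 1]", n_bad)
    clipped = np.clip(x, 0.0, 1.0)
    result = np.arcsin(np.sqrt(clipped))
    if result.ndim == 0:
        return float(result)
    return result


@dataclass(frozen=True)
class RegressionRow:
    """One subset regression: transformed skew against one predictor.

    ``subset_variable`` names the variable held fixed ("extent" or
    "intensity"); the regression runs on the other one. β is the slope
    per unit predictor (predictor on the 0–1 fraction scale)."""

    subset_variable: str
    subset_value: float
    predictor: str
    beta: float
    r_squared: float
    df: int
    p: float
    n: int


def expand_full_extent(df: pd.DataFrame) -> pd.DataFrame:
    """Duplicate extent-100% rows into both spatial configurations.

    The full-extent treatment is simulated once (the random and continuous
    masks coincide), but in the analysis it belongs to both configuration
    series; this restores the balanced 4 × 2 × replicates subset shape."""
    full = df[df["extent"] == 1.0]
    if full.empty:
        return df.copy()
    configs = [c for c in ("random", "continuous")]
    pieces = [df[df["extent"] < 1.0]]
    for cfg in configs:
        dup = full.copy()
        dup["configuration"] = cfg
        pieces.append(dup)
    return pd.concat(pieces, ignore_index=True)


def subset_regressions(
    table: pd.DataFrame,
    response: str = "skew",
    transform: bool = True,
) -> list[RegressionRow]:
    """OLS of (transformed) response on intensity within each extent
    level, and on extent within each intensity level.

    ``table`` needs columns extent, intensity and the response, for one
    scale. Rows with a missing response are dropped; subsets with fewer
    than 3 points are omitted with a warning.
    """
    df = table.dropna(subset=[response]).copy()
    y_all = arcsine_transform(df[response]) if transform else df[response].to_numpy()
    df["_y"] = y_all
    rows: list[RegressionRow] = []
    for subset_var, predictor in (("extent", "intensity"), ("intensity", "extent")):
        for value in sorted(df[subset_var].unique()):
            sub = df[df[subset_var] == value]
            if len(sub) < 3:
                log.warning(
                    "subset %s=%s has %d point(s); omitted", subset_var, value, len(sub)
                )
                continue
            if sub[predictor].nunique() < 2:
                log.warning(
                    "subset %s=%s has a constant predictor; omitted", subset_var, value
                )
                continue
            x = sm.add_constant(sub[predictor].to_numpy())
            fit = sm.OLS(sub["_y"].to_numpy(), x).fit()
            rows.append(
                RegressionRow(
                    subset_variable=subset_var,
                    subset_value=float(value),
                    predictor=predictor,
                    beta=float(fit.params[1]),
                    r_squared=float(fit.rsquared),
                    df=int(fit.df_resid),
                    p=float(fit.pvalues[1]),
                    n=len(sub),
                )
            )
    return rows


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test on matched scenario pairs."""

    t: float
    df: int
    p: float
    mean_of_differences: float
    n_pairs: int
    degenerate: bool = False  # zero variance of differences


def _align(metric_a, metric_b, pairing=None) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if pairing is not None:
        keys_a, keys_b = pairing
        map_a = dict(zip(map(tuple, np.atleast_2d(keys_a)), a))
        map_b = dict(zip(map(tuple, np.atleast_2d(keys_b)), b))
        missing = sorted(set(map_a) ^ set(map_b))
        if missing:
            raise ValueError(f"unmatched pairing keys: {missing[:10]}")
        common = sorted(map_a)
        a = np.array([map_a[k] for k in common])
        b = np.array([map_b[k] for k in common])
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    return a, b


def paired_comparison(metric_a, metric_b, pairing=None) -> PairedTestResult:
    """Paired t-test of metric_a against metric_b.

    ``pairing`` is an optional (keys_a, keys_b) pair of key sequences used
    to align the vectors; mismatched keys raise with the missing pairs
    listed. With zero variance of differences the t statistic is
    undefined: the result carries the mean of differences and a
    degenerate-variance flag instead.
    """
    a, b = _align(metric_a, metric_b, pairing)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    d = a - b
    n = d.size
    mod = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTestResult(
            t=np.nan, df=n - 1, p=np.nan, mean_of_differences=mod, n_pairs=n,
            degenerate=True,
        )
    t, p = sps.ttest_rel(a, b)
    return PairedTestResult(
        t=float(t), df=n - 1, p=float(p), mean_of_differences=mod, n_pairs=n
    )


def percentage_contrast(metric_a, metric_b, pairing=None) -> float:
    """Mean pairwise percentage difference, 100 × (a − b)/b over pairs.

    Pairs with a zero denominator are excluded with a logged warning."""
    a, b = _align(metric_a, metric_b, pairing)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    nonzero = b != 0
    n_dropped = int(np.count_nonzero(~nonzero))
    if n_dropped:
        log.warning("percentage contrast dropped %d pair(s) with zero denominator", n_dropped)
    if not np.any(nonzero):
        raise ValueError("no pairs with nonzero denominator")
    return float(np.mean(100.0 * (a[nonzero] - b[nonzero]) / b[nonzero]))
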