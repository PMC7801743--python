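"""Correspondence between two numerosity maps.

Given two maps over the same vertex index space (haptic vs visual, or
one stimulus condition vs another), this module quantifies geometric
overlap (shared well-fitting vertices as a percentage of each map),
preference agreement in the shared vertices (Pearson r, Fisher
z-transformed for group statistics), test–retest reliability from
odd/even run splits, and group-level comparisons of correlation
distributions (one-way ANOVA on z-values with Bonferroni post hocs).
Overlap percentages are variance-stabilized by the arcsine-square-root
transform before group tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from numtopo.hrf import HrfParams
from numtopo.prf import DEFAULT_GRID, ParameterGrid, fit_many
from numtopo.select import R2_THRESHOLD
from numtopo.timeline import RunTimeline

__all__ = [
    "OverlapReport",
    "map_overlap",
    "shared_correlation",
    "testretest_split",
    "compare_correlation_groups",
    "arcsin_proportion",
]


@dataclass(frozen=True)
class OverlapReport:
    """Shared-vertex geometry between two thresholded maps."""

    shared: np.ndarray
    pct_of_a: float
    pct_of_b: float
    pct_mean: float
    n_a: int
    n_b: int


def map_overlap(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    r2_a: np.ndarray | None = None,
    r2_b: np.ndarray | None = None,
    threshold: float = R2_THRESHOLD,
) -> OverlapReport:
    """Overlap between two vertex sets, thresholded on variance explained.

    ``mask_a``/``mask_b`` are vertex index arrays; ``r2_a``/``r2_b`` are
    per-vertex variance-explained arrays over the common index space
    (omit to skip thresholding).  Overlap is reported relative to each
    map and as the mean of the two.
    """
    a = np.unique(np.asarray(mask_a, dtype=int))
    b = np.unique(np.asarray(mask_b, dtype=int))
    if r2_a is not None:
        a = a[np.asarray(r2_a)[a] > threshold]
    if r2_b is not None:
        b = b[np.asarray(r2_b)[b] > threshold]
    if a.size == 0 or b.size == 0:
        raise ValueError("a thresholded map is empty")
    shared = np.intersect1d(a, b)
    pct_a = 100.0 * shared.size / a.size
    pct_b = 100.0 * shared.size / b.size
    return OverlapReport(
        shared=shared,
        pct_of_a=pct_a,
        pct_of_b=pct_b,
        pct_mean=0.5 * (pct_a + pct_b),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def shared_correlation(pref_a: np.ndarray, pref_b: np.ndarray, shared: np.ndarray) -> tuple[float, float, float]:
    """Pearson correlation of preferences over shared vertices: (r, p, Fisher z)."""
    shared = np.asarray(shared, dtype=int)
    if shared.size < 3:
        raise ValueError("need at least 3 shared vertices")
    xa = np.asarray(pref_a, dtype=float)[shared]
    xb = np.asarray(pref_b, dtype=float)[shared]
    if xa.std() == 0 or xb.std() == 0:
        raise ValueError("zero preference variance in a map: correlation undefined")
    r, p = stats.pearsonr(xa, xb)
    return float(r), float(p), float(np.arctanh(r))


def testretest_split(
    runs: np.ndarray,
    timeline: RunTimeline,
    hrf: HrfParams | None = None,
    threshold: float = R2_THRESHOLD,
    grid: ParameterGrid = DEFAULT_GRID,
    dt: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """Test–retest reliability of preferred numerosity across run halves.

    ``runs`` is (n_runs, n_vertices, n_frames).  The pRF model is fit
    independently on the odd-run and even-run averages; preferences are
    correlated over vertices above the variance-explained threshold in
    the odd (reference) half.  Returns (fits_odd, fits_even, r, p).
    """
    runs = np.asarray(runs, dtype=float)
    if runs.ndim != 3 or runs.shape[0] < 2:
        raise ValueError("runs must be (n_runs >= 2, n_vertices, n_frames)")
    odd = runs[0::2].mean(axis=0)
    even = runs[1::2].mean(axis=0)
    fits_odd = fit_many(odd, timeline, hrf, grid, dt)
    fits_even = fit_many(even, timeline, hrf, grid, dt)
    mask = (fits_odd["r2"].to_numpy() > threshold) & ~fits_odd["degenerate"].to_numpy()
    if mask.sum() < 3:
        raise ValueError("fewer than 3 vertices above threshold in the reference half")
    r, p = stats.pearsonr(fits_odd["pref"].to_numpy()[mask], fits_even["pref"].to_numpy()[mask])
    return fits_odd, fits_even, float(r), float(p)


def compare_correlation_groups(groups: dict[str, np.ndarray]) -> dict:
    """Group comparison of correlation coefficients on the Fisher-z scale.

    Each group is a collection of per-map correlation coefficients.
    Coefficients with |r| = 1 (infinite z) are excluded with a warning.
    Returns the one-way ANOVA F and p across groups, all-pairs post hoc
    t-tests with Bonferroni-multiplied p-values, and per-group
    one-sample t-tests of z against 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    zs: dict[str, np.ndarray] = {}
    for name, rs in groups.items():
        rs = np.asarray(rs, dtype=float)
        bad = np.abs(rs) >= 1.0
        if bad.any():
            warnings.warn(f"group {name!r}: excluding {bad.sum()} coefficient(s) with |r| = 1")
            rs = rs[~bad]
        if rs.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 usable values")
        zs[name] = np.arctanh(rs)

    names = list(zs)
    f_stat, f_p = stats.f_oneway(*[zs[n] for n in names])

    pairs = list(itertools.combinations(names, 2))
    pair_rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(zs[a], zs[b])
        pair_rows.append((a, b, float(t), min(1.0, float(p) * len(pairs))))
    pairwise = pd.DataFrame(pair_rows, columns=["group_a", "group_b", "t", "p_bonferroni"])

    onesample = pd.DataFrame(
        [
            (n, zs[n].size, *(float(v) for v in stats.ttest_1samp(zs[n], 0.0)))
            for n in names
        ],
        columns=["group", "n", "t", "p"],
    )
    return {"anova_f": float(f_stat), "anova_p": float(f_p), "pairwise": pairwise, "one_sample": onesample}


def arcsin_proportion(p) -> np.ndarray | float:
    """Variance-stabilizing arcsine-square-root transform of a proportion."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out
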