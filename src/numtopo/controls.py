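"""Control analyses: hand-motion quantification and numerosity judgment.

The motion control asks whether finger motion during haptic exploration
varies with numerosity — if it did, "numerosity tuning" could simply be
motor. Glove sensor traces are cut into exploration epochs and each
epoch/finger is summarized by three metrics: the number of distinct
movements (signal peaks above a prominence threshold), the variation of
motion (signal STD), and the duration of motion (time between the first
and last supra-threshold change in sensor value, irrespective of start
and end posture).  Metrics averaged across fingers enter a two-way
repeated-measures ANOVA (stimulus condition x numerosity); evidence for
the null is quantified by a BIC-approximate Bayes factor, which is not
equivalent to a default-prior Bayesian ANOVA.

The behavioral control summarizes numerosity-judgment accuracy (mean
error rate per participant) and speed (per-participant median reaction
times), with Friedman tests across numerosities, pairwise chi-square
tests on pooled error counts (Bonferroni corrected), and Spearman
correlations of the per-participant profiles between modalities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import AnovaRM

from numtopo.timeline import RunTimeline

__all__ = [
    "epoch_metrics",
    "average_across_fingers",
    "motion_anova",
    "behavior_summary",
    "behavior_tests",
]

#: peak prominence threshold as a fraction of the epoch's signal range
PROMINENCE_FRACTION = 0.10
#: motion-duration threshold = this multiple of the median absolute
#: successive difference over quiescent (inter-epoch) samples
DURATION_NOISE_MULT = 3.0


def _finger_columns(trace: pd.DataFrame) -> list[str]:
    return [c for c in trace.columns if c != "time"]


def epoch_metrics(
    trace: pd.DataFrame,
    timeline: RunTimeline,
    prominence_fraction: float = PROMINENCE_FRACTION,
    duration_noise_mult: float = DURATION_NOISE_MULT,
    smooth_window: int | None = None,
) -> pd.DataFrame:
    """Per-epoch, per-finger motion metrics from a glove trace.

    ``trace`` has a ``time`` column (seconds, aligned to the timeline's
    retained frames) plus one column per sensor.  Epochs shorter than 3
    samples are flagged invalid and excluded from the metrics.  No
    smoothing is applied unless ``smooth_window`` (samples) is given.
    """
    t = trace["time"].to_numpy()
    if t.size < 2:
        raise ValueError("trace too short")
    rate = 1.0 / float(np.median(np.diff(t)))
    fingers = _finger_columns(trace)

    in_epoch = np.zeros(t.size, dtype=bool)
    for ev in timeline.events:
        in_epoch |= (t >= ev.onset) & (t < ev.offset)

    rows = []
    for col in fingers:
        x_full = trace[col].to_numpy(dtype=float)
        if smooth_window and smooth_window > 1:
            x_full = np.convolve(x_full, np.ones(smooth_window) / smooth_window, mode="same")
        quiescent = np.abs(np.diff(x_full[~in_epoch])) if (~in_epoch).any() else np.array([0.0])
        thr = duration_noise_mult * float(np.median(quiescent))
        for i, ev in enumerate(timeline.events):
            sel = (t >= ev.onset) & (t < ev.offset)
            x = x_full[sel]
            if x.size < 3:
                rows.append((i, ev.onset, ev.numerosity, ev.condition, col, np.nan, np.nan, np.nan, False))
                continue
            span = x.max() - x.min()
            if span <= 0:
                n_peaks = 0
            else:
                peaks, _ = signal.find_peaks(x, prominence=prominence_fraction * span)
                n_peaks = int(peaks.size)
            d = np.abs(np.diff(x))
            active = np.flatnonzero(d > thr)
            duration = float((active[-1] - active[0] + 1) / rate) if active.size else 0.0
            rows.append((i, ev.onset, ev.numerosity, ev.condition, col, n_peaks, float(x.std()), duration, True))
    return pd.DataFrame(
        rows,
        columns=["epoch", "onset", "numerosity", "condition", "finger", "n_peaks", "motion_std", "motion_duration_s", "valid"],
    )


def average_across_fingers(metrics: pd.DataFrame) -> pd.DataFrame:
    """Average the three motion metrics across fingers within each epoch."""
    ok = metrics[metrics["valid"]]
    return (
        ok.groupby(["epoch", "numerosity", "condition"], as_index=False)[["n_peaks", "motion_std", "motion_duration_s"]]
        .mean()
        .sort_values("epoch", ignore_index=True)
    )


def motion_anova(cell_data: pd.DataFrame, value: str = "n_peaks") -> dict:
    """Two-way repeated-measures ANOVA of a motion metric.

    ``cell_data`` holds one or more observations per participant x
    condition x numerosity cell (columns ``participant``, ``condition``,
    ``numerosity`` and the metric); observations are averaged to cell
    means first.  Returns the classical RM-ANOVA table plus a
    BIC-approximate Bayes factor BF01 for dropping the numerosity factor
    (BF01 > 1 favors the no-numerosity-effect model).  The BF01 is a BIC
    approximation, not a default-prior Bayesian ANOVA.
    """
    cells = (
        cell_data.groupby(["participant", "condition", "numerosity"], as_index=False)[value].mean()
    )
    pivot = cells.pivot_table(index="participant", columns=["condition", "numerosity"], values=value)
    if pivot.isna().any().any():
        missing = [str(c) for c in pivot.columns[pivot.isna().any()]]
        raise ValueError(f"missing cells for RM-ANOVA: {missing}")

    res = AnovaRM(cells, depvar=value, subject="participant", within=["condition", "numerosity"]).fit()
    table = res.anova_table

    d = cells.rename(columns={value: "y"})
    full = ols("y ~ C(participant) + C(condition) + C(numerosity)", data=d).fit()
    null = ols("y ~ C(participant) + C(condition)", data=d).fit()
    bf01 = float(np.exp((full.bic - null.bic) / 2.0))

    return {
        "table": table,
        "f_numerosity": float(table.loc["numerosity", "F Value"]),
        "p_numerosity": float(table.loc["numerosity", "Pr > F"]),
        "f_condition": float(table.loc["condition", "F Value"]),
        "p_condition": float(table.loc["condition", "Pr > F"]),
        "f_interaction": float(table.loc["condition:numerosity", "F Value"]),
        "p_interaction": float(table.loc["condition:numerosity", "Pr > F"]),
        "bf01_numerosity_bic_approx": bf01,
    }


def behavior_summary(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-numerosity error rates and reaction-time summaries.

    Returns ``per_participant`` (error rate % and median RT per
    participant x modality x condition x numerosity) and ``group``
    (participant-averaged error rate with SEM, mean of median RTs).
    """
    df = table.copy()
    df["error"] = (df["response"] != df["numerosity"]).astype(float)
    per = (
        df.groupby(["participant", "modality", "condition", "numerosity"], as_index=False)
        .agg(error_rate_pct=("error", lambda e: 100.0 * e.mean()), median_rt_s=("rt_s", "median"), n_trials=("error", "size"))
    )
    group = (
        per.groupby(["modality", "condition", "numerosity"], as_index=False)
        .agg(
            mean_error_pct=("error_rate_pct", "mean"),
            sem_error_pct=("error_rate_pct", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
            mean_median_rt_s=("median_rt_s", "mean"),
        )
    )
    return {"per_participant": per, "group": group}


def _friedman_rt(per: pd.DataFrame) -> tuple[float, float]:
    mat = per.pivot_table(index="participant", columns="numerosity", values="median_rt_s")
    if mat.isna().any().any():
        raise ValueError("unbalanced participant x numerosity RT table")
    if mat.shape[0] < 3:
        raise ValueError("Friedman test needs at least 3 participants")
    with np.errstate(invalid="ignore"):
        chi2, p = stats.friedmanchisquare(*[mat[c].to_numpy() for c in mat.columns])
    if np.isnan(chi2):  # all ranks tied within every participant
        return 0.0, 1.0
    return float(chi2), float(p)


def behavior_tests(table: pd.DataFrame) -> dict:
    """Statistical tests on a behavioral trial table.

    Per (modality, condition) group: a Friedman test of per-participant
    median RTs across numerosities, and pairwise chi-square tests on
    participant-pooled error counts with Bonferroni correction.  Between
    every pair of groups: Spearman correlations of the concatenated
    per-participant per-numerosity RT and error profiles.
    """
    summary = behavior_summary(table)
    per = summary["per_participant"]
    df = table.copy()
    df["error"] = (df["response"] != df["numerosity"]).astype(int)

    friedman_rows = []
    chi_frames = []
    for (mod, cond), sub in per.groupby(["modality", "condition"]):
        chi2, p = _friedman_rt(sub)
        friedman_rows.append((mod, cond, chi2, p))

        pooled = df[(df["modality"] == mod) & (df["condition"] == cond)].groupby("numerosity")["error"].agg(["sum", "size"])
        pairs = list(itertools.combinations(pooled.index, 2))
        for a, b in pairs:
            tbl = np.array(
                [
                    [pooled.loc[a, "sum"], pooled.loc[a, "size"] - pooled.loc[a, "sum"]],
                    [pooled.loc[b, "sum"], pooled.loc[b, "size"] - pooled.loc[b, "sum"]],
                ]
            )
            if tbl[:, 0].sum() == 0:  # no errors anywhere: chi-square undefined/zero
                chi, pr = 0.0, 1.0
            else:
                chi, pr, _, _ = stats.chi2_contingency(tbl, correction=False)
            chi_frames.append((mod, cond, a, b, float(chi), min(1.0, float(pr) * len(pairs))))
    friedman = pd.DataFrame(friedman_rows, columns=["modality", "condition", "chi2", "p"])
    error_pairwise = pd.DataFrame(
        chi_frames, columns=["modality", "condition", "numerosity_a", "numerosity_b", "chi2", "p_bonferroni"]
    )

    spearman_rows = []
    keys = sorted(per.groupby(["modality", "condition"]).groups)
    for (ka, kb) in itertools.combinations(keys, 2):
        a = per[(per["modality"] == ka[0]) & (per["condition"] == ka[1])].set_index(["participant", "numerosity"])
        b = per[(per["modality"] == kb[0]) & (per["condition"] == kb[1])].set_index(["participant", "numerosity"])
        common = a.index.intersection(b.index)
        if len(common) < 3:
            continue
        for measure in ("median_rt_s", "error_rate_pct"):
            va = a.loc[common, measure].to_numpy()
            vb = b.loc[common, measure].to_numpy()
            if np.std(va) == 0 or np.std(vb) == 0:
                rs, p = np.nan, np.nan
            else:
                rs, p = stats.spearmanr(va, vb)
            spearman_rows.append((f"{ka[0]}/{ka[1]}", f"{kb[0]}/{kb[1]}", measure, float(rs), float(p)))
    spearman = pd.DataFrame(spearman_rows, columns=["group_a", "group_b", "measure", "r_s", "p"])

    return {"friedman": friedman, "error_pairwise": error_pairwise, "spearman": spearman}
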