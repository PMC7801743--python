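"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the structure of the study's data at the level
the analysis consumes it: voxel time series following the log-Gaussian
numerosity pRF forward model (plus untuned "on-off" voxels and
pure-noise null voxels), triangulated cortical patches carrying a
monotone preferred-numerosity gradient between a low and a high border,
data-glove finger traces with numerosity-independent motion, and
behavioral trial tables with subitizing-range accuracy.  They make no
attempt at biophysical realism (no draining veins, no cortical folding,
no physiological noise spectra); what passing tests establish is that
the analysis recovers known parameters from data generated by its own
forward model, not that it is robust to every artifact of real fMRI.

All generators are pure functions of their parameters and an explicit
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from numtopo.hrf import HrfParams
from numtopo.prf import get_engine
from numtopo.surface import RoiMap, SurfacePatch
from numtopo.timeline import RunTimeline

__all__ = [
    "VoxelTruth",
    "RtParams",
    "simulate_voxel",
    "simulate_voxels",
    "simulate_runs",
    "simulate_patch",
    "simulate_glove",
    "bump_train",
    "simulate_behavior",
    "DEFAULT_NOISE_SD",
]

#: Default noise SD (signal units, for unit response amplitude).  Equal
#: to the SD of the noiseless tuned prediction on the haptic protocol at
#: unit amplitude, so the noiseless model explains roughly half the
#: variance of a simulated tuned voxel (R^2 ~ 0.5) — the regime of the
#: well-fitting map voxels this pipeline is meant for.
DEFAULT_NOISE_SD = 0.75


@dataclass(frozen=True)
class VoxelTruth:
    """Ground-truth generative parameters of one simulated voxel."""

    voxel_class: str  # "tuned" | "on_off" | "null"
    pref: float = 3.0
    sigma_log: float = 0.4
    amplitude: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.voxel_class not in ("tuned", "on_off", "null"):
            raise ValueError(f"unknown voxel class {self.voxel_class!r}")
        if self.pref <= 0 or self.sigma_log <= 0:
            raise ValueError("pref and sigma_log must be positive")


def _noiseless_series(timeline: RunTimeline, truth: VoxelTruth, hrf: HrfParams | None, dt: float | None) -> np.ndarray:
    engine = get_engine(timeline, hrf, dt)
    if truth.voxel_class == "tuned":
        pred = engine.predict(truth.pref, truth.sigma_log)
    elif truth.voxel_class == "on_off":
        pred = engine.predict_onoff()
    else:
        pred = np.zeros(engine.n_frames)
    return truth.baseline + truth.amplitude * pred


def _noise(n: int, noise_sd: float, ar1_rho: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not -1 < ar1_rho < 1:
        raise ValueError("|ar1_rho| must be < 1")
    w = rng.standard_normal(n) * noise_sd
    if ar1_rho == 0:
        return w
    e = np.empty(n)
    e[0] = w[0]
    c = np.sqrt(1 - ar1_rho**2)
    for t in range(1, n):
        e[t] = ar1_rho * e[t - 1] + c * w[t]
    return e


def simulate_voxel(
    timeline: RunTimeline,
    truth: VoxelTruth,
    hrf: HrfParams | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    ar1_rho: float = 0.0,
    seed: int = 0,
    dt: float | None = None,
) -> np.ndarray:
    """One voxel time series (length = retained frames) from the forward model."""
    rng = np.random.default_rng(seed)
    clean = _noiseless_series(timeline, truth, hrf, dt)
    return clean + _noise(clean.size, noise_sd, ar1_rho, rng)


def simulate_voxels(
    timeline: RunTimeline,
    truths: Sequence[VoxelTruth],
    hrf: HrfParams | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    ar1_rho: float = 0.0,
    seed: int = 0,
    dt: float | None = None,
) -> np.ndarray:
    """Stack of voxel series, one row per ground-truth entry."""
    rng = np.random.default_rng(seed)
    out = np.empty((len(truths), timeline.n_frames_retained))
    for i, truth in enumerate(truths):
        clean = _noiseless_series(timeline, truth, hrf, dt)
        out[i] = clean + _noise(clean.size, noise_sd, ar1_rho, rng)
    return out


def simulate_runs(
    timeline: RunTimeline,
    truth: VoxelTruth,
    n_runs: int,
    hrf: HrfParams | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    ar1_rho: float = 0.0,
    seed: int = 0,
    dt: float | None = None,
) -> np.ndarray:
    """Repeated runs of one voxel: (n_runs x frames), independent noise per run."""
    rng = np.random.default_rng(seed)
    clean = _noiseless_series(timeline, truth, hrf, dt)
    out = np.empty((n_runs, clean.size))
    for r in range(n_runs):
        out[r] = clean + _noise(clean.size, noise_sd, ar1_rho, rng)
    return out


def simulate_patch(
    n_rows: int,
    n_cols: int,
    spacing: float = 2.0,
    pref_range: tuple[float, float] = (1.0, 7.0),
    width_slope: float = 0.25,
    sigma_base: float = 0.35,
    pref_jitter: float = 0.0,
    seed: int = 0,
) -> tuple[SurfacePatch, RoiMap, pd.DataFrame]:
    """Regular triangulated strip with a log-spaced preference gradient.

    Preferred numerosity is log-spaced along the column axis from
    ``pref_range[0]`` (first column, the low border) to ``pref_range[1]``
    (last column, the high border), emulating a topographic map whose
    preference progresses monotonically between its end borders.  Tuning
    width follows ``sigma = sigma_base + width_slope * ln(pref)``, the
    widening-with-preference organization of such maps.  ``pref_jitter``
    adds multiplicative log-normal scatter to per-vertex preference.

    Returns the mesh, the ROI (all vertices, with first/last columns as
    the low/high borders), and a ground-truth table.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("n_rows and n_cols must be >= 2")
    low, high = pref_range
    if not 0 < low < high:
        raise ValueError("pref_range must satisfy 0 < low < high")
    rng = np.random.default_rng(seed)

    jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    verts = np.column_stack([jj.ravel() * spacing, ii.ravel() * spacing, np.zeros(n_rows * n_cols)])
    faces = []
    for i in range(n_rows - 1):
        for j in range(n_cols - 1):
            a = i * n_cols + j
            b = a + 1
            c = a + n_cols
            d = c + 1
            faces.append((a, b, c))
            faces.append((b, d, c))
    patch = SurfacePatch(vertices=verts, faces=np.asarray(faces))

    col_pref = np.geomspace(low, high, n_cols)
    pref = np.tile(col_pref, n_rows)
    if pref_jitter > 0:
        pref = pref * np.exp(rng.normal(0.0, pref_jitter, size=pref.size))
    sigma = sigma_base + width_slope * np.log(pref)

    members = np.arange(n_rows * n_cols)
    low_border = members[members % n_cols == 0]
    high_border = members[members % n_cols == n_cols - 1]
    roi = RoiMap(members=members, low_border=low_border, high_border=high_border)

    truth = pd.DataFrame(
        {
            "vertex": members,
            "voxel_class": "tuned",
            "pref": pref,
            "sigma_log": sigma,
            "amplitude": 1.0,
            "baseline": 0.0,
        }
    )
    return patch, roi, truth


def bump_train(n_samples: int, rate: float, k: int, rng: np.random.Generator | None = None,
               bump_width_s: float = 0.4, amp_range: tuple[float, float] = (0.3, 0.6)) -> np.ndarray:
    """``k`` non-overlapping half-sine motion bumps inside one epoch.

    Bump centers are evenly spread across the epoch (with optional
    random amplitudes when ``rng`` is given) so that each bump produces
    exactly one detectable peak.
    """
    out = np.zeros(n_samples)
    if k <= 0:
        return out
    w = max(3, int(round(bump_width_s * rate)))
    centers = ((np.arange(k) + 0.5) / k * n_samples).astype(int)
    for c in centers:
        amp = amp_range[0] if rng is None else rng.uniform(*amp_range)
        i0 = max(0, c - w // 2)
        i1 = min(n_samples, i0 + w)
        out[i0:i1] += amp * np.sin(np.linspace(0, np.pi, i1 - i0))
    return out


def simulate_glove(
    timeline: RunTimeline,
    rate: float = 52.0,
    motion_profile: float | Mapping[int, float] | Callable[[int], float] = 2.0,
    seed: int = 0,
    n_fingers: int = 5,
    noise_sd: float = 0.01,
    baseline_level: float = 0.5,
) -> pd.DataFrame:
    """Multichannel finger-sensor traces for one run.

    Inside each exploration epoch, each finger receives a Poisson number
    of smooth motion bumps with mean ``motion_profile`` (a constant, a
    per-numerosity mapping, or a callable); between epochs the sensors
    rest at ``baseline_level`` plus sensor noise.  A constant profile
    therefore yields epoch metrics that are independent of numerosity in
    expectation — the null hypothesis of the motion control analysis.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(timeline.retained_duration * rate))
    t = np.arange(n_samples) / rate

    if callable(motion_profile):
        profile = motion_profile
    elif isinstance(motion_profile, Mapping):
        profile = lambda n: motion_profile[n]  # noqa: E731
    else:
        profile = lambda n: float(motion_profile)  # noqa: E731

    data = {"time": t}
    for f in range(n_fingers):
        trace = np.full(n_samples, baseline_level)
        for ev in timeline.events:
            i0 = int(round(ev.onset * rate))
            i1 = min(int(round(ev.offset * rate)), n_samples)
            k = rng.poisson(profile(ev.numerosity))
            trace[i0:i1] += bump_train(i1 - i0, rate, k, rng)
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, size=n_samples)
        data[f"finger_{f + 1}"] = trace
    return pd.DataFrame(data)


@dataclass(frozen=True)
class RtParams:
    """Reaction-time generator: median RT = base + per_item * numerosity,
    with multiplicative log-normal noise of log-SD ``sigma_log``."""

    base: float = 0.8
    per_item: float = 0.35
    sigma_log: float = 0.25


def simulate_behavior(
    n_trials_per_numerosity: int = 20,
    subitizing_limit: int = 3,
    error_slope: float = 0.15,
    rt_params: RtParams = RtParams(),
    seed: int = 0,
    numerosities: Sequence[int] = tuple(range(1, 8)),
    participant: str = "p1",
    modality: str = "haptic",
    condition: str = "equal_size",
) -> pd.DataFrame:
    """Trial table of numerosity judgments for one participant.

    Judgment is error-free up to ``subitizing_limit`` (the subitizing
    range); above it, error probability grows linearly at
    ``error_slope`` per item.  Erroneous responses miss by one item.
    Reaction time increases with numerosity with log-normal scatter.
    """
    if n_trials_per_numerosity < 1:
        raise ValueError("n_trials_per_numerosity must be >= 1")
    rng = np.random.default_rng(seed)
    trials = np.repeat(list(numerosities), n_trials_per_numerosity)
    rng.shuffle(trials)
    rows = []
    lo, hi = min(numerosities), max(numerosities)
    for n in trials:
        p_err = float(np.clip(error_slope * (n - subitizing_limit), 0.0, 1.0))
        if rng.random() < p_err:
            candidates = [m for m in (n - 1, n + 1) if lo <= m <= hi]
            response = int(rng.choice(candidates))
        else:
            response = int(n)
        rt = (rt_params.base + rt_params.per_item * n) * float(np.exp(rng.normal(0.0, rt_params.sigma_log)))
        rows.append((participant, modality, condition, int(n), response, rt))
    return pd.DataFrame(rows, columns=["participant", "modality", "condition", "numerosity", "response", "rt_s"])
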