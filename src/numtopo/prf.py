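"""Numerosity population-receptive-field (pRF) model and fitting.

Each voxel's aggregate numerosity tuning is modelled as a Gaussian in
log-numerosity space with two parameters: preferred numerosity (the
Gaussian mean, reported in linear units) and tuning width (the Gaussian
standard deviation in log units, reported also as linear full width at
half maximum).  The predicted neural response to the stimulus sequence
is the tuning function evaluated at the presented numerosity (zero when
no stimulus is present), convolved with the HRF and sampled at the
scanner frame times.  Fitting is an exhaustive grid search over
(preference, width) candidates — amplitude and baseline solved by
ordinary least squares per candidate — followed by bounded Nelder–Mead
refinement of the best candidate.  Variance explained is 1 - RSS/TSS on
the training series, which with OLS scaling equals the squared
correlation between prediction and data.

The candidate grid deliberately extends well outside the presented
numerosity range (1–7) so that estimates inside the range are not an
artifact of a truncated search; out-of-range fits are removed later by
:func:`range_mask`.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from numtopo.hrf import HrfParams, two_gamma_hrf
from numtopo.timeline import RunTimeline, design_vector

__all__ = [
    "TuningFit",
    "ParameterGrid",
    "DEFAULT_GRID",
    "tuning_response",
    "fwhm_linear",
    "predict_bold",
    "PredictionEngine",
    "get_engine",
    "fit_prf",
    "fit_many",
    "estimate_subject_hrf",
    "range_mask",
    "write_fits",
    "read_fits",
]

#: half-width factor: the tuning function falls to half maximum at
#: ln(n) = ln(pref) +/- sigma_log * sqrt(2 ln 2)
_HALF_MAX_C = float(np.sqrt(2.0 * np.log(2.0)))


def tuning_response(n, pref, sigma_log):
    """Log-Gaussian tuning: ``exp(-(ln n - ln pref)^2 / (2 sigma^2))``.

    Natural logarithms throughout; any other base is absorbed by a
    rescaling of ``sigma_log``.  Accepts scalars or arrays (broadcast).
    """
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("numerosity must be positive")
    if np.any(np.asarray(pref) <= 0) or np.any(np.asarray(sigma_log) <= 0):
        raise ValueError("pref and sigma_log must be positive")
    z = (np.log(n) - np.log(pref)) / sigma_log
    return np.exp(-0.5 * z**2)


def fwhm_linear(pref: float, sigma_log: float) -> float:
    """Linear-units full width at half maximum of the log-Gaussian."""
    lp = np.log(pref)
    return float(np.exp(lp + _HALF_MAX_C * sigma_log) - np.exp(lp - _HALF_MAX_C * sigma_log))


@dataclass(frozen=True)
class TuningFit:
    """Per-voxel pRF estimate."""

    pref: float
    sigma_log: float
    fwhm_lin: float
    amplitude: float
    baseline: float
    r2: float
    degenerate: bool = False


@dataclass(frozen=True)
class ParameterGrid:
    """Log-spaced candidate grid for the exhaustive search stage."""

    pref_min: float = 0.5
    pref_max: float = 40.0
    n_pref: int = 60
    sigma_min: float = 0.05
    sigma_max: float = 3.0
    n_sigma: int = 40

    @functools.cached_property
    def prefs(self) -> np.ndarray:
        return np.geomspace(self.pref_min, self.pref_max, self.n_pref)

    @functools.cached_property
    def sigmas(self) -> np.ndarray:
        return np.geomspace(self.sigma_min, self.sigma_max, self.n_sigma)

    @functools.cached_property
    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        p, s = np.meshgrid(self.prefs, self.sigmas, indexing="ij")
        return p.ravel(), s.ravel()

    @property
    def log_bounds(self) -> list[tuple[float, float]]:
        return [
            (np.log(self.pref_min), np.log(self.pref_max)),
            (np.log(self.sigma_min), np.log(self.sigma_max)),
        ]


DEFAULT_GRID = ParameterGrid()


class PredictionEngine:
    """Cached forward model for one (timeline, HRF, dt) triple.

    Precomputes the high-resolution design and a sparse operator ``M``
    such that ``M @ neural_trace`` is the HRF-convolved prediction
    sampled at the retained frame times.  This makes per-candidate
    prediction a single sparse mat-vec, which is what keeps grid search
    and Nelder–Mead refinement cheap.
    """

    def __init__(self, timeline: RunTimeline, hrf: HrfParams | None = None, dt: float | None = None):
        if hrf is None:
            hrf = HrfParams()
        if dt is None:
            dt = timeline.natural_dt
        durations = [e.duration for e in timeline.events]
        if durations and dt > min(durations) + 1e-12:
            raise ValueError(f"dt={dt} is coarser than the shortest event ({min(durations)} s)")
        self.timeline = timeline
        self.hrf = hrf
        self.dt = dt
        _, values = design_vector(timeline, dt)
        self.present = ~np.isnan(values)
        self.log_design = np.where(self.present, np.log(np.where(self.present, values, 1.0)), 0.0)
        self.n_samples = values.size
        self.n_frames = timeline.n_frames_retained
        # dt-scaled kernel: M @ trace approximates the continuous
        # convolution, making predictions independent of the dt choice
        kernel = two_gamma_hrf(hrf, dt) * dt
        self._sampler = self._build_sampler(kernel)
        self._grid_cache: dict[ParameterGrid, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _build_sampler(self, kernel: np.ndarray) -> sparse.csr_matrix:
        s = int(round(self.timeline.tr / self.dt))
        L = kernel.size
        rows, cols, data = [], [], []
        for k in range(self.n_frames):
            top = k * s
            j0 = max(0, top - L + 1)
            j = np.arange(j0, min(top, self.n_samples - 1) + 1)
            rows.append(np.full(j.size, k))
            cols.append(j)
            data.append(kernel[top - j])
        return sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_frames, self.n_samples),
        )

    def neural_trace(self, pref: float, sigma_log: float) -> np.ndarray:
        z = (self.log_design - np.log(pref)) / sigma_log
        return np.where(self.present, np.exp(-0.5 * z**2), 0.0)

    def predict(self, pref: float, sigma_log: float) -> np.ndarray:
        """Unit-scale predicted BOLD series at the retained frame times."""
        return self._sampler @ self.neural_trace(pref, sigma_log)

    def predict_onoff(self) -> np.ndarray:
        """Prediction of the numerosity-blind on-off (presence) model."""
        return self._sampler @ self.present.astype(float)

    def grid_predictions(self, grid: ParameterGrid):
        """Standardized predictions for every grid candidate.

        Returns ``(z_pred, valid, raw)`` where ``z_pred`` is the
        (candidates x frames) matrix of zero-mean unit-norm predictions,
        ``valid`` flags candidates with non-constant predictions, and
        ``raw`` is the unstandardized prediction matrix.
        """
        if grid not in self._grid_cache:
            prefs, sigmas = grid.pairs
            z = (self.log_design[None, :] - np.log(prefs)[:, None]) / sigmas[:, None]
            traces = np.where(self.present[None, :], np.exp(-0.5 * z**2), 0.0)
            raw = (self._sampler @ traces.T).T
            centered = raw - raw.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(centered, axis=1)
            # candidates whose prediction is numerically flat (tuning so
            # narrow it responds to nothing presented) are no model at all
            valid = norms > 1e-6
            zp = np.zeros_like(centered)
            zp[valid] = centered[valid] / norms[valid, None]
            self._grid_cache[grid] = (zp, valid, raw)
        return self._grid_cache[grid]


@functools.lru_cache(maxsize=16)
def get_engine(timeline: RunTimeline, hrf: HrfParams | None = None, dt: float | None = None) -> PredictionEngine:
    return PredictionEngine(timeline, hrf, dt)


def predict_bold(
    timeline: RunTimeline,
    pref: float,
    sigma_log: float,
    hrf: HrfParams | None = None,
    dt: float | None = None,
) -> np.ndarray:
    """Predicted fMRI series (unit scale, before amplitude/baseline)."""
    if pref <= 0 or sigma_log <= 0:
        raise ValueError("pref and sigma_log must be positive")
    return get_engine(timeline, hrf, dt).predict(pref, sigma_log)


def _ols_scale(pred: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on (pred, 1): returns (amplitude, baseline, r2)."""
    pc = pred - pred.mean()
    yc = y - y.mean()
    vp = pc @ pc
    vy = yc @ yc
    if vp < 1e-20 or vy < 1e-20:
        return 0.0, float(y.mean()), 0.0
    amp = float((pc @ yc) / vp)
    base = float(y.mean() - amp * pred.mean())
    r2 = float((pc @ yc) ** 2 / (vp * vy))
    return amp, base, r2


def _fit_from_params(engine: PredictionEngine, pref: float, sigma_log: float, y: np.ndarray) -> TuningFit:
    pred = engine.predict(pref, sigma_log)
    amp, base, r2 = _ols_scale(pred, y)
    # a negative-going fit keeps its variance explained but is flagged:
    # tuned responses are modelled positive, so downstream selection
    # treats flagged fits as non-tuned, while the r2 null distribution
    # stays continuous (no artificial mass at zero)
    return TuningFit(
        pref=float(pref),
        sigma_log=float(sigma_log),
        fwhm_lin=fwhm_linear(pref, sigma_log),
        amplitude=amp,
        baseline=base,
        r2=r2,
        degenerate=amp <= 0,
    )


def _refine(engine: PredictionEngine, y: np.ndarray, pref0: float, sigma0: float, grid: ParameterGrid) -> tuple[float, float]:
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)

    def neg_corr(x):
        pred = engine.predict(np.exp(x[0]), np.exp(x[1]))
        pc = pred - pred.mean()
        pnorm = np.linalg.norm(pc)
        if pnorm < 1e-6:  # numerically flat prediction: worst score
            return 1.0
        return -float(pc @ yc) / (pnorm * ynorm)

    res = optimize.minimize(
        neg_corr,
        x0=[np.log(pref0), np.log(sigma0)],
        method="Nelder-Mead",
        bounds=grid.log_bounds,
        options={"xatol": 1e-6, "fatol": 1e-12, "maxfev": 300},
    )
    return float(np.exp(res.x[0])), float(np.exp(res.x[1]))


def fit_many(
    series: np.ndarray,
    timeline: RunTimeline,
    hrf: HrfParams | None = None,
    grid: ParameterGrid = DEFAULT_GRID,
    dt: float | None = None,
    refine: bool = True,
) -> pd.DataFrame:
    """Fit the pRF model to each row of a (voxels x frames) matrix.

    Grid search scores every candidate by its correlation with the
    series (equivalent to OLS R^2 with the amplitude sign constrained
    positive; negative-amplitude candidates are skipped).  The best
    candidate is refined by bounded Nelder–Mead on (ln pref, ln sigma).
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    engine = get_engine(timeline, hrf, dt)
    if series.shape[1] != engine.n_frames:
        raise ValueError(f"series has {series.shape[1]} frames, timeline retains {engine.n_frames}")
    zp, valid, _ = engine.grid_predictions(grid)
    prefs, sigmas = grid.pairs

    yc = series - series.mean(axis=1, keepdims=True)
    ynorm = np.linalg.norm(yc, axis=1)
    ok = ynorm > 1e-12
    zy = np.zeros_like(yc)
    zy[ok] = yc[ok] / ynorm[ok, None]

    corr = zp @ zy.T  # candidates x voxels
    corr[~valid, :] = -np.inf
    best = np.argmax(corr, axis=0)

    rows = []
    for v in range(series.shape[0]):
        y = series[v]
        if not ok[v]:
            rows.append(TuningFit(grid.prefs[0], grid.sigmas[0], fwhm_linear(grid.prefs[0], grid.sigmas[0]), 0.0, float(y.mean()), 0.0, True))
            continue
        c = best[v]
        if not np.isfinite(corr[c, v]):
            rows.append(TuningFit(grid.prefs[0], grid.sigmas[0], fwhm_linear(grid.prefs[0], grid.sigmas[0]), 0.0, float(y.mean()), 0.0, True))
            continue
        # argmax of corr prefers positive-amplitude candidates; when every
        # candidate correlates negatively the least-negative one is refined
        # and the resulting fit carries the degenerate (negative-going) flag
        pref, sig = prefs[c], sigmas[c]
        if refine:
            pref, sig = _refine(engine, y, pref, sig, grid)
        rows.append(_fit_from_params(engine, pref, sig, y))
    out = pd.DataFrame([f.__dict__ for f in rows])
    out.insert(0, "voxel", np.arange(len(rows)))
    return out


def fit_prf(
    series: np.ndarray,
    timeline: RunTimeline,
    hrf: HrfParams | None = None,
    grid: ParameterGrid = DEFAULT_GRID,
    dt: float | None = None,
    refine: bool = True,
) -> TuningFit:
    """Fit the pRF model to a single voxel time series."""
    df = fit_many(np.asarray(series)[None, :], timeline, hrf, grid, dt, refine)
    r = df.iloc[0]
    return TuningFit(
        pref=r.pref,
        sigma_log=r.sigma_log,
        fwhm_lin=r.fwhm_lin,
        amplitude=r.amplitude,
        baseline=r.baseline,
        r2=r.r2,
        degenerate=bool(r.degenerate),
    )


def estimate_subject_hrf(
    series: np.ndarray,
    fits: pd.DataFrame,
    timeline: RunTimeline,
    hrf0: HrfParams | None = None,
    dt: float | None = None,
    r2_min: float = 0.3,
    grid: ParameterGrid = DEFAULT_GRID,
) -> tuple[HrfParams, pd.DataFrame]:
    """Participant-level HRF re-estimation followed by a pRF refit.

    Holding each well-fitting voxel's (pref, sigma) fixed, the shared
    peak delay and undershoot ratio are optimized to maximize the summed
    variance explained; all voxels are then refit once with the new HRF.
    Only these two HRF parameters are free — they dominate the kernel's
    latency and post-stimulus dip, the features a timing change in the
    data can constrain.
    """
    if hrf0 is None:
        hrf0 = HrfParams()
    series = np.atleast_2d(np.asarray(series, dtype=float))
    sel = np.flatnonzero((fits["r2"].to_numpy() > r2_min) & ~fits["degenerate"].to_numpy())
    if sel.size == 0:
        warnings.warn("no voxel above the r2 threshold; returning the canonical HRF unchanged")
        return hrf0, fits

    base_engine = get_engine(timeline, hrf0, dt)
    traces = np.stack(
        [base_engine.neural_trace(fits["pref"].iat[v], fits["sigma_log"].iat[v]) for v in sel]
    )
    ys = series[sel]
    yc = ys - ys.mean(axis=1, keepdims=True)
    ynorm = np.linalg.norm(yc, axis=1)

    def neg_summed_r2(x):
        pd_, ratio = x
        try:
            eng = PredictionEngine(timeline, HrfParams(peak_delay=pd_, undershoot_ratio=ratio,
                                                       undershoot_delay=hrf0.undershoot_delay,
                                                       peak_dispersion=hrf0.peak_dispersion,
                                                       undershoot_dispersion=hrf0.undershoot_dispersion), dt)
        except ValueError:
            return 1e6
        preds = (eng._sampler @ traces.T).T
        pc = preds - preds.mean(axis=1, keepdims=True)
        pnorm = np.linalg.norm(pc, axis=1)
        num = np.einsum("ij,ij->i", pc, yc)
        denom = pnorm * ynorm
        r = np.where(denom > 1e-20, num / np.maximum(denom, 1e-20), 0.0)
        return -float(np.sum(r**2))

    res = optimize.minimize(
        neg_summed_r2,
        x0=[hrf0.peak_delay, hrf0.undershoot_ratio],
        method="Nelder-Mead",
        bounds=[(3.0, 10.0), (0.0, 0.9)],
        options={"xatol": 1e-4, "fatol": 1e-10, "maxfev": 200},
    )
    hrf_new = HrfParams(
        peak_delay=float(res.x[0]),
        undershoot_delay=hrf0.undershoot_delay,
        peak_dispersion=hrf0.peak_dispersion,
        undershoot_dispersion=hrf0.undershoot_dispersion,
        undershoot_ratio=float(res.x[1]),
    )
    refit = fit_many(series, timeline, hrf_new, grid, dt)
    return hrf_new, refit


def range_mask(fits: pd.DataFrame, low: float = 1.0, high: float = 7.0) -> np.ndarray:
    """True for fits whose preferred numerosity lies in [low, high]."""
    if low >= high:
        raise ValueError("low must be < high")
    pref = fits["pref"].to_numpy() if isinstance(fits, pd.DataFrame) else np.asarray(fits)
    return (pref >= low) & (pref <= high)


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, sep="\t", index=False)


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
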