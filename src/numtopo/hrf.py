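"""Hemodynamic response function (HRF).

The BOLD signal is modelled as the neural response convolved with a
canonical double-gamma HRF: the difference of two gamma densities, one
for the positive peak and one for the late undershoot, scaled to unit
peak.  The peak delay and undershoot ratio are the parameters refit per
participant (see :func:`numtopo.prf.estimate_subject_hrf`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HrfParams", "two_gamma_hrf", "HRF_DURATION_S"]

#: Length of the sampled kernel in seconds; the canonical response has
#: decayed to numerical zero well before this point.
HRF_DURATION_S = 32.0


@dataclass(frozen=True)
class HrfParams:
    """Parameters of the double-gamma HRF.

    Delays and dispersions are in seconds.  With dispersion 1 the peak
    of the positive gamma lies at ``peak_delay - 1`` (the gamma-density
    mode), so the canonical parameters place the peak near 5 s.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion", "undershoot_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 <= self.undershoot_ratio < 1:
            raise ValueError(f"undershoot_ratio must be in [0, 1), got {self.undershoot_ratio}")


def two_gamma_hrf(params: HrfParams | None = None, dt: float = 0.1) -> np.ndarray:
    """Sample the double-gamma HRF kernel at resolution ``dt``.

    Parameters
    ----------
    params
        HRF parameters; defaults to the canonical set.
    dt
        Sampling step in seconds.

    Returns
    -------
    numpy.ndarray
        Kernel sampled on ``[0, 32 s)``, scaled so its maximum is 1.
    """
    if params is None:
        params = HrfParams()
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    t = np.arange(0.0, HRF_DURATION_S, dt)
    peak = stats.gamma.pdf(t, a=params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion)
    under = stats.gamma.pdf(
        t, a=params.undershoot_delay / params.undershoot_dispersion, scale=params.undershoot_dispersion
    )
    kernel = peak - params.undershoot_ratio * under
    top = kernel.max()
    if top <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return kernel / top
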