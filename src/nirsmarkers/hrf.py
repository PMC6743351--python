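"""Canonical double-gamma hemodynamic response function.

The impulse response is the difference of two gamma densities (response
minus undershoot), normalized to unit peak.  ``peak_delay`` and
``undershoot_delay`` are the *modes* of the two gammas, i.e. the actual
times of the response peak and of the undershoot trough (defaults 6 s and
16 s, dispersion 1, peak-to-undershoot ratio 6); a gamma with mode m and
dispersion d has shape m/d + 1 and scale d.  All parameters configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HrfParams:
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay,
               self.peak_dispersion, self.undershoot_dispersion) <= 0:
            raise ValueError("HRF delays and dispersions must be positive")
        if self.ratio <= 0:
            raise ValueError("peak:undershoot ratio must be positive")


def _double_gamma(t: np.ndarray, p: HrfParams) -> np.ndarray:
    # shape m/d + 1 puts the gamma mode exactly at the configured delay
    peak = stats.gamma.pdf(t, p.peak_delay / p.peak_dispersion + 1,
                           scale=p.peak_dispersion)
    under = stats.gamma.pdf(t, p.undershoot_delay / p.undershoot_dispersion + 1,
                            scale=p.undershoot_dispersion)
    return peak - under / p.ratio


def canonical_hrf(params: HrfParams, t_grid: np.ndarray) -> np.ndarray:
    """Sample the canonical HRF on a uniform grid starting at 0, unit peak.

    Raises if the grid is non-uniform.  An empty grid returns an empty array.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        return np.empty(0)
    if t[0] != 0:
        raise ValueError("t_grid must start at 0")
    if t.size > 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("t_grid must be uniformly sampled")
    h = _double_gamma(t, params)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def hrf_zero_crossing(params: HrfParams = HrfParams(), *,
                      resolution: float = 1e-4, t_max: float = 60.0) -> float:
    """First zero crossing of the HRF after its peak, located numerically.

    This marks the end of the positive lobe; for a sustained boxcar stimulus
    the convolved block response attains its maximum here (its derivative is
    the HRF itself while the stimulus is still on).
    """
    t = np.arange(0.0, t_max, resolution)
    h = _double_gamma(t, params)
    i_peak = int(np.argmax(h))
    after = np.nonzero(h[i_peak:] <= 0)[0]
    if after.size == 0:
        raise ValueError("no zero crossing within t_max")
    return float(t[i_peak + after[0]])
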