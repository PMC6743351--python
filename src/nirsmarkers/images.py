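"""Image biomarkers: topographic t-maps and channel correlation maps.

A t-map is the vector of per-channel GLM t-values; rendered topographically
(inverse-distance-weighted interpolation over the probe plane) it becomes a
48x48 raster for CNN input.  The correlation map is the 48x48 Pearson
correlation matrix of channel dHbO series over the task window and feeds
the CNN un-rendered (it is natively 48x48).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .glm import GlmFit
from .paradigm import N_CHANNELS, ProbeLayout

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopoImage:
    raster: np.ndarray
    extent: tuple[float, float, float, float]   # (xmin, xmax, ymin, ymax)
    mode: str = "idw"


def make_tmap(fits: list[GlmFit]) -> np.ndarray:
    """Vector of t-values in ascending channel order (one fit per channel)."""
    if len(fits) != N_CHANNELS:
        raise ValueError(f"need {N_CHANNELS} fits, got {len(fits)}")
    return np.array([f.tvalue for f in fits])


def render_topo(values: np.ndarray, layout: ProbeLayout, size: int = 48, *,
                power: float = 2.0) -> TopoImage:
    """Inverse-distance-weighted interpolation onto a size x size raster.

    The raster covers the probe's bounding box; a pixel coinciding with a
    channel takes that channel's value exactly.  Linear in the values, so
    doubling every channel value doubles every pixel.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (N_CHANNELS,):
        raise ValueError("one value per channel required")
    pos = layout.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    if d2.min() == 0:
        raise ValueError("coincident channel coordinates")
    xmin, ymin = pos.min(axis=0)
    xmax, ymax = pos.max(axis=0)
    gx = np.linspace(xmin, xmax, size)
    gy = np.linspace(ymax, ymin, size)   # row 0 at the top
    X, Y = np.meshgrid(gx, gy)
    pix = np.stack([X.ravel(), Y.ravel()], axis=1)
    dist = np.sqrt(((pix[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    raster = np.empty(pix.shape[0])
    exact = dist.min(axis=1) == 0
    if exact.any():
        raster[exact] = values[np.argmin(dist[exact], axis=1)]
    w = 1.0 / np.power(dist[~exact], power)
    raster[~exact] = (w @ values) / w.sum(axis=1)
    return TopoImage(raster=raster.reshape(size, size),
                     extent=(float(xmin), float(xmax), float(ymin), float(ymax)))


def tmap_outer(tvalues: np.ndarray) -> np.ndarray:
    """Alternative 48x48 "matrix" rendering: normalized outer product t t^T."""
    t = np.asarray(tvalues, dtype=float)
    norm = np.abs(t).max()
    if norm == 0:
        return np.zeros((t.size, t.size))
    u = t / norm
    return np.outer(u, u)


def correlation_map(epochs: EpochSet, window: tuple[float, float] = (0.0, 60.0),
                    *, trial: int | None = None) -> np.ndarray:
    """Pearson correlation of every channel pair's dHbO over the window.

    ``trial`` selects a single trial; by default trials are concatenated.
    Zero-variance channels get NaN rows/columns (logged); the diagonal is 1.
    """
    sl = epochs.window_slice(*window)
    if trial is None:
        data = np.concatenate([epochs.hbo[k, :, sl] for k in range(epochs.n_trials)],
                              axis=1)
    else:
        data = epochs.hbo[trial, :, sl]
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples in the window")
    sd = data.std(axis=1)
    dead = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.corrcoef(data)
    if dead.any():
        logger.warning("zero-variance channels in correlation map: %s",
                       [int(c) + 1 for c in np.nonzero(dead)[0]])
        cm[dead, :] = np.nan
        cm[:, dead] = np.nan
    np.fill_diagonal(cm, 1.0)
    ok = ~np.isnan(cm)
    cm[ok] = np.clip(cm[ok], -1.0, 1.0)
    return cm
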