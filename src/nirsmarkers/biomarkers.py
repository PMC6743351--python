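"""The 15-digital-biomarker battery computed on ROI-channel epochs.

Biomarkers 1-5 are mean changes of dHbO/dHbR between a task window and the
10 s pre-task baseline; 6-12 are least-squares slopes over fixed windows of
the rising, plateau and recovery phases (per second); 13 is the time to the
dHbO peak; 14-15 are the skewness and (non-excess, biased) kurtosis of dHbO
over 5-65 s.

Mean change supports two forms.  ``relative=True`` is the textbook relative
change ``(task mean - baseline mean) / baseline mean``; it is undefined when
the baseline mean is near zero (guard ``eps``), which is the normal state of
band-pass-filtered data.  The battery therefore defaults to the plain
difference ``task mean - baseline mean``, whose magnitudes are on the
concentration scale.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .containers import EpochSet
from .glm import RoiSelection
from .paradigm import region_of_channel
from .preprocess import trial_average

logger = logging.getLogger(__name__)

BASELINE_WINDOW = (-10.0, 0.0)
PEAK_SEARCH_WINDOW = (0.0, 60.0)
BASELINE_EPS = 1e-12


@dataclass(frozen=True)
class BiomarkerSpec:
    id: int
    name: str
    signal: str                      # "hbo" | "hbr"
    kind: str                        # mean-change | slope | peak-time | skewness | kurtosis
    window: "tuple[float, float] | str"   # (t1, t2) seconds or "0-peak"
    relative: bool = False           # mean-change only


def default_biomarkers(relative_mean_change: bool = False) -> tuple[BiomarkerSpec, ...]:
    """The battery's 15 biomarkers in their canonical order."""
    r = relative_mean_change
    return (
        BiomarkerSpec(1, "MHbO (5-65 s)", "hbo", "mean-change", (5, 65), r),
        BiomarkerSpec(2, "MHbR (5-65 s)", "hbr", "mean-change", (5, 65), r),
        BiomarkerSpec(3, "MHbO (5-25 s)", "hbo", "mean-change", (5, 25), r),
        BiomarkerSpec(4, "MHbR (5-25 s)", "hbr", "mean-change", (5, 25), r),
        BiomarkerSpec(5, "MHbO (0-peak)", "hbo", "mean-change", "0-peak", r),
        BiomarkerSpec(6, "SHbO (5-15 s)", "hbo", "slope", (5, 15)),
        BiomarkerSpec(7, "SHbR (5-15 s)", "hbr", "slope", (5, 15)),
        BiomarkerSpec(8, "SHbO (20-60 s)", "hbo", "slope", (20, 60)),
        BiomarkerSpec(9, "SHbR (20-60 s)", "hbr", "slope", (20, 60)),
        BiomarkerSpec(10, "SHbO (60-70 s)", "hbo", "slope", (60, 70)),
        BiomarkerSpec(11, "SHbR (60-70 s)", "hbr", "slope", (60, 70)),
        BiomarkerSpec(12, "SHbO (0-peak)", "hbo", "slope", "0-peak"),
        BiomarkerSpec(13, "Peak time (s)", "hbo", "peak-time", PEAK_SEARCH_WINDOW),
        BiomarkerSpec(14, "Skewness (5-65 s)", "hbo", "skewness", (5, 65)),
        BiomarkerSpec(15, "Kurtosis (5-65 s)", "hbo", "kurtosis", (5, 65)),
    )


def _window_values(times: np.ndarray, values: np.ndarray,
                   window: tuple[float, float]) -> np.ndarray:
    t1, t2 = window
    i1 = int(np.searchsorted(times, t1 - 1e-9))
    i2 = int(np.searchsorted(times, t2 - 1e-9))
    return values[i1:i2]


def mean_change(times: np.ndarray, values: np.ndarray,
                window: tuple[float, float], *,
                baseline_window: tuple[float, float] = BASELINE_WINDOW,
                relative: bool = True, eps: float = BASELINE_EPS) -> float:
    """Task-window mean minus baseline mean, optionally divided by baseline.

    Returns NaN ("degenerate baseline") when ``relative`` and the baseline
    mean's magnitude is below ``eps``.
    """
    task = _window_values(times, values, window)
    base = _window_values(times, values, baseline_window)
    if task.size == 0 or base.size == 0:
        raise ValueError("window outside the epoch")
    diff = float(task.mean() - base.mean())
    if not relative:
        return diff
    b = float(base.mean())
    if abs(b) < eps:
        return float("nan")
    return diff / b


def slope(times: np.ndarray, values: np.ndarray,
          window: tuple[float, float]) -> float:
    """Degree-1 least-squares slope of value against time, per second."""
    t = _window_values(times, times, window)
    y = _window_values(times, values, window)
    if t.size < 2:
        raise ValueError("slope window needs at least 2 samples")
    return float(np.polyfit(t, y, 1)[0])


class PeakResult(NamedTuple):
    time: float
    boundary: bool   # True when no interior local maximum existed


def peak_time(times: np.ndarray, values: np.ndarray,
              search_window: tuple[float, float] = PEAK_SEARCH_WINDOW,
              ) -> PeakResult:
    """Time of the largest local maximum within the search window.

    Falls back to the window argmax (flagged as a boundary peak) when the
    signal is monotone over the window.
    """
    t = _window_values(times, times, search_window)
    y = _window_values(times, values, search_window)
    if t.size == 0:
        raise ValueError("empty peak search window")
    if np.all(np.isnan(y)):
        raise ValueError("all-missing epoch")
    peaks, _ = sp_signal.find_peaks(y)
    if peaks.size:
        best = peaks[np.argmax(y[peaks])]
        return PeakResult(float(t[best]), False)
    return PeakResult(float(t[np.argmax(y)]), True)


def shape_moment(times: np.ndarray, values: np.ndarray, moment: str,
                 window: tuple[float, float] = (5.0, 65.0)) -> float:
    """Biased skewness or non-excess kurtosis (Gaussian -> 3) over a window."""
    y = _window_values(times, values, window)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y) == 0:
        return float("nan")
    if moment == "skewness":
        return float(stats.skew(y, bias=True))
    if moment == "kurtosis":
        return float(stats.kurtosis(y, fisher=False, bias=True))
    raise ValueError(f"unknown moment {moment!r}")


def _evaluate(spec: BiomarkerSpec, times: np.ndarray, hbo: np.ndarray,
              hbr: np.ndarray) -> tuple[float, str]:
    """Evaluate one biomarker on one (trial, channel) epoch pair."""
    values = hbo if spec.signal == "hbo" else hbr
    window = spec.window
    if window == "0-peak":
        # the window end is always the dHbO peak, also for HbR biomarkers
        pk = peak_time(times, hbo)
        window = (0.0, pk.time)
        if _window_values(times, times, window).size < 2:
            return float("nan"), "peak too early"
    if spec.kind == "mean-change":
        v = mean_change(times, values, window, relative=spec.relative)
        return v, ("degenerate baseline" if np.isnan(v) else "")
    if spec.kind == "slope":
        return slope(times, values, window), ""
    if spec.kind == "peak-time":
        pk = peak_time(times, values, spec.window)
        return pk.time, ("boundary peak" if pk.boundary else "")
    if spec.kind in ("skewness", "kurtosis"):
        v = shape_moment(times, values, spec.kind, window)
        return v, ("zero variance" if np.isnan(v) else "")
    raise ValueError(f"unknown biomarker kind {spec.kind!r}")


def extract_battery(epoch_sets: "EpochSet | list[EpochSet]",
                    roi: "RoiSelection | dict[str, RoiSelection]",
                    specs: tuple[BiomarkerSpec, ...] | None = None, *,
                    trials_averaged: bool = False) -> pd.DataFrame:
    """Long-format biomarker table over (subject, task, trial, ROI channel).

    ``roi`` is either one selection applied to every epoch set or a mapping
    from subject id to that subject's selection.  The result has one row per
    (subject, group, task, region, trial, channel, biomarker); missing values
    carry a reason code.  Repeated calls on the same inputs agree bitwise.
    """
    if isinstance(epoch_sets, EpochSet):
        epoch_sets = [epoch_sets]
    if specs is None:
        specs = default_biomarkers()
    rows: list[dict] = []
    for es in epoch_sets:
        sel = roi[es.subject] if isinstance(roi, dict) else roi
        if not sel.channels:
            logger.warning("empty ROI for subject %s task %s; skipped",
                           es.subject, es.task)
            continue
        src = trial_average(es) if trials_averaged else es
        for trial in range(src.n_trials):
            for ch in sel.channels:
                hbo = src.hbo[trial, ch - 1]
                hbr = src.hbr[trial, ch - 1]
                for spec in specs:
                    value, reason = _evaluate(spec, src.times, hbo, hbr)
                    rows.append(dict(
                        subject=es.subject, group=es.group, task=es.task,
                        region=region_of_channel(ch), trial=trial + 1,
                        channel=ch, biomarker=spec.id, name=spec.name,
                        value=value, reason=reason))
    cols = ["subject", "group", "task", "region", "trial", "channel",
            "biomarker", "name", "value", "reason"]
    return pd.DataFrame(rows, columns=cols)
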