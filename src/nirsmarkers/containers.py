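"""In-memory containers for recordings and epochs.

Arrays are stored time-major: ``(n_samples, n_channels)`` for recordings and
``(n_trials, n_channels, n_times)`` for epoch sets.  Channels are 1-based
ids stored in ascending order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class RawIntensity:
    """Two-wavelength optical intensities for one subject/task session.

    ``data`` has shape (n_samples, n_channels, 2) with the last axis ordered
    as the ``wavelengths`` tuple.  ``baseline`` optionally carries the known
    reference intensity I0 per channel/wavelength (set by the simulator so
    that optical-density conversion is exact); when absent, I0 is estimated
    from an initial rest window.
    """

    data: np.ndarray
    fs: float
    wavelengths: tuple[float, float] = (780.0, 850.0)
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    task: str = ""
    subject: str = ""
    group: str = ""
    baseline: np.ndarray | None = None  # (n_channels, 2)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 2:
            raise ValueError("intensity data must be (n_samples, n_channels, 2)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class HemoRecording:
    """Chromophore concentration-change time series with paradigm annotations.

    ``hbo``/``hbr`` share shape (n_samples, n_channels); ``onsets`` are task
    onset times in seconds from the start of the recording.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    task: str = ""
    subject: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.hbo.shape != self.hbr.shape or self.hbo.ndim != 2:
            raise ValueError("hbo and hbr must share shape (n_samples, n_channels)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.onsets.size:
            if np.any(np.diff(self.onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if self.onsets[0] < 0 or self.onsets[-1] > self.duration:
                raise ValueError("onsets must lie inside the recording")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **kw) -> "HemoRecording":
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Baseline-anchored trial windows for one subject/task session.

    ``hbo``/``hbr`` have shape (n_trials, n_channels, n_times) on the shared
    relative time grid ``times`` (t = 0 is task onset).
    """

    hbo: np.ndarray
    hbr: np.ndarray
    times: np.ndarray
    fs: float
    task: str = ""
    subject: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.hbo.shape != self.hbr.shape or self.hbo.ndim != 3:
            raise ValueError("epochs must be (n_trials, n_channels, n_times)")
        if self.times.shape != (self.hbo.shape[2],):
            raise ValueError("times must match the epoch length")

    @property
    def n_trials(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    def signal(self, name: str) -> np.ndarray:
        if name in ("hbo", "HbO"):
            return self.hbo
        if name in ("hbr", "HbR"):
            return self.hbr
        raise ValueError(f"unknown signal {name!r}")

    def window_slice(self, t1: float, t2: float) -> slice:
        """Sample slice for the half-open window [t1, t2) in seconds."""
        i1 = int(np.searchsorted(self.times, t1 - 1e-9))
        i2 = int(np.searchsorted(self.times, t2 - 1e-9))
        return slice(i1, i2)
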