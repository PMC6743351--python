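"""Experimental paradigm and probe geometry.

The block paradigm alternates 60 s of task with 30 s of rest, three trials
per task, for three mental tasks (N-back, Stroop, verbal fluency).  The
probe is a 48-channel long-separation (3 cm) prefrontal montage sampled at
8.138 Hz: channels 1-16 cover the right PFC, 17-32 the middle PFC and
33-48 the left PFC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_FS = 8.138
TASKS = ("N-back", "Stroop", "VFT")
REGIONS = ("right", "middle", "left")

N_CHANNELS = 48
_CHANNELS_PER_REGION = 16


@dataclass(frozen=True)
class ParadigmSpec:
    """Block paradigm: task/rest timing and the epoch window convention.

    Epochs are anchored on task onsets: the grid runs from ``epoch_window[0]``
    (-10 s, pre-task baseline) to ``epoch_window[1]`` (+70 s).  Windows given
    in seconds are interpreted half-open ``[t1, t2)`` when converted to
    samples; the baseline window ``[-10, 0)`` precedes every onset.
    """

    tasks: tuple[str, ...] = TASKS
    n_trials: int = 3
    task_duration: float = 60.0
    rest_duration: float = 30.0
    pre_rest: float = 30.0
    baseline_window: tuple[float, float] = (-10.0, 0.0)
    epoch_window: tuple[float, float] = (-10.0, 70.0)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.task_duration <= 0:
            raise ValueError("task_duration must be positive")
        if not self.baseline_window[0] < self.baseline_window[1] <= 0:
            raise ValueError("baseline window must precede the onset")
        if self.epoch_window[0] > self.baseline_window[0]:
            raise ValueError("epoch window must contain the baseline window")

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def onsets(self) -> np.ndarray:
        """Task onsets (s) within one task session, relative to session start."""
        period = self.task_duration + self.rest_duration
        return self.pre_rest + period * np.arange(self.n_trials)

    def session_duration(self) -> float:
        """Total duration (s) of one task session, including the tail rest."""
        return self.pre_rest + self.n_trials * (self.task_duration + self.rest_duration)


@dataclass(frozen=True)
class ProbeLayout:
    """48-channel planar probe with region labels.

    ``positions`` are planar coordinates in arbitrary units; ``channels`` are
    1-based ids in ascending order, matching the device's channel numbering.
    """

    channels: tuple[int, ...]
    positions: np.ndarray  # (n_channels, 2)
    regions: tuple[str, ...]
    distance_cm: float = 3.0

    def __post_init__(self) -> None:
        if len(self.channels) != N_CHANNELS:
            raise ValueError(f"layout must have exactly {N_CHANNELS} channels")
        if self.positions.shape != (N_CHANNELS, 2):
            raise ValueError("positions must be (48, 2)")
        if len(self.regions) != N_CHANNELS:
            raise ValueError("one region label per channel required")

    def region_of(self, channel: int) -> str:
        return self.regions[self.channels.index(channel)]

    def channels_in(self, region: str) -> tuple[int, ...]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return tuple(c for c, r in zip(self.channels, self.regions) if r == region)


def region_of_channel(channel: int) -> str:
    """Region label for a 1-based channel id (1-16 right, 17-32 middle, 33-48 left)."""
    if not 1 <= channel <= N_CHANNELS:
        raise ValueError(f"channel {channel} outside 1..{N_CHANNELS}")
    return REGIONS[(channel - 1) // _CHANNELS_PER_REGION]


def default_layout() -> ProbeLayout:
    """Default probe layout: three 4x4 channel blocks across the forehead.

    The true headset geometry is device-specific; this layout preserves what
    the analysis relies on -- region membership, distinct planar positions
    and a 3 cm source-detector separation -- on a regular grid (right PFC at
    negative x, left PFC at positive x, mirroring a front view).
    """
    channels = tuple(range(1, N_CHANNELS + 1))
    regions = tuple(region_of_channel(c) for c in channels)
    positions = np.empty((N_CHANNELS, 2))
    block_offset = {"right": -6.0, "middle": 0.0, "left": 6.0}
    for i, (ch, reg) in enumerate(zip(channels, regions)):
        k = (ch - 1) % _CHANNELS_PER_REGION
        row, col = divmod(k, 4)
        positions[i] = (block_offset[reg] + (col - 1.5) * 1.2, (1.5 - row) * 1.2)
    return ProbeLayout(channels=channels, positions=positions, regions=regions)
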