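"""Synthetic fNIRS cohort generator.

Emulates the study conditions the analysis assumes: a 15 MCI / 9 HC cohort,
48 prefrontal channels at 8.138 Hz, a 3-task x 3-trial block paradigm
(60 s task / 30 s rest), group-dependent response amplitude and onset
latency, regional activation patterns (HC larger and earlier than MCI in the
left PFC, matched elsewhere), HbO/HbR anticoupling, and physiological noise
(cardiac, respiration, Mayer waves, random-walk drift, measurement noise).

Active channels carry ``amplitude * (h (*) s)(t - latency)`` in dHbO with the
block response normalized to unit peak, so ``amplitude`` is the peak
concentration change; dHbR is ``hbr_ratio`` times the clean dHbO response
plus its own independent noise.  Inactive channels carry noise only.  Equal
seeds produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import HemoRecording, RawIntensity
from .hrf import HrfParams, canonical_hrf
from .mbll import MbllParams, hemo_to_intensity
from .paradigm import (DEFAULT_FS, N_CHANNELS, REGIONS, ParadigmSpec,
                       region_of_channel)

_CONC = 1e-6  # working concentration scale (arbitrary molar-change unit)


def _default_amplitudes() -> dict[tuple[str, str], float]:
    # HC above MCI in the left PFC with an earlier rise; middle/right matched.
    return {
        ("HC", "left"): 1.0 * _CONC, ("MCI", "left"): 0.5 * _CONC,
        ("HC", "middle"): 0.6 * _CONC, ("MCI", "middle"): 0.6 * _CONC,
        ("HC", "right"): 0.6 * _CONC, ("MCI", "right"): 0.6 * _CONC,
    }


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological and measurement noise, per component (freq Hz, amplitude)."""

    cardiac: tuple[float, float] = (1.1, 0.2 * _CONC)
    respiration: tuple[float, float] = (0.25, 0.15 * _CONC)
    mayer: tuple[float, float] = (0.1, 0.1 * _CONC)
    drift: float = 0.01 * _CONC   # random-walk step SD per sample
    white: float = 0.1 * _CONC    # measurement noise SD

    def __post_init__(self) -> None:
        for f, a in (self.cardiac, self.respiration, self.mayer):
            if f <= 0:
                raise ValueError("noise frequencies must be positive")
            if a < 0:
                raise ValueError("noise amplitudes must be non-negative")
        if self.drift < 0 or self.white < 0:
            raise ValueError("noise amplitudes must be non-negative")

    @classmethod
    def quiet(cls) -> "NoiseSpec":
        return cls(cardiac=(1.1, 0.0), respiration=(0.25, 0.0),
                   mayer=(0.1, 0.0), drift=0.0, white=0.0)


@dataclass(frozen=True)
class CohortSpec:
    n_mci: int = 15
    n_hc: int = 9
    fs: float = DEFAULT_FS
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    amplitude_by_group_region: dict[tuple[str, str], float] = field(
        default_factory=_default_amplitudes)
    latency_by_group: dict[str, float] = field(
        default_factory=lambda: {"MCI": 2.0, "HC": 0.0})
    hbr_ratio: float = -1.0 / 3.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    active_channel_fraction: float = 0.5
    hrf: HrfParams = field(default_factory=HrfParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mci < 1 or self.n_hc < 1:
            raise ValueError("both groups need at least one subject")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 < self.active_channel_fraction <= 1:
            raise ValueError("active_channel_fraction must be in (0, 1]")
        for amp in self.amplitude_by_group_region.values():
            if not np.isfinite(amp):
                raise ValueError("amplitudes must be finite")


@dataclass
class GroundTruth:
    """Injected truth: one row per (subject, channel, task), plus group labels."""

    table: pd.DataFrame
    groups: dict[str, str]

    def active_channels(self, subject: str, task: str) -> tuple[int, ...]:
        t = self.table
        sel = t[(t.subject == subject) & (t.task == task) & t.active]
        return tuple(int(c) for c in sorted(sel.channel))


def block_regressor(paradigm: ParadigmSpec, fs: float, n_samples: int,
                    hrf: HrfParams = HrfParams(), *, latency: float = 0.0,
                    ) -> np.ndarray:
    """Unit-peak block response h (*) s over a full session timeline."""
    t_h = np.arange(0.0, 32.0, 1.0 / fs)
    h = canonical_hrf(hrf, t_h)
    box = np.zeros(n_samples)
    for onset in paradigm.onsets():
        i0 = int(round((onset + latency) * fs))
        i1 = min(n_samples, i0 + int(round(paradigm.task_duration * fs)))
        if i0 < n_samples:
            box[max(i0, 0):i1] = 1.0
    resp = np.convolve(box, h)[:n_samples]
    # normalize by the single-block peak so `amplitude` is the peak dHbO
    single = np.convolve(np.ones(int(round(paradigm.task_duration * fs))), h)
    peak = single.max()
    return resp / peak if peak > 0 else resp


def _noise(rng: np.random.Generator, spec: NoiseSpec, t: np.ndarray,
           n_channels: int) -> np.ndarray:
    n = t.size
    out = np.zeros((n, n_channels))
    for f, a in (spec.cardiac, spec.respiration, spec.mayer):
        if a > 0:
            phase = rng.uniform(0, 2 * np.pi, size=n_channels)
            out += a * np.sin(2 * np.pi * f * t[:, None] + phase[None, :])
    if spec.drift > 0:
        out += np.cumsum(rng.normal(0, spec.drift, size=(n, n_channels)), axis=0)
    if spec.white > 0:
        out += rng.normal(0, spec.white, size=(n, n_channels))
    return out


def generate_cohort(spec: CohortSpec, mbll: MbllParams = MbllParams(), *,
                    tasks: tuple[str, ...] | None = None,
                    ) -> tuple[list[RawIntensity], list[HemoRecording], GroundTruth]:
    """Generate raw intensities and hemodynamic recordings for a full cohort.

    Returns one ``RawIntensity`` and one ``HemoRecording`` per subject and
    task (ordered subject-major), plus the injected ground truth.  ``tasks``
    restricts generation to a subset of the paradigm's tasks.
    """
    rng = np.random.default_rng(spec.seed)
    paradigm = spec.paradigm
    tasks = paradigm.tasks if tasks is None else tasks
    n_samples = int(round(paradigm.session_duration() * spec.fs))
    t = np.arange(n_samples) / spec.fs
    onsets = paradigm.onsets()

    subjects = ([(f"MCI{i + 1:02d}", "MCI") for i in range(spec.n_mci)]
                + [(f"HC{i + 1:02d}", "HC") for i in range(spec.n_hc)])

    n_active = max(1, int(round(spec.active_channel_fraction * 16)))
    raws: list[RawIntensity] = []
    hemos: list[HemoRecording] = []
    truth_rows: list[dict] = []
    groups: dict[str, str] = {}

    for subject, group in subjects:
        groups[subject] = group
        latency = spec.latency_by_group.get(group, 0.0)
        active: set[int] = set()
        for region in REGIONS:
            chans = [c for c in range(1, N_CHANNELS + 1)
                     if region_of_channel(c) == region]
            active.update(rng.choice(chans, size=n_active, replace=False).tolist())
        resp = block_regressor(paradigm, spec.fs, n_samples, spec.hrf,
                               latency=latency)
        for task in tasks:
            hbo = np.zeros((n_samples, N_CHANNELS))
            for ch in range(1, N_CHANNELS + 1):
                region = region_of_channel(ch)
                amp = spec.amplitude_by_group_region[(group, region)]
                is_active = ch in active
                if is_active:
                    hbo[:, ch - 1] = amp * resp
                truth_rows.append(dict(
                    subject=subject, group=group, task=task, channel=ch,
                    region=region, amplitude=amp if is_active else 0.0,
                    latency=latency, active=is_active))
            hbr = spec.hbr_ratio * hbo
            hbo = hbo + _noise(rng, spec.noise, t, N_CHANNELS)
            hbr = hbr + _noise(rng, spec.noise, t, N_CHANNELS)
            hemo = HemoRecording(hbo=hbo, hbr=hbr, fs=spec.fs, onsets=onsets,
                                 task=task, subject=subject, group=group)
            hemos.append(hemo)
            raws.append(hemo_to_intensity(hemo, mbll))

    truth = GroundTruth(table=pd.DataFrame(truth_rows), groups=groups)
    return raws, hemos, truth
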