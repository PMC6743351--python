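"""Band-pass filtering and epoch extraction.

Filtering follows the analysis convention of two fourth-order Butterworth
filters (high-pass 0.001 Hz, low-pass 0.1 Hz) applied zero-phase
(forward-backward), so biomarker time windows are not shifted by group
delay; the effective attenuation is the squared single-pass magnitude.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import EpochSet, HemoRecording
from .paradigm import ParadigmSpec


def bandpass(hemo: HemoRecording, low: float = 0.001, high: float = 0.1,
             order: int = 4) -> HemoRecording:
    """Zero-phase Butterworth high-pass (low) + low-pass (high) cascade."""
    nyq = hemo.fs / 2
    if not 0 < low < high < nyq:
        raise ValueError(
            f"cutoffs must satisfy 0 < {low} < {high} < fs/2 = {nyq:g}")
    sos_hp = signal.butter(order, low, btype="highpass", fs=hemo.fs, output="sos")
    sos_lp = signal.butter(order, high, btype="lowpass", fs=hemo.fs, output="sos")

    # low-pass first: the near-DC high-pass has a ~160 s time constant and
    # would smear any broadband edge transient across the whole record
    def run(x: np.ndarray) -> np.ndarray:
        y = signal.sosfiltfilt(sos_lp, x, axis=0)
        return signal.sosfiltfilt(sos_hp, y, axis=0)

    return hemo.copy_with(hbo=run(hemo.hbo), hbr=run(hemo.hbr))


def epoch_times(paradigm: ParadigmSpec, fs: float) -> np.ndarray:
    """Shared relative time grid for epochs, closed at both window edges."""
    t1, t2 = paradigm.epoch_window
    n = int(round((t2 - t1) * fs)) + 1
    return t1 + np.arange(n) / fs


def epoch(hemo: HemoRecording, paradigm: ParadigmSpec) -> EpochSet:
    """Cut one epoch per onset on the [-10, +70] s grid (nearest sample).

    Raises if any onset sits too close to the recording edge for the window.
    """
    if hemo.onsets.size == 0:
        raise ValueError("recording has no task onsets")
    times = epoch_times(paradigm, hemo.fs)
    n_t = times.size
    pre = int(round(-paradigm.epoch_window[0] * hemo.fs))
    hbo = np.empty((hemo.onsets.size, hemo.n_channels, n_t))
    hbr = np.empty_like(hbo)
    for k, onset in enumerate(hemo.onsets):
        i0 = int(round(onset * hemo.fs)) - pre
        i1 = i0 + n_t
        if i0 < 0 or i1 > hemo.n_samples:
            raise ValueError(
                f"trial {k + 1} (onset {onset:g} s) does not leave "
                f"[{paradigm.epoch_window[0]:g}, {paradigm.epoch_window[1]:g}] s "
                "inside the recording")
        hbo[k] = hemo.hbo[i0:i1].T
        hbr[k] = hemo.hbr[i0:i1].T
    return EpochSet(hbo=hbo, hbr=hbr, times=times, fs=hemo.fs,
                    task=hemo.task, subject=hemo.subject, group=hemo.group)


def average_epochs(epoch_sets: "EpochSet | list[EpochSet]", signal_name: str = "hbo",
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SD traces over trials (and over epoch sets if a
    list is given, e.g. subjects within a group).

    Returns ``(mean, sd)`` of shape (n_channels, n_times); SD is 0 for a
    single epoch.
    """
    if isinstance(epoch_sets, EpochSet):
        stack = epoch_sets.signal(signal_name)
    else:
        if not epoch_sets:
            raise ValueError("empty epoch selection")
        stack = np.concatenate([e.signal(signal_name) for e in epoch_sets], axis=0)
    if stack.shape[0] == 0:
        raise ValueError("empty epoch selection")
    return stack.mean(axis=0), stack.std(axis=0, ddof=0)


def trial_average(epochs: EpochSet) -> EpochSet:
    """Collapse trials to their pointwise mean (kept as a 1-trial EpochSet)."""
    return EpochSet(
        hbo=epochs.hbo.mean(axis=0, keepdims=True),
        hbr=epochs.hbr.mean(axis=0, keepdims=True),
        times=epochs.times, fs=epochs.fs, task=epochs.task,
        subject=epochs.subject, group=epochs.group)
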