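"""File I/O: SNIRF (HDF5) and plain CSV for raw intensities, plus sidecars.

The SNIRF writer emits a minimal continuous-wave file (formatVersion 1.0):
one data block whose measurement list pairs each channel with the two
wavelengths, stimulus onsets as a stim block, and probe wavelengths.  The
CSV dialect is wide: one row per sample, one column per channel/wavelength
(``ch01_780``, ``ch01_850``, ...).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import RawIntensity
from .synth import GroundTruth


def write_snirf(raw: RawIntensity, path: "str | Path") -> Path:
    path = Path(path)
    n, ch, _ = raw.data.shape
    flat = raw.data.reshape(n, ch * 2)   # channel-major, wavelength fastest
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(n) / raw.fs)
        for m in range(ch * 2):
            ml = data.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=m // 2 + 1)
            ml.create_dataset("detectorIndex", data=m // 2 + 1)
            ml.create_dataset("wavelengthIndex", data=m % 2 + 1)
            ml.create_dataset("dataType", data=1)       # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths))
        if raw.onsets.size:
            stim = nirs.create_group("stim1")
            stim.create_dataset("name", data=raw.task or "task")
            stim.create_dataset("data", data=np.column_stack(
                [raw.onsets, np.full(raw.onsets.size, 60.0),
                 np.ones(raw.onsets.size)]))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=raw.subject or "unknown")
        meta.create_dataset("Group", data=raw.group or "")
        if raw.baseline is not None:
            nirs.create_dataset("baselineIntensity", data=raw.baseline)
    return path


def read_snirf(path: "str | Path") -> RawIntensity:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        flat = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(time)))
        wl = tuple(float(w) for w in np.asarray(nirs["probe/wavelengths"]))
        onsets = np.empty(0)
        task = ""
        if "stim1" in nirs:
            onsets = np.asarray(nirs["stim1/data"])[:, 0]
            task = _as_str(nirs["stim1/name"][()])
        subject = _as_str(nirs["metaDataTags/SubjectID"][()])
        group = _as_str(nirs["metaDataTags/Group"][()])
        baseline = (np.asarray(nirs["baselineIntensity"])
                    if "baselineIntensity" in nirs else None)
    n, width = flat.shape
    return RawIntensity(data=flat.reshape(n, width // 2, 2), fs=fs,
                        wavelengths=wl, onsets=onsets, task=task,
                        subject=subject, group=group, baseline=baseline)


def _as_str(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)


def write_intensity_csv(raw: RawIntensity, path: "str | Path") -> Path:
    path = Path(path)
    n, ch, _ = raw.data.shape
    cols = {}
    for c in range(ch):
        for w, wl in enumerate(raw.wavelengths):
            cols[f"ch{c + 1:02d}_{int(wl)}"] = raw.data[:, c, w]
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def read_intensity_csv(path: "str | Path", fs: float,
                       onsets: np.ndarray | None = None, **meta) -> RawIntensity:
    df = pd.read_csv(path)
    names = df.columns
    wl = sorted({int(c.rsplit("_", 1)[1]) for c in names})
    n_ch = len(names) // 2
    data = np.empty((len(df), n_ch, 2))
    for c in range(n_ch):
        for w, l in enumerate(wl):
            data[:, c, w] = df[f"ch{c + 1:02d}_{l}"].to_numpy()
    return RawIntensity(data=data, fs=fs, wavelengths=(float(wl[0]), float(wl[1])),
                        onsets=onsets if onsets is not None else np.empty(0),
                        **meta)


def write_ground_truth(truth: GroundTruth, path: "str | Path") -> Path:
    path = Path(path)
    payload = {"groups": truth.groups,
               "records": truth.table.to_dict(orient="records")}
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: "str | Path") -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(table=pd.DataFrame(payload["records"]),
                       groups=payload["groups"])
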