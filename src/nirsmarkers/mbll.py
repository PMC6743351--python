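"""Modified Beer-Lambert law: optical intensity <-> chromophore changes.

For each channel, the optical-density change at wavelength lambda is
``dOD(lambda) = -log10(I(lambda) / I0(lambda))`` and relates linearly to the
chromophore concentration changes through the extinction-coefficient matrix
E, the source-detector distance d and the differential pathlength factor:

    dOD(lambda) = d * DPF(lambda) * [eps_HbO(lambda), eps_HbR(lambda)] . [dHbO, dHbR]

The 2x2 system is solved channel-wise.  ``hemo_to_intensity`` is the exact
inverse used by the simulator, so round trips recover concentrations to
numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import HemoRecording, RawIntensity

# Extinction coefficients in 1/(mM cm), typical compiled in-vivo values for
# adult tissue at the two device wavelengths; overridable via MbllParams.
_DEFAULT_EXTINCTION = np.array([
    [0.7360, 1.1050],   # 780 nm: eps_HbO, eps_HbR
    [1.0580, 0.6910],   # 850 nm
])


@dataclass(frozen=True)
class MbllParams:
    """Wavelengths, extinction matrix, DPF and geometric distance."""

    wavelengths: tuple[float, float] = (780.0, 850.0)
    extinction: np.ndarray = field(
        default_factory=lambda: _DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = (6.0, 6.0)
    distance_cm: float = 3.0

    def __post_init__(self) -> None:
        E = np.asarray(self.extinction, dtype=float)
        if E.shape != (2, 2):
            raise ValueError("extinction matrix must be 2x2")
        if abs(np.linalg.det(E)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        if min(self.dpf) <= 0 or self.distance_cm <= 0:
            raise ValueError("dpf and distance must be positive")
        object.__setattr__(self, "extinction", E)

    def pathlength_matrix(self) -> np.ndarray:
        """d * DPF(lambda) * E, the 2x2 map from [dHbO, dHbR] to dOD."""
        L = np.diag([self.distance_cm * self.dpf[0],
                     self.distance_cm * self.dpf[1]])
        return L @ self.extinction


def mbll_convert(intensity: RawIntensity, params: MbllParams = MbllParams(), *,
                 baseline_window: float = 30.0) -> HemoRecording:
    """Convert raw two-wavelength intensities to dHbO/dHbR concentrations.

    I0 is the stored simulator baseline when present, otherwise the mean
    intensity over the first ``baseline_window`` seconds of rest.  Raises on
    non-positive intensities, naming the first offending channel and sample.
    """
    I = intensity.data
    if np.any(I <= 0):
        s, c, w = map(int, np.argwhere(I <= 0)[0])
        raise ValueError(
            f"non-positive intensity at sample {s}, channel {c + 1}, "
            f"wavelength {intensity.wavelengths[w]:g} nm")
    if intensity.baseline is not None:
        i0 = np.asarray(intensity.baseline, dtype=float)
    else:
        n0 = max(1, min(I.shape[0], int(round(baseline_window * intensity.fs))))
        i0 = I[:n0].mean(axis=0)
    if np.any(i0 <= 0):
        raise ValueError("baseline intensity must be positive")

    dod = -np.log10(I / i0)                       # (n_samples, n_channels, 2)
    A_inv = np.linalg.inv(params.pathlength_matrix())
    conc = dod @ A_inv.T                          # solves A c = dOD channel-wise
    return HemoRecording(
        hbo=conc[:, :, 0], hbr=conc[:, :, 1], fs=intensity.fs,
        onsets=intensity.onsets, task=intensity.task,
        subject=intensity.subject, group=intensity.group)


def hemo_to_intensity(hemo: HemoRecording, params: MbllParams = MbllParams(), *,
                      i0: float = 1.0) -> RawIntensity:
    """Inverse MBLL: synthesize raw intensities from concentration changes.

    The known reference I0 is stored on the result so that ``mbll_convert``
    recovers the input exactly rather than re-estimating the baseline.
    """
    A = params.pathlength_matrix()
    conc = np.stack([hemo.hbo, hemo.hbr], axis=-1)   # (n, ch, 2)
    dod = conc @ A.T
    data = i0 * np.power(10.0, -dod)
    baseline = np.full((hemo.n_channels, 2), float(i0))
    return RawIntensity(
        data=data, fs=hemo.fs, wavelengths=params.wavelengths,
        onsets=hemo.onsets, task=hemo.task, subject=hemo.subject,
        group=hemo.group, baseline=baseline)
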