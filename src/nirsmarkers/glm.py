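"""Per-channel GLM against the convolved block regressor, and ROI selection.

The measured series is modeled as ``z(t) = beta * f(t) + intercept + eps``
with ``f = h (*) s`` (canonical HRF convolved with the task boxcar).  An
intercept is included even though the activation model is usually written
without one: baseline offsets would otherwise bias the amplitude estimate.
The robust fit uses iteratively reweighted least squares with the bisquare
(Tukey biweight) function at tuning constant 4.685 -- the default of the
reference `robustfit` routine.  Channels with ``t > t_crit`` (default
1.6469) and one-sided ``p < 0.05`` form the automatic region of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .containers import EpochSet
from .hrf import HrfParams, canonical_hrf
from .preprocess import trial_average

T_CRIT_DEFAULT = 1.6469
BISQUARE_TUNING = 4.685


@dataclass(frozen=True)
class DesignModel:
    """Predicted response f(t) = h (*) s(t) plus an intercept column."""

    times: np.ndarray
    f: np.ndarray
    boxcar: np.ndarray

    def matrix(self) -> np.ndarray:
        return np.column_stack([np.ones_like(self.f), self.f])


@dataclass(frozen=True)
class GlmFit:
    beta: float
    se: float
    tvalue: float
    pvalue: float       # upper-tail (activation vs. baseline)
    dof: int
    residuals: np.ndarray
    method: str = "ols"


@dataclass(frozen=True)
class RoiSelection:
    mode: str                      # "auto" | "manual"
    channels: tuple[int, ...]      # 1-based ids, ascending
    t_crit: float = T_CRIT_DEFAULT


def _safe_t(beta: float, se: float) -> float:
    """t = beta/se, with the degenerate perfect-fit cases handled."""
    if se > 0:
        return beta / se
    return 0.0 if beta == 0 else float(np.sign(beta) * np.inf)


def build_design(times: np.ndarray, hrf: HrfParams = HrfParams(), *,
                 onsets: tuple[float, ...] = (0.0,), duration: float = 60.0,
                 ) -> DesignModel:
    """Discrete convolution of the task boxcar with the unit-peak HRF.

    ``times`` is the uniform epoch (or session) grid in seconds; ``onsets``
    are task starts on that grid.  The response is normalized to unit peak
    (left as zero for an empty boxcar).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    dt = t[1] - t[0] if t.size > 1 else 1.0
    fs = 1.0 / dt
    box = np.zeros(t.size)
    for onset in onsets:
        on = (t >= onset - 1e-9) & (t < onset + duration - 1e-9)
        box[on] = 1.0
    h = canonical_hrf(hrf, np.arange(0.0, 32.0, dt))
    f = np.convolve(box, h)[:t.size]
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return DesignModel(times=t, f=f, boxcar=box)


def fit_glm_ols(z: np.ndarray, design: DesignModel) -> GlmFit:
    """Closed-form least squares of z on [intercept, f]; t = beta / se."""
    z = np.asarray(z, dtype=float)
    X = design.matrix()
    if z.shape[0] != X.shape[0]:
        raise ValueError("series and design must share the time grid")
    if z.shape[0] <= 2:
        raise ValueError("need more than 2 samples")
    if np.ptp(design.f) == 0:
        raise ValueError("zero-variance design regressor")
    beta_hat, res_ss, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design")
    resid = z - X @ beta_hat
    dof = z.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    tval = _safe_t(float(beta_hat[1]), se)
    return GlmFit(beta=float(beta_hat[1]), se=se, tvalue=tval,
                  pvalue=float(stats.t.sf(tval, dof)), dof=dof,
                  residuals=resid, method="ols")


def fit_glm_robust(z: np.ndarray, design: DesignModel) -> GlmFit:
    """IRLS fit with bisquare weights (tuning constant 4.685).

    t and its one-sided p come from the robust covariance; on (near-)perfect
    fits where the robust scale collapses to zero, the OLS standard error is
    used instead so noiseless data yields the least-squares answer exactly.
    """
    z = np.asarray(z, dtype=float)
    X = design.matrix()
    if z.shape[0] != X.shape[0]:
        raise ValueError("series and design must share the time grid")
    if z.shape[0] <= 2:
        raise ValueError("need more than 2 samples")
    if np.ptp(design.f) == 0:
        raise ValueError("zero-variance design regressor")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.RLM(z, X, M=sm.robust.norms.TukeyBiweight(BISQUARE_TUNING)).fit()
    beta = float(res.params[1])
    se = float(res.bse[1])
    resid = z - X @ res.params
    dof = z.shape[0] - X.shape[1]
    if not np.isfinite(se) or se == 0:
        se = fit_glm_ols(z, design).se
    tval = _safe_t(beta, se)
    return GlmFit(beta=beta, se=se, tvalue=tval,
                  pvalue=float(stats.t.sf(tval, dof)), dof=dof,
                  residuals=resid, method="robust")


def fit_epochs(epochs: EpochSet, hrf: HrfParams = HrfParams(), *,
               duration: float = 60.0, robust: bool = True,
               per_trial: bool = False) -> "list[GlmFit] | list[list[GlmFit]]":
    """Fit the GLM per channel on the trial-averaged epoch (default).

    With ``per_trial=True`` returns one fit list per trial instead, as
    needed for per-trial image biomarkers.
    """
    design = build_design(epochs.times, hrf, onsets=(0.0,), duration=duration)
    fitter = fit_glm_robust if robust else fit_glm_ols
    source = epochs if per_trial else trial_average(epochs)
    all_fits = [[fitter(source.hbo[k, c], design)
                 for c in range(source.n_channels)]
                for k in range(source.n_trials)]
    return all_fits if per_trial else all_fits[0]


def select_roi(fits: "list[GlmFit] | None" = None, mode: str = "auto", *,
               t_crit: float = T_CRIT_DEFAULT, alpha: float = 0.05,
               manual_channels: "tuple[int, ...] | None" = None,
               n_channels: int = 48) -> RoiSelection:
    """Select ROI channels automatically (t > t_crit and p < alpha) or manually."""
    if mode == "auto":
        if fits is None:
            raise ValueError("auto mode needs one fit per channel")
        chans = tuple(c + 1 for c, f in enumerate(fits)
                      if f.tvalue > t_crit and f.pvalue < alpha)
        return RoiSelection(mode="auto", channels=chans, t_crit=t_crit)
    if mode == "manual":
        if manual_channels is None:
            raise ValueError("manual mode needs a channel list")
        bad = [c for c in manual_channels if not 1 <= c <= n_channels]
        if bad:
            raise ValueError(f"unknown channels in manual list: {bad}")
        return RoiSelection(mode="manual",
                            channels=tuple(sorted(set(manual_channels))),
                            t_crit=t_crit)
    raise ValueError(f"unknown ROI mode {mode!r}")
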