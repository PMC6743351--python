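import numpy as np
import pytest

import nirsmarkers as nm
from nirsmarkers.glm import GlmFit


def test_exact_fit_recovers_amplitude(default_design):
    z = 3.0 * default_design.f + 1.0
    for fitter in (nm.fit_glm_ols, nm.fit_glm_robust):
        fit = fitter(z, default_design)
        assert fit.beta == pytest.approx(3.0, abs=1e-9)
        assert np.abs(fit.residuals).max() < 1e-9


def test_robust_equals_ols_on_noiseless_data(default_design):
    z = -2.5 * default_design.f + 0.7
    ols = nm.fit_glm_ols(z, default_design)
    rob = nm.fit_glm_robust(z, default_design)
    assert rob.beta == pytest.approx(ols.beta, abs=1e-9)


def test_constant_series_has_zero_amplitude(default_design):
    fit = nm.fit_glm_ols(np.full(default_design.f.size, 4.0), default_design)
    assert fit.beta == pytest.approx(0.0, abs=1e-12)


def test_scale_equivariance(default_design):
    rng = np.random.default_rng(8)
    z = default_design.f + rng.standard_normal(default_design.f.size)
    for fitter in (nm.fit_glm_ols, nm.fit_glm_robust):
        f1 = fitter(z, default_design)
        f2 = fitter(5.0 * z, default_design)
        assert f2.beta == pytest.approx(5.0 * f1.beta, rel=1e-6)
        assert f2.tvalue == pytest.approx(f1.tvalue, rel=1e-6)


def test_null_type_one_rate_seeded(default_design):
    rng = np.random.default_rng(123)
    n = default_design.f.size
    hits = sum(nm.fit_glm_ols(rng.standard_normal(n), default_design).tvalue
               > nm.T_CRIT_DEFAULT for _ in range(400))
    assert 0.02 <= hits / 400 <= 0.08


def test_robust_beats_ols_under_outliers(default_design):
    wins = 0
    n = default_design.f.size
    for seed in range(50):
        rng = np.random.default_rng(seed)
        z = default_design.f + 0.1 * rng.standard_normal(n)
        idx = rng.choice(n, size=n // 20, replace=False)
        z[idx] += rng.choice([-1, 1], size=idx.size) * 5.0
        rob = nm.fit_glm_robust(z, default_design).beta
        ols = nm.fit_glm_ols(z, default_design).beta
        wins += abs(rob - 1.0) < abs(ols - 1.0)
    assert wins >= 45


def test_robust_and_ols_agree_on_clean_noise(default_design):
    """Median relative disagreement under Gaussian noise stays below 5%."""
    n = default_design.f.size
    rel = []
    for seed in range(30):
        rng = np.random.default_rng(100 + seed)
        z = 2.0 * default_design.f + 0.2 * rng.standard_normal(n)
        rob = nm.fit_glm_robust(z, default_design).beta
        ols = nm.fit_glm_ols(z, default_design).beta
        rel.append(abs(rob - ols) / abs(ols))
    assert np.median(rel) < 0.05


def test_design_shapes_and_degenerate_boxcars(epoch_grid):
    d = nm.build_design(epoch_grid)
    assert d.f.shape == epoch_grid.shape
    assert set(np.unique(d.boxcar)) <= {0.0, 1.0}
    # zero-duration boxcar -> f == 0
    d0 = nm.build_design(epoch_grid, duration=0.0)
    assert np.allclose(d0.f, 0)
    with pytest.raises(ValueError):
        nm.fit_glm_ols(np.zeros(epoch_grid.size), d0)
    # impulse boxcar -> f proportional to the HRF
    d1 = nm.build_design(epoch_grid, duration=1 / nm.DEFAULT_FS)
    h = nm.canonical_hrf(nm.HrfParams(), np.arange(0.0, 32.0, 1 / nm.DEFAULT_FS))
    on = int(np.argmax(d1.boxcar))
    seg = d1.f[on:on + h.size]
    assert np.allclose(seg / np.abs(seg).max(), h / np.abs(h).max(), atol=1e-9)


def test_block_design_peak_matches_zero_crossing_oracle(epoch_grid):
    d = nm.build_design(epoch_grid)
    t_peak = epoch_grid[np.argmax(d.f)]
    assert t_peak == pytest.approx(nm.hrf_zero_crossing(), abs=0.2)


def _fit(t, p):
    return GlmFit(beta=t, se=1.0, tvalue=t, pvalue=p, dof=600,
                  residuals=np.empty(0))


def test_auto_roi_threshold_membership():
    fits = [_fit(1.0, 0.16), _fit(1.7, 0.045), _fit(2.5, 0.006)]
    sel = nm.select_roi(fits, "auto")
    assert sel.channels == (2, 3)
    none = nm.select_roi([_fit(0.5, 0.3)] * 3, "auto")
    assert none.channels == ()


def test_auto_roi_monotone_in_threshold():
    rng = np.random.default_rng(0)
    fits = [_fit(t, 0.01) for t in rng.uniform(-1, 4, 48)]
    prev = set(nm.select_roi(fits, "auto", t_crit=1.0).channels)
    for crit in (1.5, 2.0, 3.0):
        cur = set(nm.select_roi(fits, "auto", t_crit=crit).channels)
        assert cur <= prev
        prev = cur


def test_manual_roi_validation():
    sel = nm.select_roi(mode="manual", manual_channels=(9, 5, 1))
    assert sel.channels == (1, 5, 9)
    with pytest.raises(ValueError, match="unknown"):
        nm.select_roi(mode="manual", manual_channels=(1, 99))
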