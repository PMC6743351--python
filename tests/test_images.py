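import numpy as np
import pytest

import nirsmarkers as nm
from nirsmarkers.glm import GlmFit


def _fits(tvalues):
    return [GlmFit(beta=t, se=1.0, tvalue=t, pvalue=0.5, dof=100,
                   residuals=np.empty(0)) for t in tvalues]


def test_tmap_orders_channels_and_validates_count():
    t = np.zeros(48)
    t[7] = 8.0
    tmap = nm.make_tmap(_fits(t))
    assert tmap.shape == (48,)
    assert np.argmax(tmap) == 7
    assert np.allclose(nm.make_tmap(_fits(np.zeros(48))), 0)
    with pytest.raises(ValueError):
        nm.make_tmap(_fits(np.zeros(47)))


def test_render_constant_field(layout):
    img = nm.render_topo(np.full(48, 3.7), layout)
    assert img.raster.shape == (48, 48)
    assert np.allclose(img.raster, 3.7)


def test_render_linearity(layout):
    rng = np.random.default_rng(0)
    v = rng.standard_normal(48)
    a = nm.render_topo(v, layout).raster
    b = nm.render_topo(2 * v, layout).raster
    assert np.allclose(b, 2 * a)


def test_render_single_source_decays_with_distance(layout):
    v = np.zeros(48)
    v[0] = 1.0
    img = nm.render_topo(v, layout)
    src = layout.positions[0]
    xs = np.linspace(*img.extent[:2], 48)
    ys = np.linspace(img.extent[3], img.extent[2], 48)
    X, Y = np.meshgrid(xs, ys)
    dist = np.hypot(X - src[0], Y - src[1]).ravel()
    vals = img.raster.ravel()
    # intensity falls off with distance from the lone source
    assert vals.min() >= 0
    assert np.argmax(vals) == np.argmin(dist)
    near = vals[dist <= np.quantile(dist, 0.1)].mean()
    far = vals[dist >= np.quantile(dist, 0.9)].mean()
    assert near > 3 * far


def test_render_permutation_safety(layout):
    rng = np.random.default_rng(3)
    v = rng.standard_normal(48)
    perm = rng.permutation(48)
    shuffled = nm.ProbeLayout(
        channels=tuple(np.array(layout.channels)[perm]),
        positions=layout.positions[perm],
        regions=tuple(np.array(layout.regions)[perm]))
    assert np.allclose(nm.render_topo(v, layout).raster,
                       nm.render_topo(v[perm], shuffled).raster)


def test_render_rejects_coincident_channels(layout):
    pos = layout.positions.copy()
    pos[1] = pos[0]
    bad = nm.ProbeLayout(channels=layout.channels, positions=pos,
                         regions=layout.regions)
    with pytest.raises(ValueError, match="coincident"):
        nm.render_topo(np.zeros(48), bad)


def _epochs_from_channels(data, fs=10.0):
    """data: (n_channels, n_samples) single-trial epoch starting at t=0."""
    x = data[None, :, :]
    return nm.EpochSet(hbo=x, hbr=np.zeros_like(x),
                       times=np.arange(data.shape[1]) / fs, fs=fs)


def test_correlation_map_identities():
    rng = np.random.default_rng(1)
    base = rng.standard_normal((48, 500))
    base[1] = base[0]            # duplicate
    base[2] = -base[0]           # negation
    cm = nm.correlation_map(_epochs_from_channels(base), window=(0, 50))
    assert cm.shape == (48, 48)
    assert np.allclose(np.diag(cm), 1.0)
    assert np.allclose(cm, cm.T)
    assert cm[0, 1] == pytest.approx(1.0)
    assert cm[0, 2] == pytest.approx(-1.0)
    assert np.nanmax(np.abs(cm)) <= 1.0


def test_correlation_map_null_level():
    """Independent white channels: off-diagonal |r| small at n = 500."""
    rng = np.random.default_rng(2)
    cm = nm.correlation_map(
        _epochs_from_channels(rng.standard_normal((48, 500))), window=(0, 50))
    off = cm[~np.eye(48, dtype=bool)]
    assert np.mean(np.abs(off) < 0.15) >= 0.95


def test_correlation_map_affine_invariance():
    rng = np.random.default_rng(4)
    data = rng.standard_normal((48, 300))
    scaled = data * rng.uniform(0.5, 3.0, size=(48, 1)) + rng.normal(size=(48, 1))
    a = nm.correlation_map(_epochs_from_channels(data), window=(0, 30))
    b = nm.correlation_map(_epochs_from_channels(scaled), window=(0, 30))
    assert np.allclose(a, b, atol=1e-10)


def test_correlation_map_zero_variance_channel_masked(caplog):
    rng = np.random.default_rng(5)
    data = rng.standard_normal((48, 300))
    data[5] = 2.0
    with caplog.at_level("WARNING"):
        cm = nm.correlation_map(_epochs_from_channels(data), window=(0, 30))
    assert np.isnan(cm[5, 6]) and np.isnan(cm[6, 5])
    assert cm[5, 5] == 1.0


def test_outer_product_mode_shape_and_scale():
    t = np.linspace(-2, 4, 48)
    m = nm.tmap_outer(t)
    assert m.shape == (48, 48)
    assert np.abs(m).max() == pytest.approx(1.0)
    assert np.allclose(m, m.T)
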