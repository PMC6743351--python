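import numpy as np
import pandas as pd
import pytest

import nirsmarkers as nm
from nirsmarkers.biomarkers import default_biomarkers

FS = nm.DEFAULT_FS


@pytest.fixture(scope="module")
def times(epoch_grid):
    return epoch_grid


def test_mean_change_worked_values(times):
    base = np.where(times < 0, 2.0, 3.0)
    assert nm.mean_change(times, base, (5, 65)) == pytest.approx(0.5)
    flipped = np.where(times < 0, -1.0, 1.0)
    assert nm.mean_change(times, flipped, (5, 65)) == pytest.approx(-2.0)
    const = np.full(times.size, 2.0)
    assert nm.mean_change(times, const, (5, 65)) == pytest.approx(0.0)


def test_mean_change_difference_form(times):
    x = np.where(times < 0, 2.0, 3.0)
    assert nm.mean_change(times, x, (5, 65), relative=False) == pytest.approx(1.0)


def test_mean_change_degenerate_baseline_is_missing(times):
    x = np.where(times < 0, 0.0, 1.0)
    assert np.isnan(nm.mean_change(times, x, (5, 65)))
    # the non-relative form stays defined
    assert nm.mean_change(times, x, (5, 65), relative=False) == pytest.approx(1.0)


def test_slope_exact_on_ramp_and_constant(times):
    assert nm.slope(times, 0.2 * times, (5, 65)) == pytest.approx(0.2)
    assert nm.slope(times, np.ones(times.size), (5, 65)) == pytest.approx(0.0)


def test_slope_ignores_symmetric_perturbation():
    """A perturbation even about the window midpoint is orthogonal to t."""
    t = np.linspace(0.0, 10.0, 101)
    tri = 1.0 - np.abs(t - 5.0) / 5.0
    y = 0.2 * t + tri
    assert nm.slope(t, y, (0, 10.0001)) == pytest.approx(0.2, abs=1e-12)


@pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
def test_slope_scale_equivariance(times, c):
    rng = np.random.default_rng(1)
    y = rng.standard_normal(times.size)
    assert nm.slope(times, c * y, (5, 65)) == pytest.approx(
        c * nm.slope(times, y, (5, 65)), rel=1e-9)


def test_peak_time_on_triangular_bump(times):
    y = np.maximum(0.0, 1.0 - np.abs(times - 12.0) / 4.0)
    pk = nm.peak_time(times, y)
    assert pk.time == pytest.approx(12.0, abs=1 / FS)
    assert not pk.boundary
    # invariant to positive scaling
    assert nm.peak_time(times, 7.3 * y).time == pk.time


def test_peak_time_monotone_epoch_flags_boundary(times):
    pk = nm.peak_time(times, times.copy(), (0, 60))
    assert pk.boundary
    assert pk.time == pytest.approx(60.0, abs=2 / FS)


def test_peak_time_of_block_response_matches_hrf_oracle(times):
    d = nm.build_design(times)
    pk = nm.peak_time(times, d.f)
    assert pk.time == pytest.approx(nm.hrf_zero_crossing(), abs=0.5)


def test_shape_moments(times):
    sym = np.sin(2 * np.pi * (times - 5) / 60.0)  # full period over 5-65 s
    assert nm.shape_moment(times, sym, "skewness") == pytest.approx(0.0, abs=0.02)
    assert nm.shape_moment(times, sym, "kurtosis") == pytest.approx(1.5, abs=0.02)
    two = np.array([-1.0, 1.0, -1.0, 1.0])
    t2 = np.array([0.0, 1.0, 2.0, 3.0])
    assert nm.shape_moment(t2, two, "kurtosis", (0, 4)) == pytest.approx(1.0)
    assert np.isnan(nm.shape_moment(times, np.ones(times.size), "kurtosis"))


def _epochs(hbo, times, **meta):
    return nm.EpochSet(hbo=hbo, hbr=-hbo / 3, times=times, fs=FS, **meta)


def test_battery_row_arithmetic(times):
    rng = np.random.default_rng(0)
    es = _epochs(rng.standard_normal((3, 48, times.size)), times,
                 subject="S1", group="HC", task="N-back")
    roi = nm.select_roi(mode="manual", manual_channels=(1, 2, 17, 33))
    table = nm.extract_battery(es, roi)
    assert len(table) == 3 * 4 * 15
    assert set(table.region) == {"right", "middle", "left"}
    # pure function: repeated calls agree bitwise
    again = nm.extract_battery(es, roi)
    pd.testing.assert_frame_equal(table, again)


def test_battery_on_zero_epochs(times):
    es = _epochs(np.zeros((1, 48, times.size)), times,
                 subject="S1", group="HC", task="N-back")
    roi = nm.select_roi(mode="manual", manual_channels=(1,))
    table = nm.extract_battery(
        es, roi, specs=default_biomarkers(relative_mean_change=True))
    mc = table[table.biomarker.isin([1, 2, 3, 4])]
    assert mc.value.isna().all()
    assert (mc.reason == "degenerate baseline").all()
    slopes = table[table.biomarker.isin([6, 7, 8, 9, 10, 11])]
    assert np.allclose(slopes.value, 0.0)


def test_battery_respects_per_subject_roi(times):
    rng = np.random.default_rng(5)
    e1 = _epochs(rng.standard_normal((2, 48, times.size)), times,
                 subject="A", group="MCI", task="VFT")
    e2 = _epochs(rng.standard_normal((2, 48, times.size)), times,
                 subject="B", group="HC", task="VFT")
    roi = {"A": nm.select_roi(mode="manual", manual_channels=(1,)),
           "B": nm.select_roi(mode="manual", manual_channels=(2, 3))}
    table = nm.extract_battery([e1, e2], roi)
    assert set(table[table.subject == "A"].channel) == {1}
    assert set(table[table.subject == "B"].channel) == {2, 3}


def test_empty_roi_region_omitted_with_warning(times, caplog):
    es = _epochs(np.zeros((1, 48, times.size)), times,
                 subject="S1", group="HC", task="N-back")
    empty = nm.RoiSelection(mode="auto", channels=())
    with caplog.at_level("WARNING"):
        table = nm.extract_battery(es, empty)
    assert table.empty
    assert "empty ROI" in caplog.text


def test_default_battery_matches_published_list():
    specs = default_biomarkers()
    assert len(specs) == 15
    assert [s.signal for s in specs[:5]] == ["hbo", "hbr", "hbo", "hbr", "hbo"]
    assert specs[12].kind == "peak-time"
    assert specs[13].kind == "skewness" and specs[14].kind == "kurtosis"
    assert specs[0].window == (5, 65) and specs[2].window == (5, 25)
    assert specs[4].window == "0-peak" and specs[11].window == "0-peak"
    assert [s.window for s in specs[5:11]] == [
        (5, 15), (5, 15), (20, 60), (20, 60), (60, 70), (60, 70)]
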