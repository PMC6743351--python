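import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nirsmarkers as nm


# --- summary-statistic t-test ----------------------------------------------

def test_equal_means_give_half_one_tailed():
    a = nm.SummaryStats(5.0, 1.0, 12)
    b = nm.SummaryStats(5.0, 1.2, 10)
    assert nm.ttest_from_summary(a, b, tail="one") == pytest.approx(0.5)


def test_summary_test_equals_sample_level_oracle():
    """Feeding a sample's own summaries reproduces the pooled t-test."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.normal(0, 1, rng.integers(5, 30))
        y = rng.normal(0.3, 1.5, rng.integers(5, 30))
        p_sum = nm.ttest_from_summary(
            nm.SummaryStats(x.mean(), x.std(ddof=1), len(x)),
            nm.SummaryStats(y.mean(), y.std(ddof=1), len(y)), tail="two")
        _, p_ref = stats.ttest_ind(x, y, equal_var=True)
        assert p_sum == pytest.approx(p_ref, rel=1e-10)


def test_zero_pooled_variance_rejected():
    with pytest.raises(ValueError):
        nm.ttest_from_summary(nm.SummaryStats(1.0, 0.0, 5),
                              nm.SummaryStats(2.0, 0.0, 5))


# --- biomarker-table t-test -------------------------------------------------

def _table(mci_vals, hc_vals):
    rows = []
    for g, vals in (("MCI", mci_vals), ("HC", hc_vals)):
        for i, v in enumerate(vals):
            rows.append(dict(subject=f"{g}{i}", group=g, task="N-back",
                             region="left", trial=1, channel=1,
                             biomarker=1, name="b1", value=v, reason=""))
    return pd.DataFrame(rows)


def test_identical_groups_are_not_significant():
    vals = [1.0, 2.0, 3.0, 4.0]
    res = nm.biomarker_ttest(_table(vals, vals), 1, "N-back", "left", tail="two")
    assert res.tvalue == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(1.0)
    assert not res.significant


def test_strong_shift_is_significant():
    rng = np.random.default_rng(1)
    res = nm.biomarker_ttest(_table(rng.normal(0, 1, 30),
                                    rng.normal(3, 1, 30)),
                             1, "N-back", "left", tail="two")
    assert res.significant and res.pvalue < 1e-6
    assert res.mean_hc > res.mean_mci


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        nm.biomarker_ttest(_table([1.0, 2.0], []), 1, "N-back", "left")


# --- LDA ---------------------------------------------------------------------

def test_lda_separates_well_separated_clusters():
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(0, 1, 60), rng.normal(8, 1, 60)])
    y = np.repeat([0, 1], 60)
    accs = nm.lda_cv(x, y, k=10, seed=0)
    assert np.mean(accs) >= 0.95


def test_lda_chance_on_permuted_labels():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(120)
    means = []
    for seed in range(50):
        y = np.random.default_rng(seed).permutation(np.repeat([0, 1], 60))
        means.append(np.mean(nm.lda_cv(x, y, k=10, seed=seed)))
    assert abs(np.mean(means) - 0.5) <= 0.1


def test_lda_accuracy_invariant_to_feature_rescaling():
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.normal(0, 1, 40), rng.normal(2, 1, 40)])
    y = np.repeat([0, 1], 40)
    a = nm.lda_cv(x, y, k=5, seed=1)
    b = nm.lda_cv(1e6 * x + 3.0, y, k=5, seed=1)
    assert a == b


def test_lda_crossval_from_table():
    rng = np.random.default_rng(5)
    table = _table(rng.normal(0, 1, 30), rng.normal(6, 1, 30))
    res = nm.lda_crossval(table, 1, task="N-back", region="left", k=5, seed=0)
    assert res.classifier == "LDA"
    assert res.mean_accuracy >= 0.95
    assert res.n_samples == 60


# --- CNN input preparation ---------------------------------------------------

def _epochs(hbo, fs=nm.DEFAULT_FS):
    times = -10.0 + np.arange(hbo.shape[2]) / fs
    return nm.EpochSet(hbo=hbo, hbr=-hbo / 3, times=times, fs=fs)


def test_resize_shape_contract(epoch_grid):
    es = _epochs(np.random.default_rng(0).standard_normal((3, 48, epoch_grid.size)))
    roi = nm.select_roi(mode="manual", manual_channels=tuple(range(1, 49)))
    out = nm.resize_hemo_for_cnn(es, roi)
    assert out.shape == (3, 48, 48)


def test_resize_constant_and_reversal(epoch_grid):
    n = epoch_grid.size
    es = _epochs(np.full((1, 48, n), 2.5))
    roi = nm.select_roi(mode="manual", manual_channels=(1, 5))
    out = nm.resize_hemo_for_cnn(es, roi)
    assert np.allclose(out[0, [0, 4]], 2.5)
    assert np.allclose(out[0, 1], 0.0)    # non-ROI rows stay zero
    rng = np.random.default_rng(1)
    x = rng.standard_normal((1, 48, n))
    sl = _epochs(x).window_slice(0.0, 60.0)
    rev = x.copy()
    rev[0, :, sl] = rev[0, :, sl][:, ::-1]
    a = nm.resize_hemo_for_cnn(_epochs(x), roi)
    b = nm.resize_hemo_for_cnn(_epochs(rev), roi)
    assert np.allclose(b[0, 0], a[0, 0, ::-1], atol=1e-9)


def test_resize_empty_roi_rejected(epoch_grid):
    es = _epochs(np.zeros((1, 48, epoch_grid.size)))
    with pytest.raises(ValueError):
        nm.resize_hemo_for_cnn(es, nm.RoiSelection(mode="auto", channels=()))


# --- CNN ---------------------------------------------------------------------

FAST_CNN = nm.CnnConfig(epochs=20, learning_rates=(1e-3,), patience=6)


def test_cnn_separates_offset_block_images():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((60, 48, 48))
    y = np.arange(60) % 2
    X[y == 1, 10:20, :] += 3.0
    res = nm.cnn_train_eval(X, y, FAST_CNN, repeats=3, seed=0)
    assert res.mean_accuracy >= 0.9


def test_cnn_2d_mode_learns_too():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((40, 48, 48))
    y = np.arange(40) % 2
    X[y == 1, :, 20:30] += 3.0
    cfg = nm.CnnConfig(mode="2d", epochs=12, learning_rates=(1e-3,), patience=5)
    res = nm.cnn_train_eval(X, y, cfg, repeats=2, seed=0)
    assert res.mean_accuracy >= 0.8


def test_cnn_subject_level_split_keeps_subjects_apart():
    from nirsmarkers.evaluate import _subject_split
    subjects = np.repeat([f"S{i}" for i in range(10)], 3)
    y = np.repeat([0, 1], 15)
    tr, te = _subject_split(subjects, y, 0.2, np.random.default_rng(0))
    assert set(subjects[tr]).isdisjoint(subjects[te])
    assert len(np.unique(y[te])) == 2


def test_report_schema_and_rows(tmp_path):
    empty = nm.report()
    assert list(empty["stats"].columns)[:3] == ["biomarker", "task", "region"]
    assert empty["stats"].empty and empty["accuracy"].empty
    rng = np.random.default_rng(8)
    res = nm.biomarker_ttest(_table(rng.normal(0, 1, 10), rng.normal(1, 1, 10)),
                             1, "N-back", "left")
    out = nm.report([res], [], out_dir=tmp_path)
    assert len(out["stats"]) == 1
    assert (tmp_path / "biomarker_stats.csv").exists()
    assert (tmp_path / "summary.json").exists()
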