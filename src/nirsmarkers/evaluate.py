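"""Group evaluation: t-tests on biomarker samples, LDA and CNN classification.

Three tracks mirror the analysis design: (1) pooled-variance two-sample
t-tests on biomarker samples (subject x trial x ROI channel) per task and
region, plus the same test computed from printed summary statistics;
(2) per-biomarker linear discriminant analysis with stratified 10-fold
cross-validation; (3) a small CNN trained on 48x48 image biomarkers (t-maps,
correlation maps, or resized dHbO matrices) with repeated subject-level
train/test splits and a learning-rate grid on an inner validation split.

Tail convention: ``tail="one"`` reports the upper-tail probability of |t|
(the observed direction), the convention under which the demographic-table
p-values reproduce; ``tail="two"`` is the standard two-sided test.  No
multiple-testing correction is applied by default; ``report`` can add a
Benjamini-Hochberg column marked as an extension.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .cnn import CnnConfig, SmallCnn
from .containers import EpochSet
from .glm import RoiSelection
from .paradigm import N_CHANNELS

ALPHA = 0.05


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


@dataclass(frozen=True)
class StatResult:
    biomarker: int
    task: str
    region: str
    mean_mci: float
    sd_mci: float
    n_mci: int
    mean_hc: float
    sd_hc: float
    n_hc: int
    tvalue: float
    pvalue: float
    tail: str
    significant: bool


@dataclass(frozen=True)
class CVResult:
    classifier: str              # "LDA" | "CNN"
    accuracies: tuple[float, ...]
    n_samples: int
    scope: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def _tail_p(t: float, dof: float, tail: str) -> float:
    if tail == "one":
        return float(stats.t.sf(abs(t), dof))
    if tail == "two":
        return float(2 * stats.t.sf(abs(t), dof))
    raise ValueError(f"unknown tail mode {tail!r}")


def ttest_from_summary(a: SummaryStats, b: SummaryStats,
                       tail: str = "one") -> float:
    """Pooled-variance two-sample t-test p-value from summary statistics."""
    dof = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / dof
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    return _tail_p(t, dof, tail)


def biomarker_ttest(table: pd.DataFrame, biomarker: int, task: str,
                    region: str, tail: str = "one") -> StatResult:
    """Pooled two-sample t-test on the (subject x trial x channel) samples."""
    sel = table[(table.biomarker == biomarker) & (table.task == task)
                & (table.region == region)].dropna(subset=["value"])
    mci = sel[sel.group == "MCI"].value.to_numpy()
    hc = sel[sel.group == "HC"].value.to_numpy()
    if len(mci) < 2 or len(hc) < 2:
        raise ValueError(
            f"need >= 2 samples per group (got {len(mci)} MCI, {len(hc)} HC)")
    t, _ = stats.ttest_ind(mci, hc, equal_var=True)
    p = _tail_p(float(t), len(mci) + len(hc) - 2, tail)
    return StatResult(
        biomarker=biomarker, task=task, region=region,
        mean_mci=float(mci.mean()), sd_mci=float(mci.std(ddof=1)), n_mci=len(mci),
        mean_hc=float(hc.mean()), sd_hc=float(hc.std(ddof=1)), n_hc=len(hc),
        tvalue=float(t), pvalue=p, tail=tail, significant=p < ALPHA)


def lda_cv(X: np.ndarray, y: np.ndarray, k: int = 10,
           seed: int = 0) -> tuple[float, ...]:
    """Stratified k-fold accuracies of a pooled-covariance Gaussian LDA.

    A singular pooled covariance falls back to ridge-style shrinkage with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} samples")
    accs = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                clf = LinearDiscriminantAnalysis(solver="svd")
                clf.fit(X[tr], y[tr])
        except Exception:
            warnings.warn("singular pooled covariance; using shrinkage LDA")
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            clf.fit(X[tr], y[tr])
        accs.append(float(clf.score(X[te], y[te])))
    return tuple(accs)


def lda_crossval(table: pd.DataFrame, biomarker: "int | list[int]",
                 task: "str | None" = None, region: "str | None" = None,
                 k: int = 10, seed: int = 0) -> CVResult:
    """Per-biomarker (or multi-feature) LDA with stratified k-fold CV.

    Samples are the individual (subject, trial, channel) biomarker values;
    with a list of biomarker ids, values are pivoted to one feature column
    each and rows with any missing feature are dropped.
    """
    ids = [biomarker] if np.isscalar(biomarker) else list(biomarker)
    sel = table[table.biomarker.isin(ids)]
    if task is not None:
        sel = sel[sel.task == task]
    if region is not None:
        sel = sel[sel.region == region]
    wide = sel.pivot_table(index=["subject", "group", "task", "trial", "channel"],
                           columns="biomarker", values="value").dropna()
    if wide.empty:
        raise ValueError("no complete samples for the requested scope")
    X = wide.to_numpy()
    y = np.asarray(wide.index.get_level_values("group") == "MCI", dtype=int)
    accs = lda_cv(X, y, k=k, seed=seed)
    scope = f"biomarker={ids} task={task or 'all'} region={region or 'all'}"
    return CVResult(classifier="LDA", accuracies=accs,
                    n_samples=X.shape[0], scope=scope)


def resize_hemo_for_cnn(epochs: EpochSet, roi: RoiSelection,
                        window: tuple[float, float] = (0.0, 60.0),
                        size: int = 48) -> np.ndarray:
    """ROI dHbO epochs as (n_trials, size, size) channel x time matrices.

    ROI channels occupy their layout rows (zero elsewhere); the time axis is
    linearly resampled to ``size`` columns over the task window.
    """
    if not roi.channels:
        raise ValueError("empty ROI")
    sl = epochs.window_slice(*window)
    t_src = epochs.times[sl]
    t_new = np.linspace(t_src[0], t_src[-1], size)
    out = np.zeros((epochs.n_trials, size, size))
    for k in range(epochs.n_trials):
        for ch in roi.channels:
            if ch > size or ch > N_CHANNELS:
                continue
            out[k, ch - 1] = np.interp(t_new, t_src, epochs.hbo[k, ch - 1, sl])
    return out


def _subject_split(subject_ids, y, test_frac, rng):
    """Stratified subject-level train/test index split."""
    subject_ids = np.asarray(subject_ids)
    test_subj = []
    for label in np.unique(y):
        subj = np.unique(subject_ids[y == label])
        subj = rng.permutation(subj)
        n_test = max(1, int(round(test_frac * len(subj))))
        test_subj.extend(subj[:n_test])
    test_mask = np.isin(subject_ids, test_subj)
    return np.nonzero(~test_mask)[0], np.nonzero(test_mask)[0]


def cnn_train_eval(images: np.ndarray, labels: np.ndarray,
                   config: CnnConfig = CnnConfig(), *, repeats: int = 6,
                   seed: int = 0, subject_ids=None, test_frac: float = 0.2,
                   scope: str = "") -> CVResult:
    """Train the small CNN and report held-out accuracy per repeat.

    Each repeat draws a stratified train/test split -- at the subject level
    when ``subject_ids`` is given, preventing trial leakage -- then selects
    the learning rate from ``config.learning_rates`` on an inner validation
    split and scores the refit model on the held-out set.
    """
    X = np.asarray(images, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 3:
        raise ValueError("images must be (n, height, width)")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    accs = []
    for r in range(repeats):
        rng = np.random.default_rng((seed + 1) * 10_000 + r)
        if subject_ids is not None:
            tr, te = _subject_split(subject_ids, y, test_frac, rng)
        else:
            order = rng.permutation(len(y))
            n_test = max(2, int(round(test_frac * len(y))))
            te, tr = order[:n_test], order[n_test:]
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("class absent in a split; stratification failed")
        # inner validation split from the training portion
        tr = rng.permutation(tr)
        n_val = max(2, int(round(0.25 * len(tr))))
        va, tr2 = tr[:n_val], tr[n_val:]
        if len(np.unique(y[tr2])) < 2:
            tr2, va = tr, tr[:n_val]
        mu, sd = X[tr2].mean(), X[tr2].std() or 1.0
        Xn = (X - mu) / sd
        best = (-np.inf, None)
        for lr in config.learning_rates:
            net = SmallCnn(config, input_shape=X.shape[1:],
                           rng=np.random.default_rng(rng.integers(2 ** 31)))
            val_acc = net.fit(Xn[tr2], y[tr2], lr=lr, X_val=Xn[va], y_val=y[va])
            if val_acc > best[0]:
                best = (val_acc, net)
        accs.append(float((best[1].predict(Xn[te]) == y[te]).mean()))
    return CVResult(classifier="CNN", accuracies=tuple(accs),
                    n_samples=len(y), scope=scope)


def report(stat_results: "list[StatResult]" = (),
           cv_results: "list[CVResult]" = (), *,
           out_dir: "str | Path | None" = None,
           fdr_column: bool = False) -> dict[str, pd.DataFrame]:
    """Assemble biomarker statistics and accuracy grids as tidy tables.

    Returns ``{"stats": ..., "accuracy": ...}`` and optionally writes both
    as CSV plus a JSON summary.  Deterministic given its inputs; empty
    inputs yield empty tables with schema headers.
    """
    stats_rows = [vars(s) for s in stat_results]
    stats_df = pd.DataFrame(stats_rows, columns=[
        "biomarker", "task", "region", "mean_mci", "sd_mci", "n_mci",
        "mean_hc", "sd_hc", "n_hc", "tvalue", "pvalue", "tail", "significant"])
    if fdr_column and not stats_df.empty:
        from statsmodels.stats.multitest import multipletests
        stats_df["pvalue_bh_extension"] = multipletests(
            stats_df.pvalue, method="fdr_bh")[1]
    acc_df = pd.DataFrame(
        [dict(classifier=c.classifier, scope=c.scope,
              mean_accuracy=c.mean_accuracy, n_samples=c.n_samples,
              accuracies=list(c.accuracies)) for c in cv_results],
        columns=["classifier", "scope", "mean_accuracy", "n_samples",
                 "accuracies"])
    out = {"stats": stats_df, "accuracy": acc_df}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stats_df.to_csv(out_dir / "biomarker_stats.csv", index=False)
        acc_df.to_csv(out_dir / "classification_accuracy.csv", index=False)
        summary = {
            "n_stat_results": len(stats_df),
            "n_significant": int(stats_df.significant.sum()) if len(stats_df) else 0,
            "classifiers": {c.scope or c.classifier: c.mean_accuracy
                            for c in cv_results},
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
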