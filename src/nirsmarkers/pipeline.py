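"""End-to-end convenience pipeline: simulate -> preprocess -> ROI -> biomarkers.

``analyze_cohort`` runs the full chain on a list of hemodynamic recordings
(band-pass, epoching, per-subject/task GLM fits, automatic ROI selection,
biomarker battery) and returns the intermediate products for downstream
statistics, LDA and CNN evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .biomarkers import extract_battery
from .containers import EpochSet, HemoRecording
from .glm import GlmFit, RoiSelection, T_CRIT_DEFAULT, fit_epochs, select_roi
from .hrf import HrfParams
from .paradigm import ParadigmSpec
from .preprocess import bandpass, epoch


@dataclass
class CohortAnalysis:
    epochs: dict[tuple[str, str], EpochSet]            # (subject, task)
    fits: dict[tuple[str, str], list[GlmFit]]
    roi: dict[tuple[str, str], RoiSelection]
    biomarkers: pd.DataFrame


def analyze_cohort(recordings: list[HemoRecording],
                   paradigm: ParadigmSpec = ParadigmSpec(), *,
                   hrf: HrfParams = HrfParams(), robust: bool = True,
                   t_crit: float = T_CRIT_DEFAULT,
                   filter_band: tuple[float, float] = (0.001, 0.1),
                   trials_averaged: bool = False) -> CohortAnalysis:
    """Run preprocessing, GLM/ROI and the biomarker battery over a cohort.

    The GLM is fit per channel on the trial-averaged epoch per subject/task;
    the automatic ROI (t > t_crit, p < 0.05) is selected per subject/task and
    the 15-biomarker battery evaluated on that subject's ROI channels.
    """
    epochs: dict[tuple[str, str], EpochSet] = {}
    fits: dict[tuple[str, str], list[GlmFit]] = {}
    roi: dict[tuple[str, str], RoiSelection] = {}
    tables = []
    for rec in recordings:
        key = (rec.subject, rec.task)
        filtered = bandpass(rec, *filter_band)
        es = epoch(filtered, paradigm)
        epochs[key] = es
        ch_fits = fit_epochs(es, hrf, duration=paradigm.task_duration,
                             robust=robust)
        fits[key] = ch_fits
        sel = select_roi(ch_fits, "auto", t_crit=t_crit)
        roi[key] = sel
        tables.append(extract_battery(es, sel, trials_averaged=trials_averaged))
    biomarkers = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return CohortAnalysis(epochs=epochs, fits=fits, roi=roi,
                          biomarkers=biomarkers)
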