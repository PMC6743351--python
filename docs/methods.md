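# Methods

This note documents the models, parameter choices and numerical conventions
behind `nirsmarkers`, and what the synthetic-cohort tests do and do not show
about real recordings.

## Signal model and preprocessing

Raw two-wavelength intensities I(λ, t) are converted channel-wise through
the modified Beer–Lambert law: ΔOD(λ) = −log₁₀(I/I₀) and
[ΔHbO, ΔHbR] = (d · DPF(λ) · E)⁻¹ · ΔOD, with source–detector distance
d = 3 cm, differential pathlength factor DPF = 6.0 at both wavelengths, and
a standard compiled extinction table at 780/850 nm (in 1/(mM·cm): HbO
0.736/1.058, HbR 1.105/0.691). Neither DPF nor extinction values affect any
round-trip result — the simulator's inverse uses the same `MbllParams` — and
both are overridable. The reference intensity I₀ is the stored simulator
baseline when present, otherwise the mean over the first 30 s of rest
(configurable). Concentrations are in an arbitrary molar-change unit; the
synthetic generator works on the 10⁻⁷–10⁻⁶ scale typical of such analyses.

Band-pass filtering uses two fourth-order Butterworth filters (high-pass
0.001 Hz, low-pass 0.1 Hz) applied zero-phase (forward–backward), so
biomarker windows are not shifted by group delay; the effective attenuation
is the squared single-pass magnitude. The low-pass runs first: the near-DC
high-pass has a ~160 s time constant, and applying it to a signal whose
edges still contain broadband content smears edge transients across a whole
300 s session. With this ordering the cascade passes a 0.01 Hz tone at
≥ 99 % amplitude, suppresses a 1.0 Hz cardiac tone to ≤ 1 %, and removes DC
to numerical precision. Whether the original analysis filtered optical
densities or concentrations is ambiguous; concentrations are filtered here
(conversion first), which for a linear chain differs only by the MBLL
matrix factor.

Epochs span [−10, +70] s around each task onset (closed at both ends,
onset mapped to the nearest sample); windows given in seconds are read as
half-open [t1, t2) in samples. The 10 s pre-task window is the baseline.
Channels are 1-based to match the device numbering.

## HRF, GLM and ROI

The canonical HRF is a double gamma normalized to unit peak. The gammas are
parameterized by their **mode**: a response peaking at `peak_delay` (6 s)
and an undershoot troughing at `undershoot_delay` (16 s), dispersion 1,
peak-to-undershoot ratio 6 (all configurable). Under this convention the
positive lobe of the default HRF ends (first zero crossing after the peak)
at 13.31 s — which is also where a sustained-boxcar block response peaks,
since its derivative is the HRF while the stimulus is on. The peak-time
biomarker tests use this numerically located zero crossing as their oracle.

Each channel is modeled as z(t) = β·f(t) + c + ε with f = h ⊗ s. An
intercept is included even though the activation model is often written
without one: with baseline offsets present, omitting it biases β. The
default fitter is iteratively reweighted least squares with the bisquare
(Tukey biweight) ψ at tuning constant 4.685 — the standard default of
`robustfit`-style routines — via `statsmodels.RLM`; on (near-)perfect fits,
where the robust scale estimate collapses, the OLS standard error is
substituted so noiseless data reduces exactly to least squares. A
closed-form OLS fitter serves as the independent oracle in tests. t = β/se
with dof = n − 2 and a one-sided (upper-tail) p. Fits run on the
trial-averaged epoch per subject/task by default; per-trial fitting is
available for per-trial image biomarkers.

The automatic ROI keeps channels with t > 1.6469 **and** p < 0.05 computed
from the actual dof (the 1.6469 constant is honored verbatim; it implies
roughly 800 dof). Note the consequence: each null channel is a one-sided 5 %
test, so across 48 channels a handful of false positives is *expected* —
that is a property of the selection rule, not of the implementation. The
ROI-recovery Monte-Carlo therefore checks exact recovery under a
familywise Bonferroni threshold (α = 0.01 over 48 channels), where exact
recovery of high-SNR channels is actually attainable, and the per-channel
5 % calibration of the verbatim threshold is asserted separately.

## Digital biomarkers

The battery holds 15 features per (subject, task, trial, ROI channel):
mean changes of ΔHbO/ΔHbR over 5–65 s, 5–25 s and 0–peak; slopes
(per second, degree-1 least squares) over 5–15, 20–60, 60–70 s and 0–peak;
ΔHbO time-to-peak (largest local maximum over 0–60 s via peak detection,
falling back to the window argmax flagged "boundary peak"); and biased
skewness and non-excess kurtosis (Gaussian → 3) over 5–65 s. "0–peak"
windows always end at the ΔHbO peak of that trial/channel, including for
HbR features.

Two forms of the mean-change feature exist. The *relative* form
(task mean − baseline mean) / baseline mean is the textbook definition and
is what `mean_change` computes by default; it is guarded (ε = 10⁻¹²)
because after high-pass filtering the 10 s baseline mean is zero-mean noise,
making the ratio's sign and magnitude arbitrary. The battery therefore
defaults to the *difference* form, task mean − baseline mean, whose values
live on the concentration scale (10⁻⁷–10⁻⁶) — consistent with how such
tables are reported — and which makes group-effect recovery well-posed.
The relative form remains available per `BiomarkerSpec`. Missing values
(degenerate baseline, zero variance, peak too early) carry reason codes and
are dropped listwise in downstream statistics.

The peak-search window is 0–60 s (the task period); the 60–70 s recovery
tail is excluded because its decay is not a response peak.

## Image biomarkers

The t-map is the 48-vector of channel t-values. For CNN input it is
rendered to 48×48 by inverse-distance-weighted interpolation (power 2,
all-channel neighborhood) over the probe's bounding box on a synthetic but
region-faithful planar layout (three 4×4 blocks: right, middle, left PFC;
how the original 48 t-values became a 48×48 image is not recoverable, so a
normalized outer-product "matrix" mode is also provided and the mode is
recorded on the image). The correlation map is the 48×48 Pearson matrix of
channel ΔHbO over the task window (trials concatenated by default) and is
used unrendered; zero-variance channels are masked to NaN with a warning.

## Classification

LDA is pooled-covariance Gaussian discriminant analysis (scikit-learn) with
stratified 10-fold cross-validation, one biomarker at a time by default
(multi-feature pivoting available); a singular pooled covariance falls back
to shrinkage with a warning. Samples are the individual
(subject × trial × ROI channel) values.

The CNN (pure numpy, authored in-package) has two convolutional and two
fully connected layers with ReLU, max-pooling and dropout 0.25, softmax
cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), batch size 4. β₂ is
configurable; values like 0.1 are accepted but 0.999 is the default since
a near-zero second-moment decay makes Adam behave like sign-SGD and is
almost certainly a transcription artifact wherever it appears. The default
convolution follows the text-CNN convention — filter width equal to the
input width, kernel height 3, sliding over rows — with a conventional 3×3
2-D mode as an alternative. Evaluation uses repeated (default 6) stratified
train/test splits at the *subject* level, preventing trial leakage, with the
learning rate chosen from {10⁻², 10⁻³, 10⁻⁴} on an inner validation split
and early stopping (patience 10). Tests and examples use a reduced budget
(20 epochs, single learning rate) appropriate to their small problem sizes.

Group t-tests are pooled-variance two-sample tests. `tail="one"` reports
the upper-tail probability of |t| — the convention under which the
demographic table's Age and Education p-values (0.36, 0.36) reproduce from
their printed means/SDs/ns; the K-MMSE row does not match any standard
two-sample test under either tail and is left as an open inconsistency of
the source table. Raw p-values are reported (no multiplicity correction,
matching the original analysis); `report` can add a Benjamini–Hochberg
column explicitly marked as an extension.

## Synthetic cohort: what it emulates, what it does not

Defaults encode the study conditions: 15 MCI / 9 HC, 8.138 Hz, three
60 s trials per task with 30 s rests and a 30 s lead-in. Active channels
(half of each region's 16, chosen per subject) carry
amplitude · (h ⊗ s)(t − latency) in ΔHbO with the block response normalized
to unit peak, so `amplitude` is the peak concentration change; ΔHbR is
−1/3 of the clean ΔHbO response plus its own noise. Group structure
mirrors the qualitative published pattern — HC left-PFC amplitude 1.0·10⁻⁶
vs MCI 0.5·10⁻⁶, other regions matched at 0.6·10⁻⁶, MCI onset delayed 2 s —
these are configuration values, not claims about patients. Noise sums
random-phase sinusoids (cardiac 1.1 Hz amp 2·10⁻⁷, respiration 0.25 Hz
1.5·10⁻⁷, Mayer 0.1 Hz 10⁻⁷), a random-walk drift (step SD 10⁻⁸) and white
measurement noise (SD 10⁻⁷); the source data's noise floor is
uncharacterized, so these are plausible placeholders chosen once. Equal
seeds give bit-identical cohorts.

Not emulated: motion artifacts, short-separation channels, inter-subject
anatomical variability, serial correlations beyond the modeled physiological
rhythms, and any nonstationarity of attention. Passing tests therefore
demonstrate that the pipeline recovers known structure under its own model
assumptions — not that the published patient-data accuracies (which depend
on a non-deposited clinical dataset) are reproducible; those headline
accuracies are deliberately not targets.

## Problem sizes and numerical choices

The test suite and acceptance script size their Monte-Carlo studies for a
single CPU: 1000 null channels for GLM calibration, 100 seeds for ROI
recovery, 20 seeds for label-permutation nulls and for end-to-end
sign-recovery (one task, full 24-subject cohorts). Tolerances: MBLL round
trips to 10⁻⁹ relative; filter contract 1 %/99 % at steady state (3000 s
tones, mid-signal amplitude); peak-time oracle ±0.5 s; type-I rate 5 ± 2 %.
Ties and degenerate inputs: zero-variance design or empty windows raise;
β = 0 with zero standard error yields t = 0; boundary peaks and degenerate
baselines are flagged, not silently dropped.
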