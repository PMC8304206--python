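# Methods

This note documents the models, estimators and design choices behind
`cardiocoupling`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Interval-series construction

The pipeline consumes per-beat fiducial annotation tables (one row per
cardiac cycle, times in ms): R peak, Q onset, T peak, T offset, S1 offset,
S2 onset, S2 offset, next S1 onset. The final row is a terminal beat that
only closes the last RR interval. From these it builds six series:

| series | definition | side |
|---|---|---|
| RRI | R(i+1) − R(i) | electrical |
| QTcI | (Toff − Qon) / √(RRI/1000) (Bazett) | electrical |
| TpeI | Toff − Tpeak | electrical |
| Tpe/QTI | TpeI / QTI | electrical |
| STI | S2on − S1off | mechanical |
| DTI | nextS1on − S2off | mechanical |

Bazett's correction uses the *same-beat* RR. Heart-rate influence on QT is
known to act with a lag of several beats, so a lagged or averaged RR would
also be defensible; same-beat RR is the simplest convention and is what the
correction formula literally states. The choice is isolated in
`bazett_correct` if a user needs to change it.

STI is defined S1-offset → S2-onset, i.e. it *excludes* the S1 sound
itself. Part of the literature defines systole S1-onset → S2-onset; the
S1-offset convention is used here throughout, and because S1 duration is
nearly constant beat-to-beat the two differ by an almost-constant offset
that z-normalization removes anyway.

### Anomalous-beat screening and the 10% rule

Real annotation streams contain mis-detected fiducials. Since no published
numeric criterion exists for "anomalous" (the decision is normally a
cardiologist's), the package codifies two configurable rules, OR-combined
per beat:

* hard physiologic bounds — RRI 300–2000 ms, STI 150–600 ms,
  DTI 100–1500 ms, TpeI 20–200 ms;
* robust outliers — residual from an 11-beat centered rolling median
  exceeding k = 5 robust SDs (1.4826 × MAD of the residuals). This catches
  ectopy-like jumps that stay inside the hard bounds.

A beat flagged in any series is removed from *all six* series, preserving
ECG–PCG beat alignment. A subject is invalid when the flagged fraction
strictly exceeds 10% ("beyond 10%" reads as a strict inequality: exactly
10.0% is still valid), or when fewer than 30 usable beats remain — entropy
estimates on shorter series are too unstable to be worth reporting.

## Series pairs and normalization

The eight canonical pairs are the electrical × mechanical product, in fixed
order: RRI–STI, RRI–DTI, QTcI–STI, QTcI–DTI, TpeI–STI, TpeI–DTI,
Tpe/QTI–STI, Tpe/QTI–DTI. Each member is z-scored (mean 0, population
SD 1) before any measure is applied; the entropy tolerance r is therefore
in SD units, the convention that makes r = 0.2 meaningful across subjects.
Constant series cannot be normalized and raise.

## Coupling measures

**XSampEn** (m = 2, r = 0.2, delay 1). Templates are drawn one from each
series; distance is the Chebyshev max-norm. Although template vectors of
length m can be indexed up to N−m+1, the estimator averages over N−m
templates at *both* lengths m and m+1, the standard sample-entropy
convention that keeps B⁽ᵐ⁾ and B⁽ᵐ⁺¹⁾ comparable. Zero matches at either
length make the conditional probability undefined; this is raised as a
distinct `UndefinedEntropyError`, not returned as ∞. At the cohort level
such features become missing values imputed with the cohort maximum — a
zero-match pair is at least as irregular as the most irregular finite
estimate observed.

**XFuzzyEn** replaces the hard threshold with the Gaussian membership
exp(−ln2·(d/r)²), which equals ½ exactly at d = r and is strictly
positive, so the estimate always exists.

**JDistEn** (m = 2, τ = 3). Each series is delay-embedded; N − m·τ
embedding vectors are used. Each series' Chebyshev self-distance matrix is
rescaled to [0, 1] by its own largest entry — some normalization is
required for the joint combination below to remain a distance in [0, 1],
and the per-matrix maximum is the choice that makes the rescaling
scale-free. The joint matrix is the element-wise geometric-mean
combination

    JD = J − √((J − D₁) ∘ (J − D₂)),

which reduces to JD = D for identical series and stays in [0, 1]; the
plain product form JD = J − (J−D₁)(J−D₂), which appears in part of the
literature but breaks the distance range, is available via
`geometric_mean=False`. The upper-triangle off-diagonal entries of JD are
histogrammed into B equal-width bins on the fixed support [0, 1], with B
from Doane's rule B = round(1 + log₂n + log₂(1 + |g₁|/σ_g₁)); empty bins
contribute nothing, and the Shannon entropy is normalized by log₂B so the
value lies in [0, 1]. Fewer than two bins (degenerate geometry) yields 0.

**MSCF / ICPSD.** The interval series are treated as evenly sampled in the
*beat domain* — the measures consume beat-indexed series directly, so
frequencies are in cycles/beat on (0, 0.5]. Spectra are Welch-averaged
(Hamming taper, 50% overlap, segment length min(N, 128), shrunk to
N/(2−overlap) when needed so that at least two segments exist — a single
segment makes coherence identically 1 and is rejected). MSCF is
|Pxy|²/(Pxx·Pyy) ∈ [0, 1]; ICPSD is |Im Sxy| = AxAy|sin Δφ|, which
vanishes for in-phase or anti-phase covariation and isolates lagged
coupling. Both are summarized by mean and SD over the full band excluding
DC; a restricted band can be configured (`fmin`/`fmax`) but no
physiological band is imposed by default, because in the beat domain the
usual Hz-defined HRV bands do not map cleanly.

**Mutual information.** Gaussian-kernel density estimates with the
multivariate Silverman bandwidth h = (4/(d+2))^{1/(d+4)} N^{−1/(d+4)} on
covariance-scaled kernels; the marginals use the d = 1 rule and the joint
the d = 2 rule (a shared d = 2 bandwidth is available behind
`per_dimension_bandwidth=False`). The estimate is the plug-in empirical
average (1/N) Σ log₂ p̂xy/(p̂x·p̂y) at the sample points. By default each
sample's own kernel is excluded from the density at that sample
(leave-one-out): including the self-match inflates the joint density more
than the marginal product and biases the MI of independent series upward
by about +0.06 bits at N = 300, while leave-one-out is near-unbiased there
at the cost of occasional small negative estimates, which are reported as
computed, never clipped. Resubstitution is available via
`leave_one_out=False`.

### Feature vector

64 features per subject, family-blocked and pair-ordered, named
`<elec>-<mech>-<suffix>`: 24 entropy (XS, XF, JD), 16 MSCF (mean, sd),
16 ICPSD (mean, sd), 8 MI.

## Group statistics

Per feature: each group's values are screened for normality with the
Kolmogorov–Smirnov statistic under the Lilliefors correction — required
because the Gaussian parameters are estimated from the same sample; the
uncorrected KS test against a fitted Gaussian is anti-conservative and is
kept only behind `normality="ks"`. If every group passes at α = 0.05 the
omnibus test is one-way ANOVA, otherwise Kruskal–Wallis. Post hoc pairwise
comparisons (two-sample t or Mann–Whitney U to match the omnibus branch)
are Bonferroni-corrected within the per-feature family of 3 comparisons:
p_adj = min(1, 3p). No cross-feature correction is applied — the report is
per-feature, and the permutation test below verifies that the per-feature
family-wise error is controlled. Stars follow the usual convention
(* p < 0.05, ** p < 0.01 after correction).

## Classification

Three binary tasks (severe vs mild-moderate, severe vs CPNCA,
mild-moderate vs CPNCA), the more-stenosed group being the positive class.
Per task and split:

1. stratified 70/30 train/test split;
2. features z-scored with training statistics only;
3. SVM-RFE on the training split: a linear SVM is refit repeatedly, each
   iteration removing the feature with the smallest squared weight (ties
   broken by column order); rank 1 = last survivor;
4. the retained count k is chosen by 5-fold CV accuracy over {8, 16, 24}
   (default; a fixed k can be configured) — k is data-dependent, so no
   particular subset size is targeted;
5. XGBoost with per-sample weight w = 2.5 on the minority class
   (equivalent to a positive-class scale factor; sweepable to reproduce a
   weight-tuning protocol), hyperparameters from a small grid
   (max_depth ∈ {2,3}, learning rate ∈ {0.1,0.3}, 100 trees) by 5-fold
   stratified CV on the training split;
6. held-out evaluation: accuracy, F1 (harmonic mean of sensitivity and
   precision), sensitivity, specificity, AUC from predicted probabilities,
   plus the confusion matrix from which all ratio metrics are exactly
   recomputable.

A single 70/30 split is one realization; by default every task is repeated
over 10 seeded splits and metrics are averaged. Feature-family masks
(`entropy`, `mscf`, `icpsd`, `mi`) allow single-family and joint-family
comparisons. AUC is computed on the test split (not within CV). Groups
with fewer than 10 subjects skip the task with a warning.

## Synthetic cohort model

The generator emulates what the coupling measures actually consume:
~5-minute beat-interval series with physiologic levels, beat-to-beat
variability, and a *single-scalar* coupling strength.

* RRI is a stationary mean-reverting AR(1) around mean_rr = 900 ms with
  coefficient 0.8 and innovation SD 25 ms (SDNN-like variability).
* QTcI, TpeI and STI are AR(1) series (same coefficient) whose innovation
  is a convex mixture with weight ρ of the *normalized RRI innovation* and
  independent unit noise, scaled by a per-series SD (8 / 6 / 10 ms). At
  ρ = 1 every derived series is an exact linear image of the RRI
  innovations; at ρ = 0 all innovations are independent. A shared-
  innovation mixture was chosen over phase coupling because it is the
  simplest mechanism whose strength is one scalar that every measure in
  the package — time-domain, spectral and information-theoretic — should
  detect.
* DTI follows from the beat budget DTI = RRI − S1 − STI − S₂ (S1 = 100 ms,
  S2 = 90 ms), as it must for the landmark times of one cycle to add up.
* QTI is recovered from QTcI by inverse Bazett; Tpe/QTI = TpeI/QTI.
* Group effects: coupling decreases with stenosis severity
  (ρ defaults 0.2 / 0.5 / 0.8 for severe / mild-moderate / CPNCA), and the
  repolarization series are elevated and more dispersed with severity
  (TpeI means 125 / 100 / 75 ms, dispersion × 1.8 / 1.3 / 1.0; the
  comparison group sits inside the 40–110 ms and 0.15–0.25 normal ranges).
  No other mean shifts are injected, so that classification tests
  genuinely exercise coupling rather than trivial level differences —
  note that z-normalization inside the measures removes level and scale
  anyway. Default group sizes 114/37/40 mirror the imbalance typical of
  cardiology recruitment.
* Annotations are laid out so that re-extraction reproduces the stored
  series exactly (inverse-Bazett QT spacing, cumulative R peaks); this
  round trip is tested to 1e-9 ms.
* Anomaly injection replaces ⌈f·n⌉ random beats with RRI far outside
  300–2000 ms and STI above its band, recording the corrupted indices, to
  exercise the screening and the 10% rule. The uniform-replacement model
  is a deliberate simplification: no published definition of "anomalous"
  exists to emulate.

What the generator does **not** model: waveform morphology, arrhythmia
dynamics, respiratory sinus arrhythmia spectra, circadian or temperature
effects, QT-RR hysteresis, non-stationarity. Passing tests on synthetic
cohorts therefore demonstrate that the estimators detect shared-innovation
coupling of known strength under physiologic levels and noise — not that
any particular clinical accuracy would be attained on real recordings.

## Numerical choices and degenerate inputs

* All generators and pipeline stages are pure functions of (config, seed);
  per-stage seeds derive from one global seed via hashed spawn keys.
* Entropy tolerance comparisons use `d <= r` (closed ball).
* Zero-match XSampEn → error → missing feature → cohort-max imputation.
* Constant series → normalization error (subject-level report), singular
  covariance → MI error.
* JDistEn with an all-zero distance matrix returns 0 (single-bin
  distribution); fewer than 2 Doane bins returns 0.
* Coherence with one segment is identically 1 and therefore rejected
  rather than reported.
* Spectral SDs use the sample convention (ddof = 1).

## Problem sizes used in the shipped checks

The test suite and acceptance script run at deliberately desk-scale sizes:
300-beat subjects (~5 min at 900 ms), 50 random pairs for the
cross-entropy reference comparison, 50 seeds for MI calibration, 20 seeds
per coupling level for effect sizes, 200 label permutations for
family-wise-error calibration, and a 60-per-group cohort with 10 repeated
splits for classification power. These sizes give stable Monte-Carlo
estimates for every tolerance asserted while keeping a full run in minutes
on one core.

## Known limitations

* The anomaly criteria are a codification, not a validated clinical rule.
* Beat-domain spectral analysis ignores the uneven wall-clock spacing of
  beats; resampling to even time would change the frequency axis.
* The leave-one-out KDE MI estimator remains biased for strongly dependent
  data (smoothing bias, visible as ~−0.03 bits at ρ = 0.8 against the
  Gaussian closed form at N = 300).
* SVM-RFE ranks features by linear-margin weights; purely nonlinear
  feature relevance can be under-ranked before the boosted classifier ever
  sees it.
* The three-group problem is handled as three binary tasks; no multi-class
  classifier is provided.
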