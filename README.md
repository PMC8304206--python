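# cardiocoupling

Quantifying cardiac **mechano-electric coupling** from synchronized ECG and
phonocardiogram (PCG) recordings, at the level of beat-interval series.

The heart's electrical activity (depolarization/repolarization, seen in the
ECG) and its mechanical activity (valve events, heard in the PCG) regulate
each other through mechano-electric feedback. Coronary artery stenosis
degrades this regulation, so the *statistical coupling* between
electrically derived and mechanically derived beat-interval series carries
diagnostic information. This package implements the full analysis chain for
that idea, aimed at biosignal researchers working with beat-level fiducial
annotations rather than raw waveforms:

1. **Interval series** — from per-beat landmark times (R peak, Q onset,
   T peak/offset, S1/S2 boundaries) build six series, one value per cardiac
   cycle: RRI, QTcI (Bazett: QTc = QT/√RR), TpeI, Tpe/QTI on the electrical
   side and STI (S1 offset → S2 onset), DTI (S2 offset → next S1 onset) on
   the mechanical side. Implausible beats are masked (hard physiologic
   bounds + rolling-median/MAD outlier rule); a subject with more than 10%
   masked beats is excluded.
2. **Coupling features** — each of the 8 electrical x mechanical pairs is
   z-normalized and scored by six measures, giving 64 features per subject:
   * cross sample entropy `XSampEn(m, r) = -ln(B⁽ᵐ⁺¹⁾/B⁽ᵐ⁾)` with
     Chebyshev template matching at tolerance `r` (default m=2, r=0.2 SD);
   * cross fuzzy entropy, replacing the hard match by the Gaussian
     membership `exp(-ln2 · (d/r)²)`;
   * joint distribution entropy: Shannon entropy (normalized by log₂B,
     B from Doane's rule) of the joint distance matrix
     `JD = J - √((J-D₁)∘(J-D₂))` of the two delay-embedded series
     (m=2, τ=3);
   * mean/SD of the magnitude-squared coherence `|Pxy|²/(Pxx·Pyy)`;
   * mean/SD of `|Im Sxy|`, the phase-lagged part of the cross-spectrum;
   * kernel-density mutual information (Gaussian kernels, Silverman
     bandwidths, leave-one-out plug-in estimate in bits).
3. **Group statistics** — Lilliefors-screened ANOVA or Kruskal–Wallis per
   feature, pairwise post hoc tests across the three stenosis groups
   (severe ≥70%, mild-moderate 30–69%, CPNCA <30%), Bonferroni-corrected at
   α = 0.05.
4. **Classification** — per pairwise group task: stratified 70/30 split,
   SVM-RFE feature ranking on the training split, weighted XGBoost
   (minority-class weight w = 2.5) tuned by five-fold CV, held-out
   accuracy / F1 / sensitivity / specificity / AUC.

Clinical recordings of this kind are generally not shareable, so the
package includes a first-class synthetic-cohort generator
(`cardiocoupling.synthetic`) producing coupled AR(1) interval series — and
matching fiducial-annotation files — whose electrical-mechanical coupling
strength ρ is an explicit per-group dial. See `docs/methods.md` for the
model and its limitations.

## Worked example

```python
import cardiocoupling as cc

config = cc.SyntheticCohortConfig(
    n_per_group={"severe": 20, "mild-moderate": 20, "cpnca": 20},
    seed=42,
)
cohort = cc.gen_cohort(config)
subject = cohort.subjects[0]
print(subject.subject_id, subject.group, "rho =", subject.coupling_rho)

fv = cc.extract_features(subject.series_set)
print(fv.values[["RRI-STI-XS", "RRI-STI-JD",
                 "RRI-STI-MSCF-mean", "RRI-STI-MI"]].round(3))
```

```
severe-000 severe rho = 0.2
RRI-STI-XS           1.687
RRI-STI-JD           0.739
RRI-STI-MSCF-mean    0.345
RRI-STI-MI           0.062
```

This severe-group subject has weak coupling (ρ = 0.2): its heart-period and
systolic-interval series share little structure, so the cross entropy is
high (1.69 — templates of one series poorly predict the other), mean
coherence is low (0.35) and mutual information is near zero (0.06 bits).

Screening the 24 entropy features across the cohort and classifying:

```python
features = cc.extract_cohort_features(cohort.subjects, families=("entropy",))
report = cc.compare_groups(features)
print(report[report["significant"]][["feature", "comparison", "p_adj"]].head(5))

results = cc.run_pairwise_tasks(features, cc.ClassifierConfig(n_repeats=5), seed=1)
print(cc.summarize_reports(results)[["task", "accuracy", "f1", "auc"]].round(3))
```

```
   feature              comparison        p_adj
RRI-STI-XS         severe vs cpnca 1.061124e-09
RRI-STI-XS  mild-moderate vs cpnca 1.331057e-09
RRI-STI-XF         severe vs cpnca 5.039699e-07
RRI-STI-XF  mild-moderate vs cpnca 1.086725e-06
RRI-STI-JD severe vs mild-moderate 8.875884e-06

                   task  accuracy    f1   auc
severe vs mild-moderate     0.833 0.838 0.894
        severe vs cpnca     0.967 0.966 0.967
 mild-moderate vs cpnca     0.850 0.805 0.925
```

The coupling features separate the groups exactly as designed: the task
with the largest coupling gap (severe vs CPNCA, Δρ = 0.6) is classified
almost perfectly, the adjacent-group tasks (Δρ = 0.3) less so.

## Command line

```bash
cardiocoupling all --seed 7 --out results/           # full pipeline
cardiocoupling features --family entropy --out results/
cardiocoupling all --config run.yaml                 # YAML-configured run
```

Each run writes annotation/series/feature CSVs, a statistics report, the
per-task classification summary and a `manifest.json` with the config hash,
seed and per-stage row counts.

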