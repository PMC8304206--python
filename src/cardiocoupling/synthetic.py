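"""Synthetic cohorts of coupled ECG/PCG beat-interval series.

Clinical recordings of the kind this pipeline analyses (synchronized ECG and
phonocardiogram from coronary-artery-disease patients) are rarely shareable,
so the package ships a generator that emulates their beat-interval structure
at the level the coupling measures consume: ~5-minute recordings (hundreds of
beats), physiologic interval ranges, beat-to-beat variability, and a tunable
electrical-mechanical coupling strength that differs by disease group.

Coupling mechanism
------------------
The heart-period series (RRI) is a mean-reverting AR(1) process.  Each
derived series (QTcI, TpeI, STI) is an AR(1) process of its own whose
innovation is a convex mixture, with weight ``rho`` (the coupling strength),
of the RRI innovation and independent noise:

    w_s[t] = sd_s * ( rho * e[t]/sd_e  +  (1 - rho) * eta_s[t] )

At ``rho = 1`` every derived series is a deterministic linear function of the
RRI innovations; at ``rho = 0`` the innovations are independent.  DTI follows
from the beat-budget identity DTI = RRI - S1 - STI - S2, as it must for the
landmark times of one cycle to add up.  The disease-group effect enters only
through ``rho`` (weaker coupling in more stenosed groups) and through the
level/dispersion of the repolarization series, not through shifts that a
z-normalized coupling measure could trivially pick up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import FiducialAnnotation, IntervalSeriesSet

__all__ = [
    "GROUPS",
    "GROUP_PROFILES",
    "SyntheticCohortConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "gen_interval_series",
    "gen_annotations",
    "inject_anomalies",
    "gen_cohort",
    "write_cohort",
]

#: Group labels in decreasing stenosis severity.  "cpnca" = chest pain with
#: normal coronary angiography (<30% stenosis), the comparison group.
GROUPS = ("severe", "mild-moderate", "cpnca")

# Fixed intra-beat durations (ms) used when laying out landmark times.
S1_DURATION = 100.0
S2_DURATION = 90.0
R_TO_S1_OFFSET = 120.0   # R peak -> S1 offset (electromechanical delay + S1)
Q_TO_R = 30.0            # Q onset precedes the R peak

#: Per-group series profiles.  QTc/Tpe levels and dispersion reflect the
#: qualitative clinical picture: severe stenosis shows elevated, more
#: dispersed repolarization intervals (TpeI above the 40-110 ms normal range,
#: Tpe/QT above 0.15-0.25), while the comparison group sits inside it.
GROUP_PROFILES: Mapping[str, Mapping[str, float]] = {
    "severe":        {"qtc_mean": 440.0, "tpe_mean": 125.0, "dispersion": 1.8},
    "mild-moderate": {"qtc_mean": 425.0, "tpe_mean": 100.0, "dispersion": 1.3},
    "cpnca":         {"qtc_mean": 410.0, "tpe_mean": 75.0,  "dispersion": 1.0},
}


def _default_rho() -> dict[str, float]:
    # Mechano-electric coupling decreases with stenosis severity.
    return {"severe": 0.2, "mild-moderate": 0.5, "cpnca": 0.8}


def _default_counts() -> dict[str, int]:
    # Mirrors the imbalanced group sizes typical of cardiology recruitment.
    return {"severe": 114, "mild-moderate": 37, "cpnca": 40}


def _default_noise_sd() -> dict[str, float]:
    return {"RRI": 25.0, "QTcI": 8.0, "TpeI": 6.0, "STI": 10.0}


@dataclass
class SyntheticCohortConfig:
    """Parameters of the synthetic cohort.

    ``coupling_rho`` maps group label to the shared-innovation fraction in
    [0, 1]; defaults are ordered severe < mild-moderate < cpnca.
    ``noise_sd`` gives the innovation SD (ms) per generated series.
    """

    n_per_group: dict[str, int] = field(default_factory=_default_counts)
    n_beats: int = 300
    mean_rr: float = 900.0
    rr_ar_coeff: float = 0.8
    coupling_rho: dict[str, float] = field(default_factory=_default_rho)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    anomaly_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats < 50:
            raise ValueError("n_beats must be at least 50")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if not 0.0 < self.rr_ar_coeff < 1.0:
            raise ValueError("rr_ar_coeff must lie in (0, 1)")
        for group, rho in self.coupling_rho.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group label {group!r}")
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"coupling_rho[{group!r}]={rho} outside [0, 1]")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("all noise SDs must be positive")
        if not 0.0 <= self.anomaly_fraction <= 1.0:
            raise ValueError("anomaly_fraction must lie in [0, 1]")


def _ar1(innovations: np.ndarray, coeff: float) -> np.ndarray:
    """Stationary AR(1) driven by the given innovations (deviation form)."""
    out = np.empty_like(innovations)
    out[0] = innovations[0] / np.sqrt(1.0 - coeff**2)
    for t in range(1, len(innovations)):
        out[t] = coeff * out[t - 1] + innovations[t]
    return out


def gen_interval_series(
    config: SyntheticCohortConfig,
    group: str,
    seed: int | np.random.SeedSequence | None = None,
) -> IntervalSeriesSet:
    """Generate one subject's six interval series for the given group.

    RRI is AR(1) around ``mean_rr``; QTcI, TpeI and STI are AR(1) series
    whose innovations mix the RRI innovation (weight ``rho`` for the group)
    with independent noise; TpeQTI and DTI are the element-wise derived
    ratio and diastole-budget series.  Deterministic under ``seed``.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(seed)
    profile = GROUP_PROFILES[group]
    rho = config.coupling_rho[group]
    n = config.n_beats
    a = config.rr_ar_coeff
    sd = config.noise_sd

    e = rng.normal(0.0, sd["RRI"], n)          # RRI innovations
    e_unit = e / sd["RRI"]
    rri = config.mean_rr + _ar1(e, a)

    def mixed(series_name: str) -> np.ndarray:
        eta = rng.normal(0.0, 1.0, n)
        w = sd[series_name] * (rho * e_unit + (1.0 - rho) * eta)
        return _ar1(w, a)

    disp = profile["dispersion"]
    qtc = profile["qtc_mean"] + disp * mixed("QTcI")
    tpe = profile["tpe_mean"] + disp * mixed("TpeI")
    sti = config.mean_rr / 3.0 + mixed("STI")

    qti = qtc * np.sqrt(rri / 1000.0)          # inverse Bazett
    tpeqti = tpe / qti
    dti = rri - S1_DURATION - sti - S2_DURATION

    return IntervalSeriesSet(rri, qtc, tpe, tpeqti, sti, dti)


def gen_annotations(
    series_set: IntervalSeriesSet,
    start_ms: float = 1000.0,
) -> FiducialAnnotation:
    """Lay out per-beat landmark times consistent with the given series.

    The emitted table has ``n_beats + 1`` rows: row *i* carries the within-
    beat landmarks of cycle *i* and the final row closes the last RR
    interval.  By construction, :func:`~.intervals.extract_interval_series`
    applied to the result reproduces the input series exactly (the QT
    landmark spacing is the inverse-Bazett image of QTcI, so the Bazett
    correction round-trips).
    """
    n = len(series_set)
    rri = series_set.series("RRI")
    qtc = series_set.series("QTcI")
    tpe = series_set.series("TpeI")
    sti = series_set.series("STI")
    dti = series_set.series("DTI")
    if np.any(rri <= 0):
        raise ValueError("annotation layout requires positive RR intervals")

    r = np.empty(n + 1)
    r[0] = start_ms
    r[1:] = start_ms + np.cumsum(rri)

    qti = qtc * np.sqrt(rri / 1000.0)

    def pad(values: np.ndarray) -> np.ndarray:
        # Terminal row reuses the last beat's within-beat geometry; it only
        # contributes its R peak when series are re-extracted.
        return np.concatenate([values, values[-1:]])

    q_onset = r - Q_TO_R
    t_offset = q_onset + pad(qti)
    t_peak = t_offset - pad(tpe)
    s1_offset = r + R_TO_S1_OFFSET
    s2_onset = s1_offset + pad(sti)
    s2_offset = s2_onset + S2_DURATION
    next_s1 = s2_offset + pad(dti)

    return FiducialAnnotation(
        beat_index=np.arange(n + 1),
        r_peak_ms=r,
        q_onset_ms=q_onset,
        t_peak_ms=t_peak,
        t_offset_ms=t_offset,
        s1_offset_ms=s1_offset,
        s2_onset_ms=s2_onset,
        s2_offset_ms=s2_offset,
        next_s1_onset_ms=next_s1,
    )


def inject_anomalies(
    series_set: IntervalSeriesSet,
    fraction: float,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[IntervalSeriesSet, np.ndarray]:
    """Corrupt ``ceil(fraction * n)`` beats with out-of-physiologic values.

    Chosen beats get an RRI far outside the 300-2000 ms plausible band
    (either a drop into 80-250 ms, mimicking a false double detection, or a
    jump into 2100-3000 ms, mimicking a missed beat) and an STI pushed above
    its plausible band.  Returns the corrupted set together with the sorted
    indices of the corrupted beats.  ``fraction = 0`` returns an unchanged
    copy.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n = len(series_set)
    n_corrupt = int(np.ceil(fraction * n))
    new = replace(series_set,
                  **{attr: series_set.series(name).copy()
                     for name, attr in IntervalSeriesSet._FIELDS.items()},
                  anomaly_mask=series_set.anomaly_mask.copy())
    if n_corrupt == 0:
        return new, np.empty(0, dtype=int)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_corrupt, replace=False))
    short = rng.random(n_corrupt) < 0.5
    new.rri[idx] = np.where(short,
                            rng.uniform(80.0, 250.0, n_corrupt),
                            rng.uniform(2100.0, 3000.0, n_corrupt))
    new.sti[idx] = rng.uniform(650.0, 1000.0, n_corrupt)
    return new, idx


@dataclass(frozen=True)
class SyntheticSubject:
    """One synthetic subject: series, matching annotations, ground truth."""

    subject_id: str
    group: str
    series_set: IntervalSeriesSet
    annotation: FiducialAnnotation
    coupling_rho: float
    corrupted_beats: np.ndarray


@dataclass(frozen=True)
class SyntheticCohort:
    """A labeled synthetic cohort, deterministic under its config seed."""

    config: SyntheticCohortConfig
    subjects: tuple[SyntheticSubject, ...]

    def __len__(self) -> int:
        return len(self.subjects)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": [s.subject_id for s in self.subjects],
            "group": [s.group for s in self.subjects],
        })


def gen_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a labeled cohort with ``n_per_group`` subjects per group.

    All randomness derives from ``config.seed`` through a spawned
    ``SeedSequence`` per subject, so cohorts are reproducible and subjects
    are statistically independent.
    """
    if any(n < 2 for n in config.n_per_group.values()):
        raise ValueError("need at least 2 subjects per group")
    root = np.random.SeedSequence(config.seed)
    subjects: list[SyntheticSubject] = []
    for group in GROUPS:
        count = config.n_per_group.get(group, 0)
        for i in range(count):
            seq = root.spawn(1)[0]
            series_seed, anomaly_seed = seq.spawn(2)
            series = gen_interval_series(config, group, seed=series_seed)
            series, corrupted = inject_anomalies(
                series, config.anomaly_fraction, seed=anomaly_seed)
            annotation = gen_annotations(series)
            subjects.append(SyntheticSubject(
                subject_id=f"{group}-{i:03d}",
                group=group,
                series_set=series,
                annotation=annotation,
                coupling_rho=config.coupling_rho[group],
                corrupted_beats=corrupted,
            ))
    return SyntheticCohort(config=config, subjects=tuple(subjects))


def write_cohort(cohort: SyntheticCohort, outdir) -> pd.DataFrame:
    """Write per-subject annotation CSVs plus the cohort label table.

    Returns the label table.  Files: ``<subject_id>.annotations.csv`` (one
    row per beat, landmark times in ms) and ``labels.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for subject in cohort.subjects:
        subject.annotation.to_csv(outdir / f"{subject.subject_id}.annotations.csv")
    labels = cohort.labels_frame()
    labels.to_csv(outdir / "labels.csv", index=False)
    return labels
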