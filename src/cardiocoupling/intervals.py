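"""Beat-interval series: construction from fiducial annotations, validation, pairing.

Six beat-domain series are derived from synchronized ECG/PCG fiducial
annotations, one value per cardiac cycle:

* ``RRI``    -- R-peak to next R-peak (ms), the heart-period series
* ``QTcI``   -- QT interval corrected for heart rate by Bazett's formula (ms)
* ``TpeI``   -- T-wave peak to T-wave offset (ms), repolarization dispersion
* ``TpeQTI`` -- TpeI / QTI ratio (dimensionless)
* ``STI``    -- S1 offset to S2 onset (ms), the PCG systolic interval
* ``DTI``    -- S2 offset to next S1 onset (ms), the PCG diastolic interval

Four of these are "electrical" (ECG-derived) and two "mechanical"
(PCG-derived); the eight electrical x mechanical pairs are the unit on which
every coupling measure operates.  Beats failing physiologic plausibility
checks are masked; a subject whose masked fraction exceeds 10% is invalid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SERIES_NAMES",
    "ELECTRICAL_SERIES",
    "MECHANICAL_SERIES",
    "PAIR_ORDER",
    "ANNOTATION_COLUMNS",
    "DEFAULT_PHYSIOLOGIC_BOUNDS",
    "FiducialAnnotation",
    "IntervalSeriesSet",
    "SeriesPair",
    "SubjectValidation",
    "InvalidSubjectError",
    "bazett_correct",
    "extract_interval_series",
    "detect_anomalous_beats",
    "validate_subject",
    "make_pairs",
    "znormalize",
]

SERIES_NAMES = ("RRI", "QTcI", "TpeI", "TpeQTI", "STI", "DTI")
ELECTRICAL_SERIES = ("RRI", "QTcI", "TpeI", "TpeQTI")
MECHANICAL_SERIES = ("STI", "DTI")

#: Canonical ordering of the eight electrical-mechanical pairs.
PAIR_ORDER = tuple(
    (elec, mech) for elec in ELECTRICAL_SERIES for mech in MECHANICAL_SERIES
)

ANNOTATION_COLUMNS = (
    "beat_index",
    "r_peak_ms",
    "q_onset_ms",
    "t_peak_ms",
    "t_offset_ms",
    "s1_offset_ms",
    "s2_onset_ms",
    "s2_offset_ms",
    "next_s1_onset_ms",
)

#: Plausible per-beat ranges (ms) used by the anomalous-beat detector.
DEFAULT_PHYSIOLOGIC_BOUNDS: Mapping[str, tuple[float, float]] = {
    "RRI": (300.0, 2000.0),
    "STI": (150.0, 600.0),
    "DTI": (100.0, 1500.0),
    "TpeI": (20.0, 200.0),
}

#: Fraction of masked beats above which a subject is discarded (strict >).
ANOMALY_FRACTION_LIMIT = 0.10

#: Minimum usable beats for a subject; entropy estimates degrade below this.
MIN_USABLE_BEATS = 30


class InvalidSubjectError(ValueError):
    """Raised when an operation requires a valid subject but the series set
    fails the anomaly-fraction or minimum-length rules."""


@dataclass(frozen=True)
class FiducialAnnotation:
    """Per-beat landmark times (ms) for one subject.

    One row per cardiac cycle.  Within a beat the ECG landmarks satisfy
    Q onset < R peak < T peak < T offset and the PCG landmarks
    S1 offset < S2 onset < S2 offset < next S1 onset.  The final row is a
    terminal beat contributing only its R peak (needed to close the last RR
    interval); it yields no complete cycle of its own.
    """

    beat_index: np.ndarray
    r_peak_ms: np.ndarray
    q_onset_ms: np.ndarray
    t_peak_ms: np.ndarray
    t_offset_ms: np.ndarray
    s1_offset_ms: np.ndarray
    s2_onset_ms: np.ndarray
    s2_offset_ms: np.ndarray
    next_s1_onset_ms: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.beat_index)
        for name in ANNOTATION_COLUMNS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if name == "beat_index":
                arr = arr.astype(int)
            object.__setattr__(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"annotation column {name!r} has length "
                                 f"{len(arr)} != {n}")
        if not all(np.isfinite(getattr(self, c)).all()
                   for c in ANNOTATION_COLUMNS[1:]):
            raise ValueError("annotation landmark times must be finite")

    def __len__(self) -> int:
        return len(self.beat_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in ANNOTATION_COLUMNS})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FiducialAnnotation":
        missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        return cls(**{c: frame[c].to_numpy() for c in ANNOTATION_COLUMNS})

    @classmethod
    def from_csv(cls, path) -> "FiducialAnnotation":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class IntervalSeriesSet:
    """The six named beat-interval series for one subject, with anomaly state.

    All six arrays have equal length (one entry per complete cardiac cycle).
    ``anomaly_mask[i]`` is True when beat ``i`` is implausible in *any*
    series; masked beats are removed jointly from all six series before
    pairing so that beat alignment between ECG and PCG is preserved.
    """

    rri: np.ndarray
    qtci: np.ndarray
    tpei: np.ndarray
    tpeqti: np.ndarray
    sti: np.ndarray
    dti: np.ndarray
    anomaly_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    _FIELDS = {"RRI": "rri", "QTcI": "qtci", "TpeI": "tpei",
               "TpeQTI": "tpeqti", "STI": "sti", "DTI": "dti"}

    def __post_init__(self) -> None:
        n = len(self.rri)
        for attr in self._FIELDS.values():
            arr = np.asarray(getattr(self, attr), dtype=float)
            setattr(self, attr, arr)
            if len(arr) != n:
                raise ValueError("all six interval series must have equal length")
        if self.anomaly_mask is None:
            self.anomaly_mask = np.zeros(n, dtype=bool)
        self.anomaly_mask = np.asarray(self.anomaly_mask, dtype=bool)
        if len(self.anomaly_mask) != n:
            raise ValueError("anomaly mask length mismatch")

    def __len__(self) -> int:
        return len(self.rri)

    def series(self, name: str) -> np.ndarray:
        try:
            return getattr(self, self._FIELDS[name])
        except KeyError:
            raise KeyError(f"unknown series {name!r}; expected one of "
                           f"{SERIES_NAMES}") from None

    @property
    def anomaly_fraction(self) -> float:
        return float(self.anomaly_mask.mean()) if len(self) else 0.0

    @property
    def valid(self) -> bool:
        """False iff the flagged fraction strictly exceeds 10%."""
        return self.anomaly_fraction <= ANOMALY_FRACTION_LIMIT

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({name: self.series(name) for name in SERIES_NAMES})
        frame.insert(0, "beat_index", np.arange(len(self)))
        frame["anomalous"] = self.anomaly_mask
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IntervalSeriesSet":
        mask = frame["anomalous"].to_numpy(dtype=bool) if "anomalous" in frame \
            else None
        return cls(*(frame[name].to_numpy(dtype=float) for name in SERIES_NAMES),
                   anomaly_mask=mask)

    @classmethod
    def from_csv(cls, path) -> "IntervalSeriesSet":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def drop_masked(self) -> "IntervalSeriesSet":
        """Remove masked beats jointly from all six series."""
        keep = ~self.anomaly_mask
        return IntervalSeriesSet(
            *(self.series(name)[keep] for name in SERIES_NAMES))


@dataclass(frozen=True)
class SeriesPair:
    """One aligned, z-normalized (electrical, mechanical) series pair."""

    elec_name: str
    mech_name: str
    x: np.ndarray  # electrical, mean 0 / SD 1
    y: np.ndarray  # mechanical, mean 0 / SD 1

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("pair members must have equal length")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def name(self) -> str:
        return f"{self.elec_name}-{self.mech_name}"


def bazett_correct(qt, rr):
    """Heart-rate-correct a QT interval by Bazett's formula.

    QTc = QT / sqrt(RR) with RR expressed in seconds; inputs and output in
    milliseconds.  Accepts scalars or arrays; every RR must be positive.
    """
    qt = np.asarray(qt, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive for Bazett correction")
    out = qt / np.sqrt(rr / 1000.0)
    return float(out) if out.ndim == 0 else out


def znormalize(values: np.ndarray) -> np.ndarray:
    """Z-score a series (mean 0, population SD 1).

    Raises on constant input: a zero-variance series carries no coupling
    information and would make tolerance-in-SD-units measures meaningless.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-normalize a constant or non-finite series")
    return (values - values.mean()) / sd


def extract_interval_series(ann: FiducialAnnotation) -> IntervalSeriesSet:
    """Build the six interval series from a fiducial annotation table.

    For beat ``i`` (all times in ms):

    * ``RRI[i]  = r_peak[i+1] - r_peak[i]``
    * ``QTI[i]  = t_offset[i] - q_onset[i]`` then ``QTcI`` via Bazett
    * ``TpeI[i] = t_offset[i] - t_peak[i]``
    * ``TpeQTI[i] = TpeI[i] / QTI[i]``
    * ``STI[i]  = s2_onset[i] - s1_offset[i]``
    * ``DTI[i]  = next_s1_onset[i] - s2_offset[i]``

    The terminal annotation row closes the final RR interval and produces no
    beat of its own.  Beats violating the within-beat landmark ordering (or
    with a non-positive RR) are recorded in the anomaly mask rather than
    raising, mirroring a manual-review workflow where isolated mis-detected
    cycles are marked for deletion.
    """
    if len(ann) < 2:
        raise ValueError("need at least two annotation rows (one complete beat)")
    n = len(ann) - 1
    sl = slice(0, n)

    rri = np.diff(ann.r_peak_ms)
    qti = (ann.t_offset_ms - ann.q_onset_ms)[sl]
    tpei = (ann.t_offset_ms - ann.t_peak_ms)[sl]
    sti = (ann.s2_onset_ms - ann.s1_offset_ms)[sl]
    dti = (ann.next_s1_onset_ms - ann.s2_offset_ms)[sl]

    ordering_ok = (
        (ann.q_onset_ms < ann.r_peak_ms)[sl]
        & (ann.r_peak_ms < ann.t_peak_ms)[sl]
        & (ann.t_peak_ms < ann.t_offset_ms)[sl]
        & (ann.s1_offset_ms < ann.s2_onset_ms)[sl]
        & (ann.s2_onset_ms < ann.s2_offset_ms)[sl]
        & (ann.s2_offset_ms < ann.next_s1_onset_ms)[sl]
        & (rri > 0)
    )
    mask = ~ordering_ok

    # Compute derived series only where the beat is well-formed; malformed
    # beats keep placeholder values and are excluded downstream via the mask.
    qtci = np.full(n, np.nan)
    tpeqti = np.full(n, np.nan)
    ok = ordering_ok & (qti > 0)
    qtci[ok] = bazett_correct(qti[ok], rri[ok])
    tpeqti[ok] = tpei[ok] / qti[ok]
    mask |= ~ok

    return IntervalSeriesSet(rri, qtci, tpei, tpeqti, sti, dti,
                             anomaly_mask=mask)


def detect_anomalous_beats(
    series_set: IntervalSeriesSet,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    k: float = 5.0,
    window: int = 11,
) -> np.ndarray:
    """Flag beats that are physiologically implausible in any series.

    Two complementary rules, OR-combined per beat:

    1. *Hard bounds* -- the value falls outside the plausible range for its
       series (``bounds``, defaults in :data:`DEFAULT_PHYSIOLOGIC_BOUNDS`;
       series without an entry are skipped by this rule).
    2. *Robust outlier* -- the residual from a centered rolling median
       (window ``window`` beats) exceeds ``k`` robust standard deviations,
       where the robust SD is 1.4826x the median absolute deviation of the
       residuals.  This catches ectopy-like jumps that remain inside the
       hard bounds.

    Returns a boolean mask (True = anomalous) combined with any mask the set
    already carries; does not mutate the input.
    """
    if bounds is None:
        bounds = DEFAULT_PHYSIOLOGIC_BOUNDS
    n = len(series_set)
    mask = series_set.anomaly_mask.copy()
    for name in SERIES_NAMES:
        values = series_set.series(name)
        finite = np.isfinite(values)
        mask |= ~finite
        if name in bounds:
            lo, hi = bounds[name]
            mask |= finite & ((values < lo) | (values > hi))
        if n >= window:
            med = (pd.Series(values)
                   .rolling(window, center=True, min_periods=1)
                   .median().to_numpy())
            resid = values - med
            mad = np.nanmedian(np.abs(resid - np.nanmedian(resid)))
            robust_sd = 1.4826 * mad
            if robust_sd > 0:
                mask |= finite & (np.abs(resid) > k * robust_sd)
    return mask


@dataclass(frozen=True)
class SubjectValidation:
    """Outcome of the 10% anomalous-beat rule for one subject."""

    valid: bool
    anomaly_fraction: float
    n_flagged: int
    n_beats: int
    cleaned: IntervalSeriesSet | None  # masked beats removed; None if invalid

    @property
    def n_usable(self) -> int:
        return self.n_beats - self.n_flagged


def validate_subject(
    series_set: IntervalSeriesSet,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    k: float = 5.0,
) -> SubjectValidation:
    """Apply the anomaly screen and the 10% invalidation rule.

    A subject is invalid when the flagged fraction strictly exceeds 10%
    (so exactly 10.0% is still valid), or when fewer than
    :data:`MIN_USABLE_BEATS` beats survive.  For valid subjects the flagged
    beats are removed from all six series jointly, keeping the ECG and PCG
    beat indices aligned.
    """
    mask = detect_anomalous_beats(series_set, bounds=bounds, k=k)
    n = len(series_set)
    n_flagged = int(mask.sum())
    fraction = n_flagged / n if n else 0.0
    screened = dataclasses.replace(series_set, anomaly_mask=mask)
    valid = fraction <= ANOMALY_FRACTION_LIMIT
    cleaned = screened.drop_masked() if valid else None
    if valid and len(cleaned) < MIN_USABLE_BEATS:
        valid, cleaned = False, None
    return SubjectValidation(valid=valid, anomaly_fraction=fraction,
                             n_flagged=n_flagged, n_beats=n, cleaned=cleaned)


def make_pairs(
    series_set: IntervalSeriesSet,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    k: float = 5.0,
) -> list[SeriesPair]:
    """Form the eight canonical z-normalized electrical-mechanical pairs.

    Runs :func:`validate_subject` first and raises
    :class:`InvalidSubjectError` for subjects failing the 10% rule or the
    minimum-length floor.  Pairs are returned in :data:`PAIR_ORDER`:
    RRI-STI, RRI-DTI, QTcI-STI, QTcI-DTI, TpeI-STI, TpeI-DTI, TpeQTI-STI,
    TpeQTI-DTI.
    """
    report = validate_subject(series_set, bounds=bounds, k=k)
    if not report.valid:
        raise InvalidSubjectError(
            f"subject invalid: {report.n_flagged}/{report.n_beats} beats "
            f"anomalous ({report.anomaly_fraction:.1%}), "
            f"{report.n_usable} usable")
    clean = report.cleaned
    normalized = {name: znormalize(clean.series(name)) for name in SERIES_NAMES}
    return [SeriesPair(elec, mech, normalized[elec], normalized[mech])
            for elec, mech in PAIR_ORDER]
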