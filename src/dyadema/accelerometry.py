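"""Epoch-level accelerometer processing: wear time, valid days, cut-points.

Counts arrive on a uniform 30-s grid (an ActiGraph-style epoch export).
Rules, all configurable:

* non-wear: any maximal run of zero-count epochs lasting strictly more
  than 60 continuous minutes (runs are evaluated over continuous time,
  including across midnight);
* valid day: >= 10 h (600 min) of wear;
* intensity: counts-per-minute = counts per 30-s epoch x 2; sedentary is
  wear with cpm < 100 (exclusive), MVPA is wear with cpm >= the member
  threshold (inclusive) -- 2020 cpm for adults, and for children the
  age-specific 4-MET solution of the Freedson MET prediction equation;
  everything else during wear is light.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EPOCH_SECONDS",
    "Thresholds",
    "EpochSeries",
    "WearAnnotation",
    "NONWEAR",
    "SEDENTARY",
    "LIGHT",
    "MVPA",
    "CLASS_NAMES",
    "detect_non_wear",
    "flag_valid_days",
    "child_mvpa_threshold",
    "mvpa_threshold_cpm",
    "classify_epochs",
    "read_epoch_csv",
    "write_epoch_csv",
]

EPOCH_SECONDS = 30
_EPOCH_MIN = EPOCH_SECONDS / 60.0

# epoch class codes
NONWEAR, SEDENTARY, LIGHT, MVPA = 0, 1, 2, 3
CLASS_NAMES = {NONWEAR: "nonwear", SEDENTARY: "sedentary", LIGHT: "light", MVPA: "mvpa"}


@dataclass(frozen=True)
class Thresholds:
    """Cut-point configuration (counts per minute) and non-wear/valid-day rules."""

    sedentary_cpm: float = 100.0        # exclusive upper bound for sedentary
    adult_mvpa_cpm: float = 2020.0      # inclusive lower bound for adult MVPA
    child_met_target: float = 4.0       # METs defining child MVPA
    nonwear_min: float = 60.0           # strict lower bound on zero-run minutes
    valid_day_wear_min: float = 600.0   # inclusive lower bound on daily wear

    def mvpa_cpm(self, member: str, age: float | None = None) -> float:
        return mvpa_threshold_cpm(member, age, self)


@dataclass(frozen=True)
class EpochSeries:
    """Uniform 30-s epoch counts for one subject (timezone-naive local time)."""

    subject_id: str
    epoch_start: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self):
        idx = pd.DatetimeIndex(self.epoch_start)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "epoch_start", idx)
        object.__setattr__(self, "counts", counts)
        if len(idx) != len(counts):
            raise ValueError("epoch_start and counts must align")
        if len(idx) == 0:
            raise ValueError("empty epoch series")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        deltas = np.diff(idx.asi8) / 1e9
        bad = np.flatnonzero(deltas != EPOCH_SECONDS)
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-uniform epoch spacing for {self.subject_id}: "
                f"{idx[i]} -> {idx[i + 1]} ({deltas[i]:.0f}s, expected {EPOCH_SECONDS}s)")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class WearAnnotation:
    """Per-epoch wear flags with per-day wear minutes and validity."""

    wear: np.ndarray                       # bool per epoch
    day_wear_minutes: pd.Series            # indexed by date
    valid_days: frozenset = field(default=frozenset())

    @property
    def wear_minutes(self) -> float:
        return float(self.wear.sum()) * _EPOCH_MIN


def _zero_runs(counts: np.ndarray):
    """(start, length) of maximal runs of zeros, via run-length encoding."""
    iszero = np.concatenate(([False], counts == 0, [False]))
    edges = np.flatnonzero(np.diff(iszero.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return starts, ends - starts


def detect_non_wear(series: EpochSeries,
                    thresholds: Thresholds = Thresholds()) -> WearAnnotation:
    """Flag non-wear: zero-count runs strictly longer than the 60-min rule.

    Runs are judged on continuous duration regardless of calendar day, so a
    run crossing midnight counts once, at its full length.
    """
    wear = np.ones(len(series), dtype=bool)
    starts, lengths = _zero_runs(series.counts)
    for s, ln in zip(starts, lengths):
        if ln * _EPOCH_MIN > thresholds.nonwear_min:
            wear[s:s + ln] = False
    dates = series.epoch_start.normalize()
    day_wear = pd.Series(wear, index=dates).groupby(level=0).sum() * _EPOCH_MIN
    ann = WearAnnotation(wear=wear, day_wear_minutes=day_wear)
    return WearAnnotation(wear=wear, day_wear_minutes=day_wear,
                          valid_days=flag_valid_days(ann, thresholds))


def flag_valid_days(annotation: WearAnnotation,
                    thresholds: Thresholds = Thresholds()) -> frozenset:
    """Dates with at least 10 h of wear (valid for downstream analysis)."""
    ok = annotation.day_wear_minutes >= thresholds.valid_day_wear_min
    return frozenset(pd.Timestamp(d) for d in annotation.day_wear_minutes.index[ok])


def child_mvpa_threshold(age: float, met_target: float = 4.0) -> float:
    """Counts-per-minute at which the Freedson child MET equation hits 4 METs.

    METs = 2.757 + 0.0015 cpm - 0.08957 age - 0.000038 cpm age, solved for
    cpm at the target MET level:
    cpm = (target - 2.757 + 0.08957 age) / (0.0015 - 0.000038 age).
    """
    if not 6 <= age <= 17:
        raise ValueError("child age must be between 6 and 17 years")
    denom = 0.0015 - 0.000038 * age
    if denom <= 0:
        raise ValueError("MET equation denominator non-positive at this age")
    return (met_target - 2.757 + 0.08957 * age) / denom


def mvpa_threshold_cpm(member: str, age: float | None = None,
                       thresholds: Thresholds = Thresholds()) -> float:
    if member == "mother":
        return thresholds.adult_mvpa_cpm
    if member == "child":
        if age is None:
            raise ValueError("child classification requires an age")
        return child_mvpa_threshold(age, thresholds.child_met_target)
    raise ValueError(f"unknown member {member!r}")


def classify_epochs(series: EpochSeries, annotation: WearAnnotation, member: str,
                    age: float | None = None,
                    thresholds: Thresholds = Thresholds()) -> np.ndarray:
    """Label every epoch nonwear / sedentary / light / mvpa (exhaustive, exclusive)."""
    cpm = series.counts * (60.0 / EPOCH_SECONDS)
    thr = mvpa_threshold_cpm(member, age, thresholds)
    labels = np.full(len(series), LIGHT, dtype=np.int8)
    labels[cpm < thresholds.sedentary_cpm] = SEDENTARY
    labels[cpm >= thr] = MVPA
    labels[~annotation.wear] = NONWEAR
    return labels


# --------------------------------------------------------------------------
# Epoch CSV dialect (timestamp, counts), with optional 10-s re-integration


def write_epoch_csv(series: EpochSeries, path) -> None:
    pd.DataFrame({
        "epoch_start": series.epoch_start.strftime("%Y-%m-%dT%H:%M:%S"),
        "counts": series.counts.astype(int),
    }).to_csv(path, index=False)


def read_epoch_csv(path, subject_id: str | None = None,
                   epoch_seconds: int = EPOCH_SECONDS) -> EpochSeries:
    """Read an epoch CSV; 10-s exports are re-integrated to 30 s by summation."""
    df = pd.read_csv(path, parse_dates=["epoch_start"])
    idx = pd.DatetimeIndex(df["epoch_start"])
    counts = df["counts"].to_numpy()
    if subject_id is None:
        subject_id = str(path)
    if epoch_seconds == EPOCH_SECONDS:
        return EpochSeries(subject_id, idx, counts)
    if EPOCH_SECONDS % epoch_seconds != 0:
        raise ValueError(f"cannot re-integrate {epoch_seconds}-s epochs to 30 s")
    k = EPOCH_SECONDS // epoch_seconds
    if len(counts) % k != 0:
        raise ValueError("epoch count not a multiple of the re-integration factor")
    deltas = np.diff(idx.asi8) / 1e9
    if (deltas != epoch_seconds).any():
        i = int(np.flatnonzero(deltas != epoch_seconds)[0])
        raise ValueError(f"non-uniform epoch spacing at {idx[i]}")
    counts30 = counts.reshape(-1, k).sum(axis=1)
    return EpochSeries(subject_id, idx[::k], counts30)
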