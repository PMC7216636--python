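"""Prompt pairing, 45-min prompt-matched windows, and the inclusion funnel.

The sampling scheme prompts the mother in the first half of an hour window
and the child in the second half of the same hour, so a mother and a child
prompt pair iff they share the scheduled hour window.  The accelerometry
window for a pair is the 45 minutes anchored 15 min after the mother's
prompt (equivalently 15 min before the child's), half-open
``[anchor, anchor + 45)``; an epoch belongs to the window iff its start
time lies in the interval.

The analysis funnel mirrors the study's narrative order: answered
self-reports -> reports with >= 30 valid wear minutes in their own window
on a valid day -> paired occasions where the child reported being with
the mother -> complete pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accelerometry import _EPOCH_MIN, MVPA, NONWEAR, SEDENTARY

__all__ = [
    "WINDOW_MINUTES",
    "ANCHOR_OFFSET_MINUTES",
    "FunnelReport",
    "SchedulingError",
    "EmptyStageError",
    "pair_prompts",
    "window_anchor",
    "extract_window",
    "window_metrics_for_prompts",
    "build_analysis_set",
]

WINDOW_MINUTES = 45
ANCHOR_OFFSET_MINUTES = 15


class SchedulingError(ValueError):
    """A prompt schedule violates the one-prompt-per-member-per-window scheme."""


class EmptyStageError(RuntimeError):
    """The inclusion funnel ran dry; carries the first empty stage name."""

    def __init__(self, stage: str):
        super().__init__(f"no observations survive funnel stage {stage!r}")
        self.stage = stage


@dataclass(frozen=True)
class FunnelReport:
    """Ordered surviving counts along the inclusion funnel."""

    stages: tuple  # of (name, count)

    def __post_init__(self):
        counts = [c for _, c in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("funnel counts must be non-increasing")

    def count(self, name: str) -> int:
        return dict(self.stages)[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "count"])


def window_anchor(mother_scheduled_ts) -> pd.Timestamp:
    """Window start: 15 min after the mother's prompt time."""
    return pd.Timestamp(mother_scheduled_ts) + pd.Timedelta(minutes=ANCHOR_OFFSET_MINUTES)


def pair_prompts(prompts: pd.DataFrame) -> pd.DataFrame:
    """Pair mother and child prompts that share a scheduled hour window.

    ``prompts`` has one row per prompt with at least ``prompt_id``,
    ``dyad_id``, ``member`` ('mother'/'child') and ``scheduled_ts``; any of
    ``wave``, ``weekend``, ``answered``, ``response_ts``, ``with_mother``,
    ``pa``, ``na`` present are carried through with member prefixes.
    Each prompt is used at most once; two same-member candidates in one
    window raise :class:`SchedulingError`.  Mother prompts with no child
    prompt in their hour remain unpaired and are dropped here (they still
    count as self-reports in the funnel).
    """
    df = prompts.copy()
    df["_window"] = pd.DatetimeIndex(df["scheduled_ts"]).floor("h")
    dup = df.groupby(["dyad_id", "_window", "member"]).size()
    if (dup > 1).any():
        key = dup[dup > 1].index[0]
        raise SchedulingError(
            f"two {key[2]} prompts in window {key[1]} for dyad {key[0]}")

    carry = [c for c in ("wave", "day", "weekend") if c in df.columns]
    per_member = [c for c in ("prompt_id", "scheduled_ts", "response_ts",
                              "answered", "pa", "na", "pa_pm_true", "pa_dev_true",
                              "na_pm_true", "na_dev_true") if c in df.columns]
    mothers = df[df["member"] == "mother"]
    children = df[df["member"] == "child"]
    m = mothers[["dyad_id", "_window"] + carry + per_member].rename(
        columns={c: f"m_{c}" for c in per_member})
    ccols = per_member + (["with_mother"] if "with_mother" in df.columns else [])
    c = children[["dyad_id", "_window"] + ccols].rename(
        columns={col: f"c_{col}" for col in per_member})
    pairs = m.merge(c, on=["dyad_id", "_window"], how="inner")

    pairs["anchor_ts"] = pd.DatetimeIndex(pairs["m_scheduled_ts"]) + pd.Timedelta(
        minutes=ANCHOR_OFFSET_MINUTES)
    if {"m_response_ts", "c_response_ts"} <= set(pairs.columns):
        diff = (pd.DatetimeIndex(pairs["c_response_ts"])
                - pd.DatetimeIndex(pairs["m_response_ts"])).total_seconds() / 60.0
        fallback = (pd.DatetimeIndex(pairs["c_scheduled_ts"])
                    - pd.DatetimeIndex(pairs["m_scheduled_ts"])).total_seconds() / 60.0
        pairs["prompt_diff"] = np.where(np.isnan(diff), fallback, diff)
    else:
        pairs["prompt_diff"] = (pd.DatetimeIndex(pairs["c_scheduled_ts"])
                                - pd.DatetimeIndex(pairs["m_scheduled_ts"])
                                ).total_seconds() / 60.0
    pairs["window_id"] = pairs["anchor_ts"].astype("int64")
    return pairs.drop(columns=["_window"]).sort_values(
        ["dyad_id", "window_id"], kind="stable").reset_index(drop=True)


def extract_window(labels: np.ndarray, epoch_index: pd.DatetimeIndex,
                   anchor) -> dict | None:
    """Accumulated wear / MVPA / sedentary minutes in [anchor, anchor + 45).

    Minutes are 0.5 x the corresponding epoch counts; partial wear is not
    rescaled (accumulated minutes).  Returns ``None`` when no epoch data
    covers the span (member missing).
    """
    anchor = pd.Timestamp(anchor)
    end = anchor + pd.Timedelta(minutes=WINDOW_MINUTES)
    i0 = int(epoch_index.searchsorted(anchor, side="left"))
    i1 = int(epoch_index.searchsorted(end, side="left"))
    if i1 <= i0:
        return None
    lab = labels[i0:i1]
    wear = lab != NONWEAR
    return {
        "wear_min": float(wear.sum()) * _EPOCH_MIN,
        "mvpa_min": float((lab == MVPA).sum()) * _EPOCH_MIN,
        "sed_min": float((lab == SEDENTARY).sum()) * _EPOCH_MIN,
        "n_epochs": int(i1 - i0),
    }


def window_metrics_for_prompts(prompts: pd.DataFrame, pairs: pd.DataFrame,
                               classified: dict, valid_days: dict) -> pd.DataFrame:
    """Prompt-matched-window accelerometry metrics for every answered prompt.

    For paired prompts both members' metrics are extracted at the shared
    pair anchor (mother prompt + 15 min).  An unpaired mother report keeps
    its own anchor 15 min after her prompt; an unpaired child report, 15
    min before theirs.  ``classified`` maps (dyad_id, member) -> (labels,
    epoch_index); ``valid_days`` maps the same key -> set of valid dates.
    """
    anchor_of = {}
    for rec in pairs.itertuples(index=False):
        anchor_of[rec.m_prompt_id] = pd.Timestamp(rec.anchor_ts)
        anchor_of[rec.c_prompt_id] = pd.Timestamp(rec.anchor_ts)
    rows = []
    for rec in prompts.itertuples(index=False):
        if not rec.answered:
            continue
        key = (rec.dyad_id, rec.member)
        sched = pd.Timestamp(rec.scheduled_ts)
        sign = 1 if rec.member == "mother" else -1
        anchor = anchor_of.get(
            rec.prompt_id,
            sched + sign * pd.Timedelta(minutes=ANCHOR_OFFSET_MINUTES))
        base = {"prompt_id": rec.prompt_id, "has_data": False, "wear_min": 0.0,
                "mvpa_min": 0.0, "sed_min": 0.0, "valid_day": False}
        if key in classified:
            labels, idx = classified[key]
            w = extract_window(labels, idx, anchor)
            if w is not None:
                base.update(has_data=True, wear_min=w["wear_min"],
                            mvpa_min=w["mvpa_min"], sed_min=w["sed_min"])
            base["valid_day"] = anchor.normalize() in valid_days.get(key, ())
        rows.append(base)
    return pd.DataFrame(rows).set_index("prompt_id")


def build_analysis_set(prompts: pd.DataFrame, pairs: pd.DataFrame,
                       metrics: pd.DataFrame,
                       min_wear_min: float = 30.0):
    """Apply the inclusion funnel and return (analysis table, FunnelReport).

    Stages (names in the report):

    1. ``answered_reports`` -- answered EMA self-reports, mother or child;
    2. ``valid_accelerometry`` -- reports with >= ``min_wear_min`` valid wear
       minutes in their own 45-min window, on a valid day;
    3. ``child_with_mother`` -- paired occasions where the child (passing
       stage 2) reported being with the mother;
    4. ``complete_pairs`` -- plus mother answered with valid accelerometry
       and both members' affect composites present.
    """
    answered = prompts[prompts["answered"].astype(bool)]
    s1 = len(answered)
    if s1 == 0:
        raise EmptyStageError("answered_reports")

    ok = metrics["has_data"] & metrics["valid_day"] & (
        metrics["wear_min"] >= min_wear_min)
    valid_ids = set(metrics.index[ok])
    s2 = int(answered["prompt_id"].isin(valid_ids).sum())
    if s2 == 0:
        raise EmptyStageError("valid_accelerometry")

    p = pairs.copy()
    child_ok = (p["c_answered"].astype(bool)
                & (p["with_mother"].fillna(0).astype(int) == 1)
                & p["c_prompt_id"].isin(valid_ids))
    s3 = int(child_ok.sum())
    if s3 == 0:
        raise EmptyStageError("child_with_mother")

    complete = (child_ok & p["m_answered"].astype(bool)
                & p["m_prompt_id"].isin(valid_ids)
                & p[["m_pa", "m_na", "c_pa", "c_na"]].notna().all(axis=1))
    s4 = int(complete.sum())
    if s4 == 0:
        raise EmptyStageError("complete_pairs")

    out = p[complete].copy()
    for mem in ("m", "c"):
        sub = metrics.loc[out[f"{mem}_prompt_id"]]
        out[f"{mem}_wear_min"] = sub["wear_min"].to_numpy()
        out[f"{mem}_mvpa_min"] = sub["mvpa_min"].to_numpy()
        out[f"{mem}_sed_min"] = sub["sed_min"].to_numpy()
        rt = pd.DatetimeIndex(out[f"{mem}_response_ts"])
        out[f"{mem}_resp_hour"] = (rt.hour + rt.minute / 60.0 + rt.second / 3600.0)
    out["weekend"] = out["weekend"].astype(int)

    funnel = FunnelReport(stages=(
        ("answered_reports", s1),
        ("valid_accelerometry", s2),
        ("child_with_mother", s3),
        ("complete_pairs", s4),
    ))
    return out.reset_index(drop=True), funnel
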