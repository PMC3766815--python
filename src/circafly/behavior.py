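"""Acute light-transition response scoring and day/night activity partition.

A fly "responds" to a lights-on or lights-off event when its beam-break
total over the 10 min after the event exceeds the total over the 10 min
before the event by strictly more than 2 counts.  Scoring requires 1-min
bins; the bin starting at the event time belongs to the post window
(half-open bin convention).

Day/night partitioning totals activity over lights-on versus lights-off
bins of complete LD days; diurnal flies show day/night ratios well above
one (about 4.5 in healthy controls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .dam import ActivitySeries
from .schedule import MIN_PER_DAY, LightSchedule

logger = logging.getLogger(__name__)

RESPONDER_THRESHOLD = 2
WINDOW_MIN = 10
LIGHTS_ON = "lights_on"
LIGHTS_OFF = "lights_off"


@dataclass
class TransitionResponse:
    fly_id: str
    event_kind: str
    event_time_min: int
    pre_counts: int
    post_counts: int
    differential: int
    responder: bool
    valid: bool = True
    reason: str | None = None


@dataclass
class DayNightSummary:
    fly_id: str
    day_total: int
    night_total: int
    overall_total: int
    ratio: float          # NaN when undefined
    ratio_defined: bool
    n_days: int


def score_transition(
    series: ActivitySeries,
    event_time_min: float,
    event_kind: str,
    window_min: int = WINDOW_MIN,
    threshold: int = RESPONDER_THRESHOLD,
) -> TransitionResponse:
    """Score one light transition for one fly.

    Pre window: the ``window_min`` one-minute bins strictly before the
    event; post window: the ``window_min`` bins from the event onward.
    Windows truncated by the recording edge, or containing flagged bins,
    invalidate the event for that fly (returned with ``valid=False``).
    """
    if series.bin_min != 1:
        raise ValueError(
            "transition scoring needs 1-min bins; record at 1-min resolution"
        )
    if event_kind not in (LIGHTS_ON, LIGHTS_OFF):
        raise ValueError(f"unknown event kind {event_kind!r}")
    e = int(round(event_time_min))
    if abs(event_time_min - e) > 1e-9:
        raise ValueError("event time must fall on a 1-min bin boundary")

    def invalid(reason: str) -> TransitionResponse:
        logger.info("%s %s@%d min skipped: %s",
                    series.fly_id, event_kind, e, reason)
        return TransitionResponse(series.fly_id, event_kind, e, 0, 0, 0,
                                  False, valid=False, reason=reason)

    if e - window_min < 0 or e + window_min > series.n_bins:
        return invalid("window truncated by recording edge")
    pre_sl = slice(e - window_min, e)
    post_sl = slice(e, e + window_min)
    if not series.ok_mask[pre_sl].all() or not series.ok_mask[post_sl].all():
        return invalid("flagged bins inside scoring window")
    pre = int(series.counts[pre_sl].sum())
    post = int(series.counts[post_sl].sum())
    diff = post - pre
    return TransitionResponse(series.fly_id, event_kind, e, pre, post, diff,
                              responder=bool(diff > threshold))


def score_all_transitions(
    series_list: list[ActivitySeries],
    schedule: LightSchedule | None = None,
    last_n_days: int = 4,
    threshold: int = RESPONDER_THRESHOLD,
) -> list[TransitionResponse]:
    """Score every lights-on/off event of the last ``last_n_days`` LD days."""
    if not series_list:
        raise ValueError("empty series collection")
    if schedule is None:
        schedule = series_list[0].schedule
    if schedule is None:
        raise ValueError("no light schedule available")
    first_day = max(0, schedule.n_days_ld - last_n_days)
    events = [
        (t, LIGHTS_ON)
        for t in schedule.lights_on_times_min()
        if t >= first_day * MIN_PER_DAY
    ] + [
        (t, LIGHTS_OFF)
        for t in schedule.lights_off_times_min()
        if t >= first_day * MIN_PER_DAY
    ]
    if not events:
        raise ValueError("no light transitions in the requested window")
    return [
        score_transition(s, t, kind, threshold=threshold)
        for s in series_list
        for (t, kind) in events
    ]


def summarize_transitions(
    responses: list[TransitionResponse],
    mode: str = "majority",
) -> pd.DataFrame:
    """Group summary per event kind: responder fraction (with 95% Wilson CI)
    and mean response amplitude (mean differential, with SEM).

    ``mode="majority"``: a fly counts as a responder for an event kind if it
    responds on strictly more than half of its valid events of that kind.
    ``mode="per_event"``: every valid fly x event score counts as one trial.
    Response amplitude is always the per-fly mean differential over valid
    events, averaged across flies.
    """
    if mode not in ("majority", "per_event"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    valid = [r for r in responses if r.valid]
    if not valid:
        raise ValueError("no valid transition events to summarize")
    df = pd.DataFrame(
        {
            "fly_id": [r.fly_id for r in valid],
            "event_kind": [r.event_kind for r in valid],
            "responder": [r.responder for r in valid],
            "differential": [r.differential for r in valid],
        }
    )
    rows = []
    for kind, sub in df.groupby("event_kind", sort=True):
        per_fly = sub.groupby("fly_id").agg(
            n_events=("responder", "size"),
            n_resp=("responder", "sum"),
            amplitude=("differential", "mean"),
        )
        if mode == "majority":
            calls = per_fly["n_resp"] > per_fly["n_events"] / 2.0
            count, nobs = int(calls.sum()), len(calls)
        else:
            count, nobs = int(sub["responder"].sum()), len(sub)
        lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
        amp = per_fly["amplitude"]
        rows.append(
            {
                "event_kind": kind,
                "n_flies": len(per_fly),
                "n_events": len(sub),
                "responder_fraction": count / nobs,
                "ci_low": lo,
                "ci_high": hi,
                "mean_amplitude": amp.mean(),
                "sem_amplitude": (amp.std(ddof=1) / np.sqrt(len(amp))
                                  if len(amp) > 1 else 0.0),
            }
        )
    return pd.DataFrame(rows).set_index("event_kind")


def day_night_ratio(
    series: ActivitySeries, schedule: LightSchedule | None = None
) -> DayNightSummary:
    """Total activity over lights-on vs lights-off bins of complete LD days.

    The ratio is flagged undefined (NaN) rather than infinite when the
    night total is zero.
    """
    if schedule is None:
        schedule = series.schedule
    if schedule is None:
        raise ValueError("no light schedule available")
    n_complete = min(schedule.n_days_ld, series.duration_min // MIN_PER_DAY)
    if n_complete < 1:
        raise ValueError("need at least one complete LD day")
    n_bins_ld = n_complete * MIN_PER_DAY // series.bin_min
    t = series.times_min[:n_bins_ld]
    counts = series.counts[:n_bins_ld]
    light = schedule.is_light(t)
    day_total = int(counts[light].sum())
    night_total = int(counts[~light].sum())
    defined = night_total > 0
    return DayNightSummary(
        fly_id=series.fly_id,
        day_total=day_total,
        night_total=night_total,
        overall_total=day_total + night_total,
        ratio=day_total / night_total if defined else float("nan"),
        ratio_defined=defined,
        n_days=n_complete,
    )
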