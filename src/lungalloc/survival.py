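"""Non-parametric waitlist and post-transplant outcome estimators.

Waitlist records carry a time from listing and one of three states:
``transplant``, ``death_or_delisting`` (the competing event) or
``censored``.  The cause-specific cumulative incidence is the
Aalen-Johansen decomposition

    CIF_k(t) = sum_{t_i <= t} S(t_i-) * d_{k,i} / n_i

with S the all-cause Kaplan-Meier survivor, d_{k,i} the cause-k events
and n_i the risk set at t_i.  Post-transplant survival uses the plain
product-limit estimator.  Ties between events and censorings at the same
time follow the standard convention: events precede censorings, i.e.
tied censored subjects are still at risk.

Point estimates only; no Greenwood/Aalen variances.
"""

from __future__ import annotations

from bisect import bisect_right
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from lungalloc.errors import ValidationError

EVENT_TRANSPLANT = "transplant"
EVENT_DEATH_OR_DELISTING = "death_or_delisting"
EVENT_CENSORED = "censored"
WAITLIST_EVENTS = frozenset({EVENT_TRANSPLANT, EVENT_DEATH_OR_DELISTING, EVENT_CENSORED})

EVENT_DEATH = "death"
SURVIVAL_EVENTS = frozenset({EVENT_DEATH, EVENT_CENSORED})


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function: value(t) = values[i] for the
    largest times[i] <= t, or ``initial`` before the first jump."""

    times: tuple[float, ...]
    values: tuple[float, ...]
    initial: float

    def __call__(self, t: float) -> float:
        i = bisect_right(self.times, t)
        return self.values[i - 1] if i else self.initial


@dataclass(frozen=True)
class EstimateResult:
    step: StepFunction
    at_horizon: float | None
    horizon: float | None


def _validate(times: Sequence[float], events: Sequence[str], allowed: frozenset[str]):
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("need at least one record")
    if (times < 0).any() or not np.isfinite(times).all():
        raise ValidationError("times must be non-negative and finite")
    bad = sorted(set(events) - allowed)
    if bad:
        raise ValidationError(f"unknown event types {bad}; expected one of {sorted(allowed)}")
    if len(events) != times.size:
        raise ValidationError("times and events must have equal length")
    return times, list(events)


def cumulative_incidence(
    times: Sequence[float],
    events: Sequence[str],
    cause: str,
    horizon: float | None = None,
) -> EstimateResult:
    """Aalen-Johansen cumulative incidence of ``cause`` under competing risks."""
    times, events = _validate(times, events, WAITLIST_EVENTS)
    if cause not in WAITLIST_EVENTS - {EVENT_CENSORED}:
        raise ValidationError(f"cause must be an event type, got {cause!r}")
    order = np.lexsort((np.asarray(events) == EVENT_CENSORED, times))
    times, events = times[order], [events[i] for i in order]

    n = len(times)
    event_times = sorted({t for t, e in zip(times, events) if e != EVENT_CENSORED})
    cif_times: list[float] = []
    cif_values: list[float] = []
    surv = 1.0
    cif = 0.0
    for t in event_times:
        at_risk = int(np.sum(times >= t))
        d_all = sum(1 for ti, e in zip(times, events) if ti == t and e != EVENT_CENSORED)
        d_cause = sum(1 for ti, e in zip(times, events) if ti == t and e == cause)
        cif += surv * d_cause / at_risk
        surv *= 1.0 - d_all / at_risk
        cif_times.append(float(t))
        cif_values.append(cif)
    step = StepFunction(tuple(cif_times), tuple(cif_values), initial=0.0)
    return EstimateResult(step, step(horizon) if horizon is not None else None, horizon)


def kaplan_meier(
    times: Sequence[float],
    events: Sequence[str],
    horizon: float | None = None,
) -> EstimateResult:
    """Product-limit survivor estimate; events are ``death``, others censored."""
    times, events = _validate(times, events, SURVIVAL_EVENTS)
    event_times = sorted({t for t, e in zip(times, events) if e == EVENT_DEATH})
    km_times: list[float] = []
    km_values: list[float] = []
    surv = 1.0
    for t in event_times:
        at_risk = int(np.sum(times >= t))
        d = sum(1 for ti, e in zip(times, events) if ti == t and e == EVENT_DEATH)
        surv *= 1.0 - d / at_risk
        km_times.append(float(t))
        km_values.append(surv)
    step = StepFunction(tuple(km_times), tuple(km_values), initial=1.0)
    return EstimateResult(step, step(horizon) if horizon is not None else None, horizon)


def all_cause_survival(times: Sequence[float], events: Sequence[str]) -> StepFunction:
    """Kaplan-Meier survivor treating every non-censored waitlist event as
    an event; complements the Aalen-Johansen decomposition
    (sum_k CIF_k(t) + S(t) = 1 at every event time)."""
    times, events = _validate(times, events, WAITLIST_EVENTS)
    mapped = [EVENT_DEATH if e != EVENT_CENSORED else EVENT_CENSORED for e in events]
    return kaplan_meier(times, mapped).step


def load_waitlist(path: str | Path) -> pd.DataFrame:
    """CSV with columns ``time,event``; events validated against the
    waitlist vocabulary."""
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty waitlist file {path}") from exc
    _validate(frame["time"].tolist(), frame["event"].tolist(), WAITLIST_EVENTS)
    return frame


def load_posttx(path: str | Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty survival file {path}") from exc
    _validate(frame["time"].tolist(), frame["event"].tolist(), SURVIVAL_EVENTS)
    return frame
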