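"""Pellet-dispenser logs and homeostatic feeding metrics.

The automated dispenser (F.E.D.) drops 20 mg grain pellets and records the
exact retrieval time; video review attributes each pellet to a consumer and
confirms it was eaten.  The homeostatic-feeding metric is the latency to
consume 0.1 g -- five pellets -- from phase start, censored at phase end
for animals that never reach the threshold.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

DEFAULT_PELLET_MASS_G = 0.02  # 20 mg pellets
DEFAULT_THRESHOLD_PELLETS = 5  # 5 x 0.02 g = 0.1 g


@dataclass(frozen=True)
class PelletEvent:
    """One pellet retrieval: when, by whom, and whether consumption was
    video-confirmed."""

    time_s: float
    consumer_id: str
    confirmed: bool = True

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("pellet event time must be nonnegative")


@dataclass(frozen=True)
class PelletLog:
    """Time-ordered pellet events for one phase, with fixed pellet mass."""

    events: tuple[PelletEvent, ...]
    pellet_mass_g: float = DEFAULT_PELLET_MASS_G

    def __post_init__(self) -> None:
        if self.pellet_mass_g <= 0:
            raise ValueError("pellet mass must be positive")
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("events must be sorted by time")

    def __len__(self) -> int:
        return len(self.events)

    def for_subject(self, subject: str, confirmed_only: bool = True) -> "PelletLog":
        kept = tuple(
            e
            for e in self.events
            if e.consumer_id == subject and (e.confirmed or not confirmed_only)
        )
        return PelletLog(events=kept, pellet_mass_g=self.pellet_mass_g)


def parse_pellet_log(
    stream: Union[str, TextIO],
    pellet_mass_g: float = DEFAULT_PELLET_MASS_G,
) -> PelletLog:
    """Parse a dispenser CSV with header ``time_s,consumer_id,confirmed``.

    Rows may arrive unordered (dispenser clock resyncs); output is sorted.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream)
    required = {"time_s", "consumer_id", "confirmed"}
    if not required.issubset(df.columns):
        raise ValueError(f"pellet log must have columns {sorted(required)}")
    events = []
    for row in df.itertuples(index=False):
        confirmed = str(row.confirmed).strip().lower() in ("1", "true", "yes")
        events.append(PelletEvent(float(row.time_s), str(row.consumer_id), confirmed))
    events.sort(key=lambda e: e.time_s)
    return PelletLog(events=tuple(events), pellet_mass_g=pellet_mass_g)


def read_pellet_log(path, pellet_mass_g: float = DEFAULT_PELLET_MASS_G) -> PelletLog:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_pellet_log(fh, pellet_mass_g)


def write_pellet_log(log: PelletLog, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": [e.time_s for e in log.events],
            "consumer_id": [e.consumer_id for e in log.events],
            "confirmed": [str(e.confirmed).lower() for e in log.events],
        }
    )
    df.to_csv(path, index=False)


def intake_mass(log: PelletLog, subject: str, confirmed_only: bool = True) -> float:
    """Grams consumed by *subject*: confirmed pellet count x pellet mass."""
    return len(log.for_subject(subject, confirmed_only)) * log.pellet_mass_g


@dataclass(frozen=True)
class LatencyResult:
    """Latency to the threshold-th confirmed pellet, censored at phase end."""

    subject_id: str
    threshold_pellets: int
    latency_s: float
    reached: bool
    censor_time_s: float


def latency_to_threshold(
    log: PelletLog,
    subject: str,
    threshold_pellets: int = DEFAULT_THRESHOLD_PELLETS,
    censor_time_s: float = 1200.0,
    confirmed_only: bool = True,
) -> LatencyResult:
    """Time of the threshold-th confirmed pellet for *subject*.

    Animals with fewer pellets are censored at *censor_time_s* with
    ``reached=False``; their reported latency is the censor time.
    """
    if threshold_pellets < 1:
        raise ValueError("threshold must be at least one pellet")
    own = log.for_subject(subject, confirmed_only)
    if len(own) >= threshold_pellets:
        t = own.events[threshold_pellets - 1].time_s
        return LatencyResult(subject, threshold_pellets, t, True, censor_time_s)
    return LatencyResult(subject, threshold_pellets, censor_time_s, False, censor_time_s)


def cumulative_threshold_curve(
    results: Sequence[LatencyResult], duration_s: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of subjects past threshold as a step function of time.

    Returns ``(times, fractions)`` where ``fractions[k]`` holds on
    ``[times[k], times[k+1])``; the curve starts at (0, fraction reached at
    t=0), is non-decreasing, and ends at the overall fraction reached.
    Censored subjects stay in the denominator and never step the curve up.
    """
    if not results:
        raise ValueError("no latency results")
    censors = {r.censor_time_s for r in results}
    if len(censors) > 1:
        raise ValueError("results must share a common censor time")
    if duration_s is None:
        duration_s = censors.pop()
    n = len(results)
    reach_times = sorted(r.latency_s for r in results if r.reached)
    times = [0.0]
    fracs = [sum(1 for t in reach_times if t <= 0.0) / n]
    for t in reach_times:
        if t <= 0.0:
            continue
        frac = sum(1 for s in reach_times if s <= t) / n
        times.append(t)
        fracs.append(frac)
    if times[-1] < duration_s:
        times.append(float(duration_s))
        fracs.append(fracs[-1])
    return np.asarray(times), np.asarray(fracs)


def mean_cumulative_pellets_curve(
    logs: Sequence[PelletLog], subjects: Sequence[str], duration_s: float = 1200.0
) -> tuple[np.ndarray, np.ndarray]:
    """Alternative group curve: mean confirmed pellet count over time.

    One (log, subject) pair per animal; returns ``(times, mean_counts)`` on
    a shared event-time grid.
    """
    if len(logs) != len(subjects):
        raise ValueError("one subject id per log")
    all_times = sorted(
        {0.0, float(duration_s)}
        | {
            e.time_s
            for log, subj in zip(logs, subjects)
            for e in log.for_subject(subj).events
            if e.time_s <= duration_s
        }
    )
    grid = np.asarray(all_times)
    counts = np.zeros_like(grid)
    for log, subj in zip(logs, subjects):
        ts = np.asarray([e.time_s for e in log.for_subject(subj).events])
        counts += np.searchsorted(np.sort(ts), grid, side="right")
    return grid, counts / len(logs)


def phase_intake_summary(
    phase_logs: dict[str, PelletLog],
    subject: str,
    threshold_pellets: int = DEFAULT_THRESHOLD_PELLETS,
    phase_duration_s: float = 1200.0,
    food_present_trial: bool = True,
) -> pd.DataFrame:
    """Per-phase intake and latency table for one subject.

    *phase_logs* maps phase name (``pre`` | ``trial`` | ``post``) to that
    phase's pellet log (times relative to phase start).  Food is not
    accessible during the pre phase, so any pre-phase event is a validation
    error, as is any trial event in a food-absent context.
    """
    rows = []
    for phase in ("pre", "trial", "post"):
        log = phase_logs.get(phase, PelletLog(events=()))
        if phase == "pre" and len(log.for_subject(subject, confirmed_only=False)):
            raise ValueError("pellet events in the pre phase, but food is inaccessible")
        if phase == "trial" and not food_present_trial and len(
            log.for_subject(subject, confirmed_only=False)
        ):
            raise ValueError("pellet events in a food-absent trial context")
        lat = latency_to_threshold(
            log, subject, threshold_pellets, censor_time_s=phase_duration_s
        )
        rows.append(
            {
                "phase": phase,
                "pellets": len(log.for_subject(subject)),
                "intake_g": intake_mass(log, subject),
                "latency_s": lat.latency_s,
                "reached_threshold": lat.reached,
            }
        )
    return pd.DataFrame(rows)
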