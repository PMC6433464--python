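"""Per-second behavioral barcodes (ethograms) and bout segmentation.

An ethogram is one subject-trial's label-per-second time series over a
trial phase (default 1200 s = 20 min).  Seconds are 0-based; bout spans are
half-open ``[start_s, end_s)``.  Unscored seconds carry the reserved token
``NONE``; a ``NONE`` second separates bouts but is never itself a state.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

from .catalogue import NONE_LABEL, BehaviorCatalogue, validate_condition

DEFAULT_DURATION_S = 1200  # 20 min trial phase

PHASES = ("pre", "trial", "post")
INTRUDERS = (None, "female", "male")
SETTINGS = ("homecage", "empty_resident", "occupied_resident")


@dataclass(frozen=True)
class TrialContext:
    """Environmental context flags for one trial phase."""

    food_present: bool = True
    intruder: Optional[str] = None
    setting: str = "homecage"

    def __post_init__(self) -> None:
        if self.intruder not in INTRUDERS:
            raise ValueError(f"intruder must be one of {INTRUDERS}")
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")


@dataclass(frozen=True)
class Ethogram:
    """One subject-trial's per-second behavioral barcode.

    ``labels[t]`` is the behavior scored during second ``[t, t+1)``; exactly
    one label per second, each either a catalogue label or ``NONE``.
    """

    labels: tuple[str, ...]
    catalogue: BehaviorCatalogue
    subject_id: str = "subject"
    condition: str = "Fed"
    context: TrialContext = field(default_factory=TrialContext)
    phase: str = "trial"

    def __post_init__(self) -> None:
        validate_condition(self.condition)
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if not self.labels:
            raise ValueError("ethogram must span at least one second")
        bad = {l for l in self.labels if l != NONE_LABEL and l not in self.catalogue}
        if bad:
            raise ValueError(f"labels outside catalogue: {sorted(bad)}")

    @property
    def duration_s(self) -> int:
        return len(self.labels)

    @property
    def scored_seconds(self) -> int:
        return sum(1 for l in self.labels if l != NONE_LABEL)

    def seconds_of(self, label: str) -> int:
        return sum(1 for l in self.labels if l == label)


@dataclass(frozen=True, order=True)
class Bout:
    """A maximal uninterrupted run of one behavior, span ``[start_s, end_s)``."""

    start_s: int
    end_s: int
    label: str

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("bout must have positive duration")
        if self.label == NONE_LABEL:
            raise ValueError("a bout cannot carry the NONE token")

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class BoutSequence:
    """Ordered, non-overlapping bouts from one ethogram."""

    bouts: tuple[Bout, ...]
    source: Optional[Ethogram] = None

    def __post_init__(self) -> None:
        for a, b in zip(self.bouts, self.bouts[1:]):
            if b.start_s < a.end_s:
                raise ValueError("bouts overlap or are unordered")
            if b.start_s == a.end_s and b.label == a.label:
                raise ValueError(
                    "consecutive same-label bouts must be separated by a NONE second"
                )

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    @property
    def total_duration_s(self) -> int:
        return sum(b.duration_s for b in self.bouts)


def segment_bouts(e: Ethogram) -> BoutSequence:
    """Segment an ethogram into maximal same-label runs, skipping NONE.

    The sum of bout durations equals the number of scored (non-NONE)
    seconds.  An all-NONE ethogram yields an empty sequence.
    """
    bouts: list[Bout] = []
    start = None
    current = NONE_LABEL
    for t, label in enumerate(e.labels):
        if label != current:
            if current != NONE_LABEL:
                bouts.append(Bout(start, t, current))
            start = t
            current = label
    if current != NONE_LABEL:
        bouts.append(Bout(start, e.duration_s, current))
    return BoutSequence(bouts=tuple(bouts), source=e)


# ---------------------------------------------------------------------------
# File dialect: UTF-8 TSV, `# key=value` metadata comment lines, then a
# `second<TAB>label` header and one row per scored second.  Missing seconds
# are NONE.  write_ethogram() emits the canonical form, which parse/read
# round-trips byte-identically.
# ---------------------------------------------------------------------------

def parse_ethogram(
    stream: Union[str, TextIO],
    catalogue: BehaviorCatalogue,
    *,
    duration_s: Optional[int] = None,
    subject_id: Optional[str] = None,
    condition: Optional[str] = None,
    context: Optional[TrialContext] = None,
    phase: Optional[str] = None,
    priority: Optional[Sequence[str]] = None,
    sep: str = "\t",
) -> Ethogram:
    """Parse a per-second barcode from delimited text.

    Rows are ``(second, label)`` with 0-based seconds; missing seconds are
    filled with NONE.  Metadata comment lines ``# key=value`` supply trial
    metadata unless overridden by keyword arguments.

    Two rows for the same second with different labels are an error unless
    *priority* (an ordered label list, highest first) resolves the tie.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    meta: dict[str, str] = {}
    rows: list[tuple[int, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        parts = line.split(sep)
        if parts[0] == "second":  # header row
            continue
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected 'second{sep}label' row")
        try:
            sec = int(parts[0])
        except ValueError:
            raise ValueError(f"line {lineno}: bad second index {parts[0]!r}") from None
        label = parts[1].strip()
        if sec < 0:
            raise ValueError(f"line {lineno}: negative second {sec}")
        if label != NONE_LABEL and label not in catalogue:
            raise ValueError(f"line {lineno}: label {label!r} not in catalogue")
        rows.append((sec, label))

    if duration_s is None:
        duration_s = int(meta.get("duration_s", DEFAULT_DURATION_S))
    for sec, _ in rows:
        if sec >= duration_s:
            raise ValueError(f"second {sec} >= duration {duration_s}")

    labels = [NONE_LABEL] * duration_s
    for sec, label in rows:
        if labels[sec] != NONE_LABEL and labels[sec] != label:
            if priority is None:
                raise ValueError(
                    f"conflicting labels for second {sec}: "
                    f"{labels[sec]!r} vs {label!r} (no priority list given)"
                )
            ranked = [l for l in (labels[sec], label) if l in priority]
            if len(ranked) < 2:
                raise ValueError(
                    f"conflicting labels for second {sec} not covered by priority list"
                )
            label = min(ranked, key=priority.index)
        labels[sec] = label

    intr = meta.get("intruder", "none")
    ctx = context or TrialContext(
        food_present=meta.get("food_present", "true").lower() == "true",
        intruder=None if intr == "none" else intr,
        setting=meta.get("setting", "homecage"),
    )
    return Ethogram(
        labels=tuple(labels),
        catalogue=catalogue,
        subject_id=subject_id or meta.get("subject_id", "subject"),
        condition=condition or meta.get("condition", "Fed"),
        context=ctx,
        phase=phase or meta.get("phase", "trial"),
    )


def write_ethogram(e: Ethogram, stream: Optional[TextIO] = None, sep: str = "\t") -> str:
    """Serialize an ethogram in the canonical dialect (non-NONE rows only)."""
    buf = io.StringIO()
    ctx = e.context
    buf.write(f"# subject_id={e.subject_id}\n")
    buf.write(f"# condition={e.condition}\n")
    buf.write(f"# phase={e.phase}\n")
    buf.write(f"# food_present={'true' if ctx.food_present else 'false'}\n")
    buf.write(f"# intruder={ctx.intruder or 'none'}\n")
    buf.write(f"# setting={ctx.setting}\n")
    buf.write(f"# duration_s={e.duration_s}\n")
    buf.write(f"second{sep}label\n")
    for sec, label in enumerate(e.labels):
        if label != NONE_LABEL:
            buf.write(f"{sec}{sep}{label}\n")
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_ethogram(path, catalogue: BehaviorCatalogue, **kwargs) -> Ethogram:
    """Read an ethogram file (see :func:`parse_ethogram`)."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_ethogram(fh, catalogue, **kwargs)


def from_jwatcher_events(
    events: Iterable[tuple[float, str]],
    catalogue: BehaviorCatalogue,
    duration_s: int = DEFAULT_DURATION_S,
    stop_code: str = "stop",
    **metadata,
) -> Ethogram:
    """Collapse timestamped keystroke events to a per-second barcode.

    Each event ``(time_s, label)`` marks the onset of a state that persists
    until the next event or an explicit *stop_code*; this onset-persistence
    rule is this adapter's documented convention.  A second is assigned the
    state active at its start.
    """
    import math

    evs = sorted(events, key=lambda ev: ev[0])
    labels = [NONE_LABEL] * duration_s
    # Second s is assigned the state set by the last event with time <= s.
    current = NONE_LABEL
    prev_t = 0.0
    for t, code in evs:
        if t < 0:
            raise ValueError("negative event time")
        for sec in range(math.ceil(prev_t), min(math.ceil(t), duration_s)):
            labels[sec] = current
        if code == stop_code:
            current = NONE_LABEL
        else:
            if code not in catalogue:
                raise ValueError(f"event code {code!r} not in catalogue")
            current = code
        prev_t = t
    for sec in range(math.ceil(prev_t), duration_s):
        labels[sec] = current
    return Ethogram(labels=tuple(labels), catalogue=catalogue, **metadata)
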