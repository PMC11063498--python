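"""The iPREFACE score: deceleration-level summation over a 30-minute window.

The score quantifies accumulated fetal distress over a 30-minute CTG window:
each non-prolonged deceleration contributes its five-tier level, and each
prolonged deceleration contributes its level multiplied by its in-window
duration rounded to the nearest whole minute (half-up).  Two clinically
anchored window variants exist:

* DCS — the 30 minutes ending at the decision for emergency cesarean delivery;
* RCT — the 30 minutes ending at CTG transducer removal.

Boundary policy (configurable only by editing the window): a non-prolonged
deceleration belongs to a window when its nadir time (onset + duration/2 when
the nadir is not annotated) lies in the half-open interval (start, end]; a
prolonged deceleration contributes only its overlap with the window, so the
same prolonged event prorates across adjacent windows without double
counting.  An overlap shorter than 30 s rounds to zero minutes and
contributes nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .events import DecelerationEvent, LaborCase, PROLONGED_MAX_S
from .exceptions import CoverageError, ScoringError

WINDOW_LENGTH_S = 1800.0

Variant = Literal["DCS", "RCT", "custom"]


def round_half_up_minutes(seconds: float) -> int:
    """Duration in whole minutes, rounded half-up (270 s -> 5 min)."""
    if seconds < 0:
        raise ValueError("duration must be non-negative")
    return int(math.floor(seconds / 60.0 + 0.5))


@dataclass(frozen=True)
class ScoreWindow:
    """A scoring window (start, end] with its coverage fraction."""

    end_time: float
    length: float = WINDOW_LENGTH_S
    variant: Variant = "custom"
    coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("window length must be positive")
        if not (0.0 <= self.coverage_fraction <= 1.0):
            raise ValueError("coverage_fraction must lie in [0, 1]")

    @property
    def start_time(self) -> float:
        return self.end_time - self.length


@dataclass(frozen=True)
class ScoreResult:
    """An iPREFACE score with per-event contributions."""

    window: ScoreWindow
    contributions: tuple[tuple[DecelerationEvent, int], ...]
    total: int
    n_events_scored: int
    n_events_excluded: int


def _gap_overlap(gaps: Sequence[tuple[float, float]], start: float, end: float) -> float:
    return sum(max(0.0, min(hi, end) - max(lo, start)) for lo, hi in gaps)


def make_window(case: LaborCase, variant: Literal["DCS", "RCT"], length: float = WINDOW_LENGTH_S) -> ScoreWindow:
    """Anchor a scoring window to a case's timeline.

    DCS ends at the decision for emergency cesarean; RCT ends at transducer
    removal.  Raises :class:`CoverageError` when the window would begin
    before the recording starts — mirroring the study-design exclusion of
    cases without 30 continuous minutes of CTG.
    """
    if variant == "DCS":
        end = case.decision_time
    elif variant == "RCT":
        end = case.removal_time
    else:
        raise ValueError(f"variant must be 'DCS' or 'RCT', got {variant!r}")
    start = end - length
    if start < case.recording_start:
        raise CoverageError(
            f"case {case.case_id}: {variant} window ({start:g}, {end:g}] begins "
            f"before recording start {case.recording_start:g} s"
        )
    covered = length - _gap_overlap(case.coverage_gaps, start, end)
    return ScoreWindow(end_time=end, length=length, variant=variant,
                       coverage_fraction=covered / length)


def event_contribution(event: DecelerationEvent, window: ScoreWindow) -> int:
    """Contribution of one leveled deceleration to a window's score.

    Non-prolonged: its level if the nadir lies in (start, end], else 0.
    Prolonged: level x in-window overlap rounded to the nearest whole minute.
    """
    if event.level is None:
        raise ScoringError(
            f"event at {event.onset:g} s has no five-tier level assigned"
        )
    if event.is_prolonged:
        if event.duration >= PROLONGED_MAX_S:
            return 0  # treated as a baseline change, never scored
        overlap = max(0.0, min(event.end, window.end_time) - max(event.onset, window.start_time))
        return event.level * round_half_up_minutes(overlap)
    in_window = window.start_time < event.nadir_time <= window.end_time
    return event.level if in_window else 0


def score_window(
    events: Iterable[DecelerationEvent],
    window: ScoreWindow,
    strict_coverage: bool = True,
) -> ScoreResult:
    """Compute the iPREFACE score of ``window`` over leveled events.

    With ``strict_coverage`` (the default for the DCS/RCT variants) a window
    that is not fully covered by the recording raises :class:`CoverageError`.
    """
    if strict_coverage and window.coverage_fraction < 1.0:
        raise CoverageError(
            f"window ending at {window.end_time:g} s covered only "
            f"{window.coverage_fraction:.3f} of its {window.length:g} s"
        )
    contributions: list[tuple[DecelerationEvent, int]] = []
    excluded = 0
    for ev in events:
        c = event_contribution(ev, window)
        if c > 0:
            contributions.append((ev, c))
        else:
            excluded += 1
    total = sum(c for _, c in contributions)
    return ScoreResult(
        window=window,
        contributions=tuple(contributions),
        total=total,
        n_events_scored=len(contributions),
        n_events_excluded=excluded,
    )


def score_case(case: LaborCase, variant: Literal["DCS", "RCT"],
               length: float = WINDOW_LENGTH_S, strict_coverage: bool = True) -> ScoreResult:
    """Convenience wrapper: anchor the variant window and score the case."""
    return score_window(case.events, make_window(case, variant, length), strict_coverage)


def score_trajectory(
    case: LaborCase,
    variant_end: float,
    step: float,
    length: float = WINDOW_LENGTH_S,
    strict_coverage: bool = False,
) -> list[tuple[float, int]]:
    """Sliding iPREFACE score: one total per window end.

    Ends run from the earliest fully covered window
    (``recording_start + length``) up to ``variant_end`` in increments of
    ``step``; each point equals an independent :func:`score_window` call.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    points: list[tuple[float, int]] = []
    end = case.recording_start + length
    while end <= variant_end + 1e-9:
        win = ScoreWindow(end_time=end, length=length, variant="custom",
                          coverage_fraction=1.0 - _gap_overlap(case.coverage_gaps, end - length, end) / length)
        res = score_window(case.events, win, strict_coverage=strict_coverage)
        points.append((end, res.total))
        end += step
    return points
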