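"""Stimulus protocols for the haptic and visual numerosity runs.

Both protocols sweep numerosities 1–7 in an ascending then descending
staircase, interleaved with baseline presentations of 20 items.  The
haptic run places sphere sets in the participant's hand for 3 s with a
4.5 s inter-stimulus interval (7.5 s period); the baseline of 20 spheres
is presented three times in a row after each sweep, and the whole
pattern repeats twice per run.  The visual run flashes dot patterns for
300 ms with 350 ms gaps (650 ms period), six presentations per
numerosity step (3.9 s), with 15.6 s baseline blocks of 20 dots after
each sweep, repeated four times per run.

Time zero is the first *retained* scanner frame; the frames discarded
at the start of each run for steady-state magnetization are represented
only by a count.  Event intervals are half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusEvent",
    "RunTimeline",
    "SphereSetSpec",
    "build_haptic_run",
    "build_visual_run",
    "sphere_spec",
    "design_vector",
    "write_events",
    "read_events",
]

Condition = Literal["haptic_equal_size", "haptic_equal_volume", "visual"]

#: haptic protocol constants (seconds)
HAPTIC_EXPLORATION_S = 3.0
HAPTIC_ISI_S = 4.5
HAPTIC_PERIOD_S = HAPTIC_EXPLORATION_S + HAPTIC_ISI_S
HAPTIC_N_DISCARDED = 8
HAPTIC_N_PATTERNS = 2

#: visual protocol constants (seconds)
VISUAL_FLASH_S = 0.300
VISUAL_GAP_S = 0.350
VISUAL_PERIOD_S = VISUAL_FLASH_S + VISUAL_GAP_S
VISUAL_FLASHES_PER_STEP = 6
VISUAL_BASELINE_BLOCK_S = 15.6
VISUAL_N_CYCLES = 4
VISUAL_N_DISCARDED = 6

BASELINE_NUMEROSITY = 20

#: sphere stimulus volumes (mm^3)
EQUAL_SIZE_SPHERE_MM3 = 21.0
EQUAL_VOLUME_TOTAL_MM3 = 420.0


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation."""

    onset: float
    duration: float
    numerosity: int
    condition: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.numerosity < 1:
            raise ValueError(f"numerosity must be a positive integer, got {self.numerosity}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class RunTimeline:
    """Ordered stimulus events plus scan parameters for one functional run."""

    events: tuple[StimulusEvent, ...]
    tr: float
    n_frames_total: int
    n_frames_discarded: int
    modality: Literal["haptic", "visual"]

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not 0 <= self.n_frames_discarded < self.n_frames_total:
            raise ValueError("n_frames_discarded must be in [0, n_frames_total)")
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        for a, b in zip(self.events, self.events[1:]):
            if b.onset < a.offset - 1e-9:
                raise ValueError(f"overlapping events at onset {b.onset}")
        if self.events and self.retained_duration < self.events[-1].offset - 1e-9:
            raise ValueError("timeline shorter than its last event")

    @property
    def n_frames_retained(self) -> int:
        return self.n_frames_total - self.n_frames_discarded

    @property
    def retained_duration(self) -> float:
        """Duration covered by retained frames, in seconds."""
        return self.n_frames_retained * self.tr

    @property
    def total_duration(self) -> float:
        """Full run duration including discarded frames, in seconds."""
        return self.n_frames_total * self.tr

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition times of retained frames (s from first retained frame)."""
        return np.arange(self.n_frames_retained) * self.tr

    @property
    def natural_dt(self) -> float:
        """A sampling step that divides both the TR and all event boundaries."""
        return 0.1 if self.modality == "haptic" else 0.05


@dataclass(frozen=True)
class SphereSetSpec:
    """Physical specification of one haptic sphere set."""

    numerosity: int
    condition: Literal["equal_size", "equal_volume"]
    individual_volume: float
    total_volume: float

    def __post_init__(self) -> None:
        if abs(self.total_volume - self.numerosity * self.individual_volume) > 1e-9:
            raise ValueError("total_volume must equal numerosity * individual_volume")


def _staircase() -> list[int]:
    """One ascending+descending numerosity sweep with baseline triplets."""
    up = list(range(1, 8))
    base = [BASELINE_NUMEROSITY] * 3
    return up + base + up[::-1] + base


def build_haptic_run(tr: float = 1.5, condition: str = "haptic_equal_size") -> RunTimeline:
    """Construct the haptic numerosity run timeline.

    Two repetitions of [1..7 ascending, 3 x 20, 7..1 descending, 3 x 20],
    each presentation a 3 s exploration followed by a 4.5 s gap, preceded
    by 8 discarded frames.  At the study TR of 1.5 s this yields 208
    frames and 312 s.
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    order = _staircase() * HAPTIC_N_PATTERNS
    events = tuple(
        StimulusEvent(onset=i * HAPTIC_PERIOD_S, duration=HAPTIC_EXPLORATION_S, numerosity=n, condition=condition)
        for i, n in enumerate(order)
    )
    stim_duration = len(order) * HAPTIC_PERIOD_S
    n_retained = int(np.ceil(stim_duration / tr - 1e-9))
    return RunTimeline(
        events=events,
        tr=tr,
        n_frames_total=n_retained + HAPTIC_N_DISCARDED,
        n_frames_discarded=HAPTIC_N_DISCARDED,
        modality="haptic",
    )


def build_visual_run(tr: float = 1.95) -> RunTimeline:
    """Construct the visual numerosity run timeline.

    Each numerosity step is six 300 ms flashes at a 650 ms period
    (3.9 s); a cycle is 7 ascending steps, a 15.6 s baseline block of 20
    dots, 7 descending steps, and a second baseline block; four cycles
    per run, preceded by 6 discarded frames.  At the study TR of 1.95 s
    this yields 182 frames and 354.9 s.
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    step_s = VISUAL_FLASHES_PER_STEP * VISUAL_PERIOD_S
    baseline_flashes = int(round(VISUAL_BASELINE_BLOCK_S / VISUAL_PERIOD_S))
    cycle_order: list[int] = []
    for n in range(1, 8):
        cycle_order += [n] * VISUAL_FLASHES_PER_STEP
    cycle_order += [BASELINE_NUMEROSITY] * baseline_flashes
    for n in range(7, 0, -1):
        cycle_order += [n] * VISUAL_FLASHES_PER_STEP
    cycle_order += [BASELINE_NUMEROSITY] * baseline_flashes
    cycle_s = 2 * (7 * step_s + VISUAL_BASELINE_BLOCK_S)

    events = []
    for c in range(VISUAL_N_CYCLES):
        t0 = c * cycle_s
        for i, n in enumerate(cycle_order):
            onset = round(t0 + i * VISUAL_PERIOD_S, 9)
            events.append(StimulusEvent(onset=onset, duration=VISUAL_FLASH_S, numerosity=n, condition="visual"))
    stim_duration = VISUAL_N_CYCLES * cycle_s
    n_retained = int(np.ceil(stim_duration / tr - 1e-9))
    return RunTimeline(
        events=tuple(events),
        tr=tr,
        n_frames_total=n_retained + VISUAL_N_DISCARDED,
        n_frames_discarded=VISUAL_N_DISCARDED,
        modality="visual",
    )


def sphere_spec(numerosity: int, condition: str) -> SphereSetSpec:
    """Volume specification of the sphere set for one haptic presentation.

    In the equal-size condition every sphere is 21 mm^3, so total volume
    grows with numerosity; in the equal-volume condition the set always
    sums to 420 mm^3, so individual spheres shrink with numerosity.
    """
    if not 1 <= numerosity <= 20:
        raise ValueError(f"numerosity must be in [1, 20], got {numerosity}")
    if condition == "equal_size":
        indiv = EQUAL_SIZE_SPHERE_MM3
        total = indiv * numerosity
    elif condition == "equal_volume":
        total = EQUAL_VOLUME_TOTAL_MM3
        indiv = total / numerosity
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return SphereSetSpec(numerosity=numerosity, condition=condition, individual_volume=indiv, total_volume=total)


def design_vector(timeline: RunTimeline, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant numerosity trace at resolution ``dt``.

    Returns ``(times, numerosity)`` covering the retained frames only;
    samples outside any stimulus interval are NaN ("absent").  ``dt``
    must divide the TR so frame times land on trace samples.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    ratio = timeline.tr / dt
    if abs(ratio - round(ratio)) * dt > 1e-9:
        raise ValueError(f"dt={dt} does not divide tr={timeline.tr}")
    n_samples = int(round(timeline.retained_duration / dt))
    times = np.arange(n_samples) * dt
    values = np.full(n_samples, np.nan)
    for ev in timeline.events:
        i0 = int(round(ev.onset / dt))
        i1 = int(round(ev.offset / dt))
        values[i0:min(i1, n_samples)] = ev.numerosity
    return times, values


# -- events-table serialization (BIDS events-file style, tab-separated) --

_EVENT_COLUMNS = ["onset", "duration", "numerosity", "condition"]


def events_frame(timeline: RunTimeline) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.onset, e.duration, e.numerosity, e.condition) for e in timeline.events],
        columns=_EVENT_COLUMNS,
    )


def write_events(timeline: RunTimeline, path: str | Path) -> None:
    events_frame(timeline).to_csv(path, sep="\t", index=False)


def read_events(
    path: str | Path,
    tr: float,
    n_frames_total: int,
    n_frames_discarded: int,
    modality: Literal["haptic", "visual"],
) -> RunTimeline:
    """Rebuild a timeline from an events table plus scan parameters."""
    df = pd.read_csv(path, sep="\t")
    events = tuple(
        StimulusEvent(
            onset=float(r.onset), duration=float(r.duration), numerosity=int(r.numerosity), condition=str(r.condition)
        )
        for r in df.itertuples()
    )
    return RunTimeline(
        events=events,
        tr=tr,
        n_frames_total=n_frames_total,
        n_frames_discarded=n_frames_discarded,
        modality=modality,
    )
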