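"""Paradigm epoch segmentation and active-cell selection.

A recording follows the fixed epoch order
``test1 → prestim → stim → poststim → test2``. All epoch intervals are
half-open ``[start, end)`` so every spike belongs to exactly one epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spikes import SpikeRaster
from .synthgen import StimulationPattern

__all__ = ["ParadigmTimeline", "EpochView", "ActiveCellSet", "segment", "select_active"]

EPOCHS = ("test1", "prestim", "stim", "poststim", "test2")


@dataclass(frozen=True)
class ParadigmTimeline:
    """Epoch boundaries (half-open, seconds) plus the stimulation pattern."""

    test1: tuple[float, float]
    prestim: tuple[float, float]
    stim: tuple[float, float]
    poststim: tuple[float, float]
    test2: tuple[float, float]
    pattern: StimulationPattern
    test_pulse_times: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        bounds = [getattr(self, e) for e in EPOCHS]
        for (s, e) in bounds:
            if e <= s:
                raise ValueError("each epoch must have positive length")
        for (_, e1), (s2, _) in zip(bounds, bounds[1:]):
            if s2 < e1:
                raise ValueError("epochs overlap or are out of order")
        s, e = self.stim
        if not (
            np.isclose(s, self.pattern.onset)
            and np.isclose(e - s, self.pattern.duration)
        ):
            raise ValueError("stim epoch must equal pattern onset/duration")

    @classmethod
    def from_durations(
        cls,
        test1: float,
        prestim: float,
        poststim: float,
        test2: float,
        pattern: StimulationPattern,
        test_pulse_rate: float = 0.4,
    ) -> "ParadigmTimeline":
        """Build a contiguous timeline; the pattern's onset is set to
        ``test1 + prestim`` and regular test pulses are placed in both
        test epochs at ``test_pulse_rate``."""
        t0 = 0.0
        t1 = t0 + test1
        t2 = t1 + prestim
        t3 = t2 + pattern.duration
        t4 = t3 + poststim
        t5 = t4 + test2
        pattern = StimulationPattern(
            kind=pattern.kind,
            frequency=pattern.frequency,
            doublet_isi=pattern.doublet_isi,
            pattern_period=pattern.pattern_period,
            onset=t2,
            duration=pattern.duration,
        )
        if test_pulse_rate > 0:
            period = 1.0 / test_pulse_rate
            p1 = t0 + np.arange(0.0, test1, period)
            p2 = t4 + np.arange(0.0, test2, period)
            pulses = np.concatenate([p1, p2])
        else:
            pulses = np.zeros(0)
        return cls(
            test1=(t0, t1),
            prestim=(t1, t2),
            stim=(t2, t3),
            poststim=(t3, t4),
            test2=(t4, t5),
            pattern=pattern,
            test_pulse_times=pulses,
        )

    def epoch(self, name: str) -> tuple[float, float]:
        if name not in EPOCHS:
            raise KeyError(name)
        return getattr(self, name)

    def duration(self, name: str) -> float:
        s, e = self.epoch(name)
        return e - s

    @property
    def total_duration(self) -> float:
        return self.test2[1]


@dataclass
class EpochView:
    """Spikes of one epoch, per cell, with the epoch interval retained."""

    name: str
    start: float
    end: float
    spikes: list[np.ndarray]

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_cells(self) -> int:
        return len(self.spikes)


def segment(raster: SpikeRaster, timeline: ParadigmTimeline) -> dict[str, EpochView]:
    """Split a raster into the five paradigm epochs.

    Each spike is assigned to exactly one epoch via the half-open
    convention; a spike exactly at an epoch start belongs to that epoch.
    """
    if timeline.total_duration > raster.duration + 1e-9:
        raise ValueError(
            f"timeline ({timeline.total_duration} s) exceeds recording "
            f"duration ({raster.duration} s)"
        )
    views = {}
    for name in EPOCHS:
        s, e = timeline.epoch(name)
        views[name] = EpochView(
            name=name,
            start=s,
            end=e,
            spikes=[t[(t >= s) & (t < e)] for t in raster.spikes],
        )
    return views


@dataclass
class ActiveCellSet:
    """Cells passing the test-pulse viability criterion."""

    cells: frozenset[int]
    response_fraction: dict[int, float]

    def __contains__(self, cell: int) -> bool:
        return cell in self.cells

    def __len__(self) -> int:
        return len(self.cells)


def select_active(
    raster: SpikeRaster,
    timeline: ParadigmTimeline,
    min_response_frac: float = 0.5,
    response_window: float = 0.1,
    which: str = "test1",
) -> ActiveCellSet:
    """Select viable cells by their response to the slow test pulses.

    A cell is active iff it fires within ``response_window`` seconds after
    at least ``min_response_frac`` of the test pulses of the chosen test
    epoch(s) (``"test1"``, ``"test2"`` or ``"both"``).
    """
    if not 0.0 <= min_response_frac <= 1.0:
        raise ValueError("min_response_frac must be in [0, 1]")
    if which == "both":
        lo, hi = timeline.test1[0], timeline.test2[1]
    else:
        lo, hi = timeline.epoch(which)
    pulses = timeline.test_pulse_times
    pulses = pulses[(pulses >= lo) & (pulses < hi)]
    if pulses.size == 0:
        raise ValueError("test epoch contains no pulses")

    cells = set()
    frac: dict[int, float] = {}
    for c, times in enumerate(raster.spikes):
        hits = 0
        for p in pulses:
            if np.any((times >= p) & (times < p + response_window)):
                hits += 1
        f = hits / pulses.size
        frac[c] = f
        if f >= min_response_frac:
            cells.add(c)
    return ActiveCellSet(cells=frozenset(cells), response_fraction=frac)
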