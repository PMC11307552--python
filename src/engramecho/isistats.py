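"""Inter-spike-interval statistics and reverberation quantification.

ISIs are successive differences of each cell's sorted spike times inside
one epoch. Histograms use a bin width equal to the recording exposure
(~20 ms), and an ISI "matches" a target period when it falls within
±1 bin of it: ``|ISI − period| ≤ bin_width``. The headline statistics
compare matched counts across the prestim / stim / poststim epochs:

    pct_increase_total  = 100 · (isis_post − isis_pre) / isis_stim
    pct_cells_increase  = 100 · (cells_post − cells_pre) / cells_stim

with counts from epochs of unequal duration rate-normalized to a common
60 s reference before the formula is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paradigm import EpochView
from .synthgen import StimulationPattern

__all__ = [
    "ISIHistogram",
    "ReverberationReport",
    "MatchResult",
    "compute_isis",
    "build_histogram",
    "match_cells_at_period",
    "refine_peak_location",
    "reverberation_stats",
    "decompose_components",
]

REFERENCE_EPOCH_S = 60.0


def compute_isis(view: EpochView) -> list[np.ndarray]:
    """Per-cell ISIs within one epoch; cells with <2 spikes yield []."""
    return [np.diff(t) if t.size >= 2 else np.zeros(0) for t in view.spikes]


@dataclass
class ISIHistogram:
    """Uniform-width ISI histogram starting at 0."""

    bin_width: float
    edges: np.ndarray
    counts: np.ndarray
    epoch: str = ""

    @property
    def n_isis(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def modal_bin(self) -> int:
        """Index of the fullest bin; ties broken toward the lower bin."""
        if self.counts.size == 0:
            raise ValueError("empty histogram has no modal bin")
        return int(np.argmax(self.counts))

    def local_maxima(self, min_frac: float = 0.0) -> np.ndarray:
        """Indices of strict-or-plateau local maxima with nonzero counts,
        plateau ties resolved to the lower bin index.

        ``min_frac`` drops minor maxima below that fraction of the tallest
        bin (used when reading off the dominant peaks of a histogram).
        """
        c = self.counts
        idx = []
        i = 0
        while i < c.size:
            j = i
            while j + 1 < c.size and c[j + 1] == c[i]:
                j += 1
            left = c[i - 1] if i > 0 else -np.inf
            right = c[j + 1] if j + 1 < c.size else -np.inf
            if c[i] > 0 and c[i] > left and c[i] > right:
                idx.append(i)
            i = j + 1
        out = np.asarray(idx, dtype=int)
        if min_frac > 0 and out.size:
            out = out[self.counts[out] >= min_frac * self.counts.max()]
        return out


def build_histogram(
    isis, bin_width: float, epoch: str = ""
) -> ISIHistogram:
    """Bin ISIs (a flat array or a per-cell list) over ``[0, max_isi]``."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(isis, (list, tuple)):
        flat = np.concatenate([np.asarray(x, float) for x in isis]) if isis else np.zeros(0)
    else:
        flat = np.asarray(isis, dtype=float)
    if flat.size == 0:
        return ISIHistogram(
            bin_width=bin_width,
            edges=np.array([0.0, bin_width]),
            counts=np.zeros(1, dtype=int),
            epoch=epoch,
        )
    n_bins = int(np.floor(flat.max() / bin_width + 1e-9)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(flat, bins=edges)
    return ISIHistogram(bin_width=bin_width, edges=edges, counts=counts, epoch=epoch)


def refine_peak_location(
    hist: ISIHistogram, isis, bin_index: int
) -> float:
    """Peak location as the mean of the ISIs within ±1 bin of ``bin_index``.

    A histogram peak whose underlying intervals sit on a bin edge is
    otherwise mis-read by half a bin; averaging the contributing ISIs
    recovers the true interval regardless of edge alignment.
    """
    if isinstance(isis, (list, tuple)):
        flat = np.concatenate([np.asarray(x, float) for x in isis]) if isis else np.zeros(0)
    else:
        flat = np.asarray(isis, dtype=float)
    lo = hist.edges[max(bin_index - 1, 0)]
    hi = hist.edges[min(bin_index + 2, len(hist.edges) - 1)]
    sel = flat[(flat >= lo) & (flat < hi)]
    if sel.size == 0:
        return float(hist.centers[bin_index])
    return float(sel.mean())


@dataclass
class MatchResult:
    """Cells/ISIs matching a target period (±1 bin) in one epoch."""

    epoch: str
    period: float
    bin_width: float
    n_isis: int
    cells: frozenset[int]
    isis_per_cell: dict[int, int] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def match_cells_at_period(
    view: EpochView,
    period: float,
    bin_width: float,
    min_matches: int = 2,
) -> MatchResult:
    """Count ISIs within ±1 bin of ``period`` and the cells carrying them.

    An ISI matches iff ``|ISI − period| ≤ bin_width``; a cell is called
    matched iff it has at least ``min_matches`` matching ISIs.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    total = 0
    cells = set()
    per_cell: dict[int, int] = {}
    for c, isis in enumerate(compute_isis(view)):
        k = int(np.count_nonzero(np.abs(isis - period) <= bin_width + 1e-12))
        if k:
            per_cell[c] = k
            total += k
            if k >= min_matches:
                cells.add(c)
    return MatchResult(
        epoch=view.name,
        period=period,
        bin_width=bin_width,
        n_isis=total,
        cells=frozenset(cells),
        isis_per_cell=per_cell,
    )


@dataclass
class ReverberationReport:
    """Percent-increase statistics for one target frequency."""

    frequency: float
    n_pre: int
    n_stim: int
    n_post: int
    cells_pre: int
    cells_stim: int
    cells_post: int
    n_active: int
    pct_increase_total: float | None
    pct_cells_increase: float | None
    per_cell_flags: dict[int, bool] = field(default_factory=dict)
    note: str = ""


def _rate_normalize(count: float, duration: float) -> float:
    return count * REFERENCE_EPOCH_S / duration


def reverberation_stats(
    pre: MatchResult,
    stim: MatchResult,
    post: MatchResult,
    n_active: int,
    durations: dict[str, float] | None = None,
) -> ReverberationReport:
    """Fold per-epoch match results into the percent-increase statistics.

    ``durations`` maps epoch name to its length in seconds; pre/post counts
    are rescaled to a 60 s reference when the epochs differ in length. The
    stimulation-epoch denominator is never rescaled (it is a fixed 10 s
    protocol, used only as the normalizer). When the stim epoch has no
    matches the statistic is undefined and reported as None.
    """
    if durations is None:
        durations = {}
    n_pre = _rate_normalize(pre.n_isis, durations.get("prestim", REFERENCE_EPOCH_S))
    n_post = _rate_normalize(post.n_isis, durations.get("poststim", REFERENCE_EPOCH_S))
    c_pre = _rate_normalize(pre.n_cells, durations.get("prestim", REFERENCE_EPOCH_S))
    c_post = _rate_normalize(post.n_cells, durations.get("poststim", REFERENCE_EPOCH_S))

    note = ""
    if stim.n_isis > 0:
        pct_total = 100.0 * (n_post - n_pre) / stim.n_isis
    else:
        pct_total = None
        note = "no ISIs matched the target period during stimulation"
    if stim.n_cells > 0:
        pct_cells = 100.0 * (c_post - c_pre) / stim.n_cells
    else:
        pct_cells = None
        note = note or "no cells matched the target period during stimulation"

    flags = {c: True for c in post.cells}
    for c in pre.cells:
        flags.setdefault(c, False)
    return ReverberationReport(
        frequency=1.0 / pre.period,
        n_pre=pre.n_isis,
        n_stim=stim.n_isis,
        n_post=post.n_isis,
        cells_pre=pre.n_cells,
        cells_stim=stim.n_cells,
        cells_post=post.n_cells,
        n_active=n_active,
        pct_increase_total=pct_total,
        pct_cells_increase=pct_cells,
        per_cell_flags=flags,
        note=note,
    )


@dataclass
class ComponentPeak:
    """Histogram mass around one frequency-component interval."""

    label: str
    period: float
    mass: int
    is_local_max: bool
    rank: int | None  # rank among local maxima by count (1 = tallest)


def decompose_components(
    hist: ISIHistogram, pattern: StimulationPattern
) -> list[ComponentPeak]:
    """Report histogram mass at the pattern's characteristic intervals.

    For a doublet (interval d, period P) these are d, P−d and P; a
    single-frequency pattern contributes only its period. Mass is the
    count within ±1 bin of each interval; ranks are positions among the
    histogram's local maxima ordered by count.
    """
    if pattern.kind == "doublet":
        targets = [
            ("doublet_isi", pattern.doublet_isi),
            ("gap", pattern.pattern_period - pattern.doublet_isi),
            ("pattern_period", pattern.pattern_period),
        ]
    else:
        targets = [("period", 1.0 / pattern.frequency)]

    maxima = hist.local_maxima()
    order = maxima[np.argsort(-hist.counts[maxima], kind="stable")]
    rank_of = {int(b): r + 1 for r, b in enumerate(order)}

    centers = hist.centers
    peaks = []
    for label, period in targets:
        near = np.abs(centers - period) <= hist.bin_width + 1e-12
        mass = int(hist.counts[near].sum())
        in_max = [int(b) for b in maxima if near[b]]
        best = min((rank_of[b] for b in in_max), default=None)
        peaks.append(
            ComponentPeak(
                label=label,
                period=period,
                mass=mass,
                is_local_max=bool(in_max),
                rank=best,
            )
        )
    return peaks
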