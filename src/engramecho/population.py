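"""Population-level statistics: E/I composition and frequency-component overlap."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .isistats import match_cells_at_period
from .paradigm import EpochView
from .synthgen import StimulationPattern

__all__ = [
    "CellAnnotation",
    "EIRatio",
    "OverlapReport",
    "annotations_from_truth",
    "read_annotations",
    "ei_ratio",
    "component_overlap",
]

CELL_TYPES = ("excitatory", "inhibitory", "unknown")


@dataclass(frozen=True)
class CellAnnotation:
    cell_id: int
    type: str  # excitatory | inhibitory | unknown
    source: str = "imported"

    def __post_init__(self) -> None:
        if self.type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.type!r}")


def annotations_from_truth(truth) -> dict[int, CellAnnotation]:
    """Lift generator ground truth into annotations."""
    return {
        c: CellAnnotation(cell_id=c, type=t, source="synthetic")
        for c, t in truth.cell_type.items()
    }


def read_annotations(path) -> dict[int, CellAnnotation]:
    """Read a cell_id,type CSV; missing/odd types become 'unknown'."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        t = str(row["type"]).strip().lower()
        if t not in CELL_TYPES:
            t = "unknown"
        c = int(row["cell_id"])
        if c in out:
            raise ValueError(f"duplicate annotation for cell {c}")
        out[c] = CellAnnotation(cell_id=c, type=t)
    return out


@dataclass
class EIRatio:
    epoch: str
    n_excitatory: int
    n_inhibitory: int
    n_unknown: int
    pct_excitatory: float | None  # None when no typed cells matched


def ei_ratio(
    matched_cells, annotations: dict[int, CellAnnotation], epoch: str = ""
) -> EIRatio:
    """Percent excitatory among the typed cells of a matched population."""
    n_e = n_i = n_u = 0
    for c in matched_cells:
        ann = annotations.get(c)
        t = ann.type if ann is not None else "unknown"
        if t == "excitatory":
            n_e += 1
        elif t == "inhibitory":
            n_i += 1
        else:
            n_u += 1
    typed = n_e + n_i
    pct = 100.0 * n_e / typed if typed else None
    return EIRatio(
        epoch=epoch,
        n_excitatory=n_e,
        n_inhibitory=n_i,
        n_unknown=n_u,
        pct_excitatory=pct,
    )


@dataclass
class OverlapReport:
    """Overlap between the high- and low-frequency component populations."""

    set_high: frozenset[int]
    set_low: frozenset[int]
    measure: str
    overlap_pct: float | None  # None when both sets are empty


def _overlap_pct(a: frozenset, b: frozenset, measure: str) -> float | None:
    if not a and not b:
        return None
    inter = len(a & b)
    if measure == "jaccard":
        return 100.0 * inter / len(a | b)
    if measure == "min_denominator":
        denom = min(len(a), len(b))
        return 100.0 * inter / denom if denom else 0.0
    if measure == "mean_denominator":
        return 100.0 * inter / (0.5 * (len(a) + len(b)))
    raise ValueError(f"unknown overlap measure {measure!r}")


def _cells_periodic_at(view, period, bin_width, min_matches, max_lag=2):
    """Cells with ≥min_matches spike intervals equal to ``period`` (±1 bin)
    at lag 1 or 2: a cell replaying a whole doublet pattern repeats with
    the pattern period at every *second* spike, never as a first-order ISI."""
    import numpy as np

    cells = set()
    for c, t in enumerate(view.spikes):
        k = 0
        for lag in range(1, max_lag + 1):
            if t.size > lag:
                iv = t[lag:] - t[:-lag]
                k += int(np.count_nonzero(np.abs(iv - period) <= bin_width + 1e-12))
        if k >= min_matches:
            cells.add(c)
    return frozenset(cells)


def component_overlap(
    view: EpochView,
    pattern: StimulationPattern,
    bin_width: float,
    measure: str = "jaccard",
    min_matches: int = 2,
) -> OverlapReport:
    """Which cells express the fast (doublet-interval) vs slow
    (pattern-period) component of a doublet pattern, and their overlap."""
    if pattern.kind != "doublet":
        raise ValueError("component_overlap requires a doublet pattern")
    high = match_cells_at_period(
        view, pattern.doublet_isi, bin_width, min_matches
    ).cells
    low = _cells_periodic_at(
        view, pattern.pattern_period, bin_width, min_matches
    )
    return OverlapReport(
        set_high=high,
        set_low=low,
        measure=measure,
        overlap_pct=_overlap_pct(high, low, measure),
    )
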