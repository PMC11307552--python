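"""Training sets, classifier training and sliding-window engram scanning."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..paradigm import ActiveCellSet, ParadigmTimeline
from ..spikes import SpikeRaster
from ..synthgen import StimulationPattern
from .nn import BiLSTMClassifier

__all__ = [
    "TrainingSet",
    "ClassifierSpec",
    "TrainingReport",
    "DetectionMap",
    "EngramEvent",
    "build_training_set",
    "train",
    "scan",
    "engram_increase",
]

SEQUENCE_LENGTH_CAP = 100  # bins


@dataclass
class TrainingSet:
    """Balanced binary spike sequences: stimulation cycles vs a null."""

    positives: np.ndarray  # (n_pos, n_bins) 0/1
    negatives: np.ndarray  # (n_neg, n_bins) 0/1
    bin_width: float
    null_kind: str
    cycle: float

    @property
    def n_bins(self) -> int:
        return self.positives.shape[1]

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (x, y) with positives labeled 1."""
        x = np.concatenate([self.positives, self.negatives])
        y = np.concatenate(
            [
                np.ones(len(self.positives), dtype=int),
                np.zeros(len(self.negatives), dtype=int),
            ]
        )
        return x, y


def _binarize(times: np.ndarray, start: float, n_bins: int, bin_width: float) -> np.ndarray:
    seq = np.zeros(n_bins)
    idx = np.floor((times - start) / bin_width + 1e-9).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    seq[idx] = 1.0  # spike counts clipped to 0/1
    return seq


def _isi_shuffle(times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute the ISIs of one sequence, keeping the first-spike offset."""
    if times.size < 3:
        return times
    isis = np.diff(times)
    return times[0] + np.concatenate([[0.0], np.cumsum(rng.permutation(isis))])


def build_training_set(
    raster: SpikeRaster,
    timeline: ParadigmTimeline,
    pattern: StimulationPattern,
    null_kind: str = "isi_shuffle",
    active: ActiveCellSet | None = None,
    bin_width: float | None = None,
    window_cycles: int = 1,
    seed: int = 0,
) -> TrainingSet:
    """Cut each active cell's stimulation epoch into one sample per
    pattern cycle and pair the positives with an equal-sized null set.

    ``null_kind`` is one of ``isi_shuffle`` (permute each positive's ISIs,
    preserving the ISI multiset and the first-spike offset),
    ``uniform_noise`` (same spike count, uniform positions),
    ``prestim_slices`` (random cycle-length windows of prestim activity) or
    ``mixed`` (half ISI shuffles, half prestim slices — scanning whole
    recordings benefits from nulls that also cover sparse spontaneous
    windows).
    Duplicate positives are kept by design: identical cycles are real,
    repeated evidence.

    ``window_cycles`` widens each sample to that many pattern cycles; a
    doublet cycle alone holds a single ISI, which an ISI shuffle cannot
    rearrange, so doublet runs want windows spanning ≥2 cycles.
    """
    if bin_width is None:
        bin_width = raster.exposure
    if window_cycles < 1:
        raise ValueError("window_cycles must be >= 1")
    cycle = window_cycles * pattern.cycle
    n_bins = int(round(cycle / bin_width))
    if n_bins > SEQUENCE_LENGTH_CAP:
        raise ValueError(
            f"pattern cycle of {n_bins} bins exceeds the sequence-length "
            f"cap of {SEQUENCE_LENGTH_CAP}; increase bin_width"
        )
    if n_bins < 1:
        raise ValueError("pattern cycle shorter than one bin")
    stim_start, stim_end = timeline.stim
    n_cycles = int(np.floor((stim_end - stim_start) / cycle + 1e-9))
    if n_cycles == 0:
        raise ValueError("stimulation epoch shorter than one pattern cycle")

    cells = sorted(active.cells) if active is not None else range(raster.n_cells)
    rng = np.random.default_rng(seed)

    positives = []
    pos_times = []  # spike times per positive, cycle-relative (for nulls)
    for c in cells:
        t = raster.spikes[c]
        for k in range(n_cycles):
            w0 = stim_start + k * cycle
            sel = t[(t >= w0) & (t < w0 + cycle)] - w0
            positives.append(_binarize(sel, 0.0, n_bins, bin_width))
            pos_times.append(sel)
    if not positives:
        raise ValueError("no active cells: cannot build a training set")
    pos = np.asarray(positives)

    def _shuffle_neg(sel):
        return _binarize(_isi_shuffle(sel, rng), 0.0, n_bins, bin_width)

    def _noise_neg(sel):
        return _binarize(
            rng.uniform(0.0, cycle, size=sel.size), 0.0, n_bins, bin_width
        )

    cell_ids = list(cells)
    p0, p1 = timeline.prestim

    def _prestim_neg(_sel):
        c = cell_ids[int(rng.integers(len(cell_ids)))]
        w0 = rng.uniform(p0, p1 - cycle)
        t = raster.spikes[c]
        return _binarize(t[(t >= w0) & (t < w0 + cycle)], w0, n_bins, bin_width)

    makers = {
        "isi_shuffle": [_shuffle_neg],
        "uniform_noise": [_noise_neg],
        "prestim_slices": [_prestim_neg],
        "mixed": [_prestim_neg, _shuffle_neg],
    }
    if null_kind not in makers:
        raise ValueError(f"unknown null_kind {null_kind!r}")
    chosen = makers[null_kind]
    negatives = [
        chosen[i % len(chosen)](sel) for i, sel in enumerate(pos_times)
    ]

    return TrainingSet(
        positives=pos,
        negatives=np.asarray(negatives),
        bin_width=bin_width,
        null_kind=null_kind,
        cycle=cycle,
    )


@dataclass(frozen=True)
class ClassifierSpec:
    """Training configuration for the two-layer bidirectional LSTM."""

    hidden: int = 64
    max_epochs: int = 200
    batch_size: int = 512
    learning_rate: float = 0.005
    gradient_clip: float = 1.0
    lr_decay: float = 0.7
    lr_decay_every: int = 15
    seed: int = 0
    holdout_frac: float = 0.2
    success_accuracy: float = 0.99
    patience: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.holdout_frac < 1.0:
            raise ValueError("holdout_frac must be in [0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")


@dataclass
class TrainingReport:
    """What happened during training.

    Pattern accuracy is scored on the positive (target-pattern) samples
    alone: an ISI shuffle of a short sequence can reproduce the original
    sequence, so a fraction of the null set may be an exact duplicate of
    the pattern and overall accuracy saturates below 100% by construction.
    The declared success point is perfect pattern accuracy on the training
    positives plus ≥``success_accuracy`` on held-out positives.
    """

    history: list[tuple[float, float]]  # (loss, overall accuracy) per epoch
    train_accuracy: float  # overall, training split
    pattern_accuracy: float  # training positives only
    holdout_accuracy: float | None  # overall, held-out split
    holdout_pattern_accuracy: float | None  # held-out positives only
    converged: bool
    n_epochs: int
    degenerate: bool = False
    note: str = ""


def train(
    ts: TrainingSet, spec: ClassifierSpec = ClassifierSpec()
) -> tuple[BiLSTMClassifier, TrainingReport]:
    """Train the classifier until the success criterion is met.

    The held-out split is taken before training (no leakage). Early
    stopping triggers after ``patience`` consecutive epochs of perfect
    training-pattern accuracy; ``max_epochs`` is a ceiling, and on
    non-convergence the last state is kept and reported as such.
    """
    x, y = ts.arrays()
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(x.shape[0])
    n_hold = int(round(spec.holdout_frac * x.shape[0]))
    hold_idx, train_idx = order[:n_hold], order[n_hold:]
    if train_idx.size == 0:
        raise ValueError("empty training split")
    train_pos = train_idx[y[train_idx] == 1]
    hold_pos = hold_idx[y[hold_idx] == 1]

    model = BiLSTMClassifier(input_size=1, hidden=spec.hidden, seed=spec.seed)
    streak = {"n": 0}

    def stop_when(epoch: int, loss: float, acc: float) -> bool:
        pattern_acc = (
            float(np.mean(model.predict(x[train_pos]) == 1))
            if train_pos.size
            else 0.0
        )
        streak["n"] = streak["n"] + 1 if pattern_acc >= 1.0 else 0
        return streak["n"] >= spec.patience

    history = model.fit_minibatches(
        x[train_idx],
        y[train_idx],
        max_epochs=spec.max_epochs,
        batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        gradient_clip=spec.gradient_clip,
        lr_decay=spec.lr_decay,
        lr_decay_every=spec.lr_decay_every,
        seed=spec.seed,
        stop_when=stop_when,
    )
    train_acc = float(np.mean(model.predict(x[train_idx]) == y[train_idx]))
    pattern_acc = (
        float(np.mean(model.predict(x[train_pos]) == 1)) if train_pos.size else 0.0
    )
    holdout_acc = (
        float(np.mean(model.predict(x[hold_idx]) == y[hold_idx]))
        if n_hold
        else None
    )
    holdout_pattern_acc = (
        float(np.mean(model.predict(x[hold_pos]) == 1)) if hold_pos.size else None
    )
    degenerate = bool(np.array_equal(ts.positives, ts.negatives))
    # a constant "everything matches" classifier scores 100% on patterns;
    # indistinguishable classes therefore never count as converged
    converged = (
        not degenerate
        and pattern_acc >= 1.0
        and (
            holdout_pattern_acc is None
            or holdout_pattern_acc >= spec.success_accuracy
        )
    )
    note = ""
    if degenerate:
        note = "positives and negatives are identical; classes indistinguishable"
    elif not converged:
        note = f"did not reach the success criterion in {len(history)} epochs"
    report = TrainingReport(
        history=history,
        train_accuracy=train_acc,
        pattern_accuracy=pattern_acc,
        holdout_accuracy=holdout_acc,
        holdout_pattern_accuracy=holdout_pattern_acc,
        converged=converged,
        n_epochs=len(history),
        degenerate=degenerate,
        note=note,
    )
    return model, report


@dataclass
class EngramEvent:
    """One merged run of suprathreshold detection windows."""

    cell: int
    start: float
    end: float
    peak_confidence: float


@dataclass
class DetectionMap:
    """Per-cell classifier confidence over sliding-window start times."""

    confidence: np.ndarray  # cells × windows, P(match) in [0, 1]
    window_starts: np.ndarray
    window_length: float
    window_step: float
    threshold: float
    events: list[EngramEvent] = field(default_factory=list)

    def events_in(self, start: float, end: float) -> list[EngramEvent]:
        """Events whose midpoint falls in [start, end)."""
        return [
            ev
            for ev in self.events
            if start <= 0.5 * (ev.start + ev.end) < end
        ]


def _merge_events(
    cell: int,
    starts: np.ndarray,
    conf: np.ndarray,
    above: np.ndarray,
    window_length: float,
    step: float,
    min_windows: int = 1,
) -> list[EngramEvent]:
    """Merge overlapping/contiguous suprathreshold windows into events.

    Runs supported by fewer than ``min_windows`` windows are dropped
    (single-step blips are overwhelmingly chance coincidences).
    """
    events = []
    i = 0
    n = above.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and starts[j + 1] - starts[j] <= window_length:
            j += 1
        if j - i + 1 >= min_windows:
            events.append(
                EngramEvent(
                    cell=cell,
                    start=float(starts[i]),
                    end=float(starts[j] + window_length),
                    peak_confidence=float(conf[i : j + 1].max()),
                )
            )
        i = j + 1
    return events


def scan(
    raster: SpikeRaster,
    model: BiLSTMClassifier,
    window_length: float,
    bin_width: float,
    window_step: float = 0.02,
    threshold: float = 0.5,
    min_windows: int = 2,
    t_range: tuple[float, float] | None = None,
    cells: list[int] | None = None,
    chunk: int = 4096,
) -> DetectionMap:
    """Slide a pattern-length window over each cell and score every
    position with the classifier; merge suprathreshold runs into events.
    """
    if window_step <= 0:
        raise ValueError("window_step must be positive")
    t0, t1 = t_range if t_range is not None else (0.0, raster.duration)
    n_bins = int(round(window_length / bin_width))
    starts = np.arange(t0, t1 - window_length + 1e-9, window_step)
    if starts.size == 0:
        raise ValueError("range shorter than one window")
    if cells is None:
        cells = list(range(raster.n_cells))

    seqs = np.zeros((len(cells) * starts.size, n_bins), dtype=np.float32)
    row = 0
    for c in cells:
        t = raster.spikes[c]
        for w0 in starts:
            sel = t[(t >= w0) & (t < w0 + window_length)]
            seqs[row] = _binarize(sel, w0, n_bins, bin_width)
            row += 1
    # most windows are duplicates (sparse background activity); classify
    # each distinct window once
    uniq, inverse = np.unique(seqs, axis=0, return_inverse=True)
    probs = model.predict_proba(uniq, chunk=chunk)[:, 1][inverse]
    conf = probs.reshape(len(cells), starts.size)

    events: list[EngramEvent] = []
    for k, c in enumerate(cells):
        events.extend(
            _merge_events(
                c,
                starts,
                conf[k],
                conf[k] > threshold,
                window_length,
                window_step,
                min_windows,
            )
        )
    return DetectionMap(
        confidence=conf,
        window_starts=starts,
        window_length=window_length,
        window_step=window_step,
        threshold=threshold,
        events=events,
    )


def engram_increase(
    n_pre: int,
    n_post: int,
    pre_duration: float = 60.0,
    post_duration: float = 60.0,
    denominator: str = "baseline",
    n_stim: int | None = None,
) -> float:
    """Percent increase in engram events post- vs prestimulation.

    ``denominator="baseline"`` uses ``max(n_pre, 1)`` (rate-normalized);
    ``denominator="stim"`` divides by the stimulation-epoch event count
    instead, mirroring the ISI-statistics formula.
    """
    rate_pre = n_pre * 60.0 / pre_duration
    rate_post = n_post * 60.0 / post_duration
    if denominator == "baseline":
        return 100.0 * (rate_post - rate_pre) / max(rate_pre, 1.0)
    if denominator == "stim":
        if n_stim is None or n_stim <= 0:
            raise ValueError("denominator='stim' requires n_stim > 0")
        return 100.0 * (rate_post - rate_pre) / n_stim
    raise ValueError(f"unknown denominator {denominator!r}")
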