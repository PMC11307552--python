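"""Spike inference from fluorescence traces.

The deconvolution stage solves the exact nonnegative problem for an
exponentially decaying calcium kernel,

    min_c ½ Σ_t (c_t − y_t)²   s.t.   s_t = c_t − γ·c_{t−1} ≥ 0,

with ``γ = exp(−exposure/tau)``, using the pool-adjacent-violators
recursion (an online active-set method; O(n) per trace). The inferred
jump sizes ``s_t`` estimate per-event spike amplitudes, which are then
thresholded against a robust (MAD-based) noise estimate.

Slow-onset (glial) calcium waves are detected by their 10–90% rise time
and masked out before deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraceMatrix",
    "SpikeRaster",
    "WaveMask",
    "infer_spikes",
    "exclude_slow_waves",
    "deconvolve_ar1",
    "robust_noise_sd",
]


@dataclass
class TraceMatrix:
    """ΔF/F fluorescence, cells × frames, sampled at ``exposure`` s/frame."""

    values: np.ndarray
    exposure: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells × frames)")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.exposure

    def frame_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) * self.exposure


@dataclass
class SpikeRaster:
    """Per-cell sorted spike times (seconds) over one recording."""

    spikes: list[np.ndarray]
    duration: float
    exposure: float = 0.02

    def __post_init__(self) -> None:
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        for c, s in enumerate(self.spikes):
            if s.size and (np.any(np.diff(s) <= 0)):
                raise ValueError(f"cell {c}: spike times not strictly increasing")
            if s.size and (s[0] < 0 or s[-1] > self.duration):
                raise ValueError(f"cell {c}: spike times outside [0, duration]")

    @property
    def n_cells(self) -> int:
        return len(self.spikes)

    @property
    def n_spikes(self) -> int:
        return int(sum(s.size for s in self.spikes))

    def frame_indices(self, cell: int) -> np.ndarray:
        """Spike times quantized to frame indices (floor)."""
        return np.unique(
            np.floor(self.spikes[cell] / self.exposure + 1e-9).astype(int)
        )


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD from the MAD of first differences (insensitive to events)."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def deconvolve_ar1(y: np.ndarray, gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact NNLS deconvolution of one trace against an AR(1) kernel.

    Returns ``(s, w)`` of the same length as ``y``: ``s[t] > 0`` marks an
    inferred calcium event starting at frame ``t`` with estimated
    amplitude ``s[t]``, and ``w[t]`` is the least-squares weight of the
    pool anchored at ``t`` (the amplitude estimate's variance is σ²/w, so
    short, poorly supported pools carry large standard errors).
    """
    n = y.size
    if n == 0:
        return np.zeros(0), np.zeros(0)
    # pools: [value, weight, start, length]
    pools: list[list[float]] = [[float(y[0]), 1.0, 0, 1]]
    g = float(gamma)
    for t in range(1, n):
        pools.append([float(y[t]), 1.0, t, 1])
        while len(pools) > 1:
            v1, w1, t1, l1 = pools[-2]
            v2, w2, t2, l2 = pools[-1]
            if v2 >= g ** l1 * v1 - 1e-15 * max(1.0, abs(v1)):
                break
            f = g ** l1
            w = w1 + f * f * w2
            v = (w1 * v1 + f * w2 * v2) / w
            pools[-2] = [v, w, t1, l1 + l2]
            pools.pop()
    s = np.zeros(n)
    weights = np.zeros(n)
    prev_end_val = 0.0
    for v, w, t, l in pools:
        t = int(t)
        l = int(l)
        s[t] = v if t == 0 else v - g * prev_end_val
        weights[t] = w
        prev_end_val = v * g ** (l - 1)
    return np.maximum(s, 0.0), weights


@dataclass
class WaveMask:
    """Frames excluded as slow (glial) calcium waves, plus per-cell flags."""

    mask: np.ndarray  # bool, cells × frames; True = excluded
    non_neuronal: np.ndarray  # bool per cell
    events: list[tuple[int, int, int, float]] = field(default_factory=list)
    # (cell, start_frame, end_frame, rise_time_s) for each excluded wave


def _find_events(y: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Contiguous runs of frames with y > threshold, as [start, end)."""
    above = y > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(y.size)
    return list(zip(starts, ends))


def _rise_time(y: np.ndarray, start: int, end: int, exposure: float) -> float:
    """10–90% rise time of the event peak, on the rising flank."""
    seg = y[start:end]
    peak_idx = int(np.argmax(seg))
    peak = seg[peak_idx]
    if peak <= 0:
        return 0.0
    rising = seg[: peak_idx + 1]
    above10 = np.where(rising >= 0.1 * peak)[0]
    above90 = np.where(rising >= 0.9 * peak)[0]
    i10 = above10[0] if above10.size else 0
    i90 = above90[0] if above90.size else peak_idx
    return float((i90 - i10) * exposure)


def exclude_slow_waves(
    traces: TraceMatrix,
    rise_time_threshold: float = 1.0,
    event_threshold_sd: float = 3.0,
) -> WaveMask:
    """Mask fluorescence events whose 10–90% rise time exceeds the threshold.

    Cells where slow waves carry more than half of the total suprathreshold
    area are flagged ``non_neuronal``.
    """
    if rise_time_threshold <= 0:
        raise ValueError("rise_time_threshold must be positive")
    v = traces.values
    mask = np.zeros(v.shape, dtype=bool)
    non_neuronal = np.zeros(v.shape[0], dtype=bool)
    events: list[tuple[int, int, int, float]] = []
    for c in range(v.shape[0]):
        # low-percentile baseline: robust to long-lasting wave transients
        y = v[c] - np.percentile(v[c], 25)
        sd = robust_noise_sd(y)
        thr = max(event_threshold_sd * sd, 1e-3 * max(np.max(np.abs(y)), 1e-30))
        slow_area = 0.0
        total_area = 0.0
        for start, end in _find_events(y, thr):
            area = float(np.sum(y[start:end] - thr))
            total_area += area
            rt = _rise_time(y, start, end, traces.exposure)
            if rt > rise_time_threshold:
                # cover the subthreshold head of the slow ramp too, so no
                # residual rise leaks into deconvolution
                while start > 0 and y[start - 1] > 0.25 * thr:
                    start -= 1
                mask[c, start:end] = True
                slow_area += area
                events.append((c, start, end, rt))
        if total_area > 0 and slow_area > 0.5 * total_area:
            non_neuronal[c] = True
    return WaveMask(mask=mask, non_neuronal=non_neuronal, events=events)


def infer_spikes(
    traces: TraceMatrix,
    decay_tau: float,
    threshold_sd: float,
    wave_mask: WaveMask | None = None,
) -> SpikeRaster:
    """Infer discrete spike times from fluorescence traces.

    Each trace is baseline-subtracted (median), optionally cleaned of
    slow-wave frames, deconvolved exactly against ``exp(−t/decay_tau)``,
    and the resulting event amplitudes thresholded at
    ``threshold_sd × σ_noise/√w`` where ``w`` is the least-squares weight
    of the event's pool (``σ/√w`` is the standard error of that event's
    amplitude estimate; for a long isolated event it equals
    ``σ·√(1−γ²)``). One spike is emitted per suprathreshold event, at
    the event's frame-start time.
    """
    if decay_tau <= 0:
        raise ValueError("decay_tau must be positive")
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if not np.all(np.isfinite(traces.values)):
        raise ValueError("traces contain non-finite values")

    gamma = float(np.exp(-traces.exposure / decay_tau))
    long_pool_se = float(np.sqrt(1.0 - gamma**2))
    spikes: list[np.ndarray] = []
    for c in range(traces.n_cells):
        raw = traces.values[c]
        if wave_mask is not None and wave_mask.mask[c].any():
            keep = ~wave_mask.mask[c]
            y = raw - np.median(raw[keep]) if keep.any() else raw - np.median(raw)
            y = np.where(wave_mask.mask[c], 0.0, y)
        else:
            y = raw - np.median(raw)
        sd = robust_noise_sd(y)
        floor = 1e-9 * max(np.max(np.abs(y)), 1.0)
        s, w = deconvolve_ar1(y, gamma)
        # group jumps in adjacent frames into one event: noise can split a
        # spike's amplitude across a short pool and the pool that follows
        idx = np.where(s > 0)[0]
        frames: list[int] = []
        run_start = 0
        while run_start < idx.size:
            run_end = run_start
            while (
                run_end + 1 < idx.size
                and idx[run_end + 1] - idx[run_end] == 1
            ):
                run_end += 1
            run = idx[run_start : run_end + 1]
            amp = float(s[run].sum())
            se = sd / np.sqrt(max(float(w[run].sum()), 1.0))
            if amp > max(threshold_sd * se, floor):
                # split the run wherever per-frame evidence is individually
                # decisive (noiseless adjacent spikes stay separate), always
                # keeping the run's dominant frame
                strong = run[
                    s[run] > max(threshold_sd * sd * long_pool_se, floor)
                ]
                if strong.size == 0:
                    strong = run[[int(np.argmax(s[run]))]]
                frames.extend(int(f) for f in strong)
            run_start = run_end + 1
        spikes.append(traces.t0 + np.asarray(sorted(frames), float) * traces.exposure)
    return SpikeRaster(
        spikes=spikes,
        duration=traces.t0 + traces.duration,
        exposure=traces.exposure,
    )
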