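"""Synthetic recording generator.

Produces spike rasters with the full stimulation paradigm structure
(test pulses / prestim / stim / poststim / test pulses), known ground
truth about which cells reverberate, and an optional calcium-fluorescence
forward model so the spike-inference stage can be tested end to end.

Time is continuous seconds internally; frame quantization happens only
when traces are rendered or spikes are binned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spikes import SpikeRaster, TraceMatrix

__all__ = [
    "StimulationPattern",
    "GeneratorConfig",
    "GroundTruth",
    "CalciumModel",
    "generate_raster",
    "render_calcium",
]

#: spikes closer than this to the previous spike of the same cell are dropped
REFRACTORY_S = 0.005


@dataclass(frozen=True)
class StimulationPattern:
    """Stimulation protocol: a single frequency, or a two-spike doublet
    (interval ``doublet_isi``) repeated every ``pattern_period`` seconds.

    Parameters
    ----------
    kind
        ``"single"`` or ``"doublet"``.
    frequency
        Pulse frequency in Hz (single-frequency protocols only).
    doublet_isi
        Interval between the two spikes of a doublet, seconds.
    pattern_period
        Repetition period of the doublet, seconds.
    onset
        Stimulation start time within the recording, seconds.
    duration
        Stimulation epoch length, seconds (default 10).
    """

    kind: str = "single"
    frequency: float | None = None
    doublet_isi: float | None = None
    pattern_period: float | None = None
    onset: float = 0.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("single", "doublet"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.onset < 0:
            raise ValueError("onset must be nonnegative")
        if self.kind == "single":
            if self.frequency is None or self.frequency <= 0:
                raise ValueError("single pattern requires frequency > 0")
        else:
            if self.doublet_isi is None or self.doublet_isi <= 0:
                raise ValueError("doublet pattern requires doublet_isi > 0")
            if self.pattern_period is None or self.pattern_period <= 0:
                raise ValueError("doublet pattern requires pattern_period > 0")
            if not self.doublet_isi < self.pattern_period:
                raise ValueError("doublet_isi must be < pattern_period")

    @property
    def cycle(self) -> float:
        """Length of one pattern cycle in seconds (1/f, or the period)."""
        if self.kind == "single":
            return 1.0 / self.frequency
        return self.pattern_period

    def check_resolvable(self, exposure: float) -> None:
        """Reject patterns whose timing cannot be resolved at ``exposure``."""
        if self.kind == "single":
            if self.frequency > 1.0 / (2.0 * exposure):
                raise ValueError(
                    f"{self.frequency} Hz is not resolvable at "
                    f"{exposure * 1e3:.0f} ms exposure"
                )
        else:
            if self.doublet_isi < 2.0 * exposure:
                raise ValueError(
                    f"doublet ISI {self.doublet_isi} s is not resolvable at "
                    f"{exposure * 1e3:.0f} ms exposure"
                )

    def pulse_times(self) -> np.ndarray:
        """Absolute times of every stimulation pulse, sorted.

        Every pulse with time strictly inside ``[onset, onset + duration)``
        is emitted; a doublet's second spike is dropped if it would fall
        outside the stimulation epoch.
        """
        if self.kind == "single":
            n = int(np.floor(self.duration * self.frequency))
            rel = np.arange(n) / self.frequency
        else:
            starts = np.arange(0.0, self.duration, self.pattern_period)
            seconds = starts + self.doublet_isi
            rel = np.sort(
                np.concatenate([starts, seconds[seconds < self.duration]])
            )
        return self.onset + rel


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to simulate one recording (except the pattern)."""

    n_cells: int = 200
    background_rate: float = 0.5
    test_pulse_rate: float = 0.4
    test1_duration: float = 20.0
    prestim_duration: float = 60.0
    poststim_duration: float = 60.0
    test2_duration: float = 20.0
    reverb_fraction: float = 0.0
    reverb_duration: float = 20.0
    reverb_jitter_sd: float = 0.0
    component_assignment: str = "whole_pattern"
    ei_fraction: float = 0.8
    inhibitory_reverb_odds: float = 1.0
    stim_response_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        for name in ("reverb_fraction", "ei_fraction", "stim_response_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("background_rate", "test_pulse_rate", "reverb_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in (
            "test1_duration",
            "prestim_duration",
            "poststim_duration",
            "test2_duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.component_assignment not in ("whole_pattern", "split_by_frequency"):
            raise ValueError(
                f"unknown component_assignment {self.component_assignment!r}"
            )
        if self.reverb_duration < 0:
            raise ValueError("reverb_duration must be nonnegative")
        if self.inhibitory_reverb_odds <= 0:
            raise ValueError("inhibitory_reverb_odds must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    reverb_cells: frozenset[int]
    component_of_cell: dict[int, str]  # cell -> {"high", "low", "both"}
    cell_type: dict[int, str]  # cell -> {"excitatory", "inhibitory"}
    reverb_intervals: dict[int, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class CalciumModel:
    """Forward model turning spikes into fluorescence."""

    kernel_decay_tau: float = 0.5
    amplitude: float = 1.0
    noise_sd: float = 0.0
    glial_wave_rate: float = 0.0  # events/min across the recording
    glial_rise_time: float = 2.0
    glial_amplitude: float = 2.0
    glial_decay_tau: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_decay_tau <= 0:
            raise ValueError("kernel_decay_tau must be positive")
        if self.noise_sd < 0 or self.glial_wave_rate < 0:
            raise ValueError("noise_sd and glial_wave_rate must be nonnegative")
        if self.glial_rise_time <= 0:
            raise ValueError("glial_rise_time must be positive")


def _jittered_train(
    rel_times: np.ndarray, jitter_sd: float, rng: np.random.Generator
) -> np.ndarray:
    if jitter_sd > 0 and rel_times.size:
        rel_times = rel_times + rng.normal(0.0, jitter_sd, size=rel_times.size)
    return rel_times


def _reverb_component_times(
    pattern: StimulationPattern, component: str, duration: float
) -> np.ndarray:
    """Relative spike times for one reverberation component over ``duration``."""
    if pattern.kind == "single" or component == "both":
        proto = replace(pattern, onset=0.0, duration=duration)
        if pattern.kind == "single":
            return proto.pulse_times()
        return proto.pulse_times()
    if component == "high":
        period = pattern.doublet_isi
    elif component == "low":
        period = pattern.pattern_period
    else:  # pragma: no cover - guarded by assignment logic
        raise ValueError(f"unknown component {component!r}")
    return np.arange(0.0, duration, period)


def _apply_refractory(times: np.ndarray) -> np.ndarray:
    """Greedily drop spikes within REFRACTORY_S of the previous kept spike."""
    if times.size < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= REFRACTORY_S:
            kept.append(t)
    return np.asarray(kept)


def generate_raster(
    config: GeneratorConfig,
    pattern: StimulationPattern,
    exposure: float = 0.02,
):
    """Simulate one full recording.

    Returns ``(raster, timeline, truth)`` where *raster* is a
    :class:`~engramecho.spikes.SpikeRaster`, *timeline* a
    :class:`~engramecho.paradigm.ParadigmTimeline` and *truth* a
    :class:`GroundTruth`.

    The raster superimposes homogeneous Poisson background firing on
    (a) per-pulse Bernoulli responses to the slow test pulses, (b)
    pattern-locked stimulation spikes, and (c) — for the ground-truth
    reverberating cells — a jittered replay of their assigned frequency
    component at the start of the poststimulation epoch.
    """
    from .paradigm import ParadigmTimeline  # deferred: avoids import cycle

    pattern.check_resolvable(exposure)
    timeline = ParadigmTimeline.from_durations(
        test1=config.test1_duration,
        prestim=config.prestim_duration,
        poststim=config.poststim_duration,
        test2=config.test2_duration,
        pattern=pattern,
        test_pulse_rate=config.test_pulse_rate,
    )
    duration = timeline.test2[1]
    rng = np.random.default_rng(config.seed)

    n = config.n_cells
    cell_type = {
        c: ("excitatory" if exc else "inhibitory")
        for c, exc in enumerate(rng.random(n) < config.ei_fraction)
    }

    n_reverb = int(round(config.reverb_fraction * n))
    if n_reverb > 0:
        weights = np.array(
            [
                config.inhibitory_reverb_odds
                if cell_type[c] == "inhibitory"
                else 1.0
                for c in range(n)
            ]
        )
        reverb_cells = rng.choice(
            n, size=n_reverb, replace=False, p=weights / weights.sum()
        )
    else:
        reverb_cells = np.array([], dtype=int)
    reverb_set = frozenset(int(c) for c in reverb_cells)

    component_of_cell: dict[int, str] = {}
    if pattern.kind == "doublet" and config.component_assignment == "split_by_frequency":
        for i, c in enumerate(sorted(reverb_set)):
            component_of_cell[c] = "high" if i % 2 == 0 else "low"
    else:
        for c in sorted(reverb_set):
            component_of_cell[c] = "both"

    stim_pulses = timeline.pattern.pulse_times()
    post_start = timeline.poststim[0]
    reverb_dur = min(
        config.reverb_duration, timeline.poststim[1] - timeline.poststim[0]
    )

    spikes: list[np.ndarray] = []
    reverb_intervals: dict[int, tuple[float, float]] = {}
    for c in range(n):
        parts = []
        # homogeneous Poisson background over the whole recording
        n_bg = rng.poisson(config.background_rate * duration)
        parts.append(rng.uniform(0.0, duration, size=n_bg))
        # test-pulse responses (both test epochs)
        pulses = timeline.test_pulse_times
        answered = pulses[rng.random(pulses.size) < config.stim_response_prob]
        parts.append(answered)
        # stimulation-locked spikes
        fired = stim_pulses[rng.random(stim_pulses.size) < config.stim_response_prob]
        parts.append(fired)
        # reverberation replay
        if c in reverb_set and reverb_dur > 0:
            rel = _reverb_component_times(
                pattern, component_of_cell[c], reverb_dur
            )
            rel = _jittered_train(rel, config.reverb_jitter_sd, rng)
            t = post_start + rel
            t = t[(t >= timeline.poststim[0]) & (t < timeline.poststim[1])]
            parts.append(t)
            reverb_intervals[c] = (post_start, post_start + reverb_dur)
        times = np.sort(np.concatenate(parts))
        times = times[(times >= 0.0) & (times < duration)]
        spikes.append(_apply_refractory(times))

    raster = SpikeRaster(spikes=spikes, duration=duration, exposure=exposure)
    truth = GroundTruth(
        reverb_cells=reverb_set,
        component_of_cell=component_of_cell,
        cell_type=cell_type,
        reverb_intervals=reverb_intervals,
    )
    return raster, timeline, truth


def _glial_waveform(t: np.ndarray, onset: float, model: CalciumModel) -> np.ndarray:
    """Slow sigmoidal rise to ``glial_amplitude`` then exponential decay."""
    rel = t - onset
    rise = model.glial_rise_time
    y = np.zeros_like(t)
    up = (rel >= 0) & (rel < rise)
    y[up] = model.glial_amplitude * 0.5 * (1 - np.cos(np.pi * rel[up] / rise))
    down = rel >= rise
    y[down] = model.glial_amplitude * np.exp(-(rel[down] - rise) / model.glial_decay_tau)
    return y


def render_calcium(
    raster: SpikeRaster,
    model: CalciumModel,
    exposure: float | None = None,
) -> TraceMatrix:
    """Render a spike raster into ΔF/F fluorescence traces.

    ``trace(cell, t) = Σ_spikes amplitude · exp(−(t − t_s)/tau) · 1[t ≥ t_s]``
    sampled at frame-start times ``k·exposure``, plus i.i.d. Gaussian noise
    and, if configured, slow-rise glial-wave transients on random cells.
    """
    if exposure is None:
        exposure = raster.exposure
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    n_frames = int(round(raster.duration / exposure))
    t_frames = np.arange(n_frames) * exposure
    rng = np.random.default_rng(model.seed)

    values = np.zeros((raster.n_cells, n_frames))
    tail = int(np.ceil(12.0 * model.kernel_decay_tau / exposure))
    for c, times in enumerate(raster.spikes):
        for ts in times:
            k0 = int(np.ceil(ts / exposure - 1e-12))
            if k0 >= n_frames:
                continue
            k1 = min(n_frames, k0 + tail)
            values[c, k0:k1] += model.amplitude * np.exp(
                -(t_frames[k0:k1] - ts) / model.kernel_decay_tau
            )

    if model.glial_wave_rate > 0:
        n_waves = rng.poisson(model.glial_wave_rate * raster.duration / 60.0)
        for _ in range(n_waves):
            cell = int(rng.integers(raster.n_cells))
            onset = rng.uniform(0.0, raster.duration)
            values[cell] += _glial_waveform(t_frames, onset, model)

    if model.noise_sd > 0:
        values += rng.normal(0.0, model.noise_sd, size=values.shape)

    return TraceMatrix(values=values, exposure=exposure, t0=0.0)
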