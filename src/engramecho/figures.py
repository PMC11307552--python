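"""Standard figures: raster plot, per-epoch ISI histograms, detection heatmap."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .isistats import build_histogram, compute_isis
from .paradigm import EPOCHS, ParadigmTimeline, segment
from .spikes import SpikeRaster

log = logging.getLogger("engramecho")

__all__ = ["make_figures", "plot_raster", "plot_isi_histograms", "plot_detection"]


def plot_raster(raster: SpikeRaster, timeline: ParadigmTimeline | None, path):
    fig, ax = plt.subplots(figsize=(10, 5))
    for c, times in enumerate(raster.spikes):
        if times.size:
            ax.vlines(times, c + 0.1, c + 0.9, lw=0.4, color="black")
    if timeline is not None:
        ax.axvspan(*timeline.stim, color="red", alpha=0.15, label="stim")
        ax.legend(loc="upper right")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell")
    ax.set_xlim(0, raster.duration)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_isi_histograms(
    raster: SpikeRaster, timeline: ParadigmTimeline, bin_width: float, path
):
    views = segment(raster, timeline)
    fig, axes = plt.subplots(1, len(EPOCHS), figsize=(16, 3), sharex=True)
    for ax, name in zip(axes, EPOCHS):
        hist = build_histogram(compute_isis(views[name]), bin_width, epoch=name)
        ax.bar(hist.centers, hist.counts, width=bin_width, color="steelblue")
        ax.set_title(name)
        ax.set_xlabel("ISI (s)")
        ax.set_xlim(0, 1.5)
    axes[0].set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_detection(detection, timeline: ParadigmTimeline | None, path):
    fig, ax = plt.subplots(figsize=(10, 5))
    extent = (
        detection.window_starts[0],
        detection.window_starts[-1] + detection.window_length,
        0,
        detection.confidence.shape[0],
    )
    ax.imshow(
        detection.confidence,
        aspect="auto",
        origin="lower",
        extent=extent,
        cmap="magma",
        vmin=0.0,
        vmax=1.0,
    )
    if timeline is not None:
        for x in timeline.stim:
            ax.axvline(x, color="cyan", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_figures(result, outdir=None) -> list[Path]:
    """Render all figures for a pipeline result; missing inputs are
    skipped with a warning rather than raised."""
    outdir = Path(outdir if outdir is not None else result.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _try(fn, name, *args):
        target = outdir / name
        try:
            fn(*args, target)
            written.append(target)
        except Exception as exc:  # noqa: BLE001 - figures must not kill a run
            log.warning("skipping figure %s: %s", name, exc)

    _try(plot_raster, "raster.png", result.raster, result.timeline)
    _try(
        plot_isi_histograms,
        "isi_histograms.png",
        result.raster,
        result.timeline,
        result.raster.exposure,
    )
    if result.detection is not None:
        _try(plot_detection, "detection.png", result.detection, result.timeline)
    else:
        log.warning("no detection map; skipping heatmap")
    return written
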