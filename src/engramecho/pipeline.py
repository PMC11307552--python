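"""End-to-end pipeline: generate/ingest → infer → segment → stats → detect."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, engramnet, io, isistats, population
from .config import RunConfig, config_to_dict
from .paradigm import segment, select_active
from .spikes import SpikeRaster, exclude_slow_waves, infer_spikes
from .synthgen import generate_raster, render_calcium

log = logging.getLogger("engramecho")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    raster: SpikeRaster
    timeline: object
    truth: object
    active: object
    reverb_reports: list
    detection: object | None
    engram_pct: float | None
    outdir: Path
    manifest: dict


def _target_periods(pattern):
    if pattern.kind == "single":
        return {"stim_frequency": 1.0 / pattern.frequency}
    return {
        "doublet_isi": pattern.doublet_isi,
        "gap": pattern.pattern_period - pattern.doublet_isi,
        "pattern_period": pattern.pattern_period,
    }


def run_pipeline(cfg: RunConfig, raster: SpikeRaster | None = None) -> PipelineResult:
    """Run every stage and write CSV/HDF5 outputs plus a JSON manifest.

    When ``raster`` is given it replaces the generator output (ingest
    mode); ground-truth-dependent outputs are then skipped.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    outputs: list[Path] = []
    try:
        return _run(cfg, raster, outdir, outputs)
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name):
    log.info("stage: %s", name)


def _run(cfg, raster, outdir, outputs):
    truth = None
    if raster is None:
        _stage("generate")
        raster, timeline, truth = generate_raster(
            cfg.generator, cfg.pattern, exposure=cfg.exposure
        )
    else:
        _stage("ingest")
        from .paradigm import ParadigmTimeline

        timeline = ParadigmTimeline.from_durations(
            test1=cfg.generator.test1_duration,
            prestim=cfg.generator.prestim_duration,
            poststim=cfg.generator.poststim_duration,
            test2=cfg.generator.test2_duration,
            pattern=cfg.pattern,
            test_pulse_rate=cfg.generator.test_pulse_rate,
        )

    traces = None
    if cfg.spikes.use_calcium:
        _stage("render+infer")
        traces = render_calcium(raster, cfg.calcium, exposure=cfg.exposure)
        mask = exclude_slow_waves(traces, cfg.spikes.rise_time_threshold)
        raster = infer_spikes(
            traces, cfg.spikes.decay_tau, cfg.spikes.threshold_sd, wave_mask=mask
        )

    io.write_raster_csv(raster, outdir / "raster.csv")
    outputs.append(outdir / "raster.csv")
    io.write_hdf5(
        outdir / "recording.h5",
        raster=raster,
        timeline=timeline,
        truth=truth,
        traces=traces,
    )
    outputs.append(outdir / "recording.h5")

    _stage("segment")
    views = segment(raster, timeline)
    active = select_active(
        raster,
        timeline,
        min_response_frac=cfg.paradigm.min_response_frac,
        response_window=cfg.paradigm.response_window,
        which=cfg.paradigm.which,
    )
    log.info("active cells: %d / %d", len(active), raster.n_cells)

    _stage("isistats")
    bin_width = cfg.exposure
    rows = []
    reports = []
    matched_by_epoch: dict[str, frozenset[int]] = {}
    for label, period in _target_periods(cfg.pattern).items():
        matches = {
            e: isistats.match_cells_at_period(
                views[e], period, bin_width, cfg.isistats.min_matches
            )
            for e in ("prestim", "stim", "poststim")
        }
        report = isistats.reverberation_stats(
            matches["prestim"],
            matches["stim"],
            matches["poststim"],
            n_active=len(active),
            durations={e: views[e].duration for e in matches},
        )
        reports.append(report)
        if label in ("stim_frequency", "pattern_period"):
            matched_by_epoch = {e: m.cells for e, m in matches.items()}
        for e, m in matches.items():
            rows.append(
                {
                    "epoch": e,
                    "component": label,
                    "frequency_hz": 1.0 / period,
                    "n_isis_matched": m.n_isis,
                    "n_cells_matched": m.n_cells,
                    "pct_increase_total": report.pct_increase_total,
                    "pct_cells_increase": report.pct_cells_increase,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "reverberation.csv", index=False)
    outputs.append(outdir / "reverberation.csv")

    _stage("population")
    if truth is not None:
        annotations = population.annotations_from_truth(truth)
        ei_rows = []
        for e in ("prestim", "stim", "poststim"):
            periods = _target_periods(cfg.pattern)
            period = periods.get("stim_frequency") or periods.get("doublet_isi")
            m = isistats.match_cells_at_period(
                views[e], period, bin_width, cfg.isistats.min_matches
            )
            r = population.ei_ratio(m.cells, annotations, epoch=e)
            ei_rows.append(vars(r))
        pd.DataFrame(ei_rows).to_csv(outdir / "ei_ratio.csv", index=False)
        outputs.append(outdir / "ei_ratio.csv")
    if cfg.pattern.kind == "doublet":
        ov_rows = []
        for e in ("prestim", "stim", "poststim"):
            rep = population.component_overlap(
                views[e],
                cfg.pattern,
                bin_width,
                measure=cfg.population.measure,
                min_matches=cfg.isistats.min_matches,
            )
            ov_rows.append(
                {
                    "epoch": e,
                    "n_high": len(rep.set_high),
                    "n_low": len(rep.set_low),
                    "measure": rep.measure,
                    "overlap_pct": rep.overlap_pct,
                }
            )
        pd.DataFrame(ov_rows).to_csv(outdir / "overlap.csv", index=False)
        outputs.append(outdir / "overlap.csv")

    detection = None
    engram_pct = None
    if cfg.engramnet.enabled:
        _stage("engramnet")
        ts = engramnet.build_training_set(
            raster,
            timeline,
            timeline.pattern,
            null_kind=cfg.engramnet.null_kind,
            active=active,
            bin_width=bin_width,
            window_cycles=cfg.engramnet.window_cycles,
            seed=cfg.seed,
        )
        model, train_report = engramnet.train(ts, cfg.engramnet.classifier)
        log.info(
            "training: %d epochs, train acc %.3f, holdout %s",
            train_report.n_epochs,
            train_report.train_accuracy,
            train_report.holdout_accuracy,
        )
        model.save(outdir / "model.npz")
        outputs.append(outdir / "model.npz")
        detection = engramnet.scan(
            raster,
            model,
            window_length=ts.cycle,
            bin_width=bin_width,
            window_step=cfg.engramnet.window_step,
            threshold=cfg.engramnet.threshold,
        )
        io.write_events_csv(detection.events, timeline, outdir / "engrams.csv")
        outputs.append(outdir / "engrams.csv")
        io.write_detection_hdf5(detection, outdir / "detection.h5")
        outputs.append(outdir / "detection.h5")
        n_pre = len(detection.events_in(*timeline.prestim))
        n_post = len(detection.events_in(*timeline.poststim))
        engram_pct = engramnet.engram_increase(
            n_pre,
            n_post,
            pre_duration=timeline.duration("prestim"),
            post_duration=timeline.duration("poststim"),
        )
        with (outdir / "engram_stats.json").open("w") as fh:
            json.dump(
                {
                    "n_pre": n_pre,
                    "n_post": n_post,
                    "pct_increase": engram_pct,
                    "train_accuracy": train_report.train_accuracy,
                    "holdout_accuracy": train_report.holdout_accuracy,
                },
                fh,
                indent=2,
            )
        outputs.append(outdir / "engram_stats.json")

    _stage("manifest")
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "config": config_to_dict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(config_to_dict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
        },
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        raster=raster,
        timeline=timeline,
        truth=truth,
        active=active,
        reverb_reports=reports,
        detection=detection,
        engram_pct=engram_pct,
        outdir=outdir,
        manifest=manifest,
    )
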