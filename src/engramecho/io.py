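"""File formats: spike-raster CSV, HDF5 containers, trace CSV.

The raster CSV is ``cell_id,spike_time_s`` with ``# key=value`` comment
headers carrying recording metadata (duration, exposure, cell count) so
the file round-trips without a sidecar. The HDF5 container stores the
ragged spike lists as offsets+values, plus traces, the timeline and the
generator ground truth when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .paradigm import EPOCHS, ParadigmTimeline
from .spikes import SpikeRaster, TraceMatrix
from .synthgen import GroundTruth, StimulationPattern

__all__ = [
    "write_raster_csv",
    "read_raster_csv",
    "write_hdf5",
    "read_raster_hdf5",
    "read_traces_hdf5",
    "read_traces_csv",
    "write_events_csv",
]


def write_raster_csv(raster: SpikeRaster, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# duration_s={float(raster.duration)!r}\n")
        fh.write(f"# exposure_s={float(raster.exposure)!r}\n")
        fh.write(f"# n_cells={raster.n_cells}\n")
        fh.write("cell_id,spike_time_s\n")
        for c, times in enumerate(raster.spikes):
            for t in times:
                fh.write(f"{c},{float(t)!r}\n")


def read_raster_csv(path) -> SpikeRaster:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if not {"cell_id", "spike_time_s"} <= set(df.columns):
        raise ValueError("raster CSV needs cell_id and spike_time_s columns")
    n_cells = int(meta.get("n_cells", df["cell_id"].max() + 1 if len(df) else 0))
    duration = float(
        meta.get("duration_s", df["spike_time_s"].max() if len(df) else 1.0)
    )
    exposure = float(meta.get("exposure_s", 0.02))
    spikes = [np.zeros(0)] * n_cells
    for c, grp in df.groupby("cell_id"):
        spikes[int(c)] = np.sort(grp["spike_time_s"].to_numpy(dtype=float))
    return SpikeRaster(spikes=spikes, duration=duration, exposure=exposure)


def _pattern_to_json(p: StimulationPattern) -> str:
    return json.dumps(
        {
            "kind": p.kind,
            "frequency": p.frequency,
            "doublet_isi": p.doublet_isi,
            "pattern_period": p.pattern_period,
            "onset": p.onset,
            "duration": p.duration,
        }
    )


def _pattern_from_json(s: str) -> StimulationPattern:
    return StimulationPattern(**json.loads(s))


def write_hdf5(
    path,
    raster: SpikeRaster | None = None,
    timeline: ParadigmTimeline | None = None,
    truth: GroundTruth | None = None,
    traces: TraceMatrix | None = None,
) -> None:
    with h5py.File(path, "w") as fh:
        if raster is not None:
            offsets = np.cumsum([0] + [s.size for s in raster.spikes])
            values = (
                np.concatenate(raster.spikes) if raster.n_spikes else np.zeros(0)
            )
            grp = fh.create_group("spikes")
            grp.create_dataset("offsets", data=offsets)
            grp.create_dataset("values", data=values)
            grp.attrs["duration_s"] = raster.duration
            grp.attrs["exposure_s"] = raster.exposure
        if timeline is not None:
            bounds = np.array([timeline.epoch(e) for e in EPOCHS])
            ds = fh.create_dataset("timeline", data=bounds)
            ds.attrs["epochs"] = ",".join(EPOCHS)
            ds.attrs["pattern"] = _pattern_to_json(timeline.pattern)
            fh.create_dataset(
                "test_pulse_times", data=timeline.test_pulse_times
            )
        if truth is not None:
            grp = fh.create_group("ground_truth")
            grp.create_dataset(
                "reverb_cells", data=np.sort(np.array(list(truth.reverb_cells), dtype=int))
            )
            cells = sorted(truth.cell_type)
            grp.create_dataset("cells", data=np.array(cells, dtype=int))
            grp.create_dataset(
                "cell_type",
                data=np.array(
                    [truth.cell_type[c] for c in cells], dtype="S12"
                ),
            )
            comp_cells = sorted(truth.component_of_cell)
            grp.create_dataset(
                "component_cells", data=np.array(comp_cells, dtype=int)
            )
            grp.create_dataset(
                "component",
                data=np.array(
                    [truth.component_of_cell[c] for c in comp_cells], dtype="S8"
                ),
            )
        if traces is not None:
            ds = fh.create_dataset("traces", data=traces.values)
            ds.attrs["exposure_s"] = traces.exposure
            ds.attrs["t0_s"] = traces.t0


def read_raster_hdf5(path):
    """Returns (raster, timeline | None, truth | None)."""
    with h5py.File(path, "r") as fh:
        grp = fh["spikes"]
        offsets = grp["offsets"][()]
        values = grp["values"][()]
        spikes = [
            values[offsets[i] : offsets[i + 1]] for i in range(len(offsets) - 1)
        ]
        raster = SpikeRaster(
            spikes=spikes,
            duration=float(grp.attrs["duration_s"]),
            exposure=float(grp.attrs["exposure_s"]),
        )
        timeline = None
        if "timeline" in fh:
            ds = fh["timeline"]
            bounds = ds[()]
            pattern = _pattern_from_json(ds.attrs["pattern"])
            kwargs = {
                name: tuple(bounds[i]) for i, name in enumerate(EPOCHS)
            }
            timeline = ParadigmTimeline(
                pattern=pattern,
                test_pulse_times=fh["test_pulse_times"][()],
                **kwargs,
            )
        truth = None
        if "ground_truth" in fh:
            grp = fh["ground_truth"]
            cells = grp["cells"][()]
            types = [t.decode() for t in grp["cell_type"][()]]
            comp_cells = grp["component_cells"][()]
            comps = [t.decode() for t in grp["component"][()]]
            truth = GroundTruth(
                reverb_cells=frozenset(int(c) for c in grp["reverb_cells"][()]),
                component_of_cell={
                    int(c): comp for c, comp in zip(comp_cells, comps)
                },
                cell_type={int(c): t for c, t in zip(cells, types)},
            )
    return raster, timeline, truth


def read_traces_hdf5(path) -> TraceMatrix:
    with h5py.File(path, "r") as fh:
        ds = fh["traces"]
        return TraceMatrix(
            values=ds[()],
            exposure=float(ds.attrs["exposure_s"]),
            t0=float(ds.attrs.get("t0_s", 0.0)),
        )


def read_traces_csv(path, exposure: float, t0: float = 0.0) -> TraceMatrix:
    """Wide CSV: first column cell_id, remaining columns one frame each."""
    df = pd.read_csv(path)
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return TraceMatrix(values=values, exposure=exposure, t0=t0)


def write_detection_hdf5(detection, path) -> None:
    """Detection map: /confidence (cells × windows) with scan attrs."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("confidence", data=detection.confidence)
        ds.attrs["step_s"] = detection.window_step
        ds.attrs["threshold"] = detection.threshold
        ds.attrs["window_length_s"] = detection.window_length
        fh.create_dataset("window_starts", data=detection.window_starts)


def write_events_csv(events, timeline: ParadigmTimeline | None, path) -> None:
    rows = []
    for ev in events:
        epoch = ""
        if timeline is not None:
            mid = 0.5 * (ev.start + ev.end)
            for name in EPOCHS:
                s, e = timeline.epoch(name)
                if s <= mid < e:
                    epoch = name
                    break
        rows.append(
            {
                "cell_id": ev.cell,
                "start_s": ev.start,
                "end_s": ev.end,
                "peak_conf": ev.peak_confidence,
                "epoch": epoch,
            }
        )
    pd.DataFrame(
        rows, columns=["cell_id", "start_s", "end_s", "peak_conf", "epoch"]
    ).to_csv(path, index=False)
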