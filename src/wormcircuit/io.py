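"""File formats, configuration and pipeline orchestration.

Conventions: voxel indices are 0-based; time is in seconds from recording
start; positions are micrometers; angles are degrees.  CSV files are UTF-8,
comma-separated, ``.`` decimal, header mandatory.  Movies are one multi-page
TIFF per channel, pages ordered volume-major (all z-planes of volume 0,
then volume 1, ...), with per-page (t, z) metadata in an accompanying CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import FormatError, InvalidConfigError, SchemaError
from .events import EventTrain
from .traces import TwoChannelMovie

__all__ = [
    "RunManifest",
    "write_movie",
    "read_movie",
    "read_table",
    "read_events",
    "write_events",
    "read_track",
    "write_track",
    "write_annotations",
    "read_annotations",
    "write_traces",
    "read_traces",
    "run_pipeline",
    "SCHEMAS",
]

SCHEMAS = {
    "events": ["onset_s", "duration_s"],
    "tracks": ["t_s", "x_um", "y_um"],
    "annotations": ["t_index", "neuron_id", "x_vox", "y_vox", "z_vox"],
    "traces": ["t_s", "neuron_id", "stage", "value"],
    "movie_meta": ["page", "t_index", "z_index", "t_s"],
    "mosaic_counts": ["cell_type", "k"],
}

TRACE_STAGES = ("raw_red", "raw_green", "artifact", "corrected")


@dataclass
class RunManifest:
    """Reproducibility record written once per pipeline run."""

    config: dict
    seed: int
    tool_version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stage_timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")


def sha256_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------- movies

def write_movie(movie: TwoChannelMovie, path_red, path_green,
                path_meta) -> None:
    """One multi-page TIFF per channel plus a (page, t, z) metadata CSV."""
    n_t, n_z = movie.n_volumes, movie.red_volumes.shape[1]
    for path, data in ((path_red, movie.red_volumes),
                       (path_green, movie.green_volumes)):
        pages = data.reshape(n_t * n_z, *data.shape[2:]).astype(np.float32)
        tifffile.imwrite(path, pages)
    meta = pd.DataFrame({
        "page": np.arange(n_t * n_z),
        "t_index": np.repeat(np.arange(n_t), n_z),
        "z_index": np.tile(np.arange(n_z), n_t),
        "t_s": np.repeat(np.arange(n_t) / movie.frame_rate, n_z),
    })
    meta.to_csv(path_meta, index=False)


def read_movie(path_red, path_green, path_meta,
               voxel_size=(0.4, 0.4, 1.2)) -> TwoChannelMovie:
    """Assemble a two-channel movie from per-channel TIFFs and metadata.

    The metadata CSV defines the (t, z) grid; a page count inconsistent
    with that grid is rejected.
    """
    meta = read_table(path_meta, "movie_meta")
    n_t = int(meta["t_index"].max()) + 1
    n_z = int(meta["z_index"].max()) + 1
    expected = n_t * n_z
    if len(meta) != expected:
        raise FormatError(f"metadata lists {len(meta)} pages but the (t, z) "
                          f"grid implies {expected}")
    channels = {}
    for name, path in (("red", path_red), ("green", path_green)):
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.shape[0] != expected:
            raise FormatError(f"{name} TIFF has {pages.shape[0]} pages, "
                              f"expected {expected} (={n_t} volumes x {n_z} "
                              f"z-planes)")
        order = meta.sort_values("page").index
        t_idx = meta.loc[order, "t_index"].to_numpy()
        z_idx = meta.loc[order, "z_index"].to_numpy()
        vol = np.empty((n_t, n_z, *pages.shape[1:]), dtype=pages.dtype)
        vol[t_idx, z_idx] = pages
        channels[name] = vol
    if channels["red"].shape != channels["green"].shape:
        raise FormatError(f"red/green shapes differ: {channels['red'].shape} "
                          f"vs {channels['green'].shape}")
    t_s = meta.drop_duplicates("t_index").sort_values("t_index")["t_s"]
    dt = np.diff(t_s.to_numpy())
    frame_rate = 1.0 / float(np.median(dt)) if dt.size else 1.0
    return TwoChannelMovie(red_volumes=channels["red"],
                           green_volumes=channels["green"],
                           frame_rate=frame_rate, voxel_size=voxel_size)


# ---------------------------------------------------------------- tables

def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate its header against a named schema.

    Unknown columns are preserved; missing required columns raise a
    SchemaError listing them.
    """
    required = SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} "
                          f"for schema {schema!r}", columns=missing)
    return df


def read_events(path, recording_length: float | None = None) -> EventTrain:
    df = read_table(path, "events")
    if (df["duration_s"] <= 0).any():
        raise SchemaError(f"{path}: durations must be positive",
                          columns=["duration_s"])
    if recording_length is None:
        recording_length = float((df["onset_s"] + df["duration_s"]).max()) \
            if len(df) else 1.0
    try:
        return EventTrain(df["onset_s"].to_numpy(),
                          df["duration_s"].to_numpy(), recording_length)
    except InvalidConfigError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_events(events: EventTrain, path) -> None:
    events.to_frame().to_csv(path, index=False)


def read_track(path, dorsal_side: int = 1, frame_rate: float | None = None):
    from .behavior import WormTrack

    df = read_table(path, "tracks")
    t = df["t_s"].to_numpy()
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return WormTrack(timestamps=t,
                     positions=df[["x_um", "y_um"]].to_numpy(),
                     dorsal_side=dorsal_side, frame_rate=frame_rate)


def write_track(track, path) -> None:
    pd.DataFrame({"t_s": track.timestamps,
                  "x_um": track.positions[:, 0],
                  "y_um": track.positions[:, 1]}).to_csv(path, index=False)


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations[SCHEMAS["annotations"]].to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    return read_table(path, "annotations")


def write_traces(result: dict, frame_rate: float, path) -> None:
    """Long-format trace table: one row per (time, neuron, stage)."""
    rows = []
    for neuron_id, d in result["neurons"].items():
        n = d["raw_red"].values.size
        t_s = np.arange(n) / frame_rate
        for stage, vals in (("raw_red", d["raw_red"].values),
                            ("raw_green", d["raw_green"].values),
                            ("artifact", d["artifact"]),
                            ("corrected", d["corrected"].values)):
            rows.append(pd.DataFrame({"t_s": t_s, "neuron_id": neuron_id,
                                      "stage": stage, "value": vals}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              float_format="%.12g")


def read_traces(path) -> pd.DataFrame:
    df = read_table(path, "traces")
    bad = set(df["stage"]) - set(TRACE_STAGES)
    if bad:
        raise SchemaError(f"{path}: unknown trace stage(s) {sorted(bad)}",
                          columns=["stage"])
    return df


# ---------------------------------------------------------------- pipeline

def run_pipeline(config: dict, outdir) -> RunManifest:
    """Run simulate -> extract -> analyze -> behavior -> mosaic end to end.

    ``config`` keys: ``seed`` (int), ``stages`` (subset of the five stage
    names; default all), and optional ``simulation`` overrides applied to
    :class:`~wormcircuit.synthetic.SimulationConfig`.  Outputs and a run
    manifest land in ``outdir``.  Deterministic stages reproduce identical
    outputs for identical manifests.
    """
    from . import behavior as bh
    from . import events as ev_mod
    from . import mosaic as mo
    from . import synthetic as syn
    from . import traces as tr

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages",
                        ["simulate", "extract", "analyze", "behavior",
                         "mosaic"])
    known = {"simulate", "extract", "analyze", "behavior", "mosaic"}
    unknown = set(stages) - known
    if unknown:
        raise InvalidConfigError(f"unknown stage(s) {sorted(unknown)}")
    if ("extract" in stages or "analyze" in stages) \
            and "simulate" not in stages:
        raise InvalidConfigError(
            "extract/analyze stages need the simulate stage for input")
    manifest = RunManifest(config=config, seed=seed)
    sim_overrides = dict(config.get("simulation", {}))
    track_overrides = sim_overrides.pop("track", None)
    if track_overrides is not None:
        sim_overrides["track"] = syn.TrackParams(**track_overrides)
    sim_cfg = dataclasses.replace(syn.SimulationConfig(random_seed=seed),
                                  **sim_overrides)

    def timed(name, fn):
        t0 = time.perf_counter()
        out = fn()
        manifest.stage_timings_s[name] = round(time.perf_counter() - t0, 4)
        return out

    movie = events = extraction = None
    if "simulate" in stages:
        def _simulate():
            ev = syn.simulate_event_train(sim_cfg)
            mv, _truth = syn.simulate_calcium_movie(sim_cfg, ev)
            write_events(ev, outdir / "events.csv")
            write_movie(mv, outdir / "red.tif", outdir / "green.tif",
                        outdir / "movie_meta.csv")
            ann = pd.DataFrame(
                [{"t_index": ti, "neuron_id": f"neuron{i}",
                  "x_vox": p[0], "y_vox": p[1], "z_vox": p[2]}
                 for ti in range(sim_cfg.n_volumes)
                 for i, p in enumerate(sim_cfg.neuron_positions)])
            write_annotations(ann, outdir / "annotations.csv")
            tk, _ = syn.simulate_worm_track(sim_cfg)
            write_track(tk, outdir / "track.csv")
            return ev, mv, ann, tk
        events, movie, annotations, track = timed("simulate", _simulate)

    if "extract" in stages:
        extraction = timed("extract", lambda: tr.extract_corrected_traces(
            movie, annotations, events))
        write_traces(extraction, movie.frame_rate, outdir / "traces.csv")

    if "analyze" in stages and extraction is not None:
        def _analyze():
            rows = []
            for neuron_id, d in extraction["neurons"].items():
                w = ev_mod.align_to_events(d["corrected"].values,
                                           movie.frame_rate, events)
                if w.is_empty():
                    continue
                eta = ev_mod.event_triggered_average(w)
                rows.append(pd.DataFrame({
                    "neuron_id": neuron_id, "rel_time_s": eta.rel_time,
                    "mean_change_ratio": eta.mean, "sem": eta.sem,
                    "n_events": eta.n_events}))
            if rows:
                pd.concat(rows, ignore_index=True).to_csv(
                    outdir / "eta.csv", index=False, float_format="%.12g")
        timed("analyze", _analyze)

    if "behavior" in stages:
        def _behavior():
            tk = track if "simulate" in stages else read_track(
                config["track_csv"], config.get("dorsal_side", 1))
            metrics = bh.track_metrics(
                tk, window_s=min(120.0, tk.duration + 1.0 / tk.frame_rate))
            pd.DataFrame([metrics]).to_csv(outdir / "behavior_metrics.csv",
                                           index=False)
        timed("behavior", _behavior)

    if "mosaic" in stages:
        def _mosaic():
            tree = mo.load_rim_fixture_tree()
            est = mo.estimate_transmission(config.get("mosaic_f", 39 / 181),
                                           config.get("mosaic_D", 18))
            for cond in ("divergence", "P0"):
                tab = mo.predict_retention_table(tree, est.p, cond)
                tab.to_csv(outdir / f"retention_{cond}.csv", index=False)
        timed("mosaic", _mosaic)

    for f in sorted(outdir.glob("*.csv")):
        manifest.input_digests[f.name] = sha256_digest(f)
    manifest.write(outdir / "manifest.json")
    return manifest
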