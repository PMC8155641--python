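"""Batch pipeline over the coverslip/area folder layout.

A coverslip folder contains one subfolder per imaged area; each area holds
the fluorescence movies (``movie*.tif``), an ROI file (``rois.tif`` label
image or ``rois.json`` polygons), and optionally a brightfield image
(provenance only — ROIs are supplied as files, not drawn here). For every
movie the pipeline writes traces, thresholded spikes, per-neuron noise
estimates, activity metrics, and the STTC pair table and matrix, all as
CSV. One SNR threshold applies across the whole coverslip, and the run log
records it together with every seed, so a run is fully reproducible.

Failures are isolated per area: a broken area is reported and skipped
while the remaining areas are still processed.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity_metrics as am
from . import connectivity as conn
from . import spike_detection as sd
from . import traces_io as tio

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "process_area"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis settings; every numeric field must be positive."""

    frame_rate: float = 500.0
    snr_threshold: float = 16.0
    kmeans_seed: int = 0
    noise_window_frames: int = 100
    baseline_halfwidth_frames: int = 250
    poly_order: int = 3
    dt_ms: float = 10.0
    polarity: int = 1
    input_dir: str | Path = "."
    output_dir: str | Path = "output"

    def __post_init__(self) -> None:
        for name in ("frame_rate", "snr_threshold", "noise_window_frames",
                     "baseline_halfwidth_frames", "poly_order", "dt_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    outputs: dict[str, list[Path]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _find_roi_file(area: Path) -> Path:
    for name in ("rois.tif", "rois.tiff", "rois.png", "rois.json"):
        p = area / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no ROI file (rois.tif/.png/.json) in {area}")


def process_area(area: Path, out_dir: Path, config: RunConfig,
                 log_lines: list[str]) -> list[Path]:
    """Analyze all movies of one area; returns the files written."""
    movies = sorted(area.glob("movie*.tif")) + sorted(area.glob("movie*.tiff"))
    if not movies:
        raise FileNotFoundError(f"no movie*.tif files in {area}")
    roi_path = _find_roi_file(area)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for movie_path in movies:
        movie = tio.load_movie(movie_path, frame_rate=config.frame_rate)
        rois = tio.load_rois(roi_path, image_shape=movie.image_shape)
        stem = movie_path.stem
        bg_trace = tio.extract_trace(movie, rois.background, roi_label="background")
        traces = []
        for lab, mask in zip(rois.labels, rois.masks):
            raw = tio.extract_trace(movie, mask, roi_label=lab)
            traces.append(tio.background_correct(raw, bg_trace))
        written.append(_write_csv(tio.traces_to_frame(traces), out_dir / f"{stem}_traces.csv"))

        spike_rows, noise_rows, metric_rows, isi_rows, trains = [], [], [], [], []
        for trace in traces:
            work = trace if config.polarity == 1 else sd.invert_trace(trace)
            labels = sd.cluster_frames(work, seed=config.kmeans_seed)
            events = sd.extract_events(work, labels)
            events, noise = sd.score_events(
                work, labels, events, noise_window=config.noise_window_frames,
                baseline_halfwidth=config.baseline_halfwidth_frames)
            train = sd.apply_threshold(events, config.snr_threshold,
                                       duration=trace.duration_ms,
                                       neuron_id=trace.roi_label)
            trains.append(train)
            noise_rows.append({"neuron_id": trace.roi_label,
                               "noise_sigma_dff": noise.sigma,
                               "window_frames": noise.window_frames})
            for ev in events:
                if ev.snr >= config.snr_threshold:
                    spike_rows.append({
                        "neuron_id": trace.roi_label, "peak_time_ms": ev.peak_time,
                        "amplitude_dff": ev.amplitude_dff, "snr": ev.snr,
                        "edge": ev.edge})
            dff = sd.to_dff(work, labels, config.baseline_halfwidth_frames)
            flat = am.flatten_trace(dff, poly_order=config.poly_order, labels=labels)
            metrics = am.frequency_stats(train)
            metrics.auc = am.auc(flat, config.frame_rate)
            metric_rows.append({"neuron_id": trace.roi_label,
                                "n_spikes": metrics.n_spikes,
                                "mean_freq_hz": metrics.mean_frequency,
                                "auc_dffms": metrics.auc})
            for isi, inst in zip(metrics.isis, metrics.instantaneous_frequencies):
                isi_rows.append({"neuron_id": trace.roi_label, "isi_ms": isi,
                                 "inst_freq_hz": inst, "ln_isi": np.log(isi)})
            log_lines.append(_stamp(
                f"{area.name}/{stem} roi {trace.roi_label}: "
                f"{train.n_spikes} spikes, noise sigma {noise.sigma:.6g}, "
                f"snr threshold {config.snr_threshold}"))

        cols = ["neuron_id", "peak_time_ms", "amplitude_dff", "snr", "edge"]
        written.append(_write_csv(pd.DataFrame(spike_rows, columns=cols),
                                  out_dir / f"{stem}_spikes.csv"))
        written.append(_write_csv(pd.DataFrame(noise_rows),
                                  out_dir / f"{stem}_noise.csv"))
        written.append(_write_csv(pd.DataFrame(metric_rows),
                                  out_dir / f"{stem}_metrics.csv"))
        written.append(_write_csv(
            pd.DataFrame(isi_rows, columns=["neuron_id", "isi_ms", "inst_freq_hz", "ln_isi"]),
            out_dir / f"{stem}_isi.csv"))
        if len(trains) >= 2:
            params = conn.STTCParams(dt=config.dt_ms, duration=movie.duration_ms)
            written.append(_write_csv(conn.matrix_to_pairs(trains, params),
                                      out_dir / f"{stem}_sttc_pairs.csv"))
            mat = conn.sttc_matrix(trains, params)
            mat_path = out_dir / f"{stem}_sttc_matrix.csv"
            mat.to_csv(mat_path, index_label="neuron_id")
            written.append(mat_path)
    return written


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def _stamp(msg: str) -> str:
    return f"{datetime.datetime.now().isoformat(timespec='seconds')} {msg}"


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Process every area folder under the coverslip input directory.

    One failing area does not stop the others; all failures are collected
    in the result (and should map to a nonzero exit in a CLI caller).
    """
    root = Path(config.input_dir)
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    areas = sorted(p for p in root.iterdir() if p.is_dir())
    if not areas:
        raise FileNotFoundError(f"no area folders under {root}")
    result = PipelineResult()
    log_lines = [_stamp(f"config: {dataclasses.asdict(config)}")]
    for area in areas:
        try:
            result.outputs[area.name] = process_area(
                area, out_root / area.name, config, log_lines)
        except Exception as exc:  # isolate per-area failures
            result.failures[area.name] = str(exc)
            log_lines.append(_stamp(f"AREA FAILED {area.name}: {exc}"))
            logger.warning("area %s failed: %s", area.name, exc)
    (out_root / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return result
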