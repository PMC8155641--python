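"""Ground-truth synthetic data: spike trains, fluorescence traces, movies.

Every pipeline stage is testable without real recordings. Spike trains are
homogeneous Poisson processes thinned by an absolute refractory period;
correlated pairs share spikes copied (with optional jitter) from a common
parent process, giving a single knob — the sharing probability — that the
tiling coefficient should track. Traces place a stereotyped transient
(linear rise over a frame or two, then millisecond-scale exponential
decay) on a slowly photobleaching baseline with additive Gaussian noise;
the transient amplitude is defined multiplicatively so its ΔF/F is
invariant to bleaching, which is exactly why ΔF/F is the working scale.
Optional baseline artifacts (a step, or sinusoidal oscillation) mimic the
unstable baselines of phototoxically stressed cells.

Defaults emulate the recording conditions of healthy cultures under this
assay: 500 Hz sampling, 20 s traces, sparse firing around 1 Hz, event
ΔF/F of 0.1 against baseline noise of 0.55% ΔF/F — an event
signal-to-noise ratio of ~18, the mean reported for control coverslips.
Detection with 3-cluster k-means is only reliable when transients stand
this far above the noise; below roughly 15x the baseline noise the
smallest k-means cluster starts absorbing noise frames and the detector
degrades (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .traces_io import Movie, RawTrace, ROISet
from .spike_detection import SpikeTrain

__all__ = [
    "SimConfig",
    "simulate_poisson_train",
    "simulate_correlated_pair",
    "render_trace",
    "render_movie",
]


@dataclass
class SimConfig:
    """Generator settings; identical seeds reproduce identical outputs.

    rate : Hz — mean firing rate of the Poisson train.
    duration : ms — recording length (default 20 s).
    refractory : ms — absolute refractory period enforced by thinning.
    frame_rate : Hz — sampling rate of the rendered trace (default 500).
    f0 : baseline fluorescence intensity (arbitrary units).
    amplitude_dff : peak ΔF/F of one transient.
    decay_tau : ms — exponential decay constant of the transient.
    rise_frames : frames of linear rise to the peak.
    noise_sd : additive Gaussian noise, intensity units.
    bleach_rate : fractional fluorescence loss per second.
    sub_rate : Hz — rate of subthreshold (synaptic-potential-like) events.
    sub_amplitude_dff : peak ΔF/F of a subthreshold event.
    sub_decay_tau : ms — decay constant of subthreshold events (slower
        than the action-potential transient, as for synaptic potentials).
    artifact : "none", "step" (+20% baseline jump at midpoint), or
        "oscillation" (sinusoidal baseline wobble).
    """

    rate: float = 1.0
    duration: float = 20_000.0
    refractory: float = 2.0
    frame_rate: float = 500.0
    f0: float = 100.0
    amplitude_dff: float = 0.1
    decay_tau: float = 2.0
    rise_frames: int = 1
    noise_sd: float = 0.55
    bleach_rate: float = 0.001
    sub_rate: float = 0.0
    sub_amplitude_dff: float = 0.02
    sub_decay_tau: float = 20.0
    artifact: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")
        if not self.amplitude_dff > 0:
            raise ValueError("amplitude_dff must be positive")
        if self.artifact not in ("none", "step", "oscillation"):
            raise ValueError(f"unknown artifact kind {self.artifact!r}")


def _thin_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Drop spikes closer than the refractory period to the last kept spike."""
    if times.size == 0 or refractory <= 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def simulate_poisson_train(cfg: SimConfig, neuron_id: int | str = 0,
                           rng: np.random.Generator | None = None) -> SpikeTrain:
    """Homogeneous Poisson spike train thinned by the refractory period."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.rate == 0:
        return SpikeTrain(times=np.empty(0), duration=cfg.duration, neuron_id=neuron_id)
    rate_per_ms = cfg.rate / 1000.0
    # oversample gaps, then trim to the duration
    n_guess = max(16, int(2 * rate_per_ms * cfg.duration + 10))
    gaps = rng.exponential(1.0 / rate_per_ms, size=n_guess)
    times = np.cumsum(gaps)
    while times.size and times[-1] < cfg.duration:
        extra = rng.exponential(1.0 / rate_per_ms, size=n_guess)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    times = times[times < cfg.duration]
    times = _thin_refractory(times, cfg.refractory)
    return SpikeTrain(times=times, duration=cfg.duration, neuron_id=neuron_id)


def simulate_correlated_pair(parent_rate: float, p_share: float, jitter_sd: float,
                             indep_rate: float, duration: float, seed: int,
                             refractory: float = 2.0,
                             ids: tuple = (0, 1)) -> tuple[SpikeTrain, SpikeTrain]:
    """Correlated train pair via a common-parent construction.

    Each spike of a parent Poisson process is copied into each child with
    probability ``p_share`` and jittered by centered Gaussian noise of sd
    ``jitter_sd``; each child additionally receives independent Poisson
    spikes at ``indep_rate``. With ``p_share=1``, zero jitter and no
    independent spikes the children are identical; with ``p_share=0`` they
    are independent.
    """
    if not 0 <= p_share <= 1:
        raise ValueError("p_share must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    parent = simulate_poisson_train(
        SimConfig(rate=parent_rate, duration=duration, refractory=refractory),
        rng=rng)
    children = []
    for nid in ids:
        copied = parent.times[rng.random(parent.n_spikes) < p_share] if p_share > 0 \
            else np.empty(0)
        if jitter_sd > 0 and copied.size:
            copied = copied + rng.normal(0.0, jitter_sd, size=copied.size)
        own = simulate_poisson_train(
            SimConfig(rate=indep_rate, duration=duration, refractory=refractory),
            rng=rng).times if indep_rate > 0 else np.empty(0)
        t = np.concatenate([copied, own])
        t = np.sort(t[(t >= 0) & (t < duration)])
        t = _thin_refractory(t, refractory)
        children.append(SpikeTrain(times=t, duration=duration, neuron_id=nid))
    return children[0], children[1]


def _event_kernel(frame_rate: float, rise_frames: int, decay_tau: float) -> np.ndarray:
    """Unit-peak transient: linear rise over rise_frames, exponential decay."""
    tau_frames = decay_tau * frame_rate / 1000.0
    n_decay = int(np.ceil(7 * tau_frames)) + 1
    rise = np.arange(1, rise_frames + 1) / rise_frames
    decay = np.exp(-np.arange(1, n_decay) / tau_frames)
    return np.concatenate([rise, decay])


def render_trace(train: SpikeTrain, cfg: SimConfig,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[RawTrace, np.ndarray]:
    """Render a spike train into a fluorescence trace.

    trace[t] = f0 · bleach(t) · artifact(t) · (1 + amplitude · Σ spike kernels
               + sub_amplitude · Σ subthreshold kernels) + noise

    Returns the trace and the ground-truth event peak frames (spikes whose
    peak would fall past the last frame are omitted from the truth). The
    peak of an isolated noiseless transient equals ``amplitude_dff`` in
    ΔF/F exactly, because amplitude scales the baseline multiplicatively.

    Besides the action-potential transients, slower low-amplitude
    subthreshold events (Poisson at ``sub_rate``) ride on the baseline —
    the synaptic-potential population that gives the frame intensities
    their three-cluster structure (baseline / subthreshold / spike).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)  # decouple from spike generation
    n_frames = int(round(cfg.duration * cfg.frame_rate / 1000.0))
    kernel = _event_kernel(cfg.frame_rate, cfg.rise_frames, cfg.decay_tau)
    signal = np.zeros(n_frames)
    truth = []
    for t_ms in train.times:
        onset = int(np.floor(t_ms * cfg.frame_rate / 1000.0))
        peak = onset + cfg.rise_frames
        if peak >= n_frames:
            continue
        stop = min(onset + 1 + len(kernel), n_frames)
        signal[onset + 1:stop] += kernel[:stop - onset - 1]
        truth.append(peak)
    sub_signal = np.zeros(n_frames)
    if cfg.sub_rate > 0 and cfg.sub_amplitude_dff > 0:
        sub_kernel = _event_kernel(cfg.frame_rate, cfg.rise_frames, cfg.sub_decay_tau)
        sub_train = simulate_poisson_train(
            SimConfig(rate=cfg.sub_rate, duration=cfg.duration,
                      refractory=cfg.refractory, frame_rate=cfg.frame_rate), rng=rng)
        for t_ms in sub_train.times:
            onset = int(np.floor(t_ms * cfg.frame_rate / 1000.0))
            stop = min(onset + 1 + len(sub_kernel), n_frames)
            if stop > onset + 1:
                sub_signal[onset + 1:stop] += sub_kernel[:stop - onset - 1]
    t_s = np.arange(n_frames) / cfg.frame_rate
    baseline = cfg.f0 * np.exp(-cfg.bleach_rate * t_s)
    if cfg.artifact == "step":
        baseline = baseline * np.where(np.arange(n_frames) >= n_frames // 2, 1.2, 1.0)
    elif cfg.artifact == "oscillation":
        baseline = baseline * (1.0 + 0.05 * np.sin(2 * np.pi * 1.0 * t_s))
    values = baseline * (1.0 + cfg.amplitude_dff * signal
                         + cfg.sub_amplitude_dff * sub_signal)
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=n_frames)
    trace = RawTrace(values=values, frame_rate=cfg.frame_rate,
                     roi_label=train.neuron_id, background_corrected=False)
    return trace, np.asarray(truth, dtype=int)


def render_movie(traces: list[RawTrace], centers: list[tuple[float, float]],
                 radii: list[float], shape: tuple[int, int],
                 background_level: float = 10.0) -> tuple[Movie, ROISet]:
    """Paint each trace onto a disk ROI over a flat background.

    Disks must be disjoint and inside the frame. The returned ROISet holds
    the exact disk masks plus a background mask placed in a disk-free
    corner, so extraction round-trips the input traces exactly at zero
    noise.
    """
    if not traces:
        raise ValueError("no traces to render")
    if len(traces) != len(centers) or len(traces) != len(radii):
        raise ValueError("traces, centers and radii must have equal lengths")
    n = len(traces[0])
    if any(len(t) != n for t in traces):
        raise ValueError("traces have unequal lengths")
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    masks = []
    for (r0, c0), rad in zip(centers, radii):
        if r0 - rad < 0 or r0 + rad >= rows or c0 - rad < 0 or c0 + rad >= cols:
            raise ValueError(f"disk at {(r0, c0)} radius {rad} extends outside {shape}")
        masks.append((rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2)
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                raise ValueError(f"disks {i} and {j} overlap")
    any_disk = np.logical_or.reduce(masks)
    bg_mask = _corner_background_mask(any_disk)

    frames = np.full((n, rows, cols), float(background_level), dtype=np.float32)
    for mask, trace in zip(masks, traces):
        frames[:, mask] = trace.values[:, None].astype(np.float32)
    movie = Movie(frames=frames, frame_rate=traces[0].frame_rate)
    rois = ROISet(labels=[t.roi_label for t in traces], masks=masks,
                  background=bg_mask, image_shape=shape)
    return movie, rois


def _corner_background_mask(occupied: np.ndarray, size: int = 4) -> np.ndarray:
    """First size×size square (raster order) free of any disk pixel."""
    rows, cols = occupied.shape
    for r in range(rows - size + 1):
        for c in range(cols - size + 1):
            if not occupied[r:r + size, c:c + size].any():
                mask = np.zeros_like(occupied)
                mask[r:r + size, c:c + size] = True
                return mask
    raise ValueError("no disk-free region available for a background ROI")


def write_simulation(out_dir: str | Path, movie: Movie, rois: ROISet,
                     trains: list[SpikeTrain], cfg: SimConfig) -> dict[str, Path]:
    """Write a simulated area to disk: movie TIFF, ROI label image,
    ground-truth spikes CSV, and the generator config as a YAML sidecar."""
    import pandas as pd
    import tifffile
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["movie"] = out_dir / "movie_000.tif"
    tifffile.imwrite(paths["movie"], movie.frames, photometric="minisblack")
    label_img = np.zeros(rois.image_shape, dtype=np.uint16)
    for lab, mask in zip(rois.labels, rois.masks):
        label_img[mask] = lab
    bg_label = max(rois.labels) + 1
    label_img[rois.background] = bg_label
    paths["rois"] = out_dir / "rois.tif"
    tifffile.imwrite(paths["rois"], label_img)
    truth = pd.DataFrame([
        {"neuron_id": tr.neuron_id, "peak_time_ms": t}
        for tr in trains for t in tr.times
    ], columns=["neuron_id", "peak_time_ms"])
    paths["truth"] = out_dir / "ground_truth_spikes.csv"
    truth.to_csv(paths["truth"], index=False)
    paths["config"] = out_dir / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return paths
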