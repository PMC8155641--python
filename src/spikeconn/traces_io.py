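"""Movie and ROI input, per-neuron trace extraction, background correction.

A recording is a multi-page grayscale TIFF stack. Regions of interest come
either as a label image (0 = outside, k = neuron k) or as a JSON list of
polygons; one extra ROI covers a patch of background, whose mean trace is
subtracted frame-by-frame from every neuron trace before spike detection.
The frame rate is never read from file metadata — it is supplied by the
caller, because acquisition software writes it inconsistently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image, ImageDraw

__all__ = [
    "Movie",
    "ROISet",
    "RawTrace",
    "load_movie",
    "save_movie",
    "load_rois",
    "rois_from_label_image",
    "rois_from_polygons",
    "extract_trace",
    "background_correct",
    "traces_to_frame",
]

BACKGROUND_LABEL = 0


class MovieFormatError(ValueError):
    """Raised when a file is not a readable single-channel multi-frame movie."""


@dataclass
class Movie:
    """A fluorescence movie: 3-D stack ``(frame, row, col)`` plus frame rate.

    Parameters
    ----------
    frames : ndarray
        Non-negative intensities, at least two frames.
    frame_rate : float
        Acquisition rate in Hz (the study's recordings use 500 Hz).
    pixel_size : float, optional
        Pixel edge in micrometres; metadata only.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise MovieFormatError(
                f"movie must be a 3-D (frame, row, col) stack, got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise MovieFormatError("movie must contain at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("movie intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("movie intensities must be non-negative")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.frame_rate

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms


@dataclass
class ROISet:
    """Labeled neuron masks plus one background mask over a shared geometry."""

    labels: list[int]
    masks: list[np.ndarray]
    background: np.ndarray
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.masks):
            raise ValueError("labels and masks must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ROI labels must be unique")
        shape = tuple(self.image_shape)
        for lab, m in zip(self.labels, self.masks):
            m = np.asarray(m, dtype=bool)
            if m.shape != shape:
                raise ValueError(f"mask for ROI {lab} does not fit image shape {shape}")
            if not m.any():
                raise ValueError(f"mask for ROI {lab} is empty")
        bg = np.asarray(self.background, dtype=bool)
        if bg.shape != shape:
            raise ValueError("background mask does not fit image shape")
        if not bg.any():
            raise ValueError("background mask is empty")
        for lab, m in zip(self.labels, self.masks):
            if np.array_equal(bg, np.asarray(m, dtype=bool)):
                raise ValueError(f"background mask equals neuron mask {lab}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class RawTrace:
    """Per-frame mean intensity of one ROI (arbitrary units)."""

    values: np.ndarray
    frame_rate: float
    roi_label: int | str = 0
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_ms(self) -> float:
        return len(self.values) * 1000.0 / self.frame_rate

    def times_ms(self) -> np.ndarray:
        """Frame times in ms; frame 0 maps to 0 ms."""
        return np.arange(len(self.values)) * (1000.0 / self.frame_rate)


def load_movie(path: str | Path, frame_rate: float, pixel_size: float | None = None) -> Movie:
    """Read a multi-page grayscale TIFF movie.

    ``frame_rate`` is required; it is deliberately not taken from TIFF tags.
    RGB stacks and single-frame files are rejected with a format error.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            page0 = tf.pages[0]
            if page0.samplesperpixel != 1:
                raise MovieFormatError(
                    f"{path.name}: expected single-channel movie, "
                    f"got {page0.samplesperpixel} samples per pixel"
                )
            frames = tf.asarray()
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"could not read movie {path}: {exc}") from exc
    if frames.ndim == 2:
        raise MovieFormatError(f"{path.name}: single-frame TIFF is not a movie")
    if frames.ndim != 3:
        raise MovieFormatError(
            f"{path.name}: expected grayscale (frame, row, col) stack, got shape {frames.shape}"
        )
    return Movie(frames=frames, frame_rate=frame_rate, pixel_size=pixel_size)


def save_movie(movie: Movie, path: str | Path) -> Path:
    """Write the stack as a multi-page TIFF (lossless; round-trips bit-identically)."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames, photometric="minisblack")
    return path


def rois_from_label_image(label_image: np.ndarray, background_label: int | None = None,
                          background_mask: np.ndarray | None = None) -> ROISet:
    """Build an ROISet from a label image (0 = outside, k = neuron k).

    The background ROI is given either as a dedicated label value in the
    image or as an explicit mask.
    """
    lab = np.asarray(label_image)
    if lab.ndim != 2:
        raise ValueError("label image must be 2-D")
    values = sorted(int(v) for v in np.unique(lab) if v != 0)
    if background_label is not None:
        if background_label not in values:
            raise ValueError(f"background label {background_label} not present in image")
        bg = lab == background_label
        values = [v for v in values if v != background_label]
    elif background_mask is not None:
        bg = np.asarray(background_mask, dtype=bool)
    else:
        raise ValueError("supply background_label or background_mask")
    if not values:
        raise ValueError("label image contains no neuron ROIs")
    masks = [lab == v for v in values]
    return ROISet(labels=values, masks=masks, background=bg, image_shape=lab.shape)


def rois_from_polygons(polygons: dict, image_shape: tuple[int, int]) -> ROISet:
    """Rasterize polygon ROIs (even-odd fill) into an ROISet.

    ``polygons`` maps ``"background"`` and string neuron labels to lists of
    ``[row, col]`` vertices (0-based pixel coordinates).
    """
    if "background" not in polygons:
        raise ValueError("polygon ROI set must include a 'background' entry")
    labels, masks = [], []
    bg = None
    for key, verts in polygons.items():
        mask = _rasterize_polygon(verts, image_shape)
        if key == "background":
            bg = mask
        else:
            labels.append(int(key))
            masks.append(mask)
    order = np.argsort(labels)
    return ROISet(
        labels=[labels[i] for i in order],
        masks=[masks[i] for i in order],
        background=bg,
        image_shape=tuple(image_shape),
    )


def _rasterize_polygon(vertices, image_shape) -> np.ndarray:
    # PIL polygon fill is scanline even-odd; PIL uses (x, y) = (col, row)
    img = Image.new("1", (image_shape[1], image_shape[0]), 0)
    xy = [(float(c), float(r)) for r, c in vertices]
    ImageDraw.Draw(img).polygon(xy, fill=1)
    return np.array(img, dtype=bool)


def load_rois(path: str | Path, image_shape: tuple[int, int] | None = None,
              background_label: int | None = None) -> ROISet:
    """Load ROIs from a label-image TIFF/PNG or a polygon JSON file.

    For label images the background ROI must carry the highest label unless
    ``background_label`` names it explicitly. Polygon JSON carries a
    ``"background"`` key and needs ``image_shape``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        if image_shape is None:
            raise ValueError("image_shape is required for polygon ROI files")
        with open(path) as fh:
            return rois_from_polygons(json.load(fh), image_shape)
    if path.suffix.lower() in {".tif", ".tiff"}:
        lab = tifffile.imread(path)
    else:
        lab = np.array(Image.open(path))
    if background_label is None:
        values = [int(v) for v in np.unique(lab) if v != 0]
        if len(values) < 2:
            raise ValueError("label image must contain at least one neuron and a background ROI")
        background_label = max(values)
    return rois_from_label_image(lab, background_label=background_label)


def extract_trace(movie: Movie, mask: np.ndarray, roi_label: int | str = 0) -> RawTrace:
    """Mean intensity over the mask pixels, per frame."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != movie.image_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match movie geometry {movie.image_shape}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty")
    values = movie.frames[:, mask].mean(axis=1)
    return RawTrace(values=values, frame_rate=movie.frame_rate, roi_label=roi_label,
                    background_corrected=False)


def background_correct(neuron: RawTrace, background: RawTrace) -> RawTrace:
    """Subtract the background-ROI trace frame-by-frame.

    Subtraction (rather than division) treats out-of-focus dye fluorescence
    as an additive offset, so event amplitudes in intensity units are
    preserved. The result may be negative; it is not clipped.
    """
    if len(neuron) != len(background):
        raise ValueError(
            f"trace length mismatch: neuron {len(neuron)} vs background {len(background)}"
        )
    if neuron.frame_rate != background.frame_rate:
        raise ValueError("frame rates differ between neuron and background traces")
    return RawTrace(
        values=neuron.values - background.values,
        frame_rate=neuron.frame_rate,
        roi_label=neuron.roi_label,
        background_corrected=True,
    )


def traces_to_frame(traces: list[RawTrace]) -> pd.DataFrame:
    """Tabulate traces as one column per ROI with a leading time_ms column."""
    if not traces:
        raise ValueError("no traces to tabulate")
    n = len(traces[0])
    if any(len(t) != n for t in traces):
        raise ValueError("traces have unequal lengths")
    out = {"time_ms": traces[0].times_ms()}
    for t in traces:
        out[f"roi_{t.roi_label}"] = t.values
    return pd.DataFrame(out)
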