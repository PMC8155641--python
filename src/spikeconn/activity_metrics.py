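"""Firing-rate, interspike-interval, and area-under-curve metrics.

Per neuron the headline numbers are the mean firing frequency (spike count
over recording duration), the interspike intervals and their reciprocals
(instantaneous frequencies), and the signed trapezoidal integral of the
polynomial-flattened ΔF/F trace. ISI distributions are summarized on a
natural-log axis, which spreads the characteristic timing bands (tens of ms
to seconds) evenly. Cohort-level helpers compute the quiescent fraction
(neurons with zero detected spikes) and normalization of any metric to a
reference condition, as used when expressing developmental time-courses
relative to the youngest cultures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_detection import BASELINE, FrameLabels, SpikeTrain

__all__ = [
    "NeuronMetrics",
    "frequency_stats",
    "isi_distribution",
    "flatten_trace",
    "auc",
    "quiescent_fraction",
    "normalize_to_reference",
]


@dataclass
class NeuronMetrics:
    """Firing metrics for one neuron."""

    neuron_id: int | str
    n_spikes: int
    mean_frequency: float          # Hz
    isis: np.ndarray               # ms
    instantaneous_frequencies: np.ndarray  # Hz, one per ISI
    auc: float | None = None       # ΔF/F·ms


def frequency_stats(train: SpikeTrain) -> NeuronMetrics:
    """Mean frequency, ISIs, and instantaneous frequencies for one train.

    Quiescent and single-spike trains are valid: the ISI list is empty and
    the mean frequency is still count/duration.
    """
    isis = np.diff(train.times)
    with np.errstate(divide="ignore"):
        inst = np.where(isis > 0, 1000.0 / isis, np.inf)
    return NeuronMetrics(
        neuron_id=train.neuron_id,
        n_spikes=train.n_spikes,
        mean_frequency=train.n_spikes / (train.duration / 1000.0),
        isis=isis,
        instantaneous_frequencies=inst,
    )


def isi_distribution(isis, bin_edges) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of ln(ISI) with counts and relative frequencies.

    ``bin_edges`` are on the ln(ms) scale. Relative frequencies sum to 1
    for nonempty input.
    """
    isis = np.asarray(isis, dtype=float)
    if np.any(isis <= 0):
        raise ValueError("ISIs must be positive for log transformation")
    counts, _ = np.histogram(np.log(isis), bins=np.asarray(bin_edges, dtype=float))
    total = counts.sum()
    rel = counts / total if total > 0 else counts.astype(float)
    return counts, rel


def flatten_trace(dff: np.ndarray, poly_order: int = 3,
                  labels: FrameLabels | None = None,
                  clip_sigma: float = 2.0, clip_iterations: int = 3) -> np.ndarray:
    """Remove slow baseline drift by polynomial subtraction.

    A least-squares polynomial of ``poly_order`` is fit to the trace and
    subtracted. Event mass must not pull the fit upward, so spike- and
    subthreshold-labeled frames are excluded when ``labels`` are supplied;
    without labels the fit is made robust by iteratively discarding points
    more than ``clip_sigma`` residual standard deviations from the current
    fit. Order 3 by default: enough curvature for photobleaching decay,
    too stiff to absorb millisecond transients.
    """
    dff = np.asarray(dff, dtype=float)
    n = len(dff)
    if n <= poly_order + 1:
        raise ValueError(f"trace length {n} too short for order-{poly_order} fit")
    x = np.arange(n, dtype=float)
    if labels is not None:
        if len(labels) != n:
            raise ValueError("labels do not match trace length")
        keep = labels.labels == BASELINE
        if keep.sum() <= poly_order + 1:
            raise ValueError("too few baseline frames for polynomial fit")
        coeffs = np.polynomial.polynomial.polyfit(x[keep], dff[keep], poly_order)
    else:
        keep = np.ones(n, dtype=bool)
        coeffs = np.polynomial.polynomial.polyfit(x, dff, poly_order)
        for _ in range(clip_iterations):
            resid = dff - np.polynomial.polynomial.polyval(x, coeffs)
            sigma = resid[keep].std()
            if sigma == 0:
                break
            keep = np.abs(resid) <= clip_sigma * sigma
            if keep.sum() <= poly_order + 1:
                break
            coeffs = np.polynomial.polynomial.polyfit(x[keep], dff[keep], poly_order)
    return dff - np.polynomial.polynomial.polyval(x, coeffs)


def auc(flattened: np.ndarray, frame_rate: float) -> float:
    """Signed trapezoidal integral of a flattened ΔF/F trace, in ΔF/F·ms."""
    flattened = np.asarray(flattened, dtype=float)
    if not np.all(np.isfinite(flattened)):
        raise ValueError("trace values must be finite")
    return float(np.trapezoid(flattened, dx=1000.0 / frame_rate))


def quiescent_fraction(trains: list[SpikeTrain]) -> float:
    """Fraction of neurons with zero detected spikes.

    Equals the Y-intercept of a cumulative firing-frequency plot.
    """
    if not trains:
        raise ValueError("quiescent fraction of an empty cohort is undefined")
    return sum(1 for t in trains if t.n_spikes == 0) / len(trains)


def normalize_to_reference(values, reference_values) -> np.ndarray:
    """Divide each value by the mean of the reference condition.

    Applied per biological replicate by the caller: each replicate's values
    are normalized against that replicate's own reference mean.
    """
    reference_values = np.asarray(reference_values, dtype=float)
    if reference_values.size == 0:
        raise ValueError("reference is empty")
    ref_mean = reference_values.mean()
    if ref_mean == 0:
        raise ValueError("reference mean is zero; normalization undefined")
    return np.asarray(values, dtype=float) / ref_mean
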