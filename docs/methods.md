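# Methods

## Scope and data model

`spikeconn` analyzes single-channel fluorescence movies of voltage-dye-
loaded neurons. The unit of analysis is the per-ROI trace: the mean
intensity over a neuron's soma mask, per frame, minus the mean trace of a
background ROI. Background correction is per-frame *subtraction*; the
out-of-focus dye signal is treated as an additive offset, so event
amplitudes in intensity units are preserved (a ratiometric correction
would rescale them). Corrected traces may go negative and are not clipped.
Frame t maps to time t·1000/frame_rate ms (frame 0 → 0 ms); the frame rate
is always a user input and never read from file metadata, which
acquisition software fills inconsistently.

## Spike detection

Detection follows a deliberately simple two-stage recipe suited to sparse,
high-SNR voltage transients.

**Stage 1 — 3-cluster k-means.** The trace's intensity values (order
ignored) are partitioned into three groups by 1-D k-means (k-means++
initialization, 10 restarts, fixed seed; clustering is per trace). Sparse
firing implies the category identification: smallest cluster → spikes,
largest → baseline, remainder → subthreshold. A size tie is broken by mean
intensity (the brighter cluster becomes the spike cluster) with a logged
warning; a constant trace is rejected as degenerate. Maximal contiguous
runs of spike-labeled frames become single events; the event peak is the
brightest frame of the run (first on ties), and runs touching either end
of the recording are kept but flagged `edge`.

**Stage 2 — SNR scoring and thresholding.** Each event's amplitude is
ΔF/F = (F_peak − F₀)/F₀ with F₀ the median of baseline-labeled frames
within ±`baseline_halfwidth_frames` (default 250 frames, i.e. ±0.5 s at
500 Hz) of the peak, falling back to the global baseline-cluster median;
the median resists occasional mislabeled bright frames. The noise floor σ
is the minimum, over all sliding windows of `noise_window_frames`
(default 100) consecutive baseline-labeled ΔF/F points, of the window's
standard deviation — the minimum finds the quietest stretch so that
transient contamination cannot inflate σ. SNR = ΔF/F ÷ σ. Events with
SNR ≥ `snr_threshold` survive; survivors' peak times form the spike train.
A train with zero survivors is a valid, quiescent neuron. Negative-going
indicators are handled by reflecting the trace about its median
(`polarity = -1`).

### Operating envelope and the default threshold

Two properties of this recipe deserve explicit statement, because they
bound where it works.

*The clustering envelope.* 1-D k-means minimizes within-cluster variance
globally, so on a trace whose values are one Gaussian noise bulk plus a
handful of bright frames, dedicating a centroid to the spikes competes
against splitting the noise bulk. The comparison is scale-invariant: it
depends only on the number of frames, the number of spike-affected frames,
and the event amplitude in units of the noise σ. For 20-second recordings
at 500 Hz (10⁴ frames) with ~1 Hz firing and 1–2 bright frames per event,
isolating the spikes wins only when events stand roughly ≥15σ above the
baseline noise. Below that, the "spike" cluster absorbs the upper noise
tail and detection relies entirely on the threshold. The synthetic
generator's default amplitude-to-noise ratio of 18 sits inside the working
envelope — it matches the mean event SNR reported for this assay on
healthy control cultures (range 16–19) — and detection there recovers
≥95% of ground-truth spikes within ±1 frame with ≤2% false positives.

*The noise estimate on quiescent cells.* When a trace contains no real
events, k-means is forced to quantize pure noise into three bands. The
baseline cluster is then the truncated middle band, whose standard
deviation is ≈0.3× the true noise σ, so the SNRs of the forced false
positives are inflated ≈3× and reach ≈14 (the largest noise excursion in
10⁴ Gaussian frames, ≈4.3σ, over the truncated floor). Genuine spikes at
the default generator conditions score ≈20–60 depending on how much of the
noise bulk the baseline cluster captures. The default
`snr_threshold = 16` sits between these populations: above the forced
false-positive ceiling on quiescent cells, below the genuine-spike floor.
This is the package's analogue of the per-coverslip threshold quality
control that the assay requires in practice, and it reproduces the
sodium-channel-blocker contract: on spike-free traces the forced false
positives all fall below threshold and zero spikes are reported.

## Firing metrics

Mean frequency is count/duration. ISIs are successive spike-time
differences (ms); instantaneous frequency is 1000/ISI (Hz). ISI
distributions are histogrammed on the natural-log axis, which spreads the
millisecond-to-second dynamic range of culture firing evenly; relative
frequencies sum to 1. The quiescent fraction of a cohort is the fraction
of trains with zero spikes — the Y-intercept of a cumulative frequency
plot. `normalize_to_reference` divides values by the mean of a reference
condition and is applied per biological replicate by the caller.

**Area under the curve.** The ΔF/F trace is flattened by subtracting a
least-squares polynomial (default order 3 — enough curvature for
photobleaching decay, too stiff to absorb millisecond transients). Spike-
and subthreshold-labeled frames are excluded from the fit so event mass
cannot bias the baseline; without labels the fit is made robust by three
rounds of 2σ residual clipping. AUC is the signed composite trapezoidal
integral over the whole trace with abscissa in ms (units ΔF/F·ms);
negative lobes subtract. On traces where the middle k-means cluster is a
genuine depolarized population, AUC captures sustained depolarization; on
near-noise traces it is a small residual of integrated noise and should be
read as ≈0.

## Spike-time tiling coefficient

For trains A, B over duration T:
STTC = ½[(P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A)], where
P_A is the proportion of A's spikes with a spike of B within ±Δt and T_A
is the proportion of [0, T] covered by the union of ±Δt windows around A's
spikes. Conventions: windows are closed (a pair exactly Δt apart counts);
tiling intervals are clipped to [0, T] and overlaps counted once, computed
exactly by merging sorted intervals; an empty train yields NaN with a
warning (no correlation is defined for a silent neuron) rather than a
fabricated zero; a vanishing denominator (P·T = 1) zeroes that term with a
warning. Default Δt = 10 ms — a 20 ms window around each spike,
appropriate for monosynaptic-scale timing in cultured networks — and
configurable, since the right Δt follows from the preparation's
cross-correlation structure. Matrices require all trains to share one
duration (mixed durations are rejected, not truncated); diagonals are 1
for nonempty trains and NaN for empty ones.

## Synthetic data

The generator provides ground truth for every stage.

*Spike trains* are homogeneous Poisson processes thinned by an absolute
refractory period (default 2 ms); at the default 1 Hz the thinning
correction is negligible. *Correlated pairs* use a common-parent
construction: parent spikes are copied into each child with probability
`p_share`, jittered by centered Gaussian noise, and topped up with
independent Poisson spikes — the minimal model with one correlation knob,
which the tiling coefficient should track monotonically.

*Traces* are rendered as
f0 · bleach(t) · artifact(t) · (1 + a·Σ kernels) + noise, with a linear
rise over `rise_frames` (default 1 frame) and exponential decay
(`decay_tau`, default 2 ms — an action-potential-shaped transient at
500 Hz, spanning 1–3 frames). The amplitude enters multiplicatively, so an
event's ΔF/F is invariant to photobleaching — which is exactly why ΔF/F is
the working scale. Defaults: f0 = 100, amplitude ΔF/F = 0.1, noise
σ = 0.55 intensity units (event SNR 18, the assay's reported operating
point), bleach 0.1%/s (a photostable far-red dye; healthy analyzable cells
show near-flat baselines). Optional artifacts emulate unhealthy-cell
baselines: a +20% step at the midpoint, or a 1 Hz sinusoidal oscillation.
An optional subthreshold-event population (`sub_rate`, off by default)
adds slower, smaller transients for exercising the three-cluster
semantics. *Movies* paint each trace onto a disjoint disk over a flat
background, with the matching masks and a background mask in a disk-free
corner, so extraction round-trips exactly at zero noise.

What the generator does **not** emulate: correlated or non-Gaussian noise,
slow focus drift and motion, dye internalization, heterogeneous per-pixel
loading, overlapping neurites, or mechanistic synaptic coupling
(correlation is statistical, not conductance-based). Passing tests
therefore demonstrate the algorithmic contracts — clustering, scoring,
thresholding, tiling arithmetic — under idealized recording statistics,
not performance on degraded real-world optics.

## Numerical and design choices

- k-means: scikit-learn, k-means++, `n_init=10`, fixed `random_state`;
  deterministic given the seed.
- Noise windows slide over the subsequence of baseline-labeled ΔF/F points
  (stride 1); at least `noise_window_frames` baseline frames are required.
- Polynomial fits use `numpy.polynomial` least squares on the frame index.
- Trapezoidal integration via `numpy.trapezoid` with dx = 1000/frame_rate.
- Degenerate inputs fail loudly: constant traces, empty masks, mixed
  durations, non-positive baseline fluorescence (background
  over-subtraction), and unscored events are all rejected with specific
  errors; empty spike trains are *valid* and flow through metrics as
  quiescent neurons.
- Determinism: one `kmeans_seed` in the run config covers all stochastic
  steps of analysis; generator outputs are pure functions of their seeds.
  The same configuration and seed reproduce byte-identical CSVs.

## Problem sizes

The test suite and examples run at the package's native scale: 20-second,
500 Hz traces (10⁴ frames), 64×64-pixel movies with up to a handful of
neurons, 100-seed ensembles for the statistical contracts (rate
independence and monotonicity of the tiling coefficient), 20-seed
ensembles for detection recovery, and 200 random pairs for oracle
equivalence. Pipeline determinism uses 6-second movies to keep I/O small.

## Known limitations

- Detection assumes sparse firing; sustained high-rate firing (spike
  frames rivaling baseline frames) breaks the smallest-cluster heuristic.
- Events below ≈15× the baseline noise are outside the clustering
  envelope on 20-s traces (see above); the detector does not degrade
  gracefully there but floods with threshold-rejected candidates.
- Strong baseline drift (≫ event amplitude within a recording) drives
  k-means to cluster by time rather than by signal level; such traces are
  the "unhealthy" regime and should be excluded upstream, as the assay
  itself prescribes.
- The SNR scale is internal: on quiescent cells the truncated baseline
  cluster inflates SNRs ≈3× relative to the true noise σ, so thresholds
  are comparable within, not across, clustering regimes.
- AUC is interpretable only when the subthreshold cluster reflects genuine
  depolarization.
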