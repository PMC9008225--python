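# Methods

This note documents the models, numerical choices, and open design
decisions behind `holomea`, module by module, including what the
synthetic-data generator does and does not emulate.

## Synthetic networks and recordings

### Network model

`generate_network` samples an Erdős–Rényi-style directed graph: each
ordered neuron pair becomes an edge with probability `density`, so the
expected edge count is `density · n · (n − 1)`. Edge weights are synaptic
transmission probabilities in [0, 1]; delays are uniform in a
configurable range (default 2–10 ms, covering axonal conduction plus
synaptic latency at culture scale). Neuron positions are uniform over the
electrode bounding box — appropriate for dissociated, randomly plated
cultures — with a clustered option for aggregated ones. Note that the
branching ratio of cascades is roughly
`density · (n − 1) · mean_weight`; above ~1 the simulated network is
supercritical and sustains near-saturated reverberation limited only by
the refractory period. The defaults (n = 30, density = 0.05, weights
0.3–1.0) sit near criticality, which is the bursty regime mature cultures
actually occupy; tests that need clean parameter recovery use sparser or
two-layer graphs.

### Event-driven simulation

`simulate_recording` merges three event sources and propagates them
through the graph in time order:

* **Spontaneous firing**: per-neuron homogeneous Poisson at
  `spont_rate_hz` (default 0.5 Hz per neuron, which puts per-electrode
  rates near the ~0.8 Hz measured for active electrodes in mature
  cultures of this kind).
* **Network bursts**: burst events arrive as a Poisson process at
  `burst_rate_hz` (default 0.04 Hz, matching the baseline burst
  frequency reported for these cultures). Each participating neuron
  (probability 0.8) fires ~8 spikes with ~6 ms exponential intra-burst
  intervals after a ~10 ms onset jitter, producing the synchronized
  population events that baseline-connectivity measures rely on.
* **Direct photostimulation**: during each light pulse the targeted
  opsin-positive neuron spikes with probability `chr2_spike_prob`
  (default 0.9) at latency `direct_latency_ms ± direct_jitter_ms`
  (default 8 ± 2 ms). The direct latency is a free parameter of the
  simulator, not a biological claim: the recorded peak delay of a real
  preparation mixes channel kinetics, intensity, and pickup geometry.

Every accepted spike propagates along outgoing edges with the edge's
probability and delay (single hop per edge; multi-hop chains arise
through the graph). A 2 ms absolute refractory period per neuron bounds
recurrent cascades; this is a biophysical floor and also what keeps the
event simulation finite in supercritical graphs. The blockade switch
suppresses all synaptic propagation, emulating AMPA/NMDA receptor
blockade (NBQX/APV): only direct photoresponses and spontaneous source
events remain.

### Extracellular rendering

Each spike inserts a fixed 2-ms biphasic template (sharp negative lobe at
0.55 ms, slower positive rebound) on every electrode within
`attenuation_radius_um` (default 60 µm), scaled by the neuron's amplitude
(150–250 µV at the soma) and the smooth monotone attenuation
`1/(1 + (d/d₀)²)` with d₀ = 20 µm. With the default 3 µV noise SD this
makes a 200 µV unit cross the 5σ detection threshold out to roughly
60–70 µm and renders sub-30-µm units dominant — the radius inside which
direct pickup is observed on real arrays. The pickup radius doubles as
the recoverability criterion in ground-truth comparisons. Per-unit
amplitude differences are what the template-matching unit assigner
separates.

**What the generator does not emulate**: biophysical membrane dynamics
(no Hodgkin–Huxley/LIF), electrode impedance spectra and 1/f noise,
waveform drift and overlap-induced sorting errors, short-term synaptic
plasticity, photocurrent desensitization, and astrocyte or media effects.
Passing recovery tests therefore demonstrate the correctness of the
analysis chain under the stated statistical assumptions, not robustness
to every artifact of real recordings.

### Session maturation

`maturation_scales` provides per-session multipliers (sigmoid by default,
~0.1 → ~1.8) applied to spontaneous and burst rates via
`SimConfig.for_session`, emulating the rise of activity over weeks in
culture, with a linear alternative.

## Spike processing

* **Filtering** is zero-phase (forward–backward `sosfiltfilt`) with a
  2nd-order Butterworth high-pass at 100 Hz, so detected timestamps are
  not skewed by group delay — important for latency analysis. A causal
  single-pass option exists (`zero_phase=False`).
* **Noise estimate**: σ̂ = median(|x|)/0.6745 per channel, the standard
  spike-insensitive robust estimator; thresholds at ±5σ̂ are applied to
  the filtered signal. Silent channels get a tiny σ̂ floor and yield
  empty trains rather than errors.
* **Debounce**: supra-threshold samples closer than 1 ms collapse to one
  event timestamped at the largest-|amplitude| sample (one action
  potential, one event).
* **Unit assignment** is nearest-template by least-squares distance on
  peak-aligned 2-ms snippets, with an optional residual cut-off that
  flags unassignable events. This is deliberately minimal plumbing: it
  stands in for a full wavelet/superparamagnetic spike sorter, which is
  out of scope, and is exact when templates come from simulator ground
  truth.
* **Bursts** use the max-interval algorithm (≤ 20 ms interval to open,
  ≤ 10 ms to extend, merge below 10 ms inter-burst interval, keep ≥ 4
  spikes and ≥ 20 ms). A brute-force candidate-window oracle in the test
  suite pins the exact semantics, including edge cases (a burst may open
  with an interval in (10, 20] ms that could not extend one).
* **Active-electrode selection** keeps electrodes exceeding 0.2 Hz in at
  least two sessions and zeroes their sub-threshold sessions, so
  development can be tracked on a fixed electrode set.

## PSTH

The per-episode PSTH uses 40-µs bins over a 75-ms post-onset window,
convolved with the unnormalized Gaussian `exp(−½(t/σ)²)`, σ = 1.5 ms
(the kernel's "width" of 3 ms is read as 2σ), and divided by the pulse
count M. Because the kernel peaks at 1, a response locked to every pulse
peaks at amplitude 1 and a single spike at 1/M; the curve's integral is
N·σ·√(2π)/M, which the tests verify to 1 %. The kernel is truncated at
±5σ and edge bins keep only the kernel mass inside the window (no
renormalization) — the plain-convolution reading. A curve is `valid` only
when it pools more than 20 spikes; validity is applied uniformly to
amplitude and latency analysis. Peak latency ties break to the earliest
bin.

Distances from stimulation site to electrode default to the
**edge convention** — Euclidean centre distance minus the electrode
radius, clipped at zero — with a centre-convention switch, since both
conventions are in common use; categories are
{30, 60, 100, 200, 500, 1000} µm and larger distances are flagged out of
range. The coarse peri-event histogram (3-ms bins, 200 or 500 ms span)
tolerates a truncated final bin because neither span is a multiple of
3 ms.

## Baseline connectivity (spectral entropy)

Segments are 250 ms with 80 % overlap (50 ms hop; a 60-s recording gives
~1200 segments). The spectrum is the one-sided periodogram of the raw
(untapered) segment — a Hann taper is available but off by default, and
segments are not detrended (the 100-Hz high-pass already removes trends).
The entropy normalization divides by log(N) with N the **samples per
segment**, although only N/2 + 1 one-sided bins exist; this is
implemented literally for fidelity, so the attainable maximum is
log(n_bins)/log(N) ≈ 0.92 rather than 1. A `normalization="n_bins"`
switch gives the information-theoretically exact bound. All-zero
segments have undefined entropy and propagate as NaN, which the
correlation step drops pairwise.

Channel eligibility requires at least one sample beyond 6σ̂ — a separate,
stricter rule than the 5σ̂ detection threshold, meant to exclude inactive
electrodes from the map. The correlation is the textbook lag-0 Pearson
coefficient of the two entropy series; the surrogate null permutes the
segment order of one series. With O segments the null SD is ≈ 1/√O, so
the documented < 0.05 surrogate bound is comfortably met for recordings
of a few minutes; edge display threshold defaults to 0.1 with the
0.05–0.25 sweep supported.

## Stimulation connectivity

The displaced-impulses construction is cited rather than defined in the
source literature, so this package fixes an explicit interpretation,
flagged here prominently: the **DIF is the empirical distribution of
spike latencies relative to pulse onsets within one inter-pulse
interval**, and the baseline DIF applies the same windowing to an
equal-length span of unstimulated recording of the same unit. This
reproduces every property the method requires: stimulated-vs-unstimulated
comparison, leave-one-stimulus-out replication, and the all-zero
fallback distribution for units silent at baseline.

Validation runs N_stim two-sample KS tests (SciPy's exact/asymptotic
auto switch), each excluding the spikes of one stimulus event, and
accepts only if **all** tests reject at P < 0.01 — the original
robustness device against single spontaneous bursts, applied without
multiple-testing correction, as in the source procedure. A literal KS
against a constant-zero CDF is ill-posed, so the silent-baseline branch
rejects when the leave-one-out subset carries at least 3 spikes (the
minimum-spike guard prevents single-spike artifacts).

Two statistical limitations are worth knowing:

* With **short baselines**, a bursty unit's baseline latency sample is a
  handful of dependent clumps rather than iid draws; the KS null is then
  anti-conservative and false validations rise (the leave-one-out
  battery only protects against bursts on the stimulated side). The
  package's recovery studies therefore use a 300-s baseline span —
  minutes of baseline per session, which is also what real protocols
  record. Users analysing shorter baselines should treat isolated
  validations of bursty units with suspicion.
* The **connection strength** (maximum cross-correlation between the
  50-ms boxcar train S centred 25 ms after each onset and the spikes E
  smoothed with a σ = 1.5 ms Gaussian, on a 1-ms grid with lags bounded
  by ± one inter-pulse interval) systematically underestimates strong
  connections because the S–E overlap is small; no correction is
  attempted. Because the lag search spans the full pulse period, the
  measure is sensitive to response magnitude, not phase.

Electrode–electrode conversion: per episode, the set K of electrodes
carrying at least one valid connection increments every unordered pair in
K by one — one increment per pair per episode regardless of how many
units on an electrode responded (the natural reading when several units
co-occur). The matrix is divided by the stimulation experiment duration,
and `normalize_across_days` rescales a multi-session series by its common
maximum. Per-electrode connection counts can additionally be normalized
by the number of stimulated neurons.

## Holography

Holograms superpose laterally shifted Fresnel zone plates
`exp(iπ r²/(λ f))`; a sample target (x, y) maps to an SLM-plane centre at
(x, y)/β, and one SLM pixel demagnifies to β·Δr ≈ 1.14 µm at the sample.
An aliasing guard rejects focal distances whose adjacent-pixel phase step
exceeds π. Binarization to the ferroelectric modulator's two phase levels
{0, π} is by sign thresholding of the real part or by **bidirectional
error diffusion**: Floyd–Steinberg weights on the complex unit phasors
with serpentine (alternating) row scans, which pushes quantization noise
out of the first diffraction order and improves focus-to-background for
multi-target holograms.

The verification oracle is a band-limited angular-spectrum propagator on
a 2× zero-padded grid (padding suppresses wrap-around; the band limit
suppresses transfer-function aliasing at long distances). Within the
propagating band the transfer is unitary, which the tests check via
Parseval. Oracle-based tests run on a reduced 256×256 modulator with the
production pixel pitch and wavelength — the physics is scale-free in the
pixel count — at f = 100 mm, above that grid's aliasing bound; they
verify focus placement within one demagnified pixel for randomly drawn
targets under both binarization methods.

`min_focus_distance` evaluates β·N·Δr²/(2λ) with N the shorter SLM side
(1536), giving ≈ 15.9 mm for the production constants. Published
descriptions of comparable systems quote ≈ 6.4 mm together with a working
distance of 6.4 + 25 = 31.4 mm; the two numbers are mutually inconsistent
with the stated expression, and this package implements the expression as
stated while `working_distance` reproduces the published sum from its
printed inputs. Focus fitting is a least-squares 2-D Gaussian
(FWHM = 2√(2 ln 2)·σ, 1/e² full width = 4σ); sample→SLM calibration is an
exact-degree 2nd-order polynomial fit (≥ 6 non-degenerate pairs);
image↔image grid registration is a least-squares affine transform
(rotation, shift, linear scaling; ≥ 3 matched centroids).

## Workflow and reproducibility

`RunConfig` serializes one run completely; a single master seed derives
per-stage seeds through `numpy.random.SeedSequence.spawn`, so any run is
bit-reproducible (the determinism test compares summary bytes). The
event-driven simulator breaks heap ties by insertion order, which makes
its output independent of floating-point tie accidents. Stage toggles
allow spike-table-level analysis without waveform rendering
(`render=False`), which the recovery studies use to isolate the
statistics from the detection front end; the rendered path is exercised
by a separate end-to-end test.

## Problem sizes used in the verification suite

The shipped studies are desk-scale by design: recovery studies use
12-episode protocols (20 pulses each) over 40-neuron networks with 300-s
baselines at the spike-table level, plus a rendered 12-neuron end-to-end
run on a 4×4 array; the surrogate-null study renders 300 s of six-channel
25-kHz signal (~6000 entropy segments per channel); the hologram
placement study propagates 100 single-target holograms on the reduced
grid. These sizes give comfortable statistical margins for every asserted
bound while keeping the whole suite at around a minute of compute.
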