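# Methods

This note documents the scientific model behind `capheno`, the parameter
choices and their rationale, what the synthetic generator does and does not
emulate, and the main numerical decisions.

## 1. Imaging model

We target wide-field calcium imaging of neuronal cultures: a camera with
960 × 720 pixels at 4.40 μm/pixel (field of view 4.224 × 3.168 mm, i.e.
roughly 4.2 × 3.2 mm), acquiring at 20 frames/s for 10-minute recordings.
Each neuron's signal is the mean of a fixed 7 × 7-pixel square region of
interest (ROI) centered on its soma.

A single somatic action potential produces a calcium transient modelled as
an instantaneous-onset single exponential,

    ΔF/F0(t) = A · exp(-(t - t_spike)/τ),

with amplitude **A = 2% ΔF/F0** and decay constant **τ = 1 s**, values
typical of high-affinity chemical indicators (e.g. Fluo-4) in cultured
neurons at room temperature. Transients superpose linearly; indicator
saturation, dye bleaching kinetics and spike-history-dependent amplitudes
are *not* modelled (see §7).

## 2. Trace processing

Given a raw ROI trace F(t):

1. **Smoothing.** A centered 5-frame moving average (250 ms at 20 FPS),
   with symmetric shrunken windows at the edges so the output has the same
   length and no phase shift. 250 ms is short relative to τ = 1 s, so
   transient amplitudes are attenuated only slightly, while the
   frame-to-frame noise SD drops by √5.
2. **Drift correction.** Slow drift (bleaching, focus, lamp) is estimated
   by a natural cubic spline through knots at the centers of consecutive
   25-s blocks, each knot at the block mean. The spline is subtracted and
   its mean added back, so the corrected trace keeps the input's mean
   exactly. The 25-s block is long relative to both τ and the longest
   bursts, so the spline cannot track (and hence cannot remove) real
   transients; the acceptance suite verifies transient amplitudes are
   preserved within 5% and the mean within 0.5% under ramp and sinusoid
   drift.
3. **Baseline and normalization.** F0 is the 10th percentile of the
   corrected trace — robust to transients occupying up to ~90% of frames —
   and the normalized trace is ΔF/F0 = 100 · (F − F0)/F0 in percent.
   Non-positive baselines are rejected as degenerate.

When starting from a movie, somata are detected as local intensity maxima
above a threshold with a minimum mutual separation (default 7 px, one ROI
width), brightest first.

## 3. Activity screen

Dense cultures contain many ROIs with no discernible activity. A boosted
decision-stump classifier (AdaBoost, 50 rounds, depth-1 trees) assigns
*active*/*inactive* from five trace-shape features: fraction of frames
above a high-activity threshold, the number and mean duration of
supra-threshold intervals, and the trace maximum and SD. The default
threshold is 2 × the robust noise SD (1.4826 × median absolute deviation)
of each trace. The classifier is trained on a small hand-labeled subset
(the pipeline emulates this with 100 labeled traces per class drawn from
the generator's ground truth) and applied to the full population. Ties
(zero vote margin) resolve to *active* so that borderline neurons are
inspected rather than silently dropped.

## 4. Spike inference: peeling

Spike times are recovered from ΔF/F0 by iterative template subtraction:

1. A Schmitt trigger scans the residual with a high threshold of
   **0.8% ΔF/F0** and a low (release) threshold of half that. An *event* is
   a maximal run of samples above the low threshold lasting at least
   2 frames and containing at least one sample at or above the high
   threshold; the spike onset is the run's first sample at or above the
   high threshold.
2. One template (A = 2%, τ = 1 s) is subtracted at the earliest event's
   onset, and the scan resumes from the start of that run.
3. When the forward scan finds nothing, one confirmation pass over the full
   residual guards against events reshaped by earlier subtractions; the
   algorithm stops when that pass is clean.

Events are peeled strictly earliest-first. This matters under noise: a
single transient whose decay dips briefly below the release threshold looks
like several short runs, and subtracting a template at each of them in one
sweep would register several spurious spikes. Peeling one event and
rescanning lets the first subtraction absorb the entire transient.

The 0.8% threshold is 40% of the single-spike amplitude and 6.4 robust SDs
above the typical noise floor (0.5 a.u. on a baseline of 100 a.u. →
0.5% ΔF/F0 before smoothing, ~0.22% after), which yields a hit rate ≥ 0.9
(measured ≈ 1.0) and < 0.1 false positives per 10 s at noise
SD = amplitude/8. Templates are truncated where they fall below 10⁻⁹ of
the amplitude (~21 τ), keeping the round-trip residual below 10⁻⁶ while
bounding per-event cost. On noiseless frame-aligned input, every spike with
amplitude ≥ 0.8% and ISI > 2 frames is recovered within ±1 frame.

## 5. Burst and firing features

A **burst** is a maximal run of ≥ 2 consecutive spikes whose gaps are all
strictly below 1 s. Nine features per neuron:

| feature | definition |
|---|---|
| `n_spikes` | spike count over the recording |
| `firing_rate_hz` | spike count / duration |
| `isi_mean_s`, `isi_sd_s` | mean and SD (n−1 denominator) of *all* inter-spike intervals |
| `n_bursts` | burst count |
| `spikes_per_burst` | mean spikes per burst |
| `isi_in_burst_s` | mean ISI within bursts |
| `ibi_s` | mean interval between consecutive burst starts |
| `burst_length_s` | mean burst duration (first to last spike) |

Undefined values (e.g. the IBI of a neuron with fewer than two bursts) are
NaN and are excluded per feature from group summaries; the group SEM is
SD/√n with the n−1 SD, so a printed SD of 0.6 with n = 4 corresponds to an
SEM of 0.3.

## 6. Phenotype clustering

The feature matrix is median-imputed (per feature), z-scored, and projected
with PCA (full SVD; the sign of each component is fixed by making its
largest-magnitude loading positive, so results are machine-independent).
k-means with k = 8 and 50 seeded restarts clusters the scores; k = 8 is a
fixed design choice, overridable in the config. Per-feature contributions
to a component are its squared loadings normalized to 100%.

Each group is then mapped to a firing class from its median burst count B
and median IBI, checked in this order:

- **HF** (high-firing): B ≥ 40 bursts per 10-min recording or IBI ≤ 16 s;
- **LF** (low-firing): B ≤ 7 or IBI > 40 s;
- **IF** (intermediate): otherwise.

A group that never bursts (median B = 0, no defined IBI) falls back to
population spike-count tertiles. Class fractions are reported over all
clustered neurons.

## 7. Synthetic generator

The generator is the package's ground-truth instrument. Per neuron it
draws a spike train — a homogeneous Poisson background plus a
Poisson-distributed number of bursts at uniform onsets, each with
2 + Poisson(mean − 2) spikes and truncated-exponential intra-burst ISIs —
renders the trace as baseline (100 a.u.) + superposed templates +
deterministic drift (2 · sin(2πt/300 s) + 0.002 t, a ~2% slow wobble plus
bleaching-scale ramp) + Gaussian noise (SD 0.5 a.u.), and optionally paints
Gaussian somata into a movie whose 7 × 7 ROI mean equals the trace exactly.

Default phenotype specifications (10-min recordings):

| class | background (Hz) | bursts/recording | spikes/burst | intra-burst ISI (s) |
|---|---|---|---|---|
| low | 0.02 | 4 | 2.2 | 0.6 |
| intermediate | 0.05 | 16 | 2.5 | 0.5 |
| high | 0.05 | 50 | 3.5 | 0.3 |
| inactive | 0 | 0 | — | — |

These place the class medians inside the LF/IF/HF decision regions of §6
with margin (e.g. the intermediate IBI is ≈ 37 s, between the 16-s HF and
40-s LF boundaries), so end-to-end mixture recovery is a meaningful test
rather than a tautology. The generator emulates transient kinetics, drift,
shot-like noise and soma appearance; it does **not** emulate indicator
saturation, network-correlated activity between neurons, overlapping
somata, motion artifacts, or non-Gaussian camera noise.

## 8. Reproducibility and numerics

- All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawns (per stage and per neuron); derived
  seeds are reduced below 2³¹. Rerunning a pipeline with the same seed
  reproduces every artifact byte for byte, verified by SHA-256 checksums in
  the run manifest.
- Exponential templates and forward renders are computed with an AR(1)
  recursion (`scipy.signal.lfilter`), which is exact for sampled
  exponential sums and O(n).
- Configs are strictly validated (pydantic, unknown keys rejected, every
  parameter range-checked) before any stage runs; errors name the offending
  key path.
- Problem sizes in the tests and acceptance script (hundreds to 1000
  neurons, 3–20 seeds) are the package's own choices, sized to give tight
  Monte-Carlo bounds in minutes on one CPU.

## 9. Limitations

- Spike inference assumes known, fixed A and τ; amplitude heterogeneity
  across neurons degrades timing and count accuracy and is not fitted.
- Coincident spikes within one frame are resolved only as stacked
  templates; the peeler recovers their count, not sub-frame timing.
- The LF/IF/HF thresholds are fixed design constants; other preparations
  (different indicators, temperatures, ages) will need different values.
- k = 8 is not selected by any model criterion.
- The screen's emulated curation samples labels from generator ground
  truth; with real data the labeled subset comes from human annotation and
  its quality bounds the screen's.
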