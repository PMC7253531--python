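# capheno

Firing-phenotype analysis of calcium-imaging recordings from neuronal
cultures — with a matched synthetic-data generator, so the whole pipeline is
testable end to end without any microscope.

Cultured neurons loaded with a calcium indicator report action potentials as
fluorescence transients. `capheno` turns wide-field movies (or per-soma
traces) into a phenotype map of the culture:

1. **Trace processing** — extract per-soma traces from a movie (fixed-size
   square ROIs over detected somata), smooth with a 5-frame moving average,
   remove slow drift with a block-wise cubic spline, and normalize to
   % ΔF/F0 against a 10th-percentile baseline.
2. **Activity screen** — an AdaBoost decision-stump classifier, trained on a
   small hand-labeled subset, splits neurons into *active* and *inactive*
   from five trace-shape features.
3. **Spike inference** — a peeling algorithm with a Schmitt trigger
   (0.8% ΔF/F0 detection threshold) iteratively subtracts single-exponential
   transient templates (amplitude 2% ΔF/F0, τ = 1 s) to recover spike times.
4. **Burst & firing features** — nine per-neuron features: spike count,
   firing rate, ISI mean/SD, burst count, spikes per burst, within-burst
   ISI, inter-burst interval (IBI) and burst length. A burst is ≥ 2
   consecutive spikes with gaps < 1 s.
5. **Phenotype clustering** — median-impute, z-score, PCA, k-means (k = 8,
   50 restarts), then map each group to a low / intermediate / high firing
   class (LF/IF/HF) from its median burst count and IBI.

The model of a spike is an instantaneous-onset exponential transient

```
ΔF/F0(t) = A · exp(-(t - t_spike)/τ),   A = 2%  τ = 1 s,
```

and a trace is the linear superposition of one template per spike, plus
baseline, drift and Gaussian noise. The synthetic generator produces spike
trains (Poisson background + Poisson-distributed bursts), traces and movies
under exactly this model, so every stage can be validated by parameter
recovery.

## Worked example

Simulate a 120-neuron active population (10-minute recordings at 20 FPS)
and run the full in-memory analysis — processing, peeling, features,
clustering and class mapping:

```python
import numpy as np
from capheno import synthetic_data as sd
from capheno.pipeline import analyze_population

pop = sd.make_population(
    {"low": 72, "intermediate": 38, "high": 10}, seed=42
)
features, report = analyze_population(pop.traces, k=8, seed=42)

print(features[["n_spikes", "firing_rate_hz", "n_bursts", "ibi_s"]].describe().round(2))
print()
for cls, frac in report.class_fractions.items():
    print(f"{cls}: {100 * frac:.1f}%")
```

Output (runs in a few seconds):

```
       n_spikes  firing_rate_hz  n_bursts   ibi_s
count    120.00          120.00    120.00  119.00
mean     117.32            0.20     15.10   65.22
std       65.56            0.11     14.08   48.15
min       58.00            0.10      1.00    9.00
25%       76.75            0.13      5.00   26.38
50%       89.50            0.15      8.50   54.79
75%      137.50            0.23     22.00   92.43
max      356.00            0.59     62.00  284.02

LF: 60.8%
IF: 31.7%
HF: 7.5%
```

The recovered class fractions match the generating mixture (60 / 31.7 / 8.3%
of low / intermediate / high neurons) to within about one percentage point.

## Command line

The `capheno` command runs the six file-based pipeline stages
(`simulate → process → screen → infer → features → cluster`), individually
or all at once, from an optional YAML config:

```
$ cat demo.yaml
geometry:
  duration_s: 300.0
simulate:
  class_counts: {low: 30, intermediate: 16, high: 4, inactive: 10}
screen:
  n_labeled_per_class: 10

$ capheno run-all --config demo.yaml --seed 7 --outdir demo_out
done: simulate, process, screen, infer, features, cluster → demo_out
```

`demo_out/` then contains `raw_traces.csv`, `normalized_traces.csv`,
`screen_model.json`, `screen_assignments.csv`, `spikes.csv`,
`features.csv`, `report.json`, `cluster_assignments.csv` and a
`run_manifest.json` with SHA-256 checksums of every artifact. Rerunning
with the same seed reproduces every file byte for byte. Omitting
`--config` uses the built-in defaults (a 200-neuron, 84%-active
population); any subset of keys may be overridden, and invalid or unknown
keys are rejected with the offending key path.

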