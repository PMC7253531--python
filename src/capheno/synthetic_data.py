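"""Synthetic recordings with the statistical structure the analysis assumes.

Generates ground-truth spike trains, fluorescence traces and small movies so
every downstream stage (trace processing, screening, peeling, feature
extraction, clustering) is testable without any recording on disk.

Spike trains mix a homogeneous Poisson background with Poisson-distributed
burst episodes; a burst holds ≥ 2 spikes whose internal intervals are
exponential, truncated below 1 s so they satisfy the downstream burst rule.
Three firing phenotypes (low / intermediate / high, plus an inactive class)
are parameterized to the group statistics observed in stem-cell-derived
neuronal cultures: low-firing neurons show ~1–7 bursts per 10-min recording
with inter-burst intervals above 40 s, intermediate ones 7–17 bursts, and
high-firing neurons 40–60 bursts with a typical IBI of 10–16 s.

Fluorescence is the inverse of the inference model: each spike adds a
single-exponential transient (amplitude in % ΔF/F0, τ = 1 s) on a baseline,
plus slow additive drift and white Gaussian noise:

    F*(t) = baseline · (1 + (A/100) · Σᵢ e^{−(t−tᵢ)/τ} · 1[t ≥ tᵢ]) + drift(t) + ε(t)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ParameterError, PlacementError
from .spike_inference import SpikeTrain
from .trace_processing import MovieStack, RawTrace

__all__ = [
    "PhenotypeSpec",
    "TransientModel",
    "AcquisitionGeometry",
    "LabeledPopulation",
    "DEFAULT_SPECS",
    "DEFAULT_MODEL",
    "DEFAULT_GEOMETRY",
    "default_drift",
    "simulate_spike_train",
    "render_fluorescence",
    "render_movie",
    "make_population",
    "write_spikes_csv",
    "write_labels_csv",
]

CLASS_NAMES = ("low", "intermediate", "high", "inactive")


@dataclass(frozen=True)
class PhenotypeSpec:
    """Firing-phenotype parameters for one simulated neuron class.

    ``background_rate`` is the Poisson rate of isolated spikes (Hz);
    ``burst_rate`` the expected number of burst episodes per recording;
    ``spikes_per_burst_mean`` the mean burst size (≥ 2 realized);
    ``intra_burst_isi`` the mean within-burst interval (s, truncated < 1 s);
    ``duration`` the recording length in seconds.
    """

    name: str
    background_rate: float = 0.0
    burst_rate: float = 0.0
    spikes_per_burst_mean: float = 2.0
    intra_burst_isi: float = 0.5
    duration: float = 600.0

    def __post_init__(self) -> None:
        if self.name not in CLASS_NAMES:
            raise ParameterError(f"unknown phenotype name {self.name!r}")
        if min(self.background_rate, self.burst_rate, self.spikes_per_burst_mean) < 0:
            raise ParameterError("rates and counts must be non-negative")
        if self.intra_burst_isi < 0:
            raise ParameterError("intra_burst_isi must be non-negative")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.name == "inactive" and (self.background_rate > 0 or self.burst_rate > 0):
            raise ParameterError("the inactive phenotype must have zero rates")


@dataclass(frozen=True)
class TransientModel:
    """Single-spike calcium transient: amplitude (% ΔF/F0), decay τ (s), and
    the detection threshold (% ΔF/F0) used by the peeling stage."""

    amplitude: float = 2.0
    tau: float = 1.0
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.tau <= 0 or self.threshold <= 0:
            raise ParameterError("amplitude, tau and threshold must be positive")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Camera geometry: fps, frame shape (h, w), µm/px, ROI side, duration (s)."""

    fps: float = 20.0
    frame_shape: tuple[int, int] = (720, 960)
    um_per_px: float = 4.40
    roi_size_px: int = 7
    duration: float = 600.0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration <= 0:
            raise ParameterError("fps and duration must be positive")
        if self.roi_size_px < 1 or self.roi_size_px % 2 == 0:
            raise ParameterError("roi_size_px must be odd and >= 1")
        if min(self.frame_shape) < 1:
            raise ParameterError("frame_shape must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


# Study conditions: a 10-min recording at 20 FPS.  Rates anchor each class to
# the observed group ranges (bursts per recording and inter-burst intervals).
DEFAULT_SPECS: dict[str, PhenotypeSpec] = {
    "low": PhenotypeSpec(
        name="low", background_rate=0.02, burst_rate=4.0,
        spikes_per_burst_mean=2.2, intra_burst_isi=0.6,
    ),
    "intermediate": PhenotypeSpec(
        name="intermediate", background_rate=0.05, burst_rate=16.0,
        spikes_per_burst_mean=2.5, intra_burst_isi=0.5,
    ),
    "high": PhenotypeSpec(
        name="high", background_rate=0.05, burst_rate=50.0,
        spikes_per_burst_mean=3.5, intra_burst_isi=0.3,
    ),
    "inactive": PhenotypeSpec(name="inactive"),
}

DEFAULT_MODEL = TransientModel()
DEFAULT_GEOMETRY = AcquisitionGeometry()

#: Default raw-fluorescence conditions (camera units).
DEFAULT_BASELINE = 100.0
DEFAULT_NOISE_SD = 0.5


def default_drift(amplitude: float = 2.0, period_s: float = 300.0, slope_per_s: float = 0.002):
    """Slow additive drift: a sinusoid (period ≥ 100 s) plus a mild ramp.

    Emulates photobleaching and focus drift at a scale (~2% of a 100 a.u.
    baseline) the 25-s block spline removes.
    """
    def drift(t):
        t = np.asarray(t, dtype=float)
        return amplitude * np.sin(2 * np.pi * t / period_s) + slope_per_s * t

    return drift


def simulate_spike_train(spec: PhenotypeSpec, seed: int) -> SpikeTrain:
    """Draw one ground-truth spike train for a phenotype.

    Background spikes are homogeneous Poisson; burst onsets are Poisson with
    ``burst_rate`` expected episodes per recording; burst sizes are
    ``2 + Poisson(mean − 2)``; within-burst intervals are exponential with the
    given mean, truncated below 1 s.  Spikes beyond the recording are dropped;
    identical seeds give bit-identical trains.
    """
    rng = np.random.default_rng(seed)
    d = spec.duration
    times = []

    n_bg = rng.poisson(spec.background_rate * d)
    times.append(rng.uniform(0.0, d, size=n_bg))

    n_bursts = rng.poisson(spec.burst_rate)
    onsets = rng.uniform(0.0, d, size=n_bursts)
    extra_mean = max(spec.spikes_per_burst_mean - 2.0, 0.0)
    scale = spec.intra_burst_isi
    # inverse-CDF sample of Exp(scale) truncated to (0, 1):
    trunc = -np.expm1(-1.0 / scale) if scale > 0 else 1.0
    for onset in onsets:
        n_spk = 2 + rng.poisson(extra_mean)
        if scale > 0:
            u = rng.uniform(size=n_spk - 1)
            isis = -scale * np.log1p(-u * trunc)
        else:
            isis = np.zeros(n_spk - 1)
        burst = onset + np.concatenate(([0.0], np.cumsum(isis)))
        times.append(burst)

    t = np.sort(np.concatenate(times)) if times else np.empty(0)
    t = t[t < d]
    return SpikeTrain(times=t, duration=d)


def render_fluorescence(
    spikes: SpikeTrain,
    model: TransientModel = DEFAULT_MODEL,
    geometry: AcquisitionGeometry = DEFAULT_GEOMETRY,
    baseline: float = DEFAULT_BASELINE,
    noise_sd: float = 0.0,
    drift=None,
    seed: int = 0,
) -> RawTrace:
    """Forward-model a raw fluorescence trace from a spike train.

    Transients superpose linearly; the exponential sum is evaluated exactly at
    the frame times via a first-order recursion.  ``drift`` is a callable of
    time in seconds (None → no drift); noise is white Gaussian on the raw
    signal.
    """
    if baseline <= 0:
        raise ParameterError("baseline must be positive")
    fps = geometry.fps
    n = int(round(fps * spikes.duration))
    impulses = np.zeros(n)
    if spikes.n_spikes:
        frames = np.ceil(spikes.times * fps - 1e-9).astype(int)
        frames = np.clip(frames, 0, n - 1)
        weights = np.exp(-(frames / fps - spikes.times) / model.tau)
        np.add.at(impulses, frames, weights)
    decay = np.exp(-1.0 / (model.tau * fps))
    activity = lfilter([1.0], [1.0, -decay], impulses)
    values = baseline * (1.0 + (model.amplitude / 100.0) * activity)
    if drift is not None:
        values = values + drift(np.arange(n) / fps)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=n)
    return RawTrace(values=values, fps=fps)


def _blob_kernel(size_px: int, sigma: float | None = None) -> np.ndarray:
    """Compact soma profile over the ROI box, normalized to unit pixel mean
    so the ROI-averaged intensity equals the rendered trace exactly."""
    half = (size_px - 1) // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    sigma = sigma if sigma is not None else max(size_px / 3.0, 1.0)
    w = np.exp(-(y**2 + x**2) / (2 * sigma**2))
    return w / w.mean()


def render_movie(
    population: list[tuple[SpikeTrain, tuple[int, int]]],
    model: TransientModel = DEFAULT_MODEL,
    geometry: AcquisitionGeometry = DEFAULT_GEOMETRY,
    baseline: float = DEFAULT_BASELINE,
    noise_sd: float = 0.0,
    drift=None,
    seed: int = 0,
) -> MovieStack:
    """Render somata as bright blobs on a noisy background.

    Each (spike train, (y, x) center) pair is rendered with
    :func:`render_fluorescence` and painted as a compact blob whose
    ROI-averaged intensity equals that trace (exactly, when noiseless).
    Centers must leave an ROI-sized margin inside the frame.
    """
    h, w = geometry.frame_shape
    half = (geometry.roi_size_px - 1) // 2
    n = geometry.n_frames
    rng = np.random.default_rng(seed)
    frames = (
        rng.normal(0.0, noise_sd, size=(n, h, w)).astype(np.float32)
        if noise_sd > 0
        else np.zeros((n, h, w), dtype=np.float32)
    )
    kernel = _blob_kernel(geometry.roi_size_px).astype(np.float32)
    for i, (spikes, (y, x)) in enumerate(population):
        if y - half < 0 or x - half < 0 or y + half >= h or x + half >= w:
            raise PlacementError(f"soma center ({y}, {x}) violates the ROI margin")
        trace = render_fluorescence(
            spikes, model, geometry, baseline=baseline, noise_sd=0.0,
            drift=drift, seed=seed + 1 + i,
        )
        frames[:, y - half : y + half + 1, x - half : x + half + 1] += (
            trace.values.astype(np.float32)[:, None, None] * kernel[None, :, :]
        )
    return MovieStack(frames=frames, geometry=geometry)


@dataclass
class LabeledPopulation:
    """Ground-truth labeled trace set from :func:`make_population`."""

    traces: list[RawTrace]
    spike_trains: list[SpikeTrain]
    labels: list[str]
    specs: dict[str, PhenotypeSpec]

    def __len__(self) -> int:
        return len(self.traces)


def make_population(
    n_per_class: dict[str, int],
    specs: dict[str, PhenotypeSpec] | None = None,
    seed: int = 0,
    model: TransientModel = DEFAULT_MODEL,
    geometry: AcquisitionGeometry = DEFAULT_GEOMETRY,
    baseline: float = DEFAULT_BASELINE,
    noise_sd: float = DEFAULT_NOISE_SD,
    drift="default",
) -> LabeledPopulation:
    """Simulate a labeled population of raw traces.

    Class counts are realized exactly in the fixed order low, intermediate,
    high, inactive; every per-neuron random stream derives from ``seed`` so a
    rerun reproduces the population bit-for-bit.  ``drift="default"`` applies
    :func:`default_drift`; pass None to disable.
    """
    specs = dict(DEFAULT_SPECS) if specs is None else specs
    for name in n_per_class:
        if name not in specs:
            raise ParameterError(f"unknown class label {name!r}")
        if n_per_class[name] < 0:
            raise ParameterError("class counts must be non-negative")
    drift_fn = default_drift() if drift == "default" else drift

    traces: list[RawTrace] = []
    trains: list[SpikeTrain] = []
    labels: list[str] = []
    ss = np.random.SeedSequence(seed)
    total = sum(n_per_class.get(c, 0) for c in CLASS_NAMES)
    children = ss.spawn(max(total, 1))
    idx = 0
    for cls in CLASS_NAMES:
        count = n_per_class.get(cls, 0)
        spec = replace(specs[cls], duration=geometry.duration)
        for _ in range(count):
            child = children[idx]
            s_train, s_noise = child.generate_state(2) % (2**31)
            train = simulate_spike_train(spec, int(s_train))
            trace = render_fluorescence(
                train, model, geometry, baseline=baseline,
                noise_sd=noise_sd, drift=drift_fn, seed=int(s_noise),
            )
            trains.append(train)
            traces.append(trace)
            labels.append(cls)
            idx += 1
    return LabeledPopulation(traces=traces, spike_trains=trains, labels=labels, specs=specs)


def write_spikes_csv(path, trains: list[SpikeTrain], ids: list | None = None) -> None:
    """Ground-truth / inferred spike table: columns neuron_id, time_s."""
    ids = ids if ids is not None else list(range(len(trains)))
    rows = []
    for nid, train in zip(ids, trains):
        for t in train.times:
            rows.append({"neuron_id": nid, "time_s": t})
    pd.DataFrame(rows, columns=["neuron_id", "time_s"]).to_csv(path, index=False)


def write_labels_csv(path, labels: list[str], ids: list | None = None) -> None:
    ids = ids if ids is not None else list(range(len(labels)))
    pd.DataFrame({"roi_id": ids, "label": labels}).to_csv(path, index=False)
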