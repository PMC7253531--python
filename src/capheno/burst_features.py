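"""Per-neuron firing/bursting features and group summary statistics.

A burst is a maximal run of consecutive spikes whose successive inter-spike
intervals are all strictly smaller than 1 s; runs of a single spike are not
bursts.  Nine features describe each neuron: spike count (NS), firing rate
(FR, Hz), mean and SD of the inter-spike interval (ISI, s), burst count (B),
mean spikes per burst, mean within-burst ISI, mean inter-burst interval
(IBI, start-to-start, s) and mean burst length (s).  Features that are not
defined for a train (no bursts, too few spikes) are NaN and are excluded
per-feature from group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import InputError
from .spike_inference import SpikeTrain

__all__ = [
    "Burst",
    "FeatureVector",
    "GroupSummary",
    "FEATURE_NAMES",
    "detect_bursts",
    "compute_features",
    "summarize_group",
    "features_to_frame",
]

FEATURE_NAMES = (
    "n_spikes",
    "firing_rate_hz",
    "isi_mean_s",
    "isi_sd_s",
    "n_bursts",
    "spikes_per_burst",
    "isi_in_burst_s",
    "ibi_s",
    "burst_length_s",
)


@dataclass(frozen=True)
class Burst:
    """One burst: onset/offset of its spikes and how many it concatenates."""

    start: float
    end: float
    n_spikes: int

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureVector:
    """The nine firing/bursting features of one neuron (NaN = undefined)."""

    n_spikes: float
    firing_rate_hz: float
    isi_mean_s: float
    isi_sd_s: float
    n_bursts: float
    spikes_per_burst: float
    isi_in_burst_s: float
    ibi_s: float
    burst_length_s: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def detect_bursts(spikes: SpikeTrain, max_isi: float = 1.0) -> list[Burst]:
    """Group consecutive spikes with gaps strictly below ``max_isi`` seconds.

    Returns maximal runs of length ≥ 2; a gap of exactly ``max_isi`` breaks a
    run.  The input train must be sorted (``SpikeTrain`` enforces this; raw
    arrays are checked).
    """
    t = np.asarray(spikes.times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise InputError("spike train must be sorted")
    bursts: list[Burst] = []
    if t.size < 2:
        return bursts
    gaps = np.diff(t)
    linked = gaps < max_isi
    start = 0
    for i in range(t.size - 1):
        if not linked[i]:
            if i - start >= 1:
                bursts.append(Burst(start=t[start], end=t[i], n_spikes=i - start + 1))
            start = i + 1
    if (t.size - 1) - start >= 1:
        bursts.append(Burst(start=t[start], end=t[-1], n_spikes=t.size - start))
    return bursts


def compute_features(spikes: SpikeTrain, max_isi: float = 1.0) -> FeatureVector:
    """Compute the nine-feature vector of one spike train.

    ISI statistics are over all consecutive gaps of the full train (the
    within-burst ISI is reported separately); ISI SD uses the unbiased (n−1)
    estimator and needs ≥ 2 gaps.  IBI is the mean interval between
    consecutive burst starts and needs ≥ 2 bursts.
    """
    t = np.asarray(spikes.times, dtype=float)
    ns = float(t.size)
    fr = ns / spikes.duration
    gaps = np.diff(t)
    isi_mean = float(gaps.mean()) if gaps.size >= 1 else np.nan
    isi_sd = float(gaps.std(ddof=1)) if gaps.size >= 2 else np.nan

    bursts = detect_bursts(spikes, max_isi=max_isi)
    b = float(len(bursts))
    if bursts:
        spb = float(np.mean([bu.n_spikes for bu in bursts]))
        blen = float(np.mean([bu.length for bu in bursts]))
        intra = []
        # within-burst gaps: consecutive spikes inside each burst
        for bu in bursts:
            i0 = int(np.searchsorted(t, bu.start))
            intra.extend(np.diff(t[i0 : i0 + bu.n_spikes]))
        isi_in = float(np.mean(intra)) if intra else np.nan
        if len(bursts) >= 2:
            ibi = float(np.mean(np.diff([bu.start for bu in bursts])))
        else:
            ibi = np.nan
    else:
        spb = blen = isi_in = ibi = np.nan
    return FeatureVector(
        n_spikes=ns, firing_rate_hz=fr, isi_mean_s=isi_mean, isi_sd_s=isi_sd,
        n_bursts=b, spikes_per_burst=spb, isi_in_burst_s=isi_in,
        ibi_s=ibi, burst_length_s=blen,
    )


@dataclass(frozen=True)
class GroupSummary:
    """Per-feature mean, sample SD (n−1), SEM = SD/√n and n (NaN excluded)."""

    table: pd.DataFrame  # index: feature, columns: mean, sd, sem, n

    def __getitem__(self, feature: str) -> pd.Series:
        return self.table.loc[feature]


def summarize_group(vectors: list[FeatureVector]) -> GroupSummary:
    """Summarize a group of feature vectors feature-by-feature.

    Undefined (NaN) entries are dropped per feature; SD uses the n−1
    denominator so SEM = SD/√n matches standard error-of-the-mean reporting.
    """
    if isinstance(vectors, pd.DataFrame):
        df = vectors
        if df.empty:
            raise InputError("cannot summarize an empty group")
    else:
        if not vectors:
            raise InputError("cannot summarize an empty group")
        df = features_to_frame(vectors)
    rows = {}
    for name in df.columns:
        col = df[name].dropna()
        n = len(col)
        mean = float(col.mean()) if n else np.nan
        sd = float(col.std(ddof=1)) if n >= 2 else np.nan
        sem = sd / np.sqrt(n) if n >= 2 else np.nan
        rows[name] = {"mean": mean, "sd": sd, "sem": sem, "n": n}
    table = pd.DataFrame.from_dict(rows, orient="index")[["mean", "sd", "sem", "n"]]
    return GroupSummary(table=table)


def features_to_frame(vectors: list[FeatureVector], ids: list | None = None) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame (one row per neuron)."""
    df = pd.DataFrame([v.as_dict() for v in vectors], columns=list(FEATURE_NAMES))
    if ids is not None:
        df.index = pd.Index(ids, name="neuron_id")
    return df
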