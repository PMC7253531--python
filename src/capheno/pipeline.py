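"""Reproducible end-to-end pipeline: simulate → process → screen → infer →
features → cluster, with a run manifest.

Each stage reads its inputs from, and writes its outputs to, the run output
directory in plain formats (CSV/JSON/TIFF).  All randomness derives from the
single config seed through per-stage seeds, so a rerun with the same config
reproduces every deterministic artifact checksum.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import activity_screen as screen_mod
from . import burst_features as feat_mod
from . import phenotype_clustering as clust_mod
from . import spike_inference as infer_mod
from . import synthetic_data as sim_mod
from . import trace_processing as proc_mod
from .config import PipelineConfig
from .errors import DependencyError, ParameterError

__all__ = ["RunManifest", "STAGES", "run", "process_trace", "analyze_population"]

STAGES = ("simulate", "process", "screen", "infer", "features", "cluster")

_FILES = {
    "raw_traces": "raw_traces.csv",
    "ground_truth_spikes": "ground_truth_spikes.csv",
    "labels": "labels.csv",
    "movie": "movie.tif",
    "normalized_traces": "normalized_traces.csv",
    "f0": "f0.csv",
    "screen_model": "screen_model.json",
    "screen_assignments": "screen_assignments.csv",
    "spikes": "spikes.csv",
    "features": "features.csv",
    "report": "report.json",
    "cluster_assignments": "cluster_assignments.csv",
    "manifest": "run_manifest.json",
}


@dataclass
class RunManifest:
    """What a run did: config echo, version, seeds, artifact checksums."""

    config: dict
    version: str
    stage_seeds: dict[str, int]
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def record(self, stage: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs.setdefault(stage, {})[path.name] = digest

    def to_json(self, path=None) -> str:
        text = json.dumps(vars(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage '{stage}' needs missing input {path}")
    return path


def _geometry(cfg: PipelineConfig) -> sim_mod.AcquisitionGeometry:
    g = cfg.geometry
    return sim_mod.AcquisitionGeometry(
        fps=g.fps, frame_shape=(g.frame_height_px, g.frame_width_px),
        um_per_px=g.um_per_px, roi_size_px=g.roi_size_px, duration=g.duration_s,
    )


def _stage_simulate(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    geometry = _geometry(cfg)
    model = sim_mod.TransientModel(
        amplitude=cfg.simulate.amplitude_pct, tau=cfg.simulate.tau_s,
        threshold=cfg.infer.threshold_pct,
    )
    drift = sim_mod.default_drift(
        amplitude=cfg.simulate.drift_amplitude, period_s=cfg.simulate.drift_period_s
    )
    pop = sim_mod.make_population(
        cfg.simulate.class_counts, seed=seed, model=model, geometry=geometry,
        baseline=cfg.simulate.baseline, noise_sd=cfg.simulate.noise_sd, drift=drift,
    )
    ids = list(range(len(pop)))
    written = []
    proc_mod.write_traces_csv(out / _FILES["raw_traces"], pop.traces, ids)
    written.append(out / _FILES["raw_traces"])
    sim_mod.write_spikes_csv(out / _FILES["ground_truth_spikes"], pop.spike_trains, ids)
    written.append(out / _FILES["ground_truth_spikes"])
    sim_mod.write_labels_csv(out / _FILES["labels"], pop.labels, ids)
    written.append(out / _FILES["labels"])
    if cfg.simulate.write_movie:
        n_mov = min(cfg.simulate.movie_n_neurons, len(pop))
        h, w = geometry.frame_shape
        half = (geometry.roi_size_px - 1) // 2
        side = int(np.ceil(np.sqrt(max(n_mov, 1))))
        centers = [
            (half + 1 + (i // side) * max((h - 2 * half - 2) // side, 1),
             half + 1 + (i % side) * max((w - 2 * half - 2) // side, 1))
            for i in range(n_mov)
        ]
        movie = sim_mod.render_movie(
            list(zip(pop.spike_trains[:n_mov], centers)), model, geometry,
            baseline=cfg.simulate.baseline, noise_sd=cfg.simulate.noise_sd, seed=seed,
        )
        movie.to_tiff(out / _FILES["movie"])
        written.append(out / _FILES["movie"])
    return written


def _stage_process(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    traces, ids = proc_mod.read_traces_csv(_require(out / _FILES["raw_traces"], "process"))
    normalized, f0s = [], []
    for tr in traces:
        sm = proc_mod.smooth(tr, cfg.process.window_frames)
        corrected = proc_mod.correct_drift(sm, cfg.process.block_s)
        f0 = proc_mod.estimate_f0(corrected, cfg.process.f0_percentile)
        normalized.append(proc_mod.normalize_dff(corrected, f0))
        f0s.append(f0)
    proc_mod.write_traces_csv(out / _FILES["normalized_traces"], normalized, ids)
    pd.DataFrame({"roi_id": ids, "f0": f0s}).to_csv(out / _FILES["f0"], index=False)
    return [out / _FILES["normalized_traces"], out / _FILES["f0"]]


def _read_normalized(out: Path, stage: str):
    traces, ids = proc_mod.read_traces_csv(_require(out / _FILES["normalized_traces"], stage))
    # re-wrap as normalized traces (f0 bookkeeping only; values already in %)
    f0_path = out / _FILES["f0"]
    f0 = pd.read_csv(f0_path).set_index("roi_id")["f0"] if f0_path.exists() else None
    normalized = [
        proc_mod.NormalizedTrace(
            values=tr.values,
            f0=float(f0.loc[type(f0.index[0])(i)]) if f0 is not None else 1.0,
            fps=tr.fps,
        )
        for tr, i in zip(traces, ids)
    ]
    return normalized, ids


def _stage_screen(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    normalized, ids = _read_normalized(out, "screen")
    feats = [
        screen_mod.screen_features(tr, cfg.screen.threshold_pct) for tr in normalized
    ]
    labels_path = _require(out / _FILES["labels"], "screen")
    label_df = pd.read_csv(labels_path).set_index("roi_id")
    truth = [
        "inactive" if str(label_df.loc[type(label_df.index[0])(i), "label"]) == "inactive"
        else "active"
        for i in ids
    ]
    # emulate manual curation: a fixed-size labeled subset per class
    rng = np.random.default_rng(seed)
    truth_arr = np.asarray(truth)
    train_idx: list[int] = []
    for cls in ("active", "inactive"):
        pool = np.flatnonzero(truth_arr == cls)
        take = min(cfg.screen.n_labeled_per_class, pool.size)
        train_idx.extend(rng.choice(pool, size=take, replace=False).tolist())
    model = screen_mod.train_screen(
        [feats[i] for i in train_idx], truth_arr[train_idx],
        n_rounds=cfg.screen.n_rounds, seed=seed,
    )
    model.to_json(out / _FILES["screen_model"])
    results = screen_mod.classify_screen(model, feats)
    pd.DataFrame(
        {"roi_id": ids, "screen_label": [r[0] for r in results],
         "margin": [r[1] for r in results]}
    ).to_csv(out / _FILES["screen_assignments"], index=False)
    return [out / _FILES["screen_model"], out / _FILES["screen_assignments"]]


def _stage_infer(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    normalized, ids = _read_normalized(out, "infer")
    screen_path = out / _FILES["screen_assignments"]
    active = set(ids)
    if screen_path.exists():
        df = pd.read_csv(screen_path)
        active = set(str(r) for r in df.loc[df["screen_label"] == "active", "roi_id"])
    model = sim_mod.TransientModel(
        amplitude=cfg.infer.amplitude_pct, tau=cfg.infer.tau_s,
        threshold=cfg.infer.threshold_pct,
    )
    trains, kept = [], []
    for tr, i in zip(normalized, ids):
        if str(i) not in active:
            continue
        result = infer_mod.peel(tr, model, min_duration_frames=cfg.infer.min_duration_frames)
        trains.append(result.spikes)
        kept.append(i)
    sim_mod.write_spikes_csv(out / _FILES["spikes"], trains, kept)
    return [out / _FILES["spikes"]]


def _stage_features(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    spikes_path = _require(out / _FILES["spikes"], "features")
    df = pd.read_csv(spikes_path)
    duration = _geometry(cfg).duration
    vectors, ids = [], []
    for nid, grp in df.groupby("neuron_id", sort=True):
        train = infer_mod.SpikeTrain(times=np.sort(grp["time_s"].to_numpy()), duration=duration)
        vectors.append(feat_mod.compute_features(train, cfg.features.max_isi_s))
        ids.append(nid)
    table = feat_mod.features_to_frame(vectors, ids)
    table["duration_s"] = duration
    table.to_csv(out / _FILES["features"])
    return [out / _FILES["features"]]


def _stage_cluster(cfg: PipelineConfig, out: Path, seed: int) -> list[Path]:
    feats_path = _require(out / _FILES["features"], "cluster")
    table = pd.read_csv(feats_path, index_col="neuron_id")
    x = table[list(feat_mod.FEATURE_NAMES)]
    if len(x) < cfg.cluster.k:
        raise ParameterError(
            f"cluster stage needs at least k={cfg.cluster.k} neurons, got {len(x)}"
        )
    imputed = clust_mod.impute_median(x.to_numpy(dtype=float))
    model, scores = clust_mod.fit_pca(
        imputed, standardize=cfg.cluster.standardize,
        feature_names=tuple(feat_mod.FEATURE_NAMES),
    )
    if cfg.cluster.n_components is not None:
        scores = scores[:, : cfg.cluster.n_components]
    assignment = clust_mod.kmeans_cluster(
        scores, k=cfg.cluster.k, n_restarts=cfg.cluster.n_restarts, seed=seed
    )
    report = clust_mod.classify_groups(assignment, x, pca=model)
    report.to_json(out / _FILES["report"])
    pd.DataFrame(
        {
            "neuron_id": table.index,
            "group": assignment.labels,
            "class": [report.group_class[g] for g in assignment.labels],
        }
    ).to_csv(out / _FILES["cluster_assignments"], index=False)
    return [out / _FILES["report"], out / _FILES["cluster_assignments"]]


def process_trace(
    raw: proc_mod.RawTrace,
    window_frames: int = 5,
    block_s: float = 25.0,
    f0_percentile: float = 10.0,
) -> proc_mod.NormalizedTrace:
    """Smooth, drift-correct and ΔF/F0-normalize one raw trace (in memory)."""
    sm = proc_mod.smooth(raw, window_frames)
    corrected = proc_mod.correct_drift(sm, block_s)
    f0 = proc_mod.estimate_f0(corrected, f0_percentile)
    return proc_mod.normalize_dff(corrected, f0)


def analyze_population(
    traces: list[proc_mod.RawTrace],
    infer_model: sim_mod.TransientModel | None = None,
    k: int = 8,
    n_restarts: int = 50,
    seed: int = 0,
    max_isi_s: float = 1.0,
    window_frames: int = 5,
    block_s: float = 25.0,
    f0_percentile: float = 10.0,
) -> tuple[pd.DataFrame, "clust_mod.PhenotypeReport"]:
    """Run process → peel → features → PCA/k-means → class report in memory.

    Intended for already-screened (active) traces; returns the per-neuron
    feature table and the clustered phenotype report.
    """
    infer_model = infer_model or sim_mod.TransientModel()
    vectors = []
    for raw in traces:
        norm = process_trace(raw, window_frames, block_s, f0_percentile)
        spikes = infer_mod.peel(norm, infer_model).spikes
        vectors.append(feat_mod.compute_features(spikes, max_isi_s))
    table = feat_mod.features_to_frame(vectors)
    imputed = clust_mod.impute_median(table.to_numpy(dtype=float))
    model, scores = clust_mod.fit_pca(imputed, feature_names=tuple(feat_mod.FEATURE_NAMES))
    assignment = clust_mod.kmeans_cluster(scores, k=k, n_restarts=n_restarts, seed=seed)
    report = clust_mod.classify_groups(assignment, table, pca=model)
    return table, report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "screen": _stage_screen,
    "infer": _stage_infer,
    "features": _stage_features,
    "cluster": _stage_cluster,
}


def run(
    config: PipelineConfig,
    stages: list[str] | tuple[str, ...] | None = None,
    outdir=None,
) -> RunManifest:
    """Execute the requested stages in pipeline order and write a manifest.

    ``stages=None`` runs everything.  A stage whose upstream artifact is
    missing raises :class:`DependencyError` naming the file.
    """
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = (set(stages) - set(STAGES)) if stages is not None else set()
    if unknown:
        raise ParameterError(f"unknown stages: {sorted(unknown)}")
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(
        config=config.model_dump(), version=__version__, stage_seeds=seeds,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for stage in requested:
        for path in _STAGE_FUNCS[stage](config, out, seeds[stage]):
            manifest.record(stage, path)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / _FILES["manifest"])
    return manifest
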