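"""Text-first readers/writers for every intermediate, plus the end-to-end
pipeline.

All artifacts are plain text so any tool can inspect them: feature
trajectories as headered CSV (one file per trajectory, JSON manifest with
the frame time), discrete trajectories as one integer per line, bias traces
as COLVAR-style `#`-commented whitespace columns, docking scores as CSV,
and models as JSON.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterModel, FeatureTrajectorySet
from .msm import DiscreteTrajectorySet, TransitionModel
from .rates import BiasTrace

__all__ = [
    "read_feature_trajectories", "write_feature_trajectories",
    "read_discrete_trajectories", "write_discrete_trajectories",
    "read_bias_trace", "write_bias_trace",
    "read_docking_scores", "write_docking_scores",
    "read_transition_model", "write_transition_model",
    "read_cluster_model", "write_cluster_model",
    "PipelineConfig", "RunManifest", "run_pipeline",
]


# ---------------------------------------------------------------- features

def write_feature_trajectories(features: FeatureTrajectorySet, outdir) -> list:
    """One CSV per trajectory plus a manifest.json carrying frame_time."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = [f"f{j}" for j in range(features.n_features)]
    paths = []
    for tid, traj in zip(features.ids, features.trajs):
        path = outdir / f"{tid}.csv"
        pd.DataFrame(traj, columns=names).to_csv(path, index=False,
                                                 float_format="%.8g")
        paths.append(path)
    manifest = {"frame_time": features.frame_time,
                "trajectories": [p.name for p in paths]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return paths


def read_feature_trajectories(paths, frame_time: float | None = None
                              ) -> FeatureTrajectorySet:
    """Load delimited feature files (or a directory holding a manifest)."""
    if isinstance(paths, (str, Path)):
        outdir = Path(paths)
        if not outdir.is_dir():
            raise FileNotFoundError(f"feature directory not found: {outdir}")
        manifest = json.loads((outdir / "manifest.json").read_text())
        frame_time = manifest["frame_time"]
        paths = [outdir / name for name in manifest["trajectories"]]
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(str(p))
    if frame_time is None:
        raise ValueError("frame_time required when no manifest is present")
    trajs, header = [], None
    for p in paths:
        df = pd.read_csv(p)
        if header is None:
            header = list(df.columns)
        elif list(df.columns) != header:
            raise ValueError(f"feature header mismatch in {p}")
        if df.isna().any().any():
            bad = int(df.isna().any(axis=1).idxmax()) + 2  # +header +1-based
            raise ValueError(f"ragged/missing values in {p} near line {bad}")
        trajs.append(df.to_numpy(dtype=float))
    return FeatureTrajectorySet(trajs=trajs, frame_time=float(frame_time),
                                ids=[p.stem for p in paths])


# ------------------------------------------------------- discrete trajectories

def write_discrete_trajectories(dtrajs: DiscreteTrajectorySet, outdir) -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, d in enumerate(dtrajs.dtrajs):
        path = outdir / f"dtraj_{k:03d}.txt"
        np.savetxt(path, d, fmt="%d")
        paths.append(path)
    meta = {"frame_time": dtrajs.frame_time, "n_states": dtrajs.n_states,
            "trajectories": [p.name for p in paths]}
    (outdir / "dtraj_manifest.json").write_text(json.dumps(meta, indent=1))
    return paths


def read_discrete_trajectories(src, frame_time: float | None = None,
                               n_states: int | None = None
                               ) -> DiscreteTrajectorySet:
    if isinstance(src, (str, Path)) and Path(src).is_dir():
        d = Path(src)
        meta = json.loads((d / "dtraj_manifest.json").read_text())
        frame_time, n_states = meta["frame_time"], meta["n_states"]
        paths = [d / name for name in meta["trajectories"]]
    else:
        paths = [Path(p) for p in src]
    if frame_time is None:
        raise ValueError("frame_time required when no manifest is present")
    dtrajs = [np.loadtxt(p, dtype=np.int64, ndmin=1) for p in paths]
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    return DiscreteTrajectorySet(dtrajs=dtrajs, frame_time=float(frame_time),
                                 n_states=int(n_states))


# ----------------------------------------------------------------- bias traces

def write_bias_trace(trace: BiasTrace, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#! FIELDS time bias\n")
        fh.write(f"# kBT {trace.kBT:.10g}\n")
        for t, v in zip(trace.times, trace.bias):
            fh.write(f"{t:.10g} {v:.10g}\n")
    return path


def read_bias_trace(path, kBT: float | None = None, time_col: int = 0,
                    bias_col: int = 1) -> BiasTrace:
    """COLVAR-style reader: `#` comments, whitespace-delimited columns."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#").split()
                if len(parts) == 2 and parts[0] == "kBT":
                    kBT = float(parts[1])
                continue
            rows.append([float(x) for x in line.split()])
    if kBT is None:
        raise ValueError("kBT not given and not recorded in the file header")
    arr = np.asarray(rows, dtype=float)
    return BiasTrace(times=arr[:, time_col], bias=arr[:, bias_col], kBT=kBT)


# -------------------------------------------------------------- docking scores

def write_docking_scores(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6g")
    return path


def read_docking_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"macrostate", "score"} <= set(df.columns):
        raise ValueError("docking-score table needs 'macrostate,score' columns")
    return df


# --------------------------------------------------------------------- models

def write_transition_model(model: TransitionModel, path) -> Path:
    path = Path(path)
    payload = {"lag": model.lag,
               "transition_matrix": model.transition_matrix.tolist(),
               "stationary": model.stationary.tolist(),
               "state_map": model.state_map.tolist()}
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_transition_model(path) -> TransitionModel:
    payload = json.loads(Path(path).read_text())
    return TransitionModel(
        transition_matrix=np.asarray(payload["transition_matrix"], dtype=float),
        lag=float(payload["lag"]),
        stationary=np.asarray(payload["stationary"], dtype=float),
        state_map=np.asarray(payload["state_map"], dtype=np.int64))


def write_cluster_model(model: ClusterModel, path) -> Path:
    path = Path(path)
    payload = {"centers": model.centers.tolist(),
               "center_frames": [list(cf) for cf in model.center_frames],
               "metric": model.metric}
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_cluster_model(path) -> ClusterModel:
    payload = json.loads(Path(path).read_text())
    return ClusterModel(centers=np.asarray(payload["centers"], dtype=float),
                        center_frames=[tuple(cf) for cf in
                                       payload["center_frames"]],
                        metric=payload.get("metric", "euclidean"))


# ------------------------------------------------------------------- pipeline

@dataclass
class PipelineConfig:
    """Configuration for the end-to-end synthetic-or-real-data pipeline.

    With feature_dir=None the synthetic stage generates the stated-world
    landscape: an 8-macrostate reversible chain whose dominant states M3
    and M6 hold 43.9% and 38.9% of the population (minor states within the
    0.5-6.0% band), multi-trajectory sampling, well-separated Gaussian
    feature emission, and per-macrostate docking scores straddling the
    -5.0 kcal/mol activity cutoff such that M1, M2, M5 and M6 are
    binding-competent.
    """

    outdir: str = "pipeline_out"
    feature_dir: str | None = None
    docking_path: str | None = None
    seed: int = 1
    # synthetic stated world; populations indexed by macrostate label M1..M8
    n_macro: int = 8
    populations: tuple = (0.060, 0.042, 0.439, 0.031, 0.022, 0.389, 0.012, 0.005)
    micro_per_macro: int = 3
    mixing: float = 0.02
    frame_time: float = 0.1
    n_traj: int = 30
    n_steps: int = 20_000
    emission_sd: float = 0.08
    docking_means: tuple = (-5.7, -5.0, 2.8, -2.0, -5.3, -5.3, -1.0, -3.0)
    docking_sd: float = 0.8
    n_dock_per_state: int = 500
    # analysis parameters
    k_micro: int = 40
    medoid_sweeps: int = 5
    lag_frames: tuple = (1, 2, 3, 5, 8)
    its_tolerance: float = 0.25
    n_timescales: int = 3
    ck_kmax: int = 3
    jump_factor: float = 3.0
    mc_steps: int = 100_000
    mc_thin: int = 200
    activity_cutoff: float = -5.0
    ci_level: float = 0.80

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("populations", "docking_means", "lag_frames"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the master seed (documented hashing)."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunManifest:
    """Audit record of a pipeline run: stages, outputs, hashes, timings."""

    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def record(self, stage: str, paths, seconds: float):
        self.stages.append({"stage": stage, "seconds": round(seconds, 3)})
        for p in np.atleast_1d(paths):
            p = Path(p)
            self.outputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"stages": self.stages, "outputs": self.outputs,
             "parameters": self.parameters}, indent=1, default=str))
        return path


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full analysis chain and write every intermediate.

    Stage order: (synthesize) -> cluster -> lag scan -> estimate microstate
    MSM -> Chapman-Kolmogorov test -> BACE coarse-grain -> macrostate
    populations / free energies / MFPTs / barriers -> Monte-Carlo confidence
    intervals -> binding-competence classification.  Rerunning with an
    identical config reproduces identical output hashes.
    """
    from . import clustering, coarse_grain, kinetics, msm, synthetic, \
        uncertainty, validation

    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(parameters={k: getattr(cfg, k)
                                       for k in cfg.__dataclass_fields__})

    def timed(stage, fn):
        t0 = time.perf_counter()
        paths = fn()
        manifest.record(stage, paths, time.perf_counter() - t0)

    # ---- inputs: synthesize or load
    if cfg.feature_dir is None:
        chain = synthetic.make_metastable_chain(
            cfg.n_macro, cfg.populations,
            intra_block_sizes=[cfg.micro_per_macro] * cfg.n_macro,
            mixing=cfg.mixing, frame_time=cfg.frame_time,
            seed=cfg.stage_seed("chain"))
        dtrajs_true = synthetic.sample_discrete_trajectories(
            chain, cfg.n_traj, cfg.n_steps, seed=cfg.stage_seed("sample"))
        # means ~ N(0, 3^2) in 3 dimensions with sd 0.08 noise: typical
        # inter-state separation of tens of sd, so discretization is clean
        rng = np.random.default_rng(cfg.stage_seed("emission"))
        means = 3.0 * rng.normal(0.0, 1.0, size=(chain.n_states, 3))
        spec = synthetic.EmissionSpec(means=means,
                                      sds=np.full(chain.n_states,
                                                  cfg.emission_sd))
        features = synthetic.emit_features(dtrajs_true, spec,
                                           seed=cfg.stage_seed("emit"))
        timed("synthesize",
              lambda: write_feature_trajectories(features, outdir / "features"))
        docking = synthetic.make_docking_scores(
            [f"M{m + 1}" for m in range(cfg.n_macro)], cfg.docking_means,
            cfg.docking_sd, cfg.n_dock_per_state,
            seed=cfg.stage_seed("docking"))
        timed("docking_scores",
              lambda: write_docking_scores(docking, outdir / "docking.csv"))
    else:
        if not Path(cfg.feature_dir).exists():
            raise FileNotFoundError(cfg.feature_dir)
        features = read_feature_trajectories(cfg.feature_dir)
        docking = (read_docking_scores(cfg.docking_path)
                   if cfg.docking_path else None)

    # ---- clustering
    cluster_model = clustering.hybrid_cluster(
        features, cfg.k_micro, n_medoid_sweeps=cfg.medoid_sweeps,
        seed=cfg.stage_seed("cluster"))
    assignments = clustering.assign(features, cluster_model)
    timed("cluster", lambda: [
        write_cluster_model(cluster_model, outdir / "clusters.json"),
        *write_discrete_trajectories(assignments, outdir / "dtrajs")])

    # ---- lag scan and microstate MSM
    scan = msm.implied_timescales(assignments, cfg.lag_frames,
                                  m=cfg.n_timescales)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lag_ns = msm.select_markov_lag(scan, tolerance=cfg.its_tolerance)
    lag_frames = (int(round(lag_ns / features.frame_time))
                  if lag_ns is not None else cfg.lag_frames[0])
    counts = msm.count_transitions(assignments, lag_frames)
    micro_model = msm.estimate_tmatrix(counts)

    def write_scan():
        df = pd.DataFrame(scan.timescales,
                          columns=[f"ts_{j+1}" for j in
                                   range(scan.timescales.shape[1])])
        df.insert(0, "lag_ns", scan.lags_ns)
        p = outdir / "implied_timescales.csv"
        df.to_csv(p, index=False, float_format="%.8g")
        return [p, write_transition_model(micro_model,
                                          outdir / "micro_model.json")]
    timed("estimate", write_scan)

    # ---- Chapman-Kolmogorov
    ck = validation.ck_test(assignments, micro_model,
                            k_values=range(1, cfg.ck_kmax + 1))
    def write_ck():
        rows = []
        for sc, s in enumerate(ck.states):
            for kc, k in enumerate(ck.k_values):
                rows.append({"state": int(s), "k": int(k),
                             "p_msm": ck.p_msm[sc, kc],
                             "p_md": ck.p_md[sc, kc],
                             "sigma": ck.sigma[sc, kc],
                             "passed": bool(ck.passed[sc, kc]),
                             "testable": bool(ck.testable[sc, kc])})
        p = outdir / "ck_test.json"
        p.write_text(json.dumps(
            {"fraction_passed": ck.fraction_passed, "cells": rows}, indent=1))
        return p
    timed("cktest", write_ck)

    # ---- BACE coarse-graining
    bace = coarse_grain.bace_merge(counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n_macro = coarse_grain.select_macrostate_count(
            bace, jump_factor=cfg.jump_factor)
    macro = coarse_grain.lump(micro_model, counts, bace.maps[n_macro])
    def write_macro():
        p = outdir / "macro_model.json"
        p.write_text(json.dumps({
            "n_macrostates": int(n_macro),
            "mapping": bace.maps[n_macro].tolist(),
            "merge_costs": {str(k): v for k, v in bace.merge_costs.items()},
            "populations": macro.populations.tolist(),
            "transition_matrix": macro.model.transition_matrix.tolist(),
            "lag": macro.model.lag}, indent=1))
        return p
    timed("coarse_grain", write_macro)

    # ---- kinetics
    mfpts = kinetics.mfpt_matrix(macro.model)
    ref = int(np.argmax(macro.populations))
    fe = kinetics.relative_free_energies(macro.populations, ref=ref)
    barriers = kinetics.relative_barriers(mfpts)
    def write_kin():
        k = mfpts.n_states
        labels = [f"M{i+1}" for i in range(k)]
        dfm = pd.DataFrame(mfpts.mfpts, index=labels, columns=labels)
        dfm["out_mean"] = mfpts.source_means
        dfm.loc["in_mean"] = list(mfpts.destination_means) + [np.nan]
        p1 = outdir / "mfpt_ns.csv"
        dfm.to_csv(p1, float_format="%.6g")
        dfb = pd.DataFrame(barriers.values, index=labels, columns=labels)
        p2 = outdir / "barriers_kT.csv"
        dfb.to_csv(p2, float_format="%.6g")
        p3 = outdir / "free_energies_kT.csv"
        pd.DataFrame({"macrostate": labels, "population": macro.populations,
                      "free_energy_kT": fe.values}).to_csv(
            p3, index=False, float_format="%.6g")
        return [p1, p2, p3]
    timed("kinetics", write_kin)

    # ---- uncertainty
    macro_counts = msm.CountMatrix(counts=macro.macro_counts,
                                   lag_in_frames=counts.lag_in_frames,
                                   frame_time=counts.frame_time)
    samples = uncertainty.sample_tmatrices(
        macro_counts, n_steps=cfg.mc_steps, thin=cfg.mc_thin,
        seed=cfg.stage_seed("tmatrix_mc"))
    pop_cis = uncertainty.ci_populations(samples, level=cfg.ci_level)
    mfpt_cis, _ = uncertainty.ci_mfpt(samples, target=ref, level=cfg.ci_level)
    def write_unc():
        rows = [{"state": f"M{i+1}", "point": ci.point, "lo": ci.lower,
                 "hi": ci.upper, "level": ci.level}
                for i, ci in enumerate(pop_cis)]
        p1 = outdir / "population_ci.csv"
        pd.DataFrame(rows).to_csv(p1, index=False, float_format="%.6g")
        rows = [{"state": f"M{i+1}", "point": ci.point, "lo": ci.lower,
                 "hi": ci.upper, "level": ci.level}
                for i, ci in enumerate(mfpt_cis)]
        p2 = outdir / f"mfpt_to_M{ref+1}_ci.csv"
        pd.DataFrame(rows).to_csv(p2, index=False, float_format="%.6g")
        return [p1, p2]
    timed("uncertainty", write_unc)

    # ---- activity classification
    if docking is not None:
        # docking labels follow the generator's macrostate labels, so pair
        # them with the generator's populations (estimated macrostates carry
        # their own arbitrary indexing)
        pops = None
        if cfg.feature_dir is None:
            pops = {f"M{m+1}": float(p) for m, p in enumerate(cfg.populations)}
        labels = coarse_grain.classify_binding_competence(
            docking, cutoff=cfg.activity_cutoff, populations=pops)
        def write_cls():
            p = outdir / "activity.csv"
            pd.DataFrame({"macrostate": labels.means.index,
                          "mean_score": labels.means.values,
                          "label": labels.labels.values}).to_csv(
                p, index=False, float_format="%.6g")
            p2 = outdir / "activity_summary.json"
            p2.write_text(json.dumps(
                {"cutoff": labels.cutoff,
                 "active_population": labels.active_population}, indent=1))
            return [p, p2]
        timed("classify", write_cls)

    manifest.write(outdir / "manifest_run.json")
    return manifest
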