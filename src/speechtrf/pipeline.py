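"""End-to-end orchestration of the six-stage workflow.

Per trial: (1) power of the original EEG, (2) TRF estimation from the
original EEG and the target+masker envelopes, (3) EEG prediction from those
TRFs, (4) binning-based compensation per channel, (5) SNR of the compensated
EEG (reported as the SNR difference), (6) TRF re-estimation from the
compensated EEG. Aggregated outputs: residual maps, N1/P2 peaks, variance
profiles, SNR tables, and cluster-permutation comparisons against noise TRFs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import montage as montage_mod
from .compensation import (BinningConfig, aggregate_residuals,
                           compensate_channel_trial)
from .core import EEGRecording, LagGrid, TRFSet, mean_trf
from .evaluation import (ChannelGroups, DEFAULT_PEAK_WINDOWS, extract_peaks,
                         snr_difference, trf_variance)
from .simulate import SimulationConfig, gen_dataset
from .stats import (AdjacencyGraph, PermutationConfig,
                    cluster_permutation_test)
from .trf import BoostConfig, boost_trf, make_noise_pairing, predict_eeg

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "write_summary"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full run; defaults are desk-scale."""

    simulation: SimulationConfig = field(default_factory=lambda:
        SimulationConfig(n_subjects=4, n_trials_per_condition=3,
                         n_channels=16, trial_duration=31.0,
                         nonlinearity_kind="quadratic",
                         nonlinearity_strength=-0.01))
    boost: BoostConfig = field(default_factory=lambda:
                               BoostConfig(max_iters=400))
    binning: BinningConfig = field(default_factory=BinningConfig)
    permutation: PermutationConfig = field(default_factory=lambda:
        PermutationConfig(n_permutations=200, min_neighbors=1))
    windows: dict = field(default_factory=lambda: dict(DEFAULT_PEAK_WINDOWS))
    output_dir: str = "pipeline_out"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["conditions"] = list(self.simulation.conditions)
        return d


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    started: str
    finished: str
    stages: tuple[str, ...]
    outputs: tuple[str, ...]
    kappa: float


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _channel_names(n: int) -> tuple[str, ...]:
    if n > len(montage_mod.BIOSEMI64_LABELS):
        raise ValueError(f"at most 64 channels supported, got {n}")
    return montage_mod.BIOSEMI64_LABELS[:n]


def _relabel(eeg: EEGRecording, names: tuple[str, ...]) -> EEGRecording:
    return replace(eeg, channel_names=names)


def _groups_for(names: tuple[str, ...]) -> ChannelGroups:
    mont = {k: v for k, v in montage_mod.default_montage().items()
            if k in names}
    raw = montage_mod.default_channel_groups(mont)
    return ChannelGroups({k: tuple(v) for k, v in raw.items() if v})


def _adjacency_for(names: tuple[str, ...]) -> AdjacencyGraph:
    mont = {k: v for k, v in montage_mod.default_montage().items()
            if k in names}
    return AdjacencyGraph.from_sets(montage_mod.build_adjacency(mont))


def run_pipeline(config: PipelineConfig | None = None) -> RunManifest:
    """Execute stages 1-6 on a (simulated) dataset and persist all tables."""
    if config is None:
        config = PipelineConfig()
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    names = _channel_names(sim.n_channels)
    groups = _groups_for(names)
    adjacency = _adjacency_for(names)
    grid = LagGrid.from_range(sim.fs)

    stages_done: list[str] = []
    outputs: list[str] = []
    stage = "simulate"
    try:
        trials = [dataclasses.replace(
            t,
            observed_eeg=_relabel(t.observed_eeg, names),
            clean_eeg=_relabel(t.clean_eeg, names))
            for t in gen_dataset(sim)]
        stages_done.append(stage)

        # per-trial stages 1-6
        snr_rows = []
        residuals: dict[str, list[np.ndarray]] = {c: [] for c in
                                                  sim.conditions}
        orig_trfs: dict[tuple[int, str], list[TRFSet]] = {}
        comp_trfs: dict[tuple[int, str], list[TRFSet]] = {}
        kappas: list[float] = []
        stage = "per-trial (power/TRF/predict/compensate/SNR/re-TRF)"
        for t in trials:
            envs = (t.target_env, t.masker_env)
            beta_orig = boost_trf(t.observed_eeg, envs, config.boost, grid)
            pred = predict_eeg(beta_orig, envs, measured=t.observed_eeg)
            kappa = float(np.mean(pred.mse_per_channel))
            kappas.append(kappa)

            comp_data = np.empty_like(t.observed_eeg.data)
            resid = np.empty(t.observed_eeg.n_channels)
            for ch in range(t.observed_eeg.n_channels):
                res = compensate_channel_trial(
                    pred.predicted.data[ch], t.observed_eeg.data[ch],
                    config.binning)
                comp_data[ch] = res.compensated_measured
                resid[ch] = res.residual
            residuals[t.condition].append(resid)
            comp_eeg = t.observed_eeg.with_data(comp_data)

            snr = snr_difference(t.observed_eeg, comp_eeg, kappa=kappa)
            for ch, db in zip(names, snr.snr_diff_db):
                snr_rows.append((t.subject, t.trial, t.condition, ch, db))

            beta_comp = boost_trf(comp_eeg, envs, config.boost, grid)
            key = (t.subject, t.condition)
            orig_trfs.setdefault(key, []).append(beta_orig)
            comp_trfs.setdefault(key, []).append(beta_comp)
        stages_done.append(stage)

        stage = "aggregate"
        snr_df = pd.DataFrame(
            snr_rows,
            columns=["subject", "trial", "condition", "channel",
                     "snr_diff_db"])
        snr_path = out / "snr_diff.csv"
        snr_df.to_csv(snr_path, index=False)
        outputs.append(str(snr_path))

        res_map = aggregate_residuals(
            {c: np.vstack(v) for c, v in residuals.items()},
            channel_names=names, tolerance=config.binning.tolerance)
        res_df = pd.DataFrame([
            (cond, ch, res_map.mean_residual[ci, chi],
             res_map.sign[ci, chi])
            for ci, cond in enumerate(res_map.conditions)
            for chi, ch in enumerate(names)],
            columns=["condition", "channel", "mean_residual_uV", "sign"])
        res_path = out / "residual_map.csv"
        res_df.to_csv(res_path, index=False)
        outputs.append(str(res_path))

        # subject-level (trial-averaged) TRFs per condition, orig and comp
        subj_trfs = {
            "orig": {c: [mean_trf(orig_trfs[(s, c)])
                         for s in range(sim.n_subjects)]
                     for c in sim.conditions},
            "comp": {c: [mean_trf(comp_trfs[(s, c)])
                         for s in range(sim.n_subjects)]
                     for c in sim.conditions},
        }

        peak_rows = []
        for variant, by_cond in subj_trfs.items():
            for cond, trfs in by_cond.items():
                grand = mean_trf(trfs)
                for role in grand.predictor_roles:
                    p = grand.predictor_index(role)
                    for gname, labels in groups.groups.items():
                        idx = [names.index(l) for l in labels]
                        curve = grand.coefficients[idx, p, :].mean(axis=0)
                        pk = extract_peaks(curve, grid, config.windows)
                        peak_rows.append((variant, cond, role, gname,
                                          pk.n1_amplitude, pk.n1_latency,
                                          pk.p2_amplitude, pk.p2_latency))
        peaks_df = pd.DataFrame(peak_rows, columns=[
            "variant", "condition", "predictor", "group", "n1_amplitude",
            "n1_latency_s", "p2_amplitude", "p2_latency_s"])
        peaks_path = out / "peaks.csv"
        peaks_df.to_csv(peaks_path, index=False)
        outputs.append(str(peaks_path))

        var_rows = []
        if sim.n_subjects >= 2:
            for variant, by_cond in subj_trfs.items():
                for cond, trfs in by_cond.items():
                    for role in trfs[0].predictor_roles:
                        prof = trf_variance(trfs, groups, predictor=role)
                        for gi, gname in enumerate(prof.group_names):
                            for ki, lag in enumerate(grid.lags_ms):
                                var_rows.append(
                                    (variant, cond, role, gname, lag,
                                     prof.variance[gi, ki]))
        var_df = pd.DataFrame(var_rows, columns=[
            "variant", "condition", "predictor", "group", "lag_ms",
            "variance"])
        var_path = out / "trf_variance.csv"
        var_df.to_csv(var_path, index=False)
        outputs.append(str(var_path))
        stages_done.append(stage)

        stage = "cluster-stats"
        cluster_rows = []
        intervals: dict[str, list[tuple[float, float]]] = {}
        if sim.n_subjects >= 2:
            noise_trfs = _noise_trfs(trials, config, grid, sim)
            for cond in sim.conditions:
                condA = np.stack([
                    t.coefficients[:, 0, :]  # target predictor
                    for t in subj_trfs["orig"][cond]])
                condB = np.stack([
                    noise_trfs[(s, cond)].coefficients[:, 0, :]
                    for s in range(sim.n_subjects)])
                result = cluster_permutation_test(
                    condA, condB, adjacency, config.permutation,
                    channel_names=names, lag_grid=grid)
                comparison = f"T-{cond}-vs-noise"
                intervals[comparison] = result.significant_intervals
                for i, cl in enumerate(result.clusters):
                    lo, hi = cl.lag_extent
                    chans = sorted({names[c] for c, _ in cl.members})
                    cluster_rows.append(
                        (comparison, i, cl.mass, cl.p_value, cl.significant,
                         grid.lags_ms[lo] / 1000, grid.lags_ms[hi] / 1000,
                         ";".join(chans)))
        cl_df = pd.DataFrame(cluster_rows, columns=[
            "comparison", "cluster", "t_mass", "p_value", "significant",
            "start_s", "end_s", "channels"])
        cl_path = out / "clusters.csv"
        cl_df.to_csv(cl_path, index=False)
        outputs.append(str(cl_path))
        stages_done.append(stage)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary_path = write_summary(
        out, peaks_df=peaks_df, snr_df=snr_df, res_df=res_df,
        intervals=intervals)
    outputs.append(str(summary_path))

    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed, started=started,
        finished=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        stages=tuple(stages_done), outputs=tuple(outputs),
        kappa=float(np.mean(kappas)))
    (out / "manifest.json").write_text(json.dumps(
        dataclasses.asdict(manifest), indent=1))
    return manifest


def _noise_trfs(trials, config: PipelineConfig, grid: LagGrid,
                sim: SimulationConfig) -> dict[tuple[int, str], TRFSet]:
    """Subject/condition noise TRFs from mismatched EEG/envelope pairs."""
    pairs = make_noise_pairing(trials, seed=config.seed)
    by_key: dict[tuple[int, str], list[TRFSet]] = {}
    for eeg, target_env, masker_env in pairs:
        trf = boost_trf(eeg, (target_env, masker_env), config.boost, grid)
        by_key.setdefault((eeg.subject, eeg.condition), []).append(trf)
    return {k: mean_trf(v) for k, v in by_key.items()}


def write_summary(out_dir: str | Path, peaks_df: pd.DataFrame,
                  snr_df: pd.DataFrame, res_df: pd.DataFrame,
                  intervals: dict[str, list[tuple[float, float]]]) -> Path:
    """One JSON summary: peaks, SNR differences, residual extrema, clusters."""
    out_dir = Path(out_dir)
    summary = {
        "peaks": peaks_df.to_dict(orient="records"),
        "snr_diff_db_mean_by_condition": (
            snr_df.groupby("condition")["snr_diff_db"].mean().to_dict()),
        "residual_extrema_uV": {
            "min": float(res_df["mean_residual_uV"].min()),
            "max": float(res_df["mean_residual_uV"].max()),
        },
        "significant_intervals_s": {
            k: [[float(lo), float(hi)] for lo, hi in v]
            for k, v in intervals.items()},
    }
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=1))
    return path
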