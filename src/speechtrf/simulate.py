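"""Synthetic auditory-EEG generator.

Produces band-limited stimulus envelopes, P1/N1/P2-shaped ground-truth
kernels, and multichannel EEG built as the sum of target- and masker-envelope
convolutions, optionally passed through a static nonlinearity, plus noise.
Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import signal as sps

from .core import EnvelopeSeries, EEGRecording, LagGrid

__all__ = [
    "SimulationConfig",
    "GroundTruthTRF",
    "SyntheticTrial",
    "gen_envelope",
    "gen_ground_truth_trf",
    "simulate_trial",
    "gen_dataset",
    "apply_nonlinearity",
]

#: per-condition (target_gain, masker_gain, noise_sd) defaults: NR_on raises
#: the target-to-masker contrast and lowers the noise floor.
DEFAULT_CONDITION_PARAMS: dict[str, tuple[float, float, float]] = {
    "NR_on": (1.0, 0.5, 1.0),
    "NR_off": (0.7, 0.7, 1.5),
}

#: (latency ms, width ms, amplitude) for the three canonical components.
DEFAULT_PEAK_PARAMS: dict[str, tuple[float, float, float]] = {
    "P1": (60.0, 15.0, 1.5),
    "N1": (100.0, 20.0, -3.0),
    "P2": (220.0, 35.0, 2.5),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Design of the simulated experiment (defaults mirror the study design)."""

    n_subjects: int = 30
    n_trials_per_condition: int = 40
    conditions: tuple[str, ...] = ("NR_on", "NR_off")
    n_channels: int = 64
    fs: float = 100.0
    trial_duration: float = 31.0
    condition_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PARAMS)
    )
    nonlinearity_kind: str = "none"
    nonlinearity_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("subject and trial counts must be >= 1")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.fs <= 0 or self.trial_duration <= 0:
            raise ValueError("fs and trial_duration must be positive")
        n = self.trial_duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"trial_duration * fs = {n} is not an integer sample count"
            )
        if self.nonlinearity_kind not in ("none", "quadratic", "saturating"):
            raise ValueError(
                f"unknown nonlinearity kind {self.nonlinearity_kind!r}"
            )
        for cond in self.conditions:
            if cond not in self.condition_params:
                raise ValueError(f"no parameters for condition {cond!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.fs))

    @property
    def trials_per_subject(self) -> int:
        return self.n_trials_per_condition * len(self.conditions)


@dataclass(frozen=True)
class GroundTruthTRF:
    """Channel-specific generating kernel: sum of three Gaussian bumps."""

    kernel: np.ndarray  # channels x lags, uV per unit envelope
    lag_grid: LagGrid
    peak_params: dict[str, tuple[float, float, float]]
    region_gains: np.ndarray  # per-channel scaling

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        g = np.asarray(self.region_gains, dtype=float)
        if k.ndim != 2 or k.shape[1] != self.lag_grid.K:
            raise ValueError(f"kernel shape {k.shape} vs K={self.lag_grid.K}")
        if g.shape != (k.shape[0],):
            raise ValueError("region_gains must be one value per channel")
        object.__setattr__(self, "kernel", k)
        object.__setattr__(self, "region_gains", g)

    @property
    def n_channels(self) -> int:
        return self.kernel.shape[0]


@dataclass(frozen=True)
class SyntheticTrial:
    target_env: EnvelopeSeries
    masker_env: EnvelopeSeries
    clean_eeg: EEGRecording
    observed_eeg: EEGRecording
    subject: int
    trial: int
    condition: str


def gen_envelope(duration: float, fs: float, seed: int,
                 role: str = "target", band: tuple[float, float] = (1.0, 8.0),
                 floor_sd: float = 2.0) -> EnvelopeSeries:
    """Rectified, band-limited (1-8 Hz) Gaussian noise with a positive floor.

    The series is unit-SD band-passed noise shifted up by ``floor_sd``
    standard deviations and clipped at zero, so the dominant spectral
    content (above DC) stays inside the passband.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if fs < 20:
        raise ValueError(f"fs must be >= 20 Hz, got {fs}")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    sd = shaped.std()
    if sd > 0:
        shaped = shaped / sd
    env = np.clip(shaped + floor_sd, 0.0, None)
    return EnvelopeSeries(env, fs=fs, role=role)


def _gaussian_bump(lags_ms: np.ndarray, latency: float, width: float,
                   amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((lags_ms - latency) / width) ** 2)


def gen_ground_truth_trf(
    config: SimulationConfig,
    seed: int,
    peak_params: dict[str, tuple[float, float, float]] | None = None,
    lag_grid: LagGrid | None = None,
    latency_jitter_ms: float = 10.0,
    amplitude_jitter: float = 0.2,
) -> GroundTruthTRF:
    """Per-subject generating kernel on the lag grid.

    Each channel's kernel is the sum of three Gaussian bumps (P1, N1, P2)
    scaled by a channel-specific region gain; latencies/amplitudes are
    jittered per subject (deterministic in ``seed``). Kernels are forced to
    zero at negative lags (causal response).
    """
    if lag_grid is None:
        lag_grid = LagGrid.from_range(config.fs)
    if lag_grid.lags_ms[0] > -100.0 or lag_grid.lags_ms[-1] < 400.0:
        raise ValueError("lag grid must cover at least [-100, 400] ms")
    params = dict(peak_params or DEFAULT_PEAK_PARAMS)
    rng = np.random.default_rng(seed)

    jittered: dict[str, tuple[float, float, float]] = {}
    for name, (lat, width, amp) in params.items():
        lat_j = lat + rng.uniform(-latency_jitter_ms, latency_jitter_ms)
        amp_j = amp * (1.0 + rng.uniform(-amplitude_jitter, amplitude_jitter))
        if not (lag_grid.lags_ms[0] <= lat_j <= lag_grid.lags_ms[-1]):
            raise ValueError(
                f"peak {name} latency {lat_j:.1f} ms outside lag grid"
            )
        jittered[name] = (lat_j, width, amp_j)

    base = np.zeros(lag_grid.K)
    for lat, width, amp in jittered.values():
        base += _gaussian_bump(lag_grid.lags_ms, lat, width, amp)
    base[lag_grid.lags_ms < 0] = 0.0

    # smooth anterior->posterior gain profile in [0.5, 1], channel-specific
    ch = np.arange(config.n_channels)
    region_gains = 0.75 + 0.25 * np.cos(
        2 * np.pi * ch / max(config.n_channels, 1)
    )
    kernel = region_gains[:, None] * base[None, :]
    return GroundTruthTRF(kernel=kernel, lag_grid=lag_grid,
                          peak_params=jittered, region_gains=region_gains)


def apply_nonlinearity(v: np.ndarray, kind: str, gamma: float) -> np.ndarray:
    """Static sample-wise nonlinearity f(v).

    quadratic: f(v) = v + gamma * v**2 (gamma<0 concave, gamma>0 convex);
    saturating: f(v) = tanh(gamma*v)/gamma; none (or gamma=0): identity.
    """
    v = np.asarray(v, dtype=float)
    if kind == "none" or gamma == 0.0:
        return v.copy()
    if kind == "quadratic":
        return v + gamma * v * v
    if kind == "saturating":
        return np.tanh(gamma * v) / gamma
    raise ValueError(f"unknown nonlinearity kind {kind!r}")


def _convolve_kernel(kernel: np.ndarray, lag_grid: LagGrid, env: np.ndarray,
                     fs: float) -> np.ndarray:
    """y(t, n) = sum_tau beta(tau, n) x(t - tau), zero-padded edges."""
    lag_samp = lag_grid.lag_samples(fs)
    T = env.shape[0]
    out = np.zeros((kernel.shape[0], T))
    for k, lag in enumerate(lag_samp):
        coefs = kernel[:, k]
        if not np.any(coefs):
            continue
        if lag >= 0:
            if lag < T:
                out[:, lag:] += coefs[:, None] * env[: T - lag]
        else:
            out[:, : T + lag] += coefs[:, None] * env[-lag:]
    return out


def simulate_trial(config: SimulationConfig, trf: GroundTruthTRF, seed: int,
                   subject: int = 0, trial: int = 0,
                   condition: str | None = None) -> SyntheticTrial:
    """One trial: clean EEG = gains * (kernel (*) envelopes); observed =
    f(clean) + noise."""
    if trf.n_channels != config.n_channels:
        raise ValueError(
            f"kernel has {trf.n_channels} channels, config {config.n_channels}"
        )
    cond = condition if condition is not None else config.conditions[0]
    target_gain, masker_gain, noise_sd = config.condition_params[cond]

    rng = np.random.default_rng(seed)
    env_seeds = rng.integers(0, 2**63 - 1, size=2)
    target = gen_envelope(config.trial_duration, config.fs,
                          int(env_seeds[0]), role="target")
    masker = gen_envelope(config.trial_duration, config.fs,
                          int(env_seeds[1]), role="masker")

    clean = (
        target_gain * _convolve_kernel(trf.kernel, trf.lag_grid,
                                       target.data, config.fs)
        + masker_gain * _convolve_kernel(trf.kernel, trf.lag_grid,
                                         masker.data, config.fs)
    )
    observed = apply_nonlinearity(clean, config.nonlinearity_kind,
                                  config.nonlinearity_strength)
    if noise_sd > 0:
        observed = observed + noise_sd * rng.standard_normal(clean.shape)

    meta = dict(subject=subject, trial=trial, condition=cond)
    return SyntheticTrial(
        target_env=target,
        masker_env=masker,
        clean_eeg=EEGRecording(clean, fs=config.fs, **meta),
        observed_eeg=EEGRecording(observed, fs=config.fs, **meta),
        subject=subject,
        trial=trial,
        condition=cond,
    )


def subject_kernel(config: SimulationConfig, subject: int) -> GroundTruthTRF:
    """Deterministic per-subject kernel derived from the global seed."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(1, subject))
    return gen_ground_truth_trf(config, seed=int(ss.generate_state(1)[0]))


def gen_dataset(config: SimulationConfig,
                subjects: tuple[int, ...] | None = None
                ) -> Iterator[SyntheticTrial]:
    """Lazily yield all trials: subjects x conditions x trials, stable order.

    Per-subject kernels and per-trial noise are drawn deterministically from
    ``config.seed``, so two runs with the same config are identical.
    """
    subj_ids = subjects if subjects is not None else tuple(
        range(config.n_subjects))
    for subject in subj_ids:
        trf = subject_kernel(config, subject)
        for cond in config.conditions:
            for trial in range(config.n_trials_per_condition):
                ss = np.random.SeedSequence(
                    entropy=config.seed,
                    spawn_key=(subject, config.conditions.index(cond), trial),
                )
                trial_seed = int(ss.generate_state(1)[0])
                yield simulate_trial(config, trf, seed=trial_seed,
                                     subject=subject, trial=trial,
                                     condition=cond)
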