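"""Forward TRF estimation by boosting, EEG prediction, and noise pairings.

The model is y(t, n) = sum_tau beta(tau, n) x(t - tau) + eps(t, n) with a
lag grid of -100..400 ms. Estimation is sparse coordinate descent: starting
from zero coefficients, the single signed Hamming-tapered basis update that
maximally reduces training MSE is applied each iteration, with early stopping
on a held-out partition, cross-validated over partition rotations and
averaged across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import (EnvelopeSeries, EEGRecording, EstimationError, LagGrid,
                   TRFSet)

__all__ = [
    "BoostConfig",
    "PredictionResult",
    "build_lag_matrix",
    "boost_trf",
    "predict_eeg",
    "concatenate_trials",
    "make_noise_pairing",
]


@dataclass(frozen=True)
class BoostConfig:
    """Boosting hyperparameters.

    step_fraction scales the per-channel response SD into the fixed update
    magnitude; basis_width is the Hamming taper extent in ms.
    """

    step_fraction: float = 0.005
    basis_width_ms: float = 50.0
    n_partitions: int = 4
    patience: int = 1
    max_iters: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_fraction <= 0:
            raise ValueError("step_fraction must be > 0")
        if self.n_partitions < 2:
            raise ValueError("need at least 2 partitions")
        if self.patience < 1 or self.max_iters < 1:
            raise ValueError("patience and max_iters must be >= 1")


@dataclass(frozen=True)
class PredictionResult:
    """Predicted EEG, residual (measured - predicted) and per-channel MSE."""

    predicted: EEGRecording
    residual: np.ndarray | None = None
    mse_per_channel: np.ndarray | None = None


def build_lag_matrix(env: EnvelopeSeries | np.ndarray, grid: LagGrid,
                     fs: float | None = None) -> np.ndarray:
    """Lagged design matrix X (K x T): row k holds x(t - tau_k).

    Out-of-range samples are zero-filled; negative lags reference future
    samples. Column t always corresponds to output time t.
    """
    if isinstance(env, EnvelopeSeries):
        x = env.data
        fs = env.fs
    else:
        x = np.asarray(env, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    T = x.shape[0]
    if T < grid.K:
        raise ValueError(f"series length {T} < lag count {grid.K}")
    X = np.zeros((grid.K, T))
    for k, lag in enumerate(grid.lag_samples(fs)):
        if lag >= 0:
            if lag < T:
                X[k, lag:] = x[: T - lag]
        else:
            X[k, : T + lag] = x[-lag:]
    return X


def _basis_matrix(grid: LagGrid, fs: float, width_ms: float) -> np.ndarray:
    """B (K x K): row k is a Hamming bump of ``width_ms`` centered on lag k."""
    half = max(int(round(width_ms * fs / 1000.0)) // 2, 0)
    L = 2 * half + 1
    taper = np.hamming(L) if L > 1 else np.ones(1)
    B = np.zeros((grid.K, grid.K))
    for k in range(grid.K):
        lo = max(k - half, 0)
        hi = min(k + half + 1, grid.K)
        B[k, lo:hi] = taper[lo - (k - half): hi - (k - half)]
    return B


def _check_envs(eeg: EEGRecording, envs: Sequence[EnvelopeSeries]) -> None:
    if not envs:
        raise ValueError("need at least one predictor envelope")
    roles = [e.role for e in envs]
    if len(set(roles)) != len(roles):
        raise ValueError(f"predictor roles must be distinct, got {roles}")
    for e in envs:
        if e.fs != eeg.fs:
            raise ValueError(f"envelope rate {e.fs} != EEG rate {eeg.fs}")
        if e.n_samples != eeg.n_samples:
            raise ValueError(
                f"envelope length {e.n_samples} != EEG length {eeg.n_samples}"
            )
        if not np.isfinite(e.data).all():
            raise ValueError("envelope contains NaNs")
        if np.ptp(e.data) == 0:
            raise EstimationError("degenerate (constant) envelope")
    if not np.isfinite(eeg.data).all():
        raise ValueError("EEG contains NaNs")


def _partition_slices(T: int, n: int) -> list[np.ndarray]:
    bounds = np.linspace(0, T, n + 1).astype(int)
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(n)]


def _boost_fold(D_train: np.ndarray, D_val: np.ndarray, Y_train: np.ndarray,
                Y_val: np.ndarray, steps: np.ndarray, config: BoostConfig
                ) -> np.ndarray:
    """Boost every channel on one train/validation split.

    Returns per-channel coefficient vectors over the dictionary's (predictor,
    lag) atoms, taken at the best validation MSE.
    """
    n_atoms, _ = D_train.shape
    n_chan = Y_train.shape[0]
    atom_norm2 = np.einsum("et,et->e", D_train, D_train)

    coef = np.zeros((n_chan, n_atoms))
    best_coef = np.zeros_like(coef)
    resid = Y_train.copy()
    pred_val = np.zeros_like(Y_val)
    val_mse = np.mean((Y_val - pred_val) ** 2, axis=1)
    best_val = val_mse.copy()
    stale = np.zeros(n_chan, dtype=int)
    active = np.ones(n_chan, dtype=bool)

    for _ in range(config.max_iters):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        corr = D_train @ resid[idx].T  # atoms x active
        s = steps[idx]
        # MSE reduction of adding sign*s*atom: 2*s*|corr| - s^2*||atom||^2
        gain = 2.0 * s[None, :] * np.abs(corr) - (s ** 2)[None, :] * \
            atom_norm2[:, None]
        best_atom = np.argmax(gain, axis=0)
        best_gain = gain[best_atom, np.arange(idx.size)]

        for j, ch in enumerate(idx):
            if best_gain[j] <= 0:
                active[ch] = False  # no update reduces training MSE
                continue
            e = best_atom[j]
            delta = np.sign(corr[e, j]) * steps[ch]
            coef[ch, e] += delta
            resid[ch] -= delta * D_train[e]
            pred_val[ch] += delta * D_val[e]
            mse = np.mean((Y_val[ch] - pred_val[ch]) ** 2)
            if mse < best_val[ch]:
                best_val[ch] = mse
                best_coef[ch] = coef[ch]
                stale[ch] = 0
            else:
                stale[ch] += 1
                if stale[ch] >= config.patience:
                    active[ch] = False
    return best_coef


def boost_trf(eeg: EEGRecording, envs: Sequence[EnvelopeSeries],
              config: BoostConfig | None = None,
              grid: LagGrid | None = None) -> TRFSet:
    """Estimate a TRF per channel from target(+masker) envelopes by boosting.

    Both predictors are estimated jointly. The returned TRF is the mean of
    per-fold TRFs over ``n_partitions`` held-out rotations.
    """
    if config is None:
        config = BoostConfig()
    _check_envs(eeg, envs)
    if grid is None:
        grid = LagGrid.from_range(eeg.fs)
    T = eeg.n_samples
    if T < grid.K * config.n_partitions:
        raise ValueError("series too short for the partition scheme")

    # dictionary: Hamming-tapered atoms per predictor, rows = (p, k) atoms
    B = _basis_matrix(grid, eeg.fs, config.basis_width_ms)
    D = np.vstack([B @ build_lag_matrix(e, grid) for e in envs])

    steps = config.step_fraction * eeg.data.std(axis=1)
    if np.any(steps == 0):
        # flat channels get a nominal step so the all-zero TRF is returned
        steps = np.where(steps == 0, 1.0, steps)

    parts = _partition_slices(T, config.n_partitions)
    fold_coefs = []
    for f in range(config.n_partitions):
        val_idx = parts[f]
        train_idx = np.concatenate([parts[i] for i in range(len(parts))
                                    if i != f])
        fold_coefs.append(
            _boost_fold(D[:, train_idx], D[:, val_idx],
                        eeg.data[:, train_idx], eeg.data[:, val_idx],
                        steps, config)
        )
    atom_coef = np.mean(fold_coefs, axis=0)  # channels x (P*K)

    # atoms are tapered bumps: expand to plain lag coefficients via B
    P = len(envs)
    coefficients = np.empty((eeg.n_channels, P, grid.K))
    for p in range(P):
        coefficients[:, p, :] = atom_coef[:, p * grid.K:(p + 1) * grid.K] @ B
    return TRFSet(
        coefficients=coefficients,
        lag_grid=grid,
        predictor_roles=tuple(e.role for e in envs),
        fs=eeg.fs,
        channel_names=eeg.channel_names,
        subject=eeg.subject,
        trial=eeg.trial,
        condition=eeg.condition,
    )


def predict_eeg(trf: TRFSet, envs: Sequence[EnvelopeSeries],
                measured: EEGRecording | None = None) -> PredictionResult:
    """Predicted EEG = sum over predictors of the lagged-matrix product.

    If ``measured`` is supplied, the residual (measured - predicted) and
    per-channel MSE are returned; predicted + residual reconstructs the
    input exactly.
    """
    by_role = {e.role: e for e in envs}
    pred = None
    for p, role in enumerate(trf.predictor_roles):
        if role not in by_role:
            raise ValueError(f"missing envelope for predictor {role!r}")
        env = by_role[role]
        if env.fs != trf.fs:
            raise ValueError(f"envelope rate {env.fs} != TRF rate {trf.fs}")
        X = build_lag_matrix(env, trf.lag_grid)
        contrib = trf.coefficients[:, p, :] @ X
        pred = contrib if pred is None else pred + contrib

    predicted = EEGRecording(pred, fs=trf.fs, channel_names=trf.channel_names,
                             subject=trf.subject, trial=trf.trial,
                             condition=trf.condition)
    if measured is None:
        return PredictionResult(predicted=predicted)
    if measured.data.shape != pred.shape:
        raise ValueError(
            f"measured shape {measured.data.shape} != predicted {pred.shape}"
        )
    residual = measured.data - pred
    return PredictionResult(predicted=predicted, residual=residual,
                            mse_per_channel=np.mean(residual ** 2, axis=1))


def concatenate_trials(trials: Sequence) -> tuple[EEGRecording,
                                                  tuple[EnvelopeSeries, ...]]:
    """Concatenate trials along time for condition-level TRF estimation.

    All trials must share fs/channels; metadata is taken from the first
    trial with the trial index cleared.
    """
    if not trials:
        raise ValueError("no trials to concatenate")
    first = trials[0].observed_eeg
    eeg = np.concatenate([t.observed_eeg.data for t in trials], axis=1)
    target = np.concatenate([t.target_env.data for t in trials])
    masker = np.concatenate([t.masker_env.data for t in trials])
    rec = replace(first, data=eeg, trial=None)
    return rec, (EnvelopeSeries(target, fs=first.fs, role="target"),
                 EnvelopeSeries(masker, fs=first.fs, role="masker"))


def make_noise_pairing(trials: Sequence, seed: int = 0) -> list[tuple]:
    """Mismatch each EEG trial with the envelopes of the next trial.

    Trials are grouped by (subject, condition); within each group the
    envelope assignment is a circular shift of the trial order by one, so
    the pairing is a bijection with no self-pairs. Returns tuples of
    (observed_eeg, mismatched_target_env, mismatched_masker_env).
    """
    groups: dict[tuple, list] = {}
    for t in trials:
        groups.setdefault((t.subject, t.condition), []).append(t)
    pairs = []
    for key in sorted(groups, key=str):
        group = groups[key]
        if len(group) < 2:
            raise ValueError(
                f"subject/condition {key} has a single trial; cannot mismatch"
            )
        for i, t in enumerate(group):
            donor = group[(i + 1) % len(group)]
            pairs.append((t.observed_eeg, donor.target_env, donor.masker_env))
    return pairs
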