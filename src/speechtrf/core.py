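"""Core data containers shared across the pipeline.

The two sampled-series types (:class:`EnvelopeSeries`, :class:`EEGRecording`)
are thin, validated wrappers around numpy arrays carrying the sampling rate
and provenance metadata; :class:`LagGrid` and :class:`TRFSet` hold estimated
temporal response functions on a uniform lag axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "EnvelopeSeries",
    "EEGRecording",
    "LagGrid",
    "TRFSet",
    "AlignmentError",
    "DegenerateBinningError",
    "EstimationError",
]


class AlignmentError(ValueError):
    """Envelope/EEG pair cannot be aligned (insufficient overlap)."""


class DegenerateBinningError(ValueError):
    """Binning produced an empty bin or a degenerate outer-bin line."""


class EstimationError(RuntimeError):
    """TRF estimation cannot proceed (e.g. constant envelope)."""


@dataclass(frozen=True)
class EnvelopeSeries:
    """A single-channel sampled stimulus envelope.

    Parameters
    ----------
    data : 1-D array of envelope samples.
    fs : sampling rate in Hz.
    role : stream role, ``"target"`` or ``"masker"`` (free-form allowed).
    """

    data: np.ndarray
    fs: float
    role: str = "target"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"envelope must be 1-D, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("envelope contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "data", arr)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "EnvelopeSeries":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass(frozen=True)
class EEGRecording:
    """A channels x time EEG matrix with rate and provenance metadata."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = ()
    subject: int | None = None
    trial: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"EEG must be 2-D (channels x time), got {arr.shape}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        names = tuple(self.channel_names)
        if not names:
            names = tuple(f"ch{i:02d}" for i in range(arr.shape[0]))
        if len(names) != arr.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {arr.shape[0]} channels"
            )
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        return replace(self, data=np.asarray(data, dtype=float))

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel label {name!r}") from None


@dataclass(frozen=True)
class LagGrid:
    """Uniform lag axis in milliseconds, e.g. -100..400 ms at 10 ms spacing."""

    lags_ms: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_ms, dtype=float)
        if lags.ndim != 1 or lags.size < 2:
            raise ValueError("lag grid needs at least two lags")
        steps = np.diff(lags)
        if not np.allclose(steps, steps[0]):
            raise ValueError("lag grid must be uniformly spaced")
        if not np.any(np.isclose(lags, 0.0)):
            raise ValueError("lag grid must include lag 0")
        object.__setattr__(self, "lags_ms", lags)

    @classmethod
    def from_range(cls, fs: float, tmin_ms: float = -100.0,
                   tmax_ms: float = 400.0) -> "LagGrid":
        step = 1000.0 / fs
        n = int(round((tmax_ms - tmin_ms) / step)) + 1
        return cls(tmin_ms + step * np.arange(n))

    @property
    def K(self) -> int:
        return self.lags_ms.size

    @property
    def step_ms(self) -> float:
        return float(self.lags_ms[1] - self.lags_ms[0])

    def lag_samples(self, fs: float) -> np.ndarray:
        """Lags converted to integer sample shifts at rate ``fs``."""
        return np.rint(self.lags_ms * fs / 1000.0).astype(int)


@dataclass(frozen=True)
class TRFSet:
    """Estimated TRF coefficients: channels x predictors x lags."""

    coefficients: np.ndarray
    lag_grid: LagGrid
    predictor_roles: tuple[str, ...]
    fs: float
    channel_names: tuple[str, ...] = ()
    subject: int | None = None
    trial: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.ndim != 3:
            raise ValueError(
                f"coefficients must be channels x predictors x lags, got {coef.shape}"
            )
        if not np.isfinite(coef).all():
            raise ValueError("TRF coefficients contain non-finite values")
        roles = tuple(self.predictor_roles)
        if len(set(roles)) != len(roles):
            raise ValueError(f"predictor roles must be distinct, got {roles}")
        if len(roles) != coef.shape[1]:
            raise ValueError(
                f"{len(roles)} roles for {coef.shape[1]} predictors"
            )
        if coef.shape[2] != self.lag_grid.K:
            raise ValueError(
                f"{coef.shape[2]} lags in coefficients vs {self.lag_grid.K} in grid"
            )
        names = tuple(self.channel_names)
        if not names:
            names = tuple(f"ch{i:02d}" for i in range(coef.shape[0]))
        if len(names) != coef.shape[0]:
            raise ValueError(f"{len(names)} channel names for {coef.shape[0]} channels")
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "predictor_roles", roles)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.coefficients.shape[1]

    def predictor_index(self, role: str) -> int:
        try:
            return self.predictor_roles.index(role)
        except ValueError:
            raise KeyError(f"unknown predictor role {role!r}") from None


def mean_trf(trfs: Sequence[TRFSet]) -> TRFSet:
    """Average a collection of TRFSets sharing grid/roles/channels."""
    if not trfs:
        raise ValueError("cannot average an empty TRF collection")
    first = trfs[0]
    stack = np.stack([t.coefficients for t in trfs])
    return replace(first, coefficients=stack.mean(axis=0), trial=None)
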