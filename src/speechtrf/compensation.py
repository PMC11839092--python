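"""Binning-based nonlinearity detection and compensation.

Per channel-trial, samples are placed in the (predicted, measured) plane;
the 20 smallest and largest predicted samples are dropped as outliers, the
retained predicted range is split into three equal-width bins, a line is
fitted through the two outer-bin mean points, and the middle-bin measured
samples are shifted by a constant so their new mean falls on that line.
The pre-shift deviation (middle-bin mean minus the line) is the
nonlinearity residual: positive = concave, negative = convex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DegenerateBinningError

__all__ = [
    "BinningConfig",
    "BinSummary",
    "CompensationResult",
    "NonlinearityMap",
    "partition_bins",
    "compensate_channel_trial",
    "aggregate_residuals",
]


@dataclass(frozen=True)
class BinningConfig:
    n_outliers_per_tail: int = 20
    n_bins: int = 3
    tolerance: float = 0.0  # uV threshold for concave/convex labelling

    def __post_init__(self) -> None:
        if self.n_outliers_per_tail < 0:
            raise ValueError("n_outliers_per_tail must be >= 0")
        if self.n_bins < 3 or self.n_bins % 2 == 0:
            raise ValueError("n_bins must be odd and >= 3")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass(frozen=True)
class BinSummary:
    """Per-bin counts and means plus the retained sample indices."""

    counts: np.ndarray
    mean_predicted: np.ndarray
    mean_measured: np.ndarray
    bin_of_sample: np.ndarray  # -1 for excluded outliers, else bin index
    retained_index: np.ndarray
    edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class CompensationResult:
    """Compensated series plus the middle-bin residual r and shift = -r."""

    compensated_measured: np.ndarray
    residual: float
    shift: float
    slope: float
    intercept: float
    summary: BinSummary


@dataclass(frozen=True)
class NonlinearityMap:
    """Per-channel mean residual per condition, with sign labels."""

    conditions: tuple[str, ...]
    channel_names: tuple[str, ...]
    mean_residual: np.ndarray  # conditions x channels, uV
    sign: np.ndarray  # same shape, values in {"concave", "convex", "neutral"}


def partition_bins(predicted: np.ndarray, measured: np.ndarray,
                   config: BinningConfig | None = None) -> BinSummary:
    """Drop per-tail outliers by predicted rank, then equal-width bin.

    Ties at the outlier boundary are broken by stable original-order rank.
    The retained predicted range [min, max] is split into ``n_bins``
    equal-width intervals; the last interval is closed.
    """
    if config is None:
        config = BinningConfig()
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape or predicted.ndim != 1:
        raise ValueError("predicted and measured must be equal-length 1-D")
    T = predicted.size
    n_out = config.n_outliers_per_tail
    if T <= 2 * n_out + config.n_bins:
        raise ValueError(
            f"{T} samples too few for {n_out}/tail exclusion and "
            f"{config.n_bins} bins"
        )

    order = np.argsort(predicted, kind="stable")
    retained = np.sort(order[n_out: T - n_out])
    p_ret = predicted[retained]

    lo, hi = p_ret.min(), p_ret.max()
    if hi == lo:
        raise DegenerateBinningError("retained predicted range is a point")
    edges = np.linspace(lo, hi, config.n_bins + 1)
    # interval k is [edges[k], edges[k+1]), last interval closed
    bin_idx = np.minimum(
        ((p_ret - lo) / (hi - lo) * config.n_bins).astype(int),
        config.n_bins - 1,
    )

    counts = np.bincount(bin_idx, minlength=config.n_bins)
    mid = config.n_bins // 2
    if counts[0] == 0 or counts[-1] == 0 or counts[mid] == 0:
        raise DegenerateBinningError(
            f"empty outer or middle bin (counts {counts.tolist()})"
        )
    mean_pred = np.array([
        p_ret[bin_idx == b].mean() if counts[b] else np.nan
        for b in range(config.n_bins)
    ])
    m_ret = measured[retained]
    mean_meas = np.array([
        m_ret[bin_idx == b].mean() if counts[b] else np.nan
        for b in range(config.n_bins)
    ])
    bin_of_sample = np.full(T, -1, dtype=int)
    bin_of_sample[retained] = bin_idx
    return BinSummary(counts=counts, mean_predicted=mean_pred,
                      mean_measured=mean_meas, bin_of_sample=bin_of_sample,
                      retained_index=retained, edges=edges)


def compensate_channel_trial(predicted: np.ndarray, measured: np.ndarray,
                             config: BinningConfig | None = None
                             ) -> CompensationResult:
    """Shift middle-bin measured samples onto the outer-bin chord.

    The line L passes through (x1, y1) and (x3, y3), the outer bins' mean
    points; every middle-bin sample gets the constant shift
    L(x_mid) - y_mid, so the new middle-bin mean equals L(x_mid) exactly.
    Samples outside the middle bin are untouched.
    """
    if config is None:
        config = BinningConfig()
    summary = partition_bins(predicted, measured, config)
    mid = summary.n_bins // 2
    x1, x3 = summary.mean_predicted[0], summary.mean_predicted[-1]
    y1, y3 = summary.mean_measured[0], summary.mean_measured[-1]
    if x3 == x1:
        raise DegenerateBinningError("outer-bin mean predicted values equal")
    slope = (y3 - y1) / (x3 - x1)
    intercept = y1 - slope * x1

    x_mid = summary.mean_predicted[mid]
    y_mid = summary.mean_measured[mid]
    line_at_mid = slope * x_mid + intercept
    residual = float(y_mid - line_at_mid)
    shift = -residual

    compensated = np.asarray(measured, dtype=float).copy()
    in_mid = summary.bin_of_sample == mid
    compensated[in_mid] += shift
    return CompensationResult(compensated_measured=compensated,
                              residual=residual, shift=shift,
                              slope=float(slope), intercept=float(intercept),
                              summary=summary)


def aggregate_residuals(residuals: dict[str, np.ndarray],
                        channel_names: tuple[str, ...] | None = None,
                        tolerance: float = 0.0) -> NonlinearityMap:
    """Average residuals over subjects/trials into a per-channel map.

    ``residuals`` maps condition -> array with channels on the last axis and
    any leading (subject, trial) axes; the mean is taken over all leading
    axes. Sign labels: concave if mean > tolerance, convex if < -tolerance,
    else neutral.
    """
    if not residuals:
        raise ValueError("no residuals supplied")
    conditions = tuple(residuals)
    means = []
    n_channels = None
    for cond in conditions:
        arr = np.asarray(residuals[cond], dtype=float)
        if arr.size == 0:
            raise ValueError(f"condition {cond!r} has no residuals")
        flat = arr.reshape(-1, arr.shape[-1])
        if n_channels is None:
            n_channels = flat.shape[1]
        elif flat.shape[1] != n_channels:
            raise ValueError("channel counts differ across conditions")
        means.append(flat.mean(axis=0))
    mean_residual = np.vstack(means)
    if not np.isfinite(mean_residual).all():
        raise ValueError("non-finite mean residuals")
    if channel_names is None:
        channel_names = tuple(f"ch{i:02d}" for i in range(n_channels))
    sign = np.where(mean_residual > tolerance, "concave",
                    np.where(mean_residual < -tolerance, "convex", "neutral"))
    return NonlinearityMap(conditions=conditions,
                           channel_names=tuple(channel_names),
                           mean_residual=mean_residual, sign=sign)
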