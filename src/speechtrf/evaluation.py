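"""SNR differences, N1/P2 peak extraction, TRF variance, channel grouping."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import EEGRecording, LagGrid, TRFSet

__all__ = [
    "SNRResult",
    "PeakResult",
    "ChannelGroups",
    "VarianceProfile",
    "DEFAULT_PEAK_WINDOWS",
    "snr_difference",
    "extract_peaks",
    "trf_variance",
    "group_average",
]

#: component -> (start, end) seconds; from the reported analysis windows.
DEFAULT_PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "N1": (0.08, 0.12),
    "P2": (0.18, 0.25),
}


@dataclass(frozen=True)
class SNRResult:
    """Per-channel SNR difference (dB) between compensated and original EEG.

    kappa cancels: snr_diff_db = 10*log10(power_comp / power_orig).
    """

    kappa: float
    power_orig: np.ndarray
    power_comp: np.ndarray
    snr_diff_db: np.ndarray
    channel_names: tuple[str, ...]


@dataclass(frozen=True)
class PeakResult:
    """N1 (most negative) / P2 (most positive) amplitude and latency."""

    n1_amplitude: float
    n1_latency: float
    p2_amplitude: float
    p2_latency: float


@dataclass(frozen=True)
class ChannelGroups:
    """Disjoint named channel groups over a montage."""

    groups: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, labels in self.groups.items():
            labels = tuple(labels)
            if not labels:
                raise ValueError(f"group {name!r} is empty")
            overlap = seen & set(labels)
            if overlap:
                raise ValueError(f"groups overlap on {sorted(overlap)}")
            seen |= set(labels)
        object.__setattr__(
            self, "groups", {k: tuple(v) for k, v in self.groups.items()}
        )

    def validate_against(self, channel_names: Sequence[str]) -> None:
        known = set(channel_names)
        for name, labels in self.groups.items():
            missing = set(labels) - known
            if missing:
                raise KeyError(
                    f"group {name!r} references unknown channels "
                    f"{sorted(missing)}"
                )


@dataclass(frozen=True)
class VarianceProfile:
    """Across-subject variance of group-averaged TRF curves, per lag."""

    variance: np.ndarray  # groups x lags, uV^2
    group_names: tuple[str, ...]
    lag_grid: LagGrid


def snr_difference(orig: EEGRecording, comp: EEGRecording,
                   kappa: float = 1.0) -> SNRResult:
    """SNR_diff = 10 log10(P_comp/kappa) - 10 log10(P_orig/kappa) per channel.

    Powers are means of element-wise squared absolute values; kappa cancels
    exactly and only appears for reporting.
    """
    if orig.data.shape != comp.data.shape:
        raise ValueError(
            f"shape mismatch {orig.data.shape} vs {comp.data.shape}"
        )
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    p_orig = np.mean(np.abs(orig.data) ** 2, axis=1)
    p_comp = np.mean(np.abs(comp.data) ** 2, axis=1)
    if np.any(p_orig == 0):
        raise ZeroDivisionError("zero original power: SNR ratio undefined")
    # kappa cancels analytically; computing the ratio keeps that exact
    diff = 10.0 * np.log10(p_comp / p_orig)
    return SNRResult(kappa=float(kappa), power_orig=p_orig, power_comp=p_comp,
                     snr_diff_db=diff, channel_names=orig.channel_names)


def extract_peaks(trf_curve: np.ndarray, lag_grid: LagGrid,
                  windows: Mapping[str, tuple[float, float]] | None = None
                  ) -> PeakResult:
    """N1 = minimum within its window, P2 = maximum within its window.

    Latencies in seconds on the lag grid; ties break toward the earliest lag
    (argmin/argmax convention).
    """
    if windows is None:
        windows = DEFAULT_PEAK_WINDOWS
    curve = np.asarray(trf_curve, dtype=float)
    if curve.shape != (lag_grid.K,):
        raise ValueError(f"curve shape {curve.shape} != (K={lag_grid.K},)")
    lags_s = lag_grid.lags_ms / 1000.0

    def window_mask(lo: float, hi: float) -> np.ndarray:
        mask = (lags_s >= lo - 1e-12) & (lags_s <= hi + 1e-12)
        if not mask.any():
            raise ValueError(f"window [{lo}, {hi}] s outside the lag grid")
        return mask

    m1 = window_mask(*windows["N1"])
    i1 = np.flatnonzero(m1)[np.argmin(curve[m1])]
    m2 = window_mask(*windows["P2"])
    i2 = np.flatnonzero(m2)[np.argmax(curve[m2])]
    return PeakResult(
        n1_amplitude=float(curve[i1]), n1_latency=float(lags_s[i1]),
        p2_amplitude=float(curve[i2]), p2_latency=float(lags_s[i2]),
    )


def group_average(values: Mapping[str, float] | np.ndarray,
                  groups: ChannelGroups,
                  channel_names: Sequence[str] | None = None
                  ) -> dict[str, float]:
    """Arithmetic mean of per-channel values within each group."""
    if isinstance(values, Mapping):
        lookup = dict(values)
    else:
        arr = np.asarray(values, dtype=float)
        if channel_names is None or len(channel_names) != arr.shape[0]:
            raise ValueError("channel_names required for array input")
        lookup = dict(zip(channel_names, arr))
    out = {}
    for name, labels in groups.groups.items():
        try:
            out[name] = float(np.mean([lookup[l] for l in labels]))
        except KeyError as exc:
            raise KeyError(
                f"group {name!r} references unknown channel {exc.args[0]!r}"
            ) from None
    return out


def _group_curves(trf: TRFSet, predictor: str,
                  groups: ChannelGroups) -> np.ndarray:
    """groups x lags matrix of channel-group-averaged TRF curves."""
    p = trf.predictor_index(predictor)
    name_to_row = {n: i for i, n in enumerate(trf.channel_names)}
    rows = []
    for labels in groups.groups.values():
        idx = [name_to_row[l] for l in labels]
        rows.append(trf.coefficients[idx, p, :].mean(axis=0))
    return np.vstack(rows)


def trf_variance(trfsets: Sequence[TRFSet], groups: ChannelGroups,
                 predictor: str = "target", ddof: int = 1) -> VarianceProfile:
    """Per-lag variance across subjects of group-averaged TRF curves.

    Each element of ``trfsets`` is one subject's (trial-averaged) TRF. Sample
    variance (ddof=1) by default.
    """
    if len(trfsets) < 2:
        raise ValueError("need at least 2 subjects for a variance profile")
    groups.validate_against(trfsets[0].channel_names)
    curves = np.stack([_group_curves(t, predictor, groups) for t in trfsets])
    var = curves.var(axis=0, ddof=ddof)
    return VarianceProfile(variance=var,
                           group_names=tuple(groups.groups),
                           lag_grid=trfsets[0].lag_grid)
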