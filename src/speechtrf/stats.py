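"""Inferential machinery: dependent-samples t maps, cluster-based
permutation tests over (lag, channel) space, Bonferroni channel tests,
exact-binomial empirical chance level, and paired behavioral tests.

The permutation scheme flips the sign of per-subject paired differences
(within-subject condition swaps); the null summary is the maximum absolute
cluster mass per permutation, and a cluster is significant when its mass
exceeds the 95th percentile of that null (one-sided alpha = 0.05).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import LagGrid

__all__ = [
    "AdjacencyGraph",
    "PermutationConfig",
    "Cluster",
    "ClusterTestResult",
    "ChanceLevelSpec",
    "dependent_t_map",
    "cluster_permutation_test",
    "bonferroni_channel_tests",
    "empirical_chance_level",
    "paired_behavioral_test",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric channel-neighbor relation without self-neighbors."""

    labels: tuple[str, ...]
    neighbors: dict[str, frozenset]

    def __post_init__(self) -> None:
        nbrs = {l: frozenset(self.neighbors.get(l, ())) for l in self.labels}
        for l, ns in nbrs.items():
            if l in ns:
                raise ValueError(f"channel {l!r} is its own neighbor")
            for m in ns:
                if m not in nbrs:
                    raise ValueError(f"neighbor {m!r} of {l!r} not a channel")
                if l not in nbrs[m]:
                    raise ValueError(f"adjacency not symmetric: {l!r}/{m!r}")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "neighbors", nbrs)

    @classmethod
    def from_sets(cls, neighbors: Mapping[str, set]) -> "AdjacencyGraph":
        return cls(labels=tuple(neighbors), neighbors={
            k: frozenset(v) for k, v in neighbors.items()})

    def index_pairs(self, order: Sequence[str]) -> np.ndarray:
        """Neighbor pairs (i, j), i < j, as row indices into ``order``."""
        pos = {l: i for i, l in enumerate(order)}
        pairs = []
        for l, ns in self.neighbors.items():
            if l not in pos:
                continue
            for m in ns:
                if m in pos and pos[l] < pos[m]:
                    pairs.append((pos[l], pos[m]))
        return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1000
    sample_alpha: float = 0.05
    min_neighbors: int = 3  # 3 for grand-average, 1 for group analysis
    cluster_alpha: float = 0.05  # one-sided, 95th percentile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        for a in (self.sample_alpha, self.cluster_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must lie in (0, 1)")
        if self.min_neighbors < 0:
            raise ValueError("min_neighbors must be >= 0")


@dataclass(frozen=True)
class Cluster:
    members: tuple[tuple[int, int], ...]  # (channel index, lag index)
    mass: float
    p_value: float
    significant: bool

    @property
    def lag_extent(self) -> tuple[int, int]:
        lags = [l for _, l in self.members]
        return min(lags), max(lags)


@dataclass(frozen=True)
class ClusterTestResult:
    clusters: tuple[Cluster, ...]
    t_map: np.ndarray  # channels x lags
    threshold: float
    null_max_mass: np.ndarray
    channel_names: tuple[str, ...]
    lag_grid: LagGrid | None = None

    @property
    def significant_intervals(self) -> list[tuple[float, float]]:
        """Merged significant time intervals in seconds (needs a lag grid)."""
        if self.lag_grid is None:
            raise ValueError("no lag grid attached")
        lags_s = self.lag_grid.lags_ms / 1000.0
        spans = sorted(
            (lags_s[c.lag_extent[0]], lags_s[c.lag_extent[1]])
            for c in self.clusters if c.significant
        )
        merged: list[tuple[float, float]] = []
        for lo, hi in spans:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
            else:
                merged.append((lo, hi))
        return merged


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t over axis 0 with +/-inf sentinels for zero variance."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean * np.sqrt(n) / sd
        t = np.where(sd == 0,
                     np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def dependent_t_map(condA: np.ndarray, condB: np.ndarray) -> np.ndarray:
    """Paired t statistic per (channel, lag); df = n_subjects - 1.

    Inputs are subjects x channels x lags arrays with matched subject order.
    """
    A = np.asarray(condA, dtype=float)
    B = np.asarray(condB, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    if A.ndim != 3 or A.shape[0] < 2:
        raise ValueError("need subjects x channels x lags with >= 2 subjects")
    return _paired_t(A - B)


def _extract_clusters(t_map: np.ndarray, threshold: float,
                      nbr_pairs: np.ndarray, min_neighbors: int
                      ) -> list[tuple[list[tuple[int, int]], float]]:
    """Spatiotemporal clusters of suprathreshold same-sign samples.

    A sample enters a cluster only if at least ``min_neighbors`` adjacent
    channels are simultaneously suprathreshold with the same sign. Links:
    adjacent lags on one channel, neighboring channels at one lag.
    """
    C, L = t_map.shape
    out: list[tuple[list[tuple[int, int]], float]] = []
    for sign in (1.0, -1.0):
        mask = (sign * t_map) > threshold
        if not mask.any():
            continue
        if min_neighbors > 0:
            cnt = np.zeros((C, L), dtype=int)
            if nbr_pairs.size:
                i, j = nbr_pairs[:, 0], nbr_pairs[:, 1]
                np.add.at(cnt, i, mask[j].astype(int))
                np.add.at(cnt, j, mask[i].astype(int))
            keep = mask & (cnt >= min_neighbors)
        else:
            keep = mask
        if not keep.any():
            continue
        node_id = -np.ones((C, L), dtype=int)
        nodes = np.argwhere(keep)
        node_id[keep] = np.arange(nodes.shape[0])
        rows, cols = [], []
        # temporal links
        tmask = keep[:, :-1] & keep[:, 1:]
        for c, l in np.argwhere(tmask):
            rows.append(node_id[c, l])
            cols.append(node_id[c, l + 1])
        # spatial links
        if nbr_pairs.size:
            smask = keep[nbr_pairs[:, 0]] & keep[nbr_pairs[:, 1]]
            for p, l in np.argwhere(smask):
                rows.append(node_id[nbr_pairs[p, 0], l])
                cols.append(node_id[nbr_pairs[p, 1], l])
        n_nodes = nodes.shape[0]
        graph = coo_matrix((np.ones(len(rows)), (rows, cols)),
                           shape=(n_nodes, n_nodes))
        n_comp, labels = connected_components(graph, directed=False)
        for comp in range(n_comp):
            members = nodes[labels == comp]
            mass = float(t_map[members[:, 0], members[:, 1]].sum())
            out.append(([tuple(m) for m in members], mass))
    return out


def cluster_permutation_test(condA: np.ndarray, condB: np.ndarray,
                             adjacency: AdjacencyGraph,
                             config: PermutationConfig | None = None,
                             channel_names: Sequence[str] | None = None,
                             lag_grid: LagGrid | None = None
                             ) -> ClusterTestResult:
    """Cluster-based permutation test between two paired conditions.

    Clusters are formed from samples with two-sided p < sample_alpha; the
    null is the maximum absolute cluster mass over within-subject condition
    swaps (sign flips of paired differences). A cluster is significant when
    its absolute mass exceeds the null's 95th percentile.
    """
    if config is None:
        config = PermutationConfig()
    A = np.asarray(condA, dtype=float)
    B = np.asarray(condB, dtype=float)
    if A.shape != B.shape or A.ndim != 3:
        raise ValueError("conditions must be matching subjects x channels x lags")
    n, C, L = A.shape
    if channel_names is None:
        channel_names = adjacency.labels[:C]
    if len(channel_names) != C:
        raise ValueError(f"{len(channel_names)} names for {C} channels")
    missing = set(channel_names) - set(adjacency.labels)
    if missing:
        raise ValueError(f"adjacency does not cover channels {sorted(missing)}")
    nbr_pairs = adjacency.index_pairs(channel_names)

    diffs = (A - B).reshape(n, C * L)
    t_crit = float(sstats.t.ppf(1 - config.sample_alpha / 2, df=n - 1))
    t_obs = _paired_t(diffs).reshape(C, L)
    obs_clusters = _extract_clusters(t_obs, t_crit, nbr_pairs,
                                     config.min_neighbors)

    # permutation sign matrix: exact enumeration when feasible
    if 2 ** n < 6:
        warnings.warn(
            f"only {2 ** n} distinct sign patterns with n={n}; "
            "falling back to exact enumeration", stacklevel=2)
    if 2 ** n <= config.n_permutations:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(config.seed)
        signs = rng.choice([1.0, -1.0], size=(config.n_permutations, n))

    ssq = np.sum(diffs ** 2, axis=0)  # invariant under sign flips
    means = signs @ diffs / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ssq[None, :] - n * means ** 2) / (n - 1)
        t_perm = means * np.sqrt(n) / np.sqrt(var)
        t_perm = np.where(var <= 0, np.where(means == 0, 0.0,
                                             np.sign(means) * np.inf), t_perm)

    null_max = np.zeros(signs.shape[0])
    for p in range(signs.shape[0]):
        clusters = _extract_clusters(t_perm[p].reshape(C, L), t_crit,
                                     nbr_pairs, config.min_neighbors)
        if clusters:
            null_max[p] = max(abs(mass) for _, mass in clusters)

    # infinite masses (zero-variance degeneracies) break quantile
    # interpolation; clipping keeps order statistics and comparisons intact
    big = 1e300
    null_max = np.minimum(null_max, big)
    cutoff = float(np.quantile(null_max, 1 - config.cluster_alpha))
    n_perm = signs.shape[0]
    result_clusters = []
    for members, mass in obs_clusters:
        m = min(abs(mass), big)
        p_val = (1 + np.sum(null_max >= m)) / (1 + n_perm)
        result_clusters.append(Cluster(
            members=tuple(members), mass=mass, p_value=float(p_val),
            significant=bool(m > cutoff),
        ))
    return ClusterTestResult(
        clusters=tuple(result_clusters), t_map=t_obs, threshold=t_crit,
        null_max_mass=null_max, channel_names=tuple(channel_names),
        lag_grid=lag_grid,
    )


def bonferroni_channel_tests(mapA: np.ndarray, mapB: np.ndarray,
                             N: int | None = None
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired t per channel with Bonferroni correction.

    Inputs are subjects x channels arrays. Corrected p = min(1, raw p * N)
    where N defaults to the channel count; significance at 0.05.
    Returns (t, corrected p, significance mask).
    """
    A = np.asarray(mapA, dtype=float)
    B = np.asarray(mapB, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("inputs must be matching subjects x channels")
    if N is None:
        N = A.shape[1]
    if N <= 0:
        raise ValueError("N must be positive")
    n = A.shape[0]
    t = _paired_t(A - B)
    raw_p = 2 * sstats.t.sf(np.abs(t), df=n - 1)
    raw_p = np.where(np.isinf(t), 0.0, raw_p)
    corrected = np.minimum(1.0, raw_p * N)
    return t, corrected, corrected < 0.05


@dataclass(frozen=True)
class ChanceLevelSpec:
    """Exact-binomial above-chance threshold parameters."""

    n: int = 30
    c: int = 2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.c < 2:
            raise ValueError("c must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def empirical_chance_level(spec: ChanceLevelSpec) -> float:
    """Smallest k with Binomial(n, 1/c) CDF(k) >= 1 - alpha, as 100*k/n."""
    k = int(sstats.binom.ppf(1 - spec.alpha, spec.n, 1.0 / spec.c))
    return 100.0 * k / spec.n


def paired_behavioral_test(accA: np.ndarray, accB: np.ndarray
                           ) -> tuple[float, float]:
    """Two-tailed paired t-test on per-subject accuracies; returns (t, p)."""
    a = np.asarray(accA, dtype=float)
    b = np.asarray(accB, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need matching 1-D accuracy vectors with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() * np.sqrt(n) / sd
    p = 2 * sstats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
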