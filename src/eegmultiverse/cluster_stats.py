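"""Group-level quantification of decoding time series.

The central statistic is the one-tailed, one-sample sign-flip permutation
cluster mass test: each participant's decoding accuracy time series is
centered at chance (0.5), per-time-point one-sample t statistics are computed
across participants, maximal contiguous supra-threshold runs form clusters,
and the cluster T-sums are compared against a Monte-Carlo null built by
randomly flipping each participant's centered series by +-1.  The maximum
cluster T-sum per permutation yields family-wise error control; clusters in
the top ``fwer_alpha`` quantile of that null are retained.  The total T-sum
over significant clusters is the per-forking-path decoding-performance
metric.

A threshold-free cluster enhancement (TFCE) alternative integrates cluster
extent and height over all forming thresholds instead of fixing one; its
per-time-point values are summed to a TFCE-sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ClusterTestConfig", "Cluster", "ClusterTestResult",
    "cluster_mass_test", "tfce_sum", "detect_baseline_artifact",
    "average_accuracy_metric",
]


@dataclass
class ClusterTestConfig:
    cluster_alpha: float = 0.05    # cluster-forming threshold (one-tailed p)
    n_permutations: int = 1024
    fwer_alpha: float = 0.05
    chance: float = 0.5
    t_clip: float = 100.0          # cap on |t|; guards sd ~ 0 blow-ups
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.cluster_alpha, self.fwer_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class Cluster:
    start_time: float
    end_time: float
    start_index: int
    end_index: int          # inclusive
    t_sum: float
    p_value: float = 1.0


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    significant_clusters: list[Cluster]
    total_t_sum: float
    t_values: np.ndarray
    times: np.ndarray
    threshold: float
    permutation_max_distribution: np.ndarray = field(
        default_factory=lambda: np.empty(0))

    def to_json(self, path=None) -> str:
        payload = {
            "threshold": self.threshold,
            "total_t_sum": self.total_t_sum,
            "clusters": [
                {"start_time": c.start_time, "end_time": c.end_time,
                 "t_sum": c.t_sum, "p_value": c.p_value,
                 "significant": c in self.significant_clusters}
                for c in self.clusters],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    """One-sample t across axis 0 against zero; zero-variance -> t = 0."""
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def _find_clusters(t: np.ndarray, threshold: float):
    """Maximal contiguous runs with t > threshold: (start, stop, t_sum)."""
    above = t > threshold
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    return [(int(a), int(b), float(t[a:b].sum()))
            for a, b in zip(starts, stops)]


def _max_cluster_sums(tmat: np.ndarray, threshold: float) -> np.ndarray:
    """Row-wise maximum cluster T-sum of a (B, T) matrix of t series.

    Rows without any supra-threshold point contribute 0.  Vectorised over
    rows via a flattened run-length encoding with sentinel gaps.
    """
    B, T = tmat.shape
    mask = tmat > threshold
    padded = np.zeros((B, T + 1), dtype=bool)
    padded[:, :T] = mask
    flat_mask = padded.ravel()
    flat_t = np.zeros(B * (T + 1))
    flat_t.reshape(B, T + 1)[:, :T] = np.where(mask, tmat, 0.0)
    d = np.diff(flat_mask.astype(np.int8), prepend=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    out = np.zeros(B)
    if starts.size:
        csum = np.concatenate([[0.0], np.cumsum(flat_t)])
        sums = csum[stops] - csum[starts]
        rows = starts // (T + 1)
        np.maximum.at(out, rows, sums)
    return out


def cluster_mass_test(accuracies: np.ndarray, times: np.ndarray,
                      config: ClusterTestConfig) -> ClusterTestResult:
    """One-tailed one-sample sign-flip permutation cluster mass test.

    ``accuracies``: (n_participants, n_times) stack of decoding time series
    on a common time axis.  Each series is centered by subtracting the chance
    level; clusters are formed where the group t exceeds the one-tailed
    critical value at ``cluster_alpha`` (df = n - 1); the Monte-Carlo null
    flips each participant's centered series by +-1.  Cluster p-values use
    the (b + 1) / (B + 1) convention; clusters with p <= ``fwer_alpha`` are
    retained.  Deterministic given ``config.seed``.
    """
    X = np.asarray(accuracies, dtype=float) - config.chance
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (n_participants >= 2, n_times) stack")
    times = np.asarray(times, dtype=float)
    n, T = X.shape
    threshold = float(stats.t.ppf(1 - config.cluster_alpha, df=n - 1))
    # clipping |t| is an order-preserving transform applied identically to
    # the observed and permuted statistics, so the permutation test remains
    # exact while tiny across-participant variances cannot blow up T-sums
    t_obs = np.clip(_t_one_sample(X), -config.t_clip, config.t_clip)
    raw = _find_clusters(t_obs, threshold)
    clusters = [Cluster(start_time=float(times[a]), end_time=float(times[b - 1]),
                        start_index=a, end_index=b - 1, t_sum=s)
                for a, b, s in raw]

    B = config.n_permutations
    rng = np.random.default_rng(config.seed)
    signs = rng.choice([-1.0, 1.0], size=(B, n))
    # under sign flips the per-participant squares are unchanged, so the
    # permuted t series follows from the flipped means and the fixed SSQ
    ssq = (X ** 2).sum(axis=0)
    m = signs @ X / n
    var = (ssq / n - m ** 2) * (n / (n - 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(var > 0, m / np.sqrt(var / n), 0.0)
    t_perm = np.clip(t_perm, -config.t_clip, config.t_clip)
    null_max = _max_cluster_sums(t_perm, threshold)

    significant = []
    for c in clusters:
        # identity flips rebuild the observed statistic through different
        # float arithmetic; a relative tolerance keeps ">=" exact
        tol = 1e-9 * max(1.0, abs(c.t_sum))
        b = int((null_max >= c.t_sum - tol).sum())
        c.p_value = (b + 1.0) / (B + 1.0)
        if c.p_value <= config.fwer_alpha:
            significant.append(c)
    total = float(sum(c.t_sum for c in significant))
    return ClusterTestResult(clusters=clusters,
                             significant_clusters=significant,
                             total_t_sum=total, t_values=t_obs, times=times,
                             threshold=threshold,
                             permutation_max_distribution=null_max)


def tfce_sum(accuracies: np.ndarray, times: np.ndarray,
             chance: float = 0.5, E: float = 0.5, H: float = 2.0,
             dh: float = 0.1, t_clip: float = 100.0) -> float:
    """Threshold-free cluster enhancement sum of the group t series.

    Each time point's TFCE value integrates ``extent^E * h^H * dh`` over all
    forming heights ``h`` below its t value (one-tailed, positive heights
    only); the values are summed over time points.  t values are clipped at
    ``t_clip`` so near-zero across-participant variance (t -> inf) cannot
    blow up the height grid.
    """
    X = np.asarray(accuracies, dtype=float) - chance
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (n_participants >= 2, n_times) stack")
    t = np.clip(_t_one_sample(X), None, t_clip)
    tmax = t.max()
    if tmax <= 0:
        return 0.0
    heights = np.arange(dh, tmax + dh, dh)
    tfce = np.zeros_like(t)
    for h in heights:
        for a, b, _ in _find_clusters(t, h - 1e-12):
            tfce[a:b] += (b - a) ** E * h ** H * dh
    return float(tfce.sum())


def detect_baseline_artifact(result: ClusterTestResult,
                             baseline_boundary: float = 0.0) -> bool:
    """True iff any significant cluster extends into the baseline period,
    i.e. starts at or before ``baseline_boundary`` (seconds; use a negative
    boundary for response-locked designs such as pre-response windows)."""
    return any(c.start_time <= baseline_boundary
               for c in result.significant_clusters)


def average_accuracy_metric(accuracy: np.ndarray, times: np.ndarray,
                            post_baseline_start: float) -> float:
    """Mean accuracy over time points strictly after the baseline boundary."""
    times = np.asarray(times, dtype=float)
    mask = times > post_baseline_start
    if not mask.any():
        raise ValueError("no time points after the baseline boundary")
    return float(np.asarray(accuracy, dtype=float)[..., mask].mean())
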