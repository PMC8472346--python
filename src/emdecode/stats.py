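"""Group-level inference on per-participant effect time series.

The tested quantity is one number per participant per timepoint —
typically chance-centred decoding accuracy (AUC - 0.5).  Three tools are
provided: pointwise one-sample t statistics, Bonferroni adjustment, and
the cluster-based sign-flip permutation test.  The permutation scheme
negates each participant's entire series with probability 1/2, the
exchangeability argument appropriate to a one-sample design: under the
null the per-participant effect is symmetric about zero, so cluster
masses of the observed map are compared with the distribution of the
maximal cluster mass over resigned cohorts, controlling the family-wise
error over timepoints without a multiplicity penalty per bin.

P-values use the (b + 1) / (n_perm + 1) convention, so the smallest
attainable p is 1/(n_perm + 1) — 0.000999 at 1000 permutations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Cluster", "ClusterResult", "one_sample_t", "bonferroni", "cluster_permutation"]


@dataclass(frozen=True)
class Cluster:
    start: int  # first sample index in the cluster
    end: int  # last sample index (inclusive)
    start_ms: float
    end_ms: float
    mass: float  # summed t over the cluster
    p: float

    @property
    def significant_at(self):  # convenience for table building
        return self.p


@dataclass
class ClusterResult:
    """Clusters of supra-threshold group t values with permutation p-values."""

    clusters: list[Cluster]
    t_series: np.ndarray
    t_thresh: float
    n_perm: int
    alpha: float
    tail: str
    seed: int
    times: np.ndarray | None = None  # ms
    meta: dict = field(default_factory=dict)

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha]

    def summary(self) -> str:
        lines = [
            f"cluster permutation: t_thresh={self.t_thresh}, n_perm={self.n_perm}, "
            f"alpha={self.alpha}, tail={self.tail}",
            f"{'start_ms':>9} {'end_ms':>9} {'mass':>10} {'p':>8}  sig",
        ]
        for c in self.clusters:
            lines.append(
                f"{c.start_ms:9.1f} {c.end_ms:9.1f} {c.mass:10.2f} {c.p:8.4f}  "
                f"{'*' if c.p < self.alpha else ''}"
            )
        if not self.clusters:
            lines.append("  (no supra-threshold clusters)")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": {
                "t_thresh": self.t_thresh,
                "n_perm": self.n_perm,
                "alpha": self.alpha,
                "tail": self.tail,
                "seed": self.seed,
            },
            "clusters": [
                {
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "mass": c.mass,
                    "p": c.p,
                    "significant": c.p < self.alpha,
                }
                for c in self.clusters
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def one_sample_t(effect: np.ndarray, mu0: float = 0.0) -> np.ndarray:
    """Pointwise one-sample t statistic, df = n_participants - 1.

    Timepoints with zero across-participant variance get +/-inf (sign of
    the mean difference) with a warning, and t=0 when the mean also
    equals ``mu0``.
    """
    x = np.atleast_2d(np.asarray(effect, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning("%d timepoints have zero variance; t set to +/-inf", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - mu0) / (sd / np.sqrt(n))
        t[zero] = np.where(mean[zero] == mu0, 0.0, np.sign(mean[zero] - mu0) * np.inf)
    return t


def bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m*p) elementwise."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


def _cluster_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of True, as (start, end_inclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    return [(int(idx[i]), int(idx[i + 1] - 1)) for i in range(0, len(idx), 2)]


def _max_cluster_masses(t_maps: np.ndarray, thresh: float, tail: str) -> np.ndarray:
    """Maximal cluster mass per row of a (n_maps, n_timepoints) t array.

    Vectorized over maps: per-row cumulative sums of thresholded |t| or t
    are segmented at run boundaries.
    """
    if tail == "two":
        score = np.abs(t_maps)
    else:
        score = t_maps
    above = score > thresh
    masses = np.zeros(t_maps.shape[0])
    vals = np.where(above, score, 0.0)
    # per-row scan; n_timepoints is small so a python loop over runs is fine,
    # but loop over rows in numpy via split indices
    for i in range(t_maps.shape[0]):
        best = 0.0
        for s, e in _cluster_runs(above[i]):
            m = vals[i, s : e + 1].sum()
            if m > best:
                best = m
        masses[i] = best
    return masses


def cluster_permutation(
    effect: np.ndarray,
    t_thresh: float = 2.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    tail: str = "one",
    seed: int = 0,
    mu0: float = 0.0,
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test on participants x timepoints.

    Observed clusters are maximal runs where t > ``t_thresh`` (one-tailed;
    |t| for two-tailed), scored by their summed t.  The null distribution
    is the maximal cluster mass over cohorts whose participant series are
    independently sign-flipped about ``mu0``.  Temporal adjacency only.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    x = np.atleast_2d(np.asarray(effect, dtype=float)) - mu0
    n_part, n_time = x.shape
    if n_part < 2:
        raise ValueError("need at least 2 participants")

    t_obs = one_sample_t(x, 0.0)
    score = np.abs(t_obs) if tail == "two" else t_obs
    runs = _cluster_runs(score > t_thresh)
    obs_masses = np.array([score[s : e + 1].sum() for s, e in runs])

    # vectorized sign-flip null: t for all permutations at once
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_part))
    m = signs @ x / n_part  # permuted means (flips leave x^2 unchanged)
    ssq = np.sum(x**2, axis=0)
    var = (ssq - n_part * m**2) / (n_part - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = m / np.sqrt(var / n_part)
    t_null = np.nan_to_num(t_null, nan=0.0, posinf=np.inf, neginf=-np.inf)
    null_max = _max_cluster_masses(t_null, t_thresh, tail)

    if times is None:
        times = np.arange(n_time, dtype=float)
    clusters = []
    for (s, e), mass in zip(runs, obs_masses):
        p = (1.0 + np.sum(null_max >= mass)) / (n_perm + 1.0)
        clusters.append(
            Cluster(
                start=s,
                end=e,
                start_ms=float(times[s]),
                end_ms=float(times[e]),
                mass=float(mass),
                p=float(p),
            )
        )
    return ClusterResult(
        clusters=clusters,
        t_series=t_obs,
        t_thresh=t_thresh,
        n_perm=n_perm,
        alpha=alpha,
        tail=tail,
        seed=seed,
        times=np.asarray(times, dtype=float),
    )
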