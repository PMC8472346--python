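"""L2 minimum-norm source estimation with dSPM noise normalization.

Given a lead field G (sensors x sources) and a noise covariance C, the
minimum-norm inverse kernel is

    M = R G' (G R G' + lambda^2 C)^{-1}

with source covariance R = I (fixed orientation, no depth weighting).
dSPM divides each source estimate by its noise sensitivity
sqrt((M C M')_jj), giving noise-normalized (z-like) activation: applying
the inverse to noise drawn from C yields unit variance per source.

The module is anatomical-model agnostic: it accepts any gain matrix,
whether from the bundled toy geometry or an externally computed forward
solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import Epochs
from .synth import LeadField

__all__ = [
    "NoiseCovariance",
    "InverseOperator",
    "SourceEstimate",
    "ROISet",
    "estimate_noise_cov",
    "make_inverse",
    "apply_inverse",
    "roi_timecourse",
]


@dataclass
class NoiseCovariance:
    cov: np.ndarray
    n_samples_used: int
    regularization: float = 0.0

    def __post_init__(self):
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-10 * np.abs(self.cov).max():
            raise ValueError("covariance must be positive semidefinite")


@dataclass
class InverseOperator:
    kernel: np.ndarray  # sources x sensors
    dspm_norm: np.ndarray  # per-source noise sensitivity, > 0
    lambda2: float
    source_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel must be finite")
        if np.any(self.dspm_norm <= 0):
            raise ValueError("dspm_norm must be strictly positive")


@dataclass
class SourceEstimate:
    """Sources x timepoints activity (dSPM units when normalized)."""

    data: np.ndarray
    source_labels: list[str]
    fs: float
    tmin: float  # ms
    dspm: bool = False

    @property
    def times(self) -> np.ndarray:
        return self.tmin + 1000.0 * np.arange(self.data.shape[-1]) / self.fs


@dataclass
class ROISet:
    """Named groups of source indices (e.g. fusiform-lh -> {0, 3})."""

    rois: dict[str, list[int]]

    def validate(self, n_sources: int) -> None:
        for name, idx in self.rois.items():
            if not idx:
                raise ValueError(f"ROI {name} is empty")
            if min(idx) < 0 or max(idx) >= n_sources:
                raise ValueError(f"ROI {name} has out-of-range source indices")


def estimate_noise_cov(
    noise_segments: np.ndarray, shrinkage: float = 0.1
) -> NoiseCovariance:
    """Empirical sensor covariance of noise epochs, shrunk toward its diagonal.

    ``noise_segments`` is (segments, channels, samples); segments are
    concatenated in time.  Shrinkage weight w gives (1-w) C + w diag(C).
    """
    x = np.asarray(noise_segments, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need at least 2 noise segments (segments x channels x samples)")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must lie in [0, 1]")
    flat = np.concatenate([seg for seg in x], axis=-1)  # channels x total samples
    flat = flat - flat.mean(axis=-1, keepdims=True)
    n = flat.shape[-1]
    c = flat @ flat.T / (n - 1)
    c = (1 - shrinkage) * c + shrinkage * np.diag(np.diag(c))
    if shrinkage == 0 and np.linalg.matrix_rank(c) < c.shape[0]:
        import warnings

        warnings.warn("noise covariance is rank deficient and unshrunk", stacklevel=2)
    return NoiseCovariance(cov=c, n_samples_used=n, regularization=shrinkage)


def make_inverse(
    lead_field: LeadField | np.ndarray,
    noise_cov: NoiseCovariance | np.ndarray,
    lambda2: float = 1.0 / 9.0,
) -> InverseOperator:
    """Build the minimum-norm kernel and its dSPM normalization.

    ``lambda2`` is the regularization weight on the noise covariance; the
    default 1/9 corresponds to the usual assumed power SNR of 3.
    """
    if isinstance(lead_field, LeadField):
        g = lead_field.gain
        labels = list(lead_field.source_labels)
    else:
        g = np.asarray(lead_field, dtype=float)
        labels = [f"src{j}" for j in range(g.shape[1])]
    c = noise_cov.cov if isinstance(noise_cov, NoiseCovariance) else np.asarray(noise_cov)
    if g.shape[0] != c.shape[0]:
        raise ValueError("lead field and covariance sensor dimensions differ")
    if lambda2 < 0:
        raise ValueError("lambda2 must be >= 0")
    a = g @ g.T + lambda2 * c
    cond = np.linalg.cond(a)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"(G G' + lambda2 C) is numerically singular (cond={cond:.2e}); "
            "use lambda2 > 0"
        )
    kernel = g.T @ np.linalg.inv(a)
    dspm_norm = np.sqrt(np.einsum("ij,jk,ik->i", kernel, c, kernel))
    dspm_norm = np.maximum(dspm_norm, np.finfo(float).tiny)
    return InverseOperator(kernel=kernel, dspm_norm=dspm_norm, lambda2=lambda2,
                           source_labels=labels)


def apply_inverse(
    data: Epochs | np.ndarray,
    inv: InverseOperator,
    dspm: bool = True,
    fs: float | None = None,
    tmin: float = 0.0,
) -> SourceEstimate | list[SourceEstimate]:
    """Project sensor data to source space: s(t) = M x(t).

    Accepts an evoked array (channels x samples) or Epochs, in which
    case the inverse is applied per trial and a list of estimates is
    returned ("single-trial" source activity).
    """
    n_sens = inv.kernel.shape[1]

    def _one(x: np.ndarray) -> np.ndarray:
        if x.shape[0] != n_sens:
            raise ValueError(
                f"channel mismatch: data has {x.shape[0]} channels, kernel expects {n_sens}"
            )
        s = inv.kernel @ x
        if dspm:
            s = s / inv.dspm_norm[:, None]
        return s

    if isinstance(data, Epochs):
        return [
            SourceEstimate(_one(trial), inv.source_labels, data.fs, data.tmin, dspm)
            for trial in data.data
        ]
    x = np.asarray(data, dtype=float)
    return SourceEstimate(_one(x), inv.source_labels, fs or float("nan"), tmin, dspm)


def roi_timecourse(
    stc: SourceEstimate, rois: ROISet, reduce: str = "mean"
) -> dict[str, np.ndarray]:
    """Per-ROI reduction over member sources at each timepoint.

    ``reduce='mean'`` averages signed traces (cancels opposed
    orientations); ``'abs-mean'`` averages magnitudes.
    """
    rois.validate(stc.data.shape[0])
    out = {}
    for name, idx in rois.rois.items():
        block = stc.data[idx]
        out[name] = np.abs(block).mean(axis=0) if reduce == "abs-mean" else block.mean(axis=0)
    return out
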