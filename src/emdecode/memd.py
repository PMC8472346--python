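"""Empirical mode decomposition with masking signals.

Single-channel EMD splits a time series into intrinsic mode functions
(IMFs) by iterative "sifting": cubic-spline envelopes are drawn through
the local maxima and minima, and the envelope mean is subtracted until
the result oscillates around zero.  Masking EMD adds a sinusoidal mask
before sifting and averages the extracted mode over several mask phases,
which steers each IMF toward a target frequency band and suppresses mode
mixing (contamination of one IMF by oscillations of widely different
time scales).

The decomposition is complete by construction: the sum of all IMFs plus
the residual trend reconstructs the input to floating-point accuracy.

IMF numbering is 1-based throughout (IMF 1 = highest-frequency mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "IMFSet",
    "MaskConfig",
    "SiftConfig",
    "sift",
    "emd",
    "masking_emd",
    "decompose_epochs",
    "count_extrema_zero_crossings",
]


# ---------------------------------------------------------------------------
# containers / configs


@dataclass
class SiftConfig:
    """Stop criterion for the sifting loop.

    ``s_number``: stop once the numbers of extrema and zero crossings have
    been unchanged (and differ by at most one) for this many consecutive
    sifting iterations.  ``max_sifts`` bounds the loop unconditionally.
    ``criterion='cauchy'`` instead stops when the normalized squared
    change between consecutive sifts drops below ``cauchy_sd``.
    """

    criterion: Literal["s_number", "cauchy"] = "s_number"
    s_number: int = 4
    max_sifts: int = 100
    cauchy_sd: float = 0.2


@dataclass
class MaskConfig:
    """Mask schedule for masking EMD.

    ``schedule='dyadic'`` places the mask for mode *k* at ``fs / 2**(k+1)``
    (50, 25, 12.5, ... Hz at fs=200), halving per mode, which yields a
    dyadic filter bank.  ``schedule='adaptive'`` sets the mask from the
    mean instantaneous frequency of the previously extracted mode.
    Mask amplitude is ``amp_sd_factor`` times the standard deviation of
    the current working signal; the mode is averaged over ``n_phases``
    equally spaced mask phases (the mask itself cancels in the average).
    """

    schedule: Literal["dyadic", "adaptive"] = "dyadic"
    amp_sd_factor: float = 2.0
    n_phases: int = 4

    def frequency(self, k: int, fs: float, prev_mean_freq: float | None = None) -> float:
        if self.schedule == "adaptive" and prev_mean_freq is not None:
            return prev_mean_freq / 2.0
        return fs / 2.0 ** (k + 1)


@dataclass
class IMFSet:
    """Stack of IMFs plus the residual trend for one signal.

    ``imfs`` has shape (n_imfs, n_samples) with IMF 1 (highest frequency)
    in row 0; the residual is whatever remains after the oscillatory
    modes are removed, so ``imfs.sum(0) + residual`` equals the input.
    """

    imfs: np.ndarray
    residual: np.ndarray
    fs: float
    source_meta: dict = field(default_factory=dict)

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual

    def imf(self, k: int) -> np.ndarray:
        """Return IMF ``k`` (1-based)."""
        if not 1 <= k <= self.n_imfs:
            raise IndexError(f"IMF index {k} out of range 1..{self.n_imfs}")
        return self.imfs[k - 1]


# ---------------------------------------------------------------------------
# extrema bookkeeping


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints count once)."""
    dx = np.diff(x)
    # collapse flat segments: carry the sign of the last nonzero slope
    sign = np.sign(dx)
    nz = sign != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    # forward-fill zero signs so plateaus inherit the preceding slope
    idx = np.where(nz, np.arange(len(sign)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, sign[np.maximum(idx, 0)], 0)
    turn = np.diff(filled)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def count_extrema_zero_crossings(x: np.ndarray) -> tuple[int, int]:
    """(#extrema, #zero crossings) over the interior of ``x``."""
    maxima, minima = _local_extrema(x)
    return maxima.size + minima.size, _zero_crossings(x)


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray, n: int, sign: float) -> np.ndarray:
    """Natural cubic spline through extrema, mirroring two edge extrema.

    The first/last two extremum positions are reflected about the signal
    endpoints (sample 0 and n-1) so the spline is anchored beyond the
    data and edge swings are damped.  ``sign`` is +1 for the upper
    (maxima) envelope and -1 for the lower.
    """
    k = min(2, idx.size)
    left = -idx[:k][::-1]
    right = 2 * (n - 1) - idx[-k:][::-1]
    pos = np.concatenate([left, idx, right])
    val = np.concatenate([x[idx[:k]][::-1], x[idx], x[idx[-k:]][::-1]])
    # clamp to the endpoints when they exceed the mirrored anchors, so the
    # envelope never fails to bound the signal at the record edges
    if sign * x[0] > sign * val[pos == left[-1]][0] and 0 not in pos:
        pos = np.concatenate([[0], pos])
        val = np.concatenate([[x[0]], val])
    if sign * x[-1] > sign * val[pos == right[0]][0] and (n - 1) not in pos:
        pos = np.concatenate([pos, [n - 1]])
        val = np.concatenate([val, [x[-1]]])
    order = np.argsort(pos)
    pos, val = pos[order], val[order]
    pos, keep = np.unique(pos, return_index=True)
    spline = CubicSpline(pos, val[keep], bc_type="natural")
    return spline(np.arange(n))


# ---------------------------------------------------------------------------
# sifting


def sift(x: np.ndarray, stop: SiftConfig | None = None) -> tuple[np.ndarray, bool]:
    """Extract the first IMF of ``x`` by envelope-mean sifting.

    Returns ``(mode, monotone)``.  If the signal has fewer than two maxima
    or two minima there is nothing to sift: the input is returned
    unchanged with ``monotone=True`` and should be treated as a residual
    trend, not an oscillatory mode.
    """
    return _sift(x, stop, min_per_side=2)


def _sift(
    x: np.ndarray, stop: SiftConfig | None, min_per_side: int
) -> tuple[np.ndarray, bool]:
    """Sifting loop; ``min_per_side`` is the extrema count below which the
    signal is declared a trend.  The relaxed setting (1) lets the mirrored
    edge extrema anchor the envelope splines, which is needed to extract
    oscillations with barely more than one cycle in the record."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        return x.copy(), True
    if not np.all(np.isfinite(x)):
        raise ValueError("sift requires finite input")
    stop = stop or SiftConfig()

    h = x.copy()
    n = x.size
    stable = 0
    prev_counts: tuple[int, int] | None = None
    for _ in range(stop.max_sifts):
        maxima, minima = _local_extrema(h)
        if maxima.size < min_per_side or minima.size < min_per_side:
            return x.copy(), True
        upper = _mirrored_envelope(h, maxima, n, +1.0)
        lower = _mirrored_envelope(h, minima, n, -1.0)
        mean = 0.5 * (upper + lower)
        h_new = h - mean

        if stop.criterion == "cauchy":
            denom = np.sum(h**2)
            sd = np.sum(mean**2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < stop.cauchy_sd:
                break
        else:
            n_ext = maxima.size + minima.size
            n_zc = _zero_crossings(h_new)
            counts = (n_ext, n_zc)
            if abs(n_ext - n_zc) <= 1 and counts == prev_counts:
                stable += 1
            else:
                stable = 0
            prev_counts = counts
            h = h_new
            if stable >= stop.s_number:
                break
    return h, False


# ---------------------------------------------------------------------------
# decompositions


def emd(x: np.ndarray, n_imfs: int = 8, stop: SiftConfig | None = None) -> IMFSet:
    """Plain EMD: repeatedly sift and subtract.

    Extracts at most ``n_imfs - 1`` oscillatory modes; the remainder is
    stored as the residual trend.  Stops early when the remainder is
    monotone (fewer than two maxima or minima).
    """
    x = np.asarray(x, dtype=float)
    working = x.copy()
    modes: list[np.ndarray] = []
    for _ in range(n_imfs - 1):
        mode, monotone = sift(working, stop)
        if monotone:
            break
        modes.append(mode)
        working = working - mode
    imfs = np.array(modes) if modes else np.empty((0, x.size))
    return IMFSet(imfs=imfs, residual=working, fs=float("nan"))


def masking_emd(
    x: np.ndarray,
    fs: float,
    n_imfs: int = 8,
    mask: MaskConfig | None = None,
    stop: SiftConfig | None = None,
) -> IMFSet:
    """Masking EMD of a single signal.

    For each mode k a sinusoidal mask at the schedule frequency is added
    at ``n_phases`` phases; each masked signal is sifted, the extracted
    modes are averaged (the mask cancels exactly across opposite phases),
    the average is subtracted, and the procedure recurses on the
    remainder.  The mask pins the local-extrema density, so slow
    oscillations cannot leak into fast modes (mode-mixing suppression).
    """
    x = np.asarray(x, dtype=float)
    mask = mask or MaskConfig()
    if fs <= 0:
        raise ValueError("fs must be positive")
    working = x.copy()
    t = np.arange(x.size) / fs
    phases = 2 * np.pi * np.arange(mask.n_phases) / mask.n_phases
    modes: list[np.ndarray] = []
    prev_mean_freq: float | None = None
    for k in range(1, n_imfs):
        f_mask = mask.frequency(k, fs, prev_mean_freq)
        if f_mask >= fs / 2:
            raise ValueError(f"mask frequency {f_mask} Hz >= Nyquist ({fs / 2} Hz)")
        amp = mask.amp_sd_factor * np.std(working)
        if amp == 0:
            break
        if f_mask * x.size / fs < 2.0:
            # fewer than two mask periods fit the record: the mask cannot
            # steer anything at this depth, and oscillations this slow
            # cannot mode-mix with faster ones -- plain sifting with relaxed
            # edge handling (mirrored extrema anchor the envelopes) suffices
            mode_k, monotone = _sift(working, stop, min_per_side=1)
            if monotone:
                break
        else:
            # stop if any masked variant cannot be sifted: a partial phase
            # average would leave mask residue in the mode
            acc = np.zeros_like(working)
            ok = True
            for phi in phases:
                m = amp * np.cos(2 * np.pi * f_mask * t + phi)
                mode, monotone = sift(working + m, stop)
                if monotone:
                    ok = False
                    break
                acc += mode
            if not ok:
                break
            mode_k = acc / mask.n_phases
        # the phase average of four sifted modes is no longer a strict IMF
        # (ripples appear where the variants disagree), and the slow-mode
        # fallback can inherit such ripple from earlier subtractions;
        # re-sift until the extrema/zero-crossing property holds, which
        # does not undo the mask's band steering
        for _ in range(10):
            n_ext, n_zc = count_extrema_zero_crossings(mode_k)
            if abs(n_ext - n_zc) <= 1:
                break
            polished, monotone = sift(mode_k, stop)
            if monotone:
                break
            mode_k = polished
        modes.append(mode_k)
        working = working - mode_k
        if mask.schedule == "adaptive":
            prev_mean_freq = _mean_frequency(mode_k, fs) or f_mask / 2
    imfs = np.array(modes) if modes else np.empty((0, x.size))
    return IMFSet(imfs=imfs, residual=working, fs=fs)


def _mean_frequency(mode: np.ndarray, fs: float) -> float | None:
    """Crude mean frequency from the zero-crossing rate."""
    zc = _zero_crossings(mode)
    dur = mode.size / fs
    return (zc / 2) / dur if dur > 0 and zc > 0 else None


def decompose_epochs(
    epochs,
    n_imfs: int = 8,
    drop_residual: bool = True,
    mask: MaskConfig | None = None,
    stop: SiftConfig | None = None,
    method: Literal["masking", "plain"] = "masking",
):
    """Decompose every trial x channel of an Epochs object independently.

    Returns an array of shape (n_components, n_trials, n_channels,
    n_samples).  With ``drop_residual`` the residual trend (the last,
    non-oscillatory component) is excluded, giving ``n_imfs - 1``
    components; otherwise the residual is appended as the final
    component so the sum over components reconstructs the input.
    Signals that terminate early (monotone remainder) contribute
    zero-padded high-index modes; failures are logged and the affected
    trial flagged, never fatal.
    """
    data = epochs.data
    n_trials, n_channels, n_samples = data.shape
    n_comp = (n_imfs - 1) + (0 if drop_residual else 1)
    out = np.zeros((n_comp, n_trials, n_channels, n_samples))
    failed: list[tuple[int, int]] = []
    for i in range(n_trials):
        for j in range(n_channels):
            try:
                if method == "masking":
                    s = masking_emd(data[i, j], epochs.fs, n_imfs, mask, stop)
                else:
                    s = emd(data[i, j], n_imfs, stop)
            except Exception:  # pragma: no cover - defensive
                logger.exception("decomposition failed for trial %d channel %d", i, j)
                failed.append((i, j))
                continue
            k = min(s.n_imfs, n_imfs - 1)
            out[:k, i, j] = s.imfs[:k]
            if not drop_residual:
                out[-1, i, j] = s.residual + s.imfs[k:].sum(axis=0)
    if failed:
        logger.warning("%d trial/channel decompositions failed: %s", len(failed), failed)
    return out
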