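"""Translation-invariant wavelet denoising with the Donoho universal threshold.

The base denoiser T is a periodized orthogonal discrete wavelet transform
followed by thresholding of the detail coefficients at lambda =
sigma * sqrt(2 ln n) and inverse transform.  The translation-invariant
estimator averages shift-denoise-unshift over a family of circular shifts
(cycle spinning): Ave_h T(S_h) with S_h(t) = X(t + h).

The transform is implemented here directly (no wavelet library in the
runtime environment): one level computes a[k] = sum_m h[m] x[(2k+m) mod N]
and d[k] = sum_m g[m] x[(2k+m) mod N] with the quadrature-mirror highpass
g[m] = (-1)^m h[L-1-m]; the resulting N x N operator is orthogonal whenever
N is even and N >= L, so the inverse is its transpose.  Signals whose length
is not divisible by 2^level are periodically padded and truncated back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveletConfig",
    "ShiftFamily",
    "wavelet_filters",
    "dwt_periodic",
    "idwt_periodic",
    "wavedec_periodic",
    "waverec_periodic",
    "max_decomposition_level",
    "estimate_sigma",
    "universal_threshold",
    "denoise_once",
    "cycle_spin_denoise",
]

_SQRT3 = math.sqrt(3.0)
_Q = 4.0 * math.sqrt(2.0)

# Orthonormal scaling (lowpass analysis) filters, sum = sqrt(2).
_SCALING_FILTERS: dict[str, tuple[float, ...]] = {
    "haar": (1.0 / math.sqrt(2.0), 1.0 / math.sqrt(2.0)),
    "db2": ((1 + _SQRT3) / _Q, (3 + _SQRT3) / _Q,
            (3 - _SQRT3) / _Q, (1 - _SQRT3) / _Q),
    "db3": (0.3326705529509569, 0.8068915093133388, 0.4598775021193313,
            -0.13501102001039084, -0.08544127388224149, 0.035226291882100656),
    "db4": (0.23037781330885523, 0.7148465705525415, 0.6308807679295904,
            -0.02798376941698385, -0.18703481171888114, 0.030841381835986965,
            0.032883011666982945, -0.010597401784997278),
}
_SCALING_FILTERS["db1"] = _SCALING_FILTERS["haar"]


def wavelet_filters(family: str) -> tuple[np.ndarray, np.ndarray]:
    """Analysis (lowpass, highpass) filter pair for an orthonormal family."""
    try:
        h = np.asarray(_SCALING_FILTERS[family], dtype=float)
    except KeyError:
        raise ValueError(
            f"unknown wavelet family {family!r}; "
            f"available: {sorted(set(_SCALING_FILTERS))}") from None
    g = ((-1.0) ** np.arange(h.size)) * h[::-1]
    return h, g


@dataclass(frozen=True)
class ShiftFamily:
    """A set of circular shifts h with 0 <= h < n, no duplicates."""

    shifts: tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        if len(set(self.shifts)) != len(self.shifts):
            raise ValueError("duplicate shifts")
        if any(not 0 <= h < self.n for h in self.shifts):
            raise ValueError("shifts must lie in [0, n)")
        if not self.shifts:
            raise ValueError("shift family is empty")

    @classmethod
    def full(cls, n: int) -> "ShiftFamily":
        return cls(shifts=tuple(range(n)), n=n)

    @classmethod
    def evenly_spaced(cls, n: int, k: int) -> "ShiftFamily":
        if k > n:
            raise ValueError(f"n_shifts {k} exceeds signal length {n}")
        shifts = np.unique((np.arange(k) * n // k)).tolist()
        return cls(shifts=tuple(int(s) for s in shifts), n=n)


@dataclass(frozen=True)
class WaveletConfig:
    """Parameters of the base denoiser and its shift family."""

    family: str = "db4"
    decomposition_level: int | None = None  # None -> min(4, max feasible)
    threshold_mode: str = "soft"
    sigma_estimate: str = "mad"
    sigma: float | None = None
    n_shifts: int | None = None  # None -> min(n, 32); cycle-spin only

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError("threshold_mode must be 'soft' or 'hard'")
        if self.sigma_estimate not in ("mad", "provided"):
            raise ValueError("sigma_estimate must be 'mad' or 'provided'")
        if self.sigma_estimate == "provided" and self.sigma is None:
            raise ValueError("sigma_estimate='provided' requires sigma")
        if self.decomposition_level is not None and self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        wavelet_filters(self.family)  # validate family eagerly


def dwt_periodic(x: np.ndarray, family: str = "db4") -> tuple[np.ndarray, np.ndarray]:
    """One level of the periodized DWT; x must have even length >= filter."""
    x = np.asarray(x, dtype=float)
    h, g = wavelet_filters(family)
    n = x.size
    if n % 2 or n < h.size:
        raise ValueError(f"signal length {n} must be even and >= {h.size}")
    a = np.zeros(n // 2)
    d = np.zeros(n // 2)
    idx = np.arange(0, n, 2)
    for m in range(h.size):
        xm = x[(idx + m) % n]
        a += h[m] * xm
        d += g[m] * xm
    return a, d


def idwt_periodic(a: np.ndarray, d: np.ndarray, family: str = "db4") -> np.ndarray:
    """Inverse of :func:`dwt_periodic` (transpose of the orthogonal operator)."""
    h, g = wavelet_filters(family)
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    n = 2 * a.size
    x = np.zeros(n)
    idx = np.arange(0, n, 2)
    for m in range(h.size):
        np.add.at(x, (idx + m) % n, h[m] * a + g[m] * d)
    return x


def max_decomposition_level(n: int, family: str = "db4") -> int:
    """Deepest level for which every stage keeps even length >= filter length."""
    h, _ = wavelet_filters(family)
    level = 0
    while n % 2 == 0 and n >= h.size:
        level += 1
        n //= 2
    return level


def wavedec_periodic(x: np.ndarray, family: str, level: int) -> list[np.ndarray]:
    """Multilevel decomposition: [a_J, d_J, d_{J-1}, ..., d_1]."""
    maxlev = max_decomposition_level(len(x), family)
    if level > maxlev:
        raise ValueError(
            f"decomposition level {level} too deep for length {len(x)}; "
            f"max level is {maxlev}")
    coeffs: list[np.ndarray] = []
    a = np.asarray(x, dtype=float)
    for _ in range(level):
        a, d = dwt_periodic(a, family)
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]


def waverec_periodic(coeffs: list[np.ndarray], family: str) -> np.ndarray:
    a = coeffs[0]
    for d in coeffs[1:]:
        a = idwt_periodic(a, d, family)
    return a


def estimate_sigma(signal: np.ndarray, family: str = "db4") -> float:
    """Noise scale via the median absolute deviation of finest-scale details.

    sigma_hat = median(|d_1|) / 0.6745, exactly 0 for a constant signal.
    The details are taken undecimated (circular convolution with the
    highpass filter, no downsampling) so the estimate is exactly invariant
    under circular shifts of the input — required for the full-shift
    cycle-spinning estimator to commute with shifts.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples to estimate sigma")
    _, g = wavelet_filters(family)
    n = x.size
    d = np.zeros(n)
    idx = np.arange(n)
    for m in range(g.size):
        d += g[m] * x[(idx + m) % n]
    return float(np.median(np.abs(d)) / 0.6745)


def universal_threshold(sigma: float, n: int) -> float:
    """Donoho universal threshold lambda = sigma * sqrt(2 ln n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(sigma * math.sqrt(2.0 * math.log(n)))


def _padded_length(n: int, level: int, filt_len: int) -> int:
    block = 2 ** level
    target = max(n, filt_len * 2 ** (level - 1))
    return block * math.ceil(target / block)


def _shrink(d: np.ndarray, lam: float, mode: str) -> np.ndarray:
    if mode == "soft":
        return np.sign(d) * np.maximum(np.abs(d) - lam, 0.0)
    return np.where(np.abs(d) > lam, d, 0.0)


def _resolve(cfg: WaveletConfig, n: int) -> tuple[int, int]:
    h, _ = wavelet_filters(cfg.family)
    if cfg.decomposition_level is None:
        pad_probe = _padded_length(n, 1, h.size)
        level = min(4, max_decomposition_level(pad_probe, cfg.family))
        level = max(level, 1)
    else:
        level = cfg.decomposition_level
    return level, h.size


def denoise_once(signal: np.ndarray, cfg: WaveletConfig | None = None) -> np.ndarray:
    """Single-pass wavelet shrinkage denoiser (the base estimator T).

    Decompose, threshold every detail band at the universal threshold
    (soft by default), reconstruct.  Output length equals input length;
    periodic padding is applied transparently when the length is not a
    multiple of 2**level.
    """
    if cfg is None:
        cfg = WaveletConfig()
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("signal too short to denoise")
    level, filt_len = _resolve(cfg, n)
    if 2 ** level > n:
        raise ValueError(
            f"decomposition level {level} too deep for length {n}; "
            f"max level is {int(math.floor(math.log2(n)))}")
    n_pad = _padded_length(n, level, filt_len)
    xp = np.pad(x, (0, n_pad - n), mode="wrap")

    if cfg.sigma_estimate == "provided":
        sigma = float(cfg.sigma)
    else:
        sigma = estimate_sigma(x, cfg.family)
    lam = universal_threshold(sigma, n)

    coeffs = wavedec_periodic(xp, cfg.family, level)
    out = [coeffs[0]] + [_shrink(d, lam, cfg.threshold_mode) for d in coeffs[1:]]
    return waverec_periodic(out, cfg.family)[:n]


def cycle_spin_denoise(signal: np.ndarray, cfg: WaveletConfig | None = None,
                       shifts: ShiftFamily | None = None) -> np.ndarray:
    """Translation-invariant estimator: average of shift-denoise-unshift.

    For each shift h the signal S_h(t) = X(t + h) is denoised with
    :func:`denoise_once` and shifted back; the pointwise average over the
    shift family is returned.  ``shifts=None`` uses min(n, 32) evenly
    spaced shifts (or ``cfg.n_shifts``); pass ``ShiftFamily.full(n)`` for
    the exact all-shifts estimator.
    """
    if cfg is None:
        cfg = WaveletConfig()
    x = np.asarray(signal, dtype=float)
    n = x.size
    if shifts is None:
        k = cfg.n_shifts if cfg.n_shifts is not None else min(n, 32)
        if k > n:
            raise ValueError(f"n_shifts {k} exceeds signal length {n}")
        shifts = ShiftFamily.evenly_spaced(n, k)
    if shifts.n != n:
        raise ValueError("shift family built for a different length")

    # estimate sigma once on the unshifted signal: the MAD estimate is not
    # exactly shift-invariant, and a per-shift sigma would break the exact
    # commutation of the full-shift estimator with circular shifts
    if cfg.sigma_estimate == "provided":
        sigma = float(cfg.sigma)
    else:
        sigma = estimate_sigma(x, cfg.family)
    base = WaveletConfig(family=cfg.family,
                         decomposition_level=cfg.decomposition_level,
                         threshold_mode=cfg.threshold_mode,
                         sigma_estimate="provided", sigma=sigma)

    acc = np.zeros(n)
    for h in shifts.shifts:
        y = denoise_once(np.roll(x, -h), base)
        acc += np.roll(y, h)
    return acc / len(shifts.shifts)
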