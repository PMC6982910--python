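"""Independent brute-force oracles used to cross-check the package.

Everything here is written in the most literal way possible (explicit
Python loops, explicit matrices) and must stay independent of the
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# wavelet transform by explicit orthogonal matrix
# ---------------------------------------------------------------------------

def dwt_matrix(n: int, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """The n x n one-level periodized analysis operator, rows = filters."""
    w = np.zeros((n, n))
    half = n // 2
    for k in range(half):
        for m in range(len(h)):
            w[k, (2 * k + m) % n] += h[m]
            w[half + k, (2 * k + m) % n] += g[m]
    return w


def oracle_wavedec(x: np.ndarray, h: np.ndarray, g: np.ndarray,
                   level: int) -> list[np.ndarray]:
    coeffs = []
    a = np.asarray(x, dtype=float)
    for _ in range(level):
        w = dwt_matrix(len(a), h, g)
        y = w @ a
        a, d = y[: len(a) // 2], y[len(a) // 2:]
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]


def oracle_waverec(coeffs: list[np.ndarray], h: np.ndarray,
                   g: np.ndarray) -> np.ndarray:
    a = coeffs[0]
    for d in coeffs[1:]:
        n = 2 * len(a)
        w = dwt_matrix(n, h, g)
        a = w.T @ np.concatenate([a, d])
    return a


def oracle_sigma(x: np.ndarray, g: np.ndarray) -> float:
    """MAD/0.6745 of undecimated finest-scale details, by explicit loops."""
    n = len(x)
    d = []
    for t in range(n):
        acc = 0.0
        for m in range(len(g)):
            acc += g[m] * x[(t + m) % n]
        d.append(abs(acc))
    return float(np.median(d) / 0.6745)


def oracle_denoise_once(x: np.ndarray, h: np.ndarray, g: np.ndarray,
                        level: int, mode: str = "soft",
                        sigma: float | None = None) -> np.ndarray:
    """Literal re-implementation of the base denoiser via explicit matrices."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    block = 2 ** level
    target = max(n, len(h) * 2 ** (level - 1))
    n_pad = block * math.ceil(target / block)
    xp = np.concatenate([x, [x[i % n] for i in range(n_pad - n)]])

    if sigma is None:
        sigma = oracle_sigma(x, g)
    lam = sigma * math.sqrt(2.0 * math.log(n))

    coeffs = oracle_wavedec(xp, h, g, level)
    out = [coeffs[0]]
    for d in coeffs[1:]:
        if mode == "soft":
            out.append(np.sign(d) * np.maximum(np.abs(d) - lam, 0.0))
        else:
            out.append(np.where(np.abs(d) > lam, d, 0.0))
    return oracle_waverec(out, h, g)[:n]


# ---------------------------------------------------------------------------
# sample-by-sample detection state machine
# ---------------------------------------------------------------------------

def oracle_detect(resultant: np.ndarray, threshold: int, debounce_on: int,
                  debounce_off: int, refractory: int) -> list[tuple[int, int]]:
    """Per-sample SLEEP/ACTIVE walk returning merged (start, end) pairs."""
    events = []
    active = False
    above = below = 0
    ev_start = ev_end = 0
    for i, v in enumerate(resultant):
        if v > threshold:
            above += 1
            below = 0
            if not active and above >= debounce_on:
                active = True
                ev_start = i - debounce_on + 1
            if active:
                ev_end = i + 1
        else:
            below += 1
            above = 0
            if active and below >= debounce_off:
                active = False
                events.append((ev_start, ev_end))
    if active:
        events.append((ev_start, ev_end))

    merged: list[tuple[int, int]] = []
    for s, e in events:
        if merged and s - merged[-1][1] < refractory:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# two-pass textbook statistics
# ---------------------------------------------------------------------------

def oracle_window_stats(seg: np.ndarray) -> dict:
    """Mean/max/min/sd/var per channel and the full covariance matrix,
    two-pass, explicit loops."""
    c, n = seg.shape
    mean = np.array([sum(seg[i]) / n for i in range(c)])
    var = np.array([sum((seg[i] - mean[i]) ** 2) / n for i in range(c)])
    cov = np.zeros((c, c))
    for i in range(c):
        for j in range(c):
            cov[i, j] = sum((seg[i] - mean[i]) * (seg[j] - mean[j])) / n
    return {
        "avg": mean,
        "max": np.array([max(seg[i]) for i in range(c)]),
        "min": np.array([min(seg[i]) for i in range(c)]),
        "sd": np.sqrt(var),
        "variance": var,
        "covariance": cov,
    }


# ---------------------------------------------------------------------------
# closed-form parameter counting
# ---------------------------------------------------------------------------

def count_network_params(widths: tuple[int, int, int, int], in_ch: int,
                         n_classes: int, expansion: int, kernel: int,
                         n_bottlenecks: int = 6) -> int:
    """Hand-computed parameter total for the reference layer stack."""

    def conv(ci, co, k):  # no bias
        return ci * co * k

    def bn(ch):  # gamma + beta
        return 2 * ch

    def bottleneck(ch):
        hidden = ch * expansion
        return (conv(ch, hidden, 1) + bn(hidden)
                + hidden * kernel + bn(hidden)  # depthwise
                + conv(hidden, ch, 1) + bn(ch))

    def linear(ci, co):
        return ci * co + co

    total = 0
    prev = in_ch
    for w in widths:
        total += conv(prev, w, kernel) + bn(w)
        if w != widths[-1]:
            total += n_bottlenecks * bottleneck(w)
        prev = w
    total += linear(widths[-1], widths[-1] // 4)
    total += linear(widths[-1] // 4, n_classes)
    return total
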