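"""Naive reference implementations used as independent oracles.

Each function here recomputes a quantity with explicit loops straight
from its defining formula, trading speed for transparency; tests compare
the package's vectorized implementations against these on small inputs.
"""

from __future__ import annotations

import math

import numpy as np


def brute_higuchi_curve(x: np.ndarray, kmax: int) -> np.ndarray:
    """L(k) for k = 1..kmax by the defining triple loop."""
    x = np.asarray(x, float)
    n = len(x)
    lk = []
    for k in range(1, kmax + 1):
        lmk = []
        for m in range(1, k + 1):
            nm = (n - m) // k
            total = 0.0
            for i in range(1, nm + 1):
                total += abs(x[m + i * k - 1] - x[m + (i - 1) * k - 1])
            lmk.append(total * (n - 1) / (nm * k) / k)
        lk.append(sum(lmk) / len(lmk))
    return np.asarray(lk)


def brute_box_counts(mask: np.ndarray, scales: list[int]) -> list[int]:
    """Occupied box counts by explicit tile loops (any rank)."""
    counts = []
    for eps in scales:
        occ = 0
        ranges = [range(0, s, eps) for s in mask.shape]
        if mask.ndim == 2:
            for r in ranges[0]:
                for c in ranges[1]:
                    if mask[r:r + eps, c:c + eps].any():
                        occ += 1
        else:
            for a in ranges[0]:
                for b in ranges[1]:
                    for c in ranges[2]:
                        if mask[a:a + eps, b:b + eps, c:c + eps].any():
                            occ += 1
        counts.append(occ)
    return counts


def brute_lacunarity(mask: np.ndarray, r: int, mode: str) -> float:
    """Λ(r) = <M^2>/<M>^2 by explicit window loops."""
    h, w = mask.shape
    masses = []
    if mode == "raster":
        for i in range(0, h - r + 1, r):
            for j in range(0, w - r + 1, r):
                masses.append(mask[i:i + r, j:j + r].sum())
    else:
        for i in range(h - r + 1):
            for j in range(w - r + 1):
                masses.append(mask[i:i + r, j:j + r].sum())
    m = np.asarray(masses, float)
    return float((m ** 2).mean() / m.mean() ** 2)


def brute_apen(x: np.ndarray, m: int, r_abs: float) -> float:
    """ApEn by the defining double loops, self-matches included."""
    x = np.asarray(x, float)
    n = len(x)

    def phi(mm):
        cnt = n - mm + 1
        logs = []
        for i in range(cnt):
            matches = 0
            for j in range(cnt):
                d = max(abs(x[i + t] - x[j + t]) for t in range(mm))
                if d <= r_abs:
                    matches += 1
            logs.append(math.log(matches / cnt))
        return sum(logs) / cnt

    return phi(m) - phi(m + 1)


def brute_sampen(x: np.ndarray, m: int, r_abs: float) -> float:
    """SampEn = -ln(A/B) by explicit unordered pair counts."""
    x = np.asarray(x, float)
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            db = max(abs(x[i + t] - x[j + t]) for t in range(m))
            if db <= r_abs:
                b += 1
                da = max(abs(x[i + t] - x[j + t]) for t in range(m + 1))
                if da <= r_abs:
                    a += 1
    return -math.log(a / b)


def brute_shannon(p: np.ndarray) -> float:
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


def brute_renyi(p: np.ndarray, q: float) -> float:
    if q == 1:
        return brute_shannon(p)
    return math.log(sum(pi ** q for pi in p if pi > 0)) / (1 - q)


def brute_tsallis(p: np.ndarray, q: float) -> float:
    if q == 1:
        return brute_shannon(p)
    return (1 - sum(pi ** q for pi in p if pi > 0)) / (q - 1)


def brute_permutation_counts(x: np.ndarray, order: int, delay: int) -> dict:
    """Ordinal pattern histogram by hand enumeration (stable ties)."""
    x = np.asarray(x, float)
    patterns: dict[tuple, int] = {}
    span = (order - 1) * delay
    for start in range(len(x) - span):
        window = [(x[start + k * delay], k) for k in range(order)]
        pat = tuple(k for _, k in sorted(window, key=lambda t: (t[0], t[1])))
        patterns[pat] = patterns.get(pat, 0) + 1
    return patterns


def ols_slope_intercept(xs, ys) -> tuple[float, float]:
    """Textbook closed-form least squares."""
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    xbar, ybar = xs.mean(), ys.mean()
    slope = ((xs - xbar) * (ys - ybar)).sum() / ((xs - xbar) ** 2).sum()
    return float(slope), float(ybar - slope * xbar)
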