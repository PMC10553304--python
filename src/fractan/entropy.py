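"""Entropy measures and compression-based complexity.

Approximate/sample entropy quantify the (un)predictability of a signal
from template matching in delay space; permutation entropy does so from
ordinal patterns.  The generalized-entropy family evaluates one-parameter
deformations of Shannon entropy (Rényi, Tsallis and relatives) on a
probability distribution — for grids that distribution is the 256-bin
grey-value histogram, so the same code serves 1D, 2D and 3D inputs.
Kolmogorov complexity is estimated as the losslessly compressed size of a
canonical serialization; logical depth is proxied by decompression time.
"""

from __future__ import annotations

import gzip
import math
import time
import zlib

import numpy as np

from .types import GreyGrid, ProbDist, ResultTable, Sequence1D

__all__ = ["histogram_probs", "approximate_entropy", "sample_entropy",
           "permutation_entropy", "generalized_entropies",
           "shannon_entropy", "renyi_entropy", "tsallis_entropy",
           "kolmogorov_complexity"]


def _values(data) -> np.ndarray:
    if isinstance(data, Sequence1D):
        return data.values
    if isinstance(data, GreyGrid):
        return data.data.ravel()
    return np.asarray(data, dtype=float).ravel()


def histogram_probs(data, bins: int = 256) -> ProbDist:
    """Empirical bin probabilities of the data values.

    Grids use equal-width bins over [0, 255]; sequences bin over
    [min, max].  Empty bins are retained with p = 0 (they drop out of
    entropy sums where ln p appears).
    """
    x = _values(data)
    if x.size == 0:
        raise ValueError("empty data")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if isinstance(data, GreyGrid):
        lo, hi = -0.5, 255.5
    else:
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            probs = np.zeros(bins)
            probs[0] = 1.0
            return ProbDist(probs, source={"bins": bins, "range": (lo, hi)})
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    return ProbDist(counts / counts.sum(), source={"bins": bins, "range": (lo, hi)})


def _resolve_r(x: np.ndarray, r: float, relative: bool) -> float:
    if relative:
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("zero SD: relative tolerance undefined for constant data")
        return r * sd
    return r


def approximate_entropy(seq, m: int = 2, r: float = 0.2,
                        relative: bool = True) -> float:
    """Approximate entropy ApEn(m, r) with self-matches included.

    ``r`` is interpreted as a multiple of the sample SD when
    ``relative`` (default 0.2), otherwise as an absolute tolerance.
    """
    x = _values(seq)
    if x.size < m + 2:
        raise ValueError("sequence too short for ApEn")
    r_abs = _resolve_r(x, r, relative)

    def phi(mm: int) -> float:
        n = x.size - mm + 1
        templates = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
        frac = (d <= r_abs).mean(axis=1)
        return float(np.log(frac).mean())

    return phi(m) - phi(m + 1)


def sample_entropy(seq, m: int = 2, r: float = 0.2,
                   relative: bool = True) -> float:
    """Sample entropy SampEn = −ln(A/B), self-matches excluded.

    A counts unordered template pairs matching at length m+1, B at
    length m (both over the N−m templates of the m+1 comparison, per
    Richman–Moorman).  Raises when either count is zero.
    """
    x = _values(seq)
    if x.size < m + 2:
        raise ValueError("sequence too short for SampEn")
    r_abs = _resolve_r(x, r, relative)
    # restrict both template sets to the common count N-m
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:x.size - m]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    db = np.abs(tm[:, None, :] - tm[None, :, :]).max(axis=2)
    da = np.abs(tm1[:, None, :] - tm1[None, :, :]).max(axis=2)
    n = tm.shape[0]
    b = int((db <= r_abs).sum() - n) // 2
    a = int((da <= r_abs).sum() - n) // 2
    if a == 0 or b == 0:
        raise ValueError("undefined (no matches) for these m, r")
    return float(-np.log(a / b))


def permutation_entropy(seq, order: int = 3, delay: int = 1,
                        variant: str = "raw") -> float:
    """Bandt–Pompe permutation entropy of ordinal patterns (nats).

    Ties are broken by earlier index first.  ``variant`` is ``raw``
    (Shannon entropy of the pattern distribution), ``per_symbol``
    (divided by order−1) or ``normalized`` (divided by ln(order!),
    giving a value in [0, 1]).
    """
    if variant not in ("raw", "per_symbol", "normalized"):
        raise ValueError(f"unknown variant {variant!r}")
    if not 2 <= order <= 8:
        raise ValueError("order must be in [2, 8]")
    x = _values(seq)
    span = (order - 1) * delay
    n_pat = x.size - span
    if n_pat < 1:
        raise ValueError("sequence too short for this order and delay")
    idx = np.arange(n_pat)[:, None] + np.arange(order)[None, :] * delay
    windows = x[idx]
    patterns = np.argsort(windows, axis=1, kind="stable")
    # encode each permutation as an integer for counting
    codes = np.zeros(n_pat, dtype=np.int64)
    for j in range(order):
        codes = codes * order + patterns[:, j]
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if variant == "per_symbol":
        return h / (order - 1)
    if variant == "normalized":
        return h / math.log(math.factorial(order))
    return h


def shannon_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def renyi_entropy(p: np.ndarray, q: float) -> float:
    p = p[p > 0]
    if abs(q - 1.0) < 1e-12:
        return shannon_entropy(p)
    return float(np.log((p ** q).sum()) / (1.0 - q))


def tsallis_entropy(p: np.ndarray, q: float) -> float:
    p = p[p > 0]
    if abs(q - 1.0) < 1e-12:
        return shannon_entropy(p)
    return float((1.0 - (p ** q).sum()) / (q - 1.0))


def _snorm(p: np.ndarray, q: float) -> float:
    if abs(q - 1.0) < 1e-12:
        return shannon_entropy(p)
    return tsallis_entropy(p, q) / float((p[p > 0] ** q).sum())


def _sescort(p: np.ndarray, q: float) -> float:
    p = p[p > 0]
    esc = p ** q
    esc = esc / esc.sum()
    return shannon_entropy(esc)


def _skappa(p: np.ndarray, kappa: float) -> float:
    p = p[p > 0]
    if abs(kappa) < 1e-12:
        return shannon_entropy(p)
    return float(-(p * (p ** kappa - p ** (-kappa)) / (2.0 * kappa)).sum())


def _sb(p: np.ndarray, b: float) -> float:
    p = p[p > 0]
    return float((1.0 - np.exp(-b * p)).sum() + (np.exp(-b) - 1.0))


def _sbeta(p: np.ndarray, beta: float) -> float:
    p = p[p > 0]
    return float(-(p ** beta * np.log(p)).sum())


def _sgamma(p: np.ndarray, gamma: float) -> float:
    p = p[p > 0]
    return float((p ** (1.0 / gamma) * np.log(1.0 / p)).sum())


def generalized_entropies(dist: ProbDist, q_list=(0.5, 2.0),
                          params: dict | None = None) -> ResultTable:
    """Evaluate the generalized-entropy family over a list of exponents.

    One row per exponent value q; Shannon entropy SE is repeated on each
    row, Rényi/Tsallis/SNorm/SEscort use order q (q = 1 returns the
    Shannon limit), and the remaining one-parameter families reuse the
    same exponent (κ = q for SKappa, b = q for SB, β = q for SBeta,
    γ = q for SGamma; entries are NaN where the exponent is out of the
    family's domain).
    """
    p = dist.probabilities
    se = shannon_entropy(p)
    records, labels = [], []
    for q in q_list:
        rec = {"q": q, "SE": se,
               "Renyi": renyi_entropy(p, q),
               "Tsallis": tsallis_entropy(p, q),
               "SNorm": _snorm(p, q),
               "SEscort": _sescort(p, q),
               "SKappa": _skappa(p, q) if -1.0 <= q <= 1.0 else np.nan,
               "SB": _sb(p, q) if q > 0 else np.nan,
               "SBeta": _sbeta(p, q),
               "SGamma": _sgamma(p, q) if q > 0 else np.nan}
        records.append(rec)
        labels.append(f"q={q:g}")
    return ResultTable.from_records(records, labels=labels)


def _serialize(data) -> bytes:
    """Canonical byte stream: doubles for sequences, row-major grey bytes."""
    if isinstance(data, GreyGrid):
        return np.ascontiguousarray(
            np.floor(data.data + 0.5).astype(np.uint8)).tobytes()
    x = _values(data)
    return np.ascontiguousarray(x.astype("<f8")).tobytes()


def kolmogorov_complexity(data, compressor: str = "zlib",
                          ld_iterations: int = 10) -> ResultTable:
    """Compression-based Kolmogorov complexity and logical depth proxy.

    KC is the compressed byte length at maximum compression level; LD is
    the median wall time of ``ld_iterations`` decompressions (hardware
    dependent — reported with a caveat flag, not comparable across
    machines).
    """
    if compressor not in ("zlib", "gzip"):
        raise ValueError(f"unknown compressor {compressor!r}")
    raw = _serialize(data)
    if compressor == "zlib":
        comp = zlib.compress(raw, level=9)
        decomp = lambda b: zlib.decompress(b)  # noqa: E731
    else:
        comp = gzip.compress(raw, compresslevel=9)
        decomp = lambda b: gzip.decompress(b)  # noqa: E731
    times = []
    for _ in range(max(1, ld_iterations)):
        t0 = time.perf_counter()
        decomp(comp)
        times.append(time.perf_counter() - t0)
    rec = {"OriginalBytes": len(raw), "KC": len(comp),
           "Ratio": len(comp) / len(raw),
           "LD_seconds": float(np.median(times)),
           "LD_hardware_dependent": True,
           "Compressor": compressor}
    return ResultTable.from_records([rec], labels=["kc"])
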