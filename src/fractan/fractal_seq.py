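"""Fractal and scaling estimators for 1D signals.

All estimators return a :class:`~fractan.types.DimensionResult`; the
regression-based ones (Higuchi, DFA, PSD Hurst) carry the underlying
log-log :class:`~fractan.types.ScalingFit`, the closed-form ones (Katz,
Petrosian, Sevcik) report the formula value with ``fit=None``.

A signal graph has fractal dimension D ∈ [1, 2]: 1 for a smooth line,
2 for a space-filling trace such as uncorrelated noise.  For fractional
Gaussian noise / Brownian motion the dimension relates to the Hurst
exponent by D = 2 − H and to the spectral exponent by β = 2H + 1 (fGn
measured on the motion scale: β = 2H − 1 for the noise itself).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import signal as sp_signal

from .scaling import loglog_fit
from .types import (AnalysisSpec, DegenerateRegressionError, DimensionResult,
                    ResultTable, ScaleSeries, Sequence1D)

__all__ = ["higuchi_dim_1d", "katz_dim", "petrosian_dim", "sevcik_dim",
           "dfa_alpha", "hurst_psd", "windowed_apply", "higuchi_curve"]


def _values(seq: Sequence1D | np.ndarray) -> np.ndarray:
    return seq.values if isinstance(seq, Sequence1D) else np.asarray(seq, float)


def higuchi_curve(seq: Sequence1D | np.ndarray, kmax: int) -> ScaleSeries:
    """Higuchi's mean curve length L(k) for delays k = 1 .. kmax.

    For each delay k and offset m = 1..k the normalized curve length is

        L_m(k) = [ Σ_i |x(m+ik) − x(m+(i−1)k)| · (N−1)/(n_m·k) ] / k

    with n_m = floor((N−m)/k); L(k) averages L_m(k) over the k offsets.
    L(k) ∝ k^(−D) for a fractal signal graph of dimension D.
    """
    x = _values(seq)
    n = x.size
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if n < 2 * kmax:
        raise ValueError(f"sequence too short for kmax={kmax} (need N >= {2 * kmax})")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = np.empty(k)
        for m in range(1, k + 1):
            idx = np.arange(m - 1, n, k)
            nm = idx.size - 1
            dist = np.abs(np.diff(x[idx])).sum()
            lengths[m - 1] = dist * (n - 1) / (nm * k) / k
        lk[k - 1] = lengths.mean()
    return ScaleSeries(scales=np.arange(1, kmax + 1, dtype=float), measures=lk)


def higuchi_dim_1d(seq: Sequence1D | np.ndarray, kmax: int = 8,
                   reg_min: int = 1, reg_max: int | None = None) -> DimensionResult:
    """Higuchi fractal dimension Dh of a signal graph (expected in [1, 2])."""
    series = higuchi_curve(seq, kmax)
    if np.all(series.measures == 0):
        raise DegenerateRegressionError("degenerate regression: constant sequence")
    fit = loglog_fit(series, reg_min=reg_min, reg_max=reg_max or kmax)
    return DimensionResult(dimension=-fit.slope, fit=fit, method="higuchi_1d",
                           params={"kmax": kmax})


def katz_dim(seq: Sequence1D | np.ndarray) -> DimensionResult:
    """Katz waveform dimension with unit abscissa spacing.

    D = log10(n) / (log10(n) + log10(d / L)) with L the total Euclidean
    path length, d the maximum distance from the first point, n = N−1.
    """
    x = _values(seq)
    n = x.size
    if n < 3:
        raise ValueError("too short: Katz dimension needs N >= 3")
    steps = np.hypot(1.0, np.diff(x))
    length = steps.sum()
    i = np.arange(n)
    d = np.hypot(i, x - x[0]).max()
    if d == 0:
        raise ValueError("zero extent: all points coincide with the start")
    log_n = np.log10(n - 1)
    dim = log_n / (log_n + np.log10(d / length))
    return DimensionResult(dimension=float(dim), fit=None, method="katz", params={})


def petrosian_dim(seq: Sequence1D | np.ndarray) -> DimensionResult:
    """Petrosian dimension from the sign-change count of the first difference."""
    x = _values(seq)
    n = x.size
    if n < 3:
        raise ValueError("too short: Petrosian dimension needs N >= 3")
    s = np.sign(np.diff(x))
    nz = s[s != 0]
    n_delta = int(np.count_nonzero(nz[1:] * nz[:-1] < 0)) if nz.size > 1 else 0
    log_n = np.log10(n)
    dim = log_n / (log_n + np.log10(n / (n + 0.4 * n_delta)))
    return DimensionResult(dimension=float(dim), fit=None, method="petrosian",
                           params={"sign_changes": n_delta})


def sevcik_dim(seq: Sequence1D | np.ndarray) -> DimensionResult:
    """Sevcik dimension on the unit-square normalized waveform."""
    x = _values(seq)
    n = x.size
    if n < 2:
        raise ValueError("too short: Sevcik dimension needs N >= 2")
    rng = np.ptp(x)
    if rng == 0:
        raise ValueError("zero amplitude range: constant sequence")
    y = (x - x.min()) / rng
    t = np.arange(n) / (n - 1)
    length = np.hypot(np.diff(t), np.diff(y)).sum()
    dim = 1.0 + np.log(length) / np.log(2.0 * (n - 1))
    return DimensionResult(dimension=float(dim), fit=None, method="sevcik", params={})


def dfa_alpha(seq: Sequence1D | np.ndarray, win_min: int = 4,
              win_max: int | None = None, n_windows: int = 20) -> DimensionResult:
    """Detrended fluctuation analysis scaling exponent α.

    The profile (cumulative sum of the mean-subtracted signal) is cut
    into non-overlapping windows of each size s, each window is linearly
    detrended, and F(s) is the RMS of the pooled residuals; α is the
    log-log slope of F(s) over ~``n_windows`` log-spaced sizes in
    [win_min, win_max] (default N/4).  α = 0.5 for white noise, α = H
    for fractional Gaussian noise.
    """
    x = _values(seq)
    n = x.size
    if win_max is None:
        win_max = n // 4
    if n < 4 * win_min or win_max > n // 2 or win_max <= win_min:
        raise ValueError("invalid DFA window range for this sequence length")
    profile = np.cumsum(x - x.mean())
    sizes = np.unique(np.round(np.geomspace(win_min, win_max, n_windows)).astype(int))
    fluct = np.empty(sizes.size)
    for j, s in enumerate(sizes):
        nwin = n // s
        segs = profile[:nwin * s].reshape(nwin, s)
        t = np.arange(s)
        tc = t - t.mean()
        denom = (tc ** 2).sum()
        slope = segs @ tc / denom
        resid = segs - segs.mean(axis=1, keepdims=True) - slope[:, None] * tc
        fluct[j] = np.sqrt((resid ** 2).mean())
    if np.all(fluct == 0):
        raise DegenerateRegressionError("degenerate regression: zero fluctuation")
    fit = loglog_fit(ScaleSeries(scales=sizes.astype(float), measures=fluct))
    return DimensionResult(dimension=fit.slope, fit=fit, method="dfa",
                           params={"win_min": win_min, "win_max": win_max})


def hurst_psd(seq: Sequence1D | np.ndarray, reg_min: int = 1,
              reg_max: int | None = None) -> DimensionResult:
    """Hurst exponent from the power spectral density slope.

    A Hann-windowed periodogram is fit by ln P vs ln f; β is minus the
    slope.  β ∈ (−1, 1) classifies the signal as fGn with H = (β+1)/2;
    β ∈ [1, 3) as fBm with H = (β−1)/2 (the boundary β = 1 counts as
    fBm) and companion graph dimension D = (5−β)/2.  By default the fit
    uses the lowest half of the nonzero frequency bins.
    """
    x = _values(seq)
    n = x.size
    if n < 64:
        raise ValueError("hurst_psd needs N >= 64")
    freq, power = sp_signal.periodogram(x, window="hann", detrend="constant")
    freq, power = freq[1:], power[1:]  # drop DC
    if not power.any():
        raise ValueError("flat spectrum: constant sequence")
    series = ScaleSeries(scales=freq, measures=np.maximum(power, 0))
    if reg_max is None:
        reg_max = max(2, len(series) // 2)
    fit = loglog_fit(series, reg_min=reg_min, reg_max=reg_max, skip_zero=True)
    beta = -fit.slope
    if beta < 1.0:
        signal_class, hurst = "fGn", (beta + 1.0) / 2.0
    else:
        signal_class, hurst = "fBm", (beta - 1.0) / 2.0
    params = {"beta": float(beta), "signal_class": signal_class}
    if 1.0 <= beta < 3.0:
        params["companion_dimension"] = (5.0 - beta) / 2.0
    return DimensionResult(dimension=float(hurst), fit=fit, method="hurst_psd",
                           params=params)


def windowed_apply(seq: Sequence1D, statistic: Callable[[Sequence1D], float],
                   spec: AnalysisSpec) -> ResultTable:
    """Apply a scalar statistic over the whole signal or sliding windows.

    ``subsequent_boxes`` uses non-overlapping windows of ``box_length``
    (remainder dropped); ``sliding_box`` advances by one sample giving
    N − L + 1 windows.  One result row per window, labelled by its
    0-based start index.
    """
    n = len(seq)
    records, labels = [], []
    if spec.range_mode == "entire":
        starts, length = [0], n
    else:
        length = spec.box_length
        if length > n:
            raise ValueError("box_length exceeds the sequence length")
        if spec.range_mode == "subsequent_boxes":
            starts = list(range(0, n - length + 1, length))
        else:
            starts = list(range(0, n - length + 1))
    for start in starts:
        window = Sequence1D(name=f"{seq.name}[{start}:{start + length}]",
                            values=seq.values[start:start + length])
        records.append({"Start": start, "Value": float(statistic(window))})
        labels.append(str(start))
    return ResultTable.from_records(records, labels=labels)
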