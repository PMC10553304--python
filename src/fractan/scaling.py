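"""Log-log regression engine and spectrum averaging.

Every regression-based dimension estimator in the toolkit reduces its data
to a :class:`~fractan.types.ScaleSeries` of (scale, measure) points and
fits ln(measure) against ln(scale) with :func:`loglog_fit`.  Spectral
estimators additionally use :func:`radial_power_average`, which bins the
discrete Fourier power spectrum of a 2D or 3D grid by integer radial
wavenumber (circular average for images, spherical average for volumes).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import (DegenerateRegressionError, FlatSpectrumError, GreyGrid,
                    ScaleSeries, ScalingFit)

__all__ = ["loglog_fit", "radial_power_average", "dyadic_scales", "grid_scales"]


def loglog_fit(series: ScaleSeries, reg_min: int = 1, reg_max: int | None = None,
               skip_zero: bool = False) -> ScalingFit:
    """Ordinary least squares of ln(measure) on ln(scale).

    Parameters
    ----------
    series
        The (scale, measure) points.
    reg_min, reg_max
        1-based inclusive indices into ``series`` delimiting the fitted
        window (mirroring the "Regression Min/Max" convention).
        ``reg_max=None`` means the last point.
    skip_zero
        If True, points with non-positive measures inside the window are
        dropped before fitting; if False (default) such a point raises.

    Raises
    ------
    DegenerateRegressionError
        If fewer than 2 usable points remain.
    ValueError
        On a non-positive measure with ``skip_zero`` disabled.
    """
    m = len(series)
    if reg_max is None:
        reg_max = m
    if not (1 <= reg_min < reg_max <= m):
        raise ValueError(f"regression window [{reg_min}, {reg_max}] invalid for {m} points")
    s = series.scales[reg_min - 1:reg_max]
    y = series.measures[reg_min - 1:reg_max]
    bad = y <= 0
    if bad.any():
        if not skip_zero:
            raise ValueError("log of non-positive measure (enable skip_zero to drop)")
        s, y = s[~bad], y[~bad]
    if len(s) < 2:
        raise DegenerateRegressionError("degenerate regression: fewer than 2 usable points")
    ln_s, ln_y = np.log(s), np.log(y)
    res = stats.linregress(ln_s, ln_y)
    # linregress r is NaN for a perfectly horizontal fit; R^2 of a constant
    # response explained by a constant prediction is 1 by convention here.
    r2 = 1.0 if np.allclose(ln_y, ln_y[0]) else float(res.rvalue ** 2)
    return ScalingFit(slope=float(res.slope), intercept=float(res.intercept),
                      r_squared=r2, reg_min=reg_min, reg_max=reg_max)


def _hann_nd(shape: tuple[int, ...]) -> np.ndarray:
    """Separable N-dimensional Hann window."""
    win = np.ones(shape)
    for axis, n in enumerate(shape):
        w = np.hanning(n)
        win = win * w.reshape([-1 if a == axis else 1 for a in range(len(shape))])
    return win


def radial_bin_power(data: np.ndarray, window: str | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Radially binned power sums and counts plus the DC power.

    Returns ``(bin_sums, bin_counts, dc_power)`` where bin ``k`` collects
    spectral samples whose radial wavenumber rounds to ``k`` (wavenumbers
    expressed in cycles per minimum grid side).  Used by
    :func:`radial_power_average` and by energy-conservation checks.
    """
    x = np.asarray(data, dtype=float)
    if min(x.shape) < 8:
        raise ValueError("all sides must be >= 8 for spectral averaging")
    if np.ptp(x) == 0:
        raise FlatSpectrumError("flat spectrum: constant input")
    if window is not None:
        if window != "hanning":
            raise ValueError(f"unknown window {window!r}")
        x = (x - x.mean()) * _hann_nd(x.shape)
    power = np.abs(np.fft.fftn(x)) ** 2
    min_side = min(x.shape)
    r2 = np.zeros(x.shape)
    for axis, n in enumerate(x.shape):
        f = np.fft.fftfreq(n) * min_side  # cycles per min-side length
        r2 = r2 + (f.reshape([-1 if a == axis else 1 for a in range(x.ndim)])) ** 2
    kbin = np.rint(np.sqrt(r2)).astype(np.int64).ravel()
    p = power.ravel()
    nbins = kbin.max() + 1
    sums = np.bincount(kbin, weights=p, minlength=nbins)
    counts = np.bincount(kbin, minlength=nbins)
    return sums, counts, float(sums[0])


def radial_power_average(grid: GreyGrid | np.ndarray,
                         window: str | None = None) -> ScaleSeries:
    """Circularly (2D) / spherically (3D) averaged power spectrum.

    The measure at scale k (k = 1 .. floor(min side / 2)) is the mean
    spectral power over samples whose radial wavenumber rounds to k; the
    DC bin is excluded.  ``window='hanning'`` multiplies the
    mean-subtracted grid by a separable Hann window first.
    """
    data = grid.data if isinstance(grid, GreyGrid) else np.asarray(grid, float)
    sums, counts, _dc = radial_bin_power(data, window)
    kmax = min(data.shape) // 2
    k = np.arange(1, kmax + 1)
    means = sums[1:kmax + 1] / counts[1:kmax + 1]
    if not means.any():
        raise FlatSpectrumError("flat spectrum: no off-DC power")
    return ScaleSeries(scales=k.astype(float), measures=means)


def dyadic_scales(max_extent: int) -> list[int]:
    """Powers of two 1, 2, 4, ... up to floor(max_extent / 2)."""
    if max_extent < 2:
        raise ValueError("max_extent must be >= 2")
    scales = []
    s = 1
    while s <= max_extent // 2:
        scales.append(s)
        s *= 2
    return scales


def grid_scales(extent: int) -> list[int]:
    """Box sizes for raster estimators on a grid of the given extent.

    Prefers the divisors of ``extent`` up to ``extent // 2`` so that
    every box tiles the grid exactly, which removes the partial-box bias
    at the far edges (for power-of-two extents this coincides with
    :func:`dyadic_scales`; for 3^L extents it yields the triadic scales
    on which exact self-similar sets count exactly).  When fewer than
    three such divisors exist (e.g. a prime extent), falls back to
    dyadic scales with far-edge partial boxes.
    """
    if extent < 2:
        raise ValueError("extent must be >= 2")
    divisors = [d for d in range(1, extent // 2 + 1) if extent % d == 0]
    if len(divisors) < 3:
        return dyadic_scales(extent)
    return divisors
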