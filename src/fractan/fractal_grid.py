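"""Fractal estimators for 2D images and 3D volumes.

Binary set estimators (box counting, pyramid, Minkowski, correlation,
lacunarity, fragmentation index) operate on a
:class:`~fractan.types.BinaryMask`; grey-value estimators (generalized
dimensions, FFT dimension, Higuchi variants) take a
:class:`~fractan.types.GreyGrid` directly.

Box rasters are anchored at the index origin; partial boxes at the far
edges count when they contain foreground, so non-power-of-two sides are
handled without cropping.  Unless a regression window is given, the
box-scale estimators fit the central scaling region (the smallest and
largest scale are dropped when at least four scales exist) to reduce
finite-size bias; the FFT dimension fits the full radial-bin range.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist

from .scaling import dyadic_scales, grid_scales, loglog_fit, radial_power_average
from .types import (BinaryMask, DegenerateRegressionError, DimensionResult,
                    GreyGrid, LacunaritySeries, ScaleSeries)

__all__ = ["box_counting_dim", "pyramid_dim", "minkowski_dim",
           "correlation_dim", "generalized_dims", "fft_dim_grid",
           "higuchi_dim_grid", "lacunarity", "ffi", "box_occupancy_series"]


def _default_window(m: int, reg_min: int | None, reg_max: int | None) -> tuple[int, int]:
    if reg_min is None and reg_max is None and m >= 4:
        return 2, m - 1
    return reg_min or 1, reg_max or m


def _box_reduce(data: np.ndarray, eps: int, how: str) -> np.ndarray:
    """Aggregate ``data`` over an eps-sided raster anchored at the origin.

    Far-edge partial boxes are padded with zeros so they still count.
    ``how`` is 'any', 'sum' or 'max'.
    """
    pad = [(0, (-s) % eps) for s in data.shape]
    if any(p[1] for p in pad):
        data = np.pad(data, pad, mode="constant")
    shape = []
    for s in data.shape:
        shape.extend([s // eps, eps])
    view = data.reshape(shape)
    axes = tuple(range(1, len(shape), 2))
    if how == "any":
        return view.any(axis=axes)
    if how == "sum":
        return view.sum(axis=axes)
    return view.max(axis=axes)


def box_occupancy_series(mask: BinaryMask) -> ScaleSeries:
    """Occupied box counts N(ε) over the grid's raster scales ε."""
    data = mask.data
    if not data.any():
        raise ValueError("empty foreground")
    scales = grid_scales(min(data.shape))
    counts = [int(_box_reduce(data, eps, "any").sum()) for eps in scales]
    return ScaleSeries(scales=np.asarray(scales, float),
                       measures=np.asarray(counts, float))


def box_counting_dim(mask: BinaryMask, reg_min: int | None = None,
                     reg_max: int | None = None) -> DimensionResult:
    """Box-counting dimension: D = −slope of ln N(ε) vs ln ε (E ∈ {2,3})."""
    series = box_occupancy_series(mask)
    lo, hi = _default_window(len(series), reg_min, reg_max)
    fit = loglog_fit(series, reg_min=lo, reg_max=hi)
    return DimensionResult(dimension=-fit.slope, fit=fit, method="box_counting",
                           params={"rank": mask.rank})


def pyramid_dim(mask: BinaryMask) -> DimensionResult:
    """Pyramid dimension: foreground counts of an OR-pooled image pyramid.

    Level ℓ downsamples by 2^ℓ with logical-OR pooling; the dimension is
    −slope of ln C_ℓ vs ln 2^ℓ, which coincides with box counting on
    dyadic scales.
    """
    data = mask.data
    if mask.rank != 2:
        raise ValueError("pyramid_dim expects a 2D mask")
    if min(data.shape) < 8:
        raise ValueError("pyramid_dim needs sides >= 8")
    if not data.any():
        raise ValueError("empty foreground")
    scales, counts = [], []
    level = 0
    current = data
    while min(current.shape) >= 1:
        scales.append(2 ** level)
        counts.append(int(current.sum()))
        if min(current.shape) == 1:
            break
        current = _box_reduce(current, 2, "any")
        level += 1
    series = ScaleSeries(scales=np.asarray(scales, float),
                         measures=np.asarray(counts, float))
    fit = loglog_fit(series)
    return DimensionResult(dimension=-fit.slope, fit=fit, method="pyramid",
                           params={"levels": len(scales)})


def minkowski_dim(mask: BinaryMask, r_max: int = 8) -> DimensionResult:
    """Minkowski (dilation) dimension of a planar set.

    A(r) is the area after dilation with a (2r+1)² square structuring
    element (Chebyshev ball), built incrementally by repeated 3×3
    dilation; D = 2 − slope of ln A against ln(2r+1).  Regressing on the
    element diameter rather than the radius makes the isolated-point,
    thin-line and filled-area cases come out at 0, 1 and 2 exactly
    (A = (2r+1)^2, (2r+1)·length, constant).
    """
    data = mask.data
    if mask.rank != 2:
        raise ValueError("minkowski_dim expects a 2D mask")
    if not data.any():
        raise ValueError("empty foreground")
    if r_max < 2:
        raise ValueError("r_max must be >= 2")
    struct = np.ones((3, 3), dtype=bool)
    areas = np.empty(r_max)
    current = data
    for r in range(1, r_max + 1):
        current = ndimage.binary_dilation(current, structure=struct)
        areas[r - 1] = current.sum()
    diameters = 2.0 * np.arange(1, r_max + 1) + 1.0
    series = ScaleSeries(scales=diameters, measures=areas)
    fit = loglog_fit(series)
    return DimensionResult(dimension=2.0 - fit.slope, fit=fit, method="minkowski",
                           params={"r_max": r_max})


def correlation_dim(mask: BinaryMask, n_radii: int = 16,
                    max_points: int = 5000, seed: int | None = None,
                    reg_min: int | None = None,
                    reg_max: int | None = None) -> DimensionResult:
    """Correlation dimension from the pairwise distance integral C(r).

    Foreground pixel coordinates (randomly subsampled to ``max_points``
    when larger) feed the correlation sum C(r) = fraction of pairs
    closer than r over log-spaced radii; D is the slope of
    ln C(r) vs ln r within the scaling window.
    """
    coords = np.argwhere(mask.data)
    if coords.shape[0] < 10:
        raise ValueError("too few foreground points (need >= 10)")
    if coords.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        coords = coords[rng.choice(coords.shape[0], max_points, replace=False)]
    dists = pdist(coords.astype(float))
    d_max = dists.max()
    if d_max == 0:
        raise DegenerateRegressionError("degenerate regression: all points coincide")
    radii = np.geomspace(1.0, d_max / 2.0, n_radii)
    c = np.searchsorted(np.sort(dists), radii, side="left") / dists.size
    keep = c > 0
    series = ScaleSeries(scales=radii[keep], measures=c[keep])
    lo, hi = _default_window(len(series), reg_min, reg_max)
    fit = loglog_fit(series, reg_min=lo, reg_max=hi)
    return DimensionResult(dimension=fit.slope, fit=fit, method="correlation",
                           params={"n_points": int(coords.shape[0])})


def generalized_dims(grid: GreyGrid, q_list=(-2.0, 0.0, 1.0, 2.0),
                     reg_min: int | None = None,
                     reg_max: int | None = None) -> list[DimensionResult]:
    """Generalized (Rényi) dimensions D_q of the grey-mass measure.

    Box masses μ_i over divisor-scale rasters; for q ≠ 1, D_q is the slope of
    ln Σ μ_i^q vs ln ε divided by (q−1); for q = 1, D_1 is the slope of
    Σ μ_i ln μ_i vs ln ε.  Empty boxes are excluded from the sums.
    """
    data = grid.data
    if grid.rank != 2:
        raise ValueError("generalized_dims expects a 2D grid")
    total = data.sum()
    if total <= 0:
        raise ValueError("zero total grey mass")
    scales = grid_scales(min(data.shape))
    mus = []
    for eps in scales:
        sums = _box_reduce(data, eps, "sum").ravel()
        mus.append(sums[sums > 0] / total)
    results = []
    for q in q_list:
        if abs(q - 1.0) < 1e-12:
            # D_1 is the slope of Σ μ ln μ vs ln ε; fitting ln exp(y) = y
            # reuses the shared regression engine.
            y = np.array([(mu * np.log(mu)).sum() for mu in mus])
            fit = loglog_fit(ScaleSeries(np.asarray(scales, float), np.exp(y)),
                             *_default_window(len(scales), reg_min, reg_max))
            dq = fit.slope
        else:
            y = np.array([(mu ** q).sum() for mu in mus])
            lo, hi = _default_window(len(scales), reg_min, reg_max)
            fit = loglog_fit(ScaleSeries(np.asarray(scales, float), y), lo, hi)
            dq = fit.slope / (q - 1.0)
        results.append(DimensionResult(dimension=float(dq), fit=fit,
                                       method="generalized", params={"q": q}))
    return results


def fft_dim_grid(grid: GreyGrid, reg_min: int = 1, reg_max: int | None = None,
                 window: str | None = "hanning") -> DimensionResult:
    """FFT dimension from the radial power-spectrum decay.

    With β the fitted spectral exponent of the circularly (2D) or
    spherically (3D) averaged power spectrum, D = (3E + 2 − β)/2, i.e.
    (8 − β)/2 for images and (11 − β)/2 for volumes.  The regression
    defaults to the full radial-bin range.
    """
    e = grid.rank
    series = radial_power_average(grid, window=window)
    fit = loglog_fit(series, reg_min=reg_min, reg_max=reg_max or len(series),
                     skip_zero=True)
    beta = -fit.slope
    dim = (3 * e + 2 - beta) / 2.0
    return DimensionResult(dimension=float(dim), fit=fit, method="fft",
                           params={"beta": float(beta), "rank": e,
                                   "window": window})


def higuchi_dim_grid(grid: GreyGrid, kmax: int = 8,
                     variant: str = "direct_differences",
                     reg_min: int = 1, reg_max: int | None = None) -> DimensionResult:
    """Higuchi-type dimension of a grey surface or volume.

    ``profiles_1d`` (2D only): the genuine 1D Higuchi length curve is
    averaged over every row and column profile; the fitted profile
    dimension in [1, 2] maps to the surface dimension by adding 1.

    ``direct_differences`` (2D or 3D): the mean absolute k-spaced grey
    difference δ(k) along each axis is normalized to M(k) = δ(k)/k^(E+1),
    calibrated so that a smooth plane ramp yields M(k) ∝ k^(−E) (D = E)
    and iid noise yields D = E + 1; the dimension is −slope of
    ln M(k) vs ln k.
    """
    from .fractal_seq import higuchi_curve

    data = grid.data
    e = grid.rank
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if min(data.shape) < 2 * kmax:
        raise ValueError("grid sides must be >= 2*kmax")
    if np.ptp(data) == 0:
        raise DegenerateRegressionError("degenerate regression: constant grid")
    k = np.arange(1, kmax + 1, dtype=float)
    if variant == "profiles_1d":
        if e != 2:
            raise ValueError("profiles_1d variant is 2D only")
        curves = [higuchi_curve(row, kmax).measures for row in data]
        curves += [higuchi_curve(col, kmax).measures for col in data.T]
        mean_l = np.mean(curves, axis=0)
        series = ScaleSeries(scales=k, measures=mean_l)
        fit = loglog_fit(series, reg_min=reg_min, reg_max=reg_max or kmax)
        dim = -fit.slope + 1.0
    elif variant == "direct_differences":
        delta = np.empty(kmax)
        for ki in range(1, kmax + 1):
            acc, cnt = 0.0, 0
            for axis in range(e):
                sl_a = [slice(None)] * e
                sl_b = [slice(None)] * e
                sl_a[axis] = slice(ki, None)
                sl_b[axis] = slice(None, -ki)
                diff = np.abs(data[tuple(sl_a)] - data[tuple(sl_b)])
                acc += diff.sum()
                cnt += diff.size
            delta[ki - 1] = acc / cnt
        series = ScaleSeries(scales=k, measures=delta / k ** (e + 1))
        fit = loglog_fit(series, reg_min=reg_min, reg_max=reg_max or kmax)
        dim = -fit.slope
    else:
        raise ValueError(f"unknown Higuchi variant {variant!r}")
    return DimensionResult(dimension=float(dim), fit=fit,
                           method=f"higuchi_{variant}",
                           params={"kmax": kmax, "rank": e})


def _integral_image(data: np.ndarray) -> np.ndarray:
    ii = data.astype(np.int64)
    for axis in range(data.ndim):
        ii = ii.cumsum(axis=axis)
    return np.pad(ii, [(1, 0)] * data.ndim, mode="constant")


def _gliding_sums(data: np.ndarray, r: int) -> np.ndarray:
    ii = _integral_image(data)
    h, w = data.shape
    out = (ii[r:h + 1, r:w + 1] - ii[:h - r + 1, r:w + 1]
           - ii[r:h + 1, :w - r + 1] + ii[:h - r + 1, :w - r + 1])
    return out


def lacunarity(mask: BinaryMask, box_sizes=None,
               mode: str = "raster") -> LacunaritySeries:
    """Lacunarity Λ(r) = ⟨M²⟩ / ⟨M⟩² of box masses at each box size.

    ``raster`` scans non-overlapping tiles (remainder truncated);
    ``gliding`` scans every fully-inside window with step 1.  For a
    homogeneous mask Λ = 1; gaps at scale r raise Λ(r).
    """
    data = mask.data
    if mask.rank != 2:
        raise ValueError("lacunarity expects a 2D mask")
    if not data.any():
        raise ValueError("empty foreground")
    if mode not in ("raster", "gliding"):
        raise ValueError(f"unknown lacunarity mode {mode!r}")
    if box_sizes is None:
        box_sizes = grid_scales(min(data.shape))
    lam = np.empty(len(box_sizes))
    for j, r in enumerate(box_sizes):
        if r > min(data.shape):
            raise ValueError(f"box size {r} exceeds the image")
        if mode == "raster":
            nr, nc = data.shape[0] // r, data.shape[1] // r
            masses = _box_reduce(data[:nr * r, :nc * r], r, "sum").ravel()
        else:
            masses = _gliding_sums(data, r).ravel()
        mean = masses.mean()
        lam[j] = (masses.astype(float) ** 2).mean() / mean ** 2 if mean > 0 else np.nan
    return LacunaritySeries(box_sizes=np.asarray(box_sizes), lacunarity=lam,
                            mode=mode)


def ffi(mask: BinaryMask) -> DimensionResult:
    """Fractal fragmentation index: FFI = D_area − D_perimeter.

    The boundary is the foreground minus its 4-connected erosion.  FFI
    is near 1 for a compact Euclidean object (area dimension 2, smooth
    perimeter dimension 1), and exactly 0 for fully fragmented dust
    where every pixel is its own boundary.
    """
    data = mask.data
    if mask.rank != 2:
        raise ValueError("ffi expects a 2D mask")
    if not data.any():
        raise ValueError("empty foreground")
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(data, structure=cross)
    boundary = data & ~interior
    if not boundary.any():
        raise ValueError("empty boundary (single filled block?)")
    # full scale range: the finest scales are where area and boundary
    # occupancy differ, so the central-window default would wash FFI out
    n_scales = len(grid_scales(min(data.shape)))
    d_area = box_counting_dim(mask, reg_min=1, reg_max=n_scales)
    d_perim = box_counting_dim(BinaryMask(boundary, threshold=mask.threshold),
                               reg_min=1, reg_max=n_scales)
    return DimensionResult(
        dimension=float(d_area.dimension - d_perim.dimension), fit=None,
        method="ffi", params={"d_area": d_area.dimension,
                              "d_perimeter": d_perim.dimension})
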