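"""Synthetic sequences, images and volumes with known ground truth.

These factories produce the standard test objects of fractal analysis:

* 1D — periodic waveforms, iid noise, chaotic maps (logistic, Henon,
  cubic, Spence), fractional Gaussian noise by Davies–Harte circulant
  embedding, fractional Brownian motion by spectral synthesis,
  Weierstrass–Mandelbrot functions with a prescribed fractal dimension,
  and binary Cantor dusts.
* 2D — noise/sine/constant images, spectral-synthesis fractal surfaces,
  diamond-square midpoint-displacement surfaces, and exact IFS sets
  (Menger carpet, Sierpinski triangle).
* 3D — noise/constant volumes, spectral-synthesis fractal volumes,
  midpoint-displacement volumes, and the Menger cube.

The spectral generators share one exponent convention: a grey-value
fractal of embedding rank E with target dimension D has Hurst exponent
H = E + 1 − D and spectral power decaying as f^(−β) with
β = 2H + E = 3E + 2 − 2D.  The three canonical walkthrough cases are
D = 1.5 → β = 2, D = 2.5 → β = 3 and D = 3.5 → β = 4.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .types import GeneratorSpec, GreyGrid, Sequence1D

__all__ = ["generate_sequence", "generate_image", "generate_volume",
           "quantize_grey"]

_WM_GAMMA = 1.5  # Weierstrass-Mandelbrot frequency ratio


def _rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_unit_phases(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Unit-modulus Fourier coefficients with exact Hermitian symmetry.

    Obtained as W/|W| for W the FFT of white Gaussian noise, so the
    inverse transform of any Hermitian amplitude pattern times this
    factor is real.  Self-conjugate bins (DC, Nyquist) come out as ±1.
    """
    w = np.fft.fftn(rng.standard_normal(shape))
    mag = np.abs(w)
    mag[mag == 0] = 1.0
    return w / mag


def _radial_wavenumber(shape: tuple[int, ...]) -> np.ndarray:
    r2 = np.zeros(shape)
    for axis, n in enumerate(shape):
        f = np.fft.fftfreq(n) * n  # integer cycle index per axis
        r2 = r2 + f.reshape([-1 if a == axis else 1 for a in range(len(shape))]) ** 2
    return np.sqrt(r2)


def _spectral_field(shape: tuple[int, ...], beta: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Real random field with power spectrum ∝ |f|^(−beta), zero DC."""
    r = _radial_wavenumber(shape)
    amp = np.zeros(shape)
    nz = r > 0
    amp[nz] = r[nz] ** (-beta / 2.0)
    field = np.fft.ifftn(amp * _random_unit_phases(shape, rng)).real
    return field


def quantize_grey(field: np.ndarray, grey_max: int = 255) -> np.ndarray:
    """Min-max scale a real field to [0, grey_max] and round half-up."""
    lo, hi = field.min(), field.max()
    if hi == lo:
        return np.full(field.shape, float(grey_max))
    scaled = (field - lo) / (hi - lo) * grey_max
    return np.floor(scaled + 0.5)


# ---------------------------------------------------------------------------
# 1D sequences
# ---------------------------------------------------------------------------

def _weierstrass_mandelbrot(n: int, dim: float, rng: np.random.Generator) -> np.ndarray:
    if not 1.0 < dim < 2.0:
        raise ValueError("W-M fractal dimension must lie in (1, 2)")
    hurst = 2.0 - dim
    t = np.linspace(0.0, 2.0 * np.pi, n)
    lg = np.log(_WM_GAMMA)
    n_lo = int(np.floor(np.log(1.0 / n) / lg))
    n_hi = int(np.ceil(np.log(n) / lg))
    x = np.zeros(n)
    for j in range(n_lo, n_hi + 1):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        x += _WM_GAMMA ** (-j * hurst) * np.sin(_WM_GAMMA ** j * t + phi)
    return x


def _fgn_davies_harte(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact stationary fGn sampling via circulant embedding."""
    if not 0.0 < hurst < 1.0:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    k = np.arange(n + 1, dtype=float)
    rho = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
                 + np.abs(k - 1) ** (2 * hurst))
    circ = np.concatenate([rho, rho[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8:
        raise ValueError("embedding not nonneg-definite")
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[n] = np.sqrt(lam[n] / m) * rng.standard_normal()
    j = np.arange(1, n)
    a = rng.standard_normal(n - 1)
    b = rng.standard_normal(n - 1)
    w[j] = np.sqrt(lam[j] / (2 * m)) * (a + 1j * b)
    w[m - j] = np.conj(w[j])
    return np.fft.fft(w)[:n].real


def _fbm_spectral(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """fBm-like trace by spectral synthesis: power ∝ f^(−(2H+1))."""
    if not 0.0 < hurst < 1.0:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    return _spectral_field((n,), 2 * hurst + 1, rng)


def _cantor_dust(ratio: float, levels: int) -> np.ndarray:
    """Binary Cantor dust: middle-removal with keep-ratio per end."""
    if not 0.0 < ratio < 0.5:
        raise ValueError("Cantor keep-ratio must lie in (0, 0.5)")
    intervals = [(0.0, 1.0)]
    for _ in range(levels):
        nxt = []
        for a, b in intervals:
            w = (b - a) * ratio
            nxt.append((a, a + w))
            nxt.append((b - w, b))
        intervals = nxt
    n = int(round(ratio ** (-levels)))
    centers = (np.arange(n) + 0.5) / n
    out = np.zeros(n)
    for a, b in intervals:
        out[(centers >= a) & (centers < b)] = 1.0
    return out


_MAP_TRANSIENT = 100


def _iterate_map(kind: str, n: int, params: dict, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(n)
    if kind == "logistic":
        a = params.get("a", 4.0)
        x = rng.uniform(0.01, 0.99)
        for _ in range(_MAP_TRANSIENT):
            x = a * x * (1 - x)
        for i in range(n):
            x = a * x * (1 - x)
            out[i] = x
    elif kind == "henon":
        a = params.get("a", 1.4)
        b = params.get("b", 0.3)
        x, y = rng.uniform(-0.1, 0.1, size=2)
        for _ in range(_MAP_TRANSIENT):
            x, y = 1 - a * x * x + y, b * x
        for i in range(n):
            x, y = 1 - a * x * x + y, b * x
            out[i] = x
    elif kind == "cubic":
        a = params.get("a", 3.0)
        x = rng.uniform(0.1, 0.9)
        for _ in range(_MAP_TRANSIENT):
            x = a * x * (1 - x * x)
        for i in range(n):
            x = a * x * (1 - x * x)
            out[i] = x
    elif kind == "spence":
        x = rng.uniform(0.01, 0.99)
        for _ in range(_MAP_TRANSIENT):
            x = abs(np.log(x))
        for i in range(n):
            x = abs(np.log(x))
            out[i] = x
    else:  # pragma: no cover - guarded by dispatch
        raise ValueError(kind)
    return out


_SEQ_KINDS = {"constant", "sine", "square", "triangle", "sawtooth", "gaussian",
              "uniform", "logistic", "henon", "cubic", "spence", "fgn_dhm",
              "fbm_ssm", "wm", "cantor"}


def generate_sequence(spec: GeneratorSpec) -> list[Sequence1D]:
    """Generate ``spec.count`` synthetic sequences of length ``spec.size``.

    Recognized kinds and their parameters (``spec.params``):

    ``constant`` (value), ``sine``/``square``/``triangle``/``sawtooth``
    (amplitude, frequency in cycles over the sequence), ``gaussian``
    (mean, sd), ``uniform`` (low, high), chaotic maps ``logistic`` (a),
    ``henon`` (a, b), ``cubic`` (a), ``spence``; ``fgn_dhm`` and
    ``fbm_ssm`` (hurst), ``wm`` (dim in (1,2)), ``cantor`` (ratio,
    levels — length is round(ratio**(-levels)), size is ignored).
    """
    if spec.kind not in _SEQ_KINDS:
        raise ValueError(f"unknown sequence kind {spec.kind!r}")
    n = int(spec.size)
    rng = _rng(spec.seed)
    p = spec.params
    seqs = []
    for i in range(spec.count):
        if spec.kind == "constant":
            x = np.full(n, float(p.get("value", 1.0)))
        elif spec.kind in ("sine", "square", "triangle", "sawtooth"):
            amp = float(p.get("amplitude", 1.0))
            freq = float(p.get("frequency", 8.0))
            phase = 2 * np.pi * freq * np.arange(n) / n
            if spec.kind == "sine":
                x = amp * np.sin(phase)
            elif spec.kind == "square":
                x = amp * signal.square(phase)
            elif spec.kind == "sawtooth":
                x = amp * signal.sawtooth(phase)
            else:
                x = amp * signal.sawtooth(phase, width=0.5)
        elif spec.kind == "gaussian":
            x = rng.normal(p.get("mean", 0.0), p.get("sd", 1.0), n)
        elif spec.kind == "uniform":
            x = rng.uniform(p.get("low", 0.0), p.get("high", 1.0), n)
        elif spec.kind in ("logistic", "henon", "cubic", "spence"):
            x = _iterate_map(spec.kind, n, p, rng)
        elif spec.kind == "fgn_dhm":
            x = _fgn_davies_harte(n, float(p.get("hurst", 0.5)), rng)
        elif spec.kind == "fbm_ssm":
            x = _fbm_spectral(n, float(p.get("hurst", 0.5)), rng)
        elif spec.kind == "wm":
            x = _weierstrass_mandelbrot(n, float(p.get("dim", 1.5)), rng)
        else:  # cantor
            x = _cantor_dust(float(p.get("ratio", 1.0 / 3.0)),
                             int(p.get("levels", 5)))
        seqs.append(Sequence1D(name=f"{spec.kind}-{i + 1}", values=x))
    return seqs


# ---------------------------------------------------------------------------
# 2D images
# ---------------------------------------------------------------------------

def _diamond_square(size: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Diamond-square midpoint displacement on a (2^k+1)-sided grid."""
    k = int(np.ceil(np.log2(max(size - 1, 1))))
    side = 2 ** k + 1
    grid = np.zeros((side, side))
    grid[0, 0], grid[0, -1], grid[-1, 0], grid[-1, -1] = rng.standard_normal(4)
    step = side - 1
    sd = 1.0
    while step > 1:
        half = step // 2
        sd *= 2.0 ** (-hurst)
        # diamond step: centers of squares
        for r in range(half, side, step):
            for c in range(half, side, step):
                avg = (grid[r - half, c - half] + grid[r - half, c + half]
                       + grid[r + half, c - half] + grid[r + half, c + half]) / 4
                grid[r, c] = avg + sd * rng.standard_normal()
        # square step: edge midpoints
        for r in range(0, side, half):
            start = half if (r // half) % 2 == 0 else 0
            for c in range(start, side, step):
                vals = []
                if r >= half:
                    vals.append(grid[r - half, c])
                if r + half < side:
                    vals.append(grid[r + half, c])
                if c >= half:
                    vals.append(grid[r, c - half])
                if c + half < side:
                    vals.append(grid[r, c + half])
                grid[r, c] = np.mean(vals) + sd * rng.standard_normal()
        step = half
    return grid[:size, :size]


def _menger_carpet_mask(level: int) -> np.ndarray:
    m = np.ones((1, 1), dtype=bool)
    for _ in range(level):
        side = m.shape[0]
        nxt = np.zeros((3 * side, 3 * side), dtype=bool)
        for r in range(3):
            for c in range(3):
                if not (r == 1 and c == 1):
                    nxt[r * side:(r + 1) * side, c * side:(c + 1) * side] = m
        m = nxt
    return m


def _embed_centered(mask: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    slices = tuple(slice((s - m) // 2, (s - m) // 2 + m)
                   for s, m in zip(shape, mask.shape))
    out[slices] = mask
    return out


def _sierpinski_chaos_game(shape: tuple[int, int], rng: np.random.Generator,
                           n_points: int | None = None) -> np.ndarray:
    h, w = shape
    verts = np.array([[h - 1, 0], [h - 1, w - 1], [0, (w - 1) / 2]], dtype=float)
    if n_points is None:
        n_points = max(100_000, 20 * h * w // 10)
    pt = verts[0].copy()
    img = np.zeros(shape, dtype=bool)
    choices = rng.integers(0, 3, size=n_points)
    for c in choices:
        pt = (pt + verts[c]) / 2.0
        img[int(round(pt[0])), int(round(pt[1]))] = True
    return img


_IMG_KINDS = {"random", "gaussian", "sine_radial", "sine_horizontal",
              "sine_vertical", "constant", "surface_fft", "surface_mpd",
              "ifs_menger", "ifs_sierpinski"}


def generate_image(spec: GeneratorSpec) -> list[GreyGrid]:
    """Generate ``spec.count`` grey images of shape ``spec.size`` = (H, W).

    Fractal kinds: ``surface_fft`` (spectral synthesis, param ``dim`` in
    (2,3), β = 8 − 2·dim), ``surface_mpd`` (diamond-square, H = 3 − dim),
    ``ifs_menger`` (param ``level``; drawn on the largest 3^L ≤ size and
    centered when size is not a power of three), ``ifs_sierpinski``.
    Grey output is min-max scaled to [0, ``grey_max``] (default 255).
    """
    if spec.kind not in _IMG_KINDS:
        raise ValueError(f"unknown image kind {spec.kind!r}")
    shape = (spec.size, spec.size) if isinstance(spec.size, int) else tuple(spec.size)
    if len(shape) != 2:
        raise ValueError("image size must be (height, width)")
    rng = _rng(spec.seed)
    p = spec.params
    grey_max = int(p.get("grey_max", 255))
    out = []
    for _ in range(spec.count):
        if spec.kind == "random":
            g = rng.integers(0, grey_max + 1, size=shape).astype(float)
        elif spec.kind == "gaussian":
            g = np.clip(rng.normal(grey_max / 2, grey_max / 6, shape), 0, grey_max)
            g = np.floor(g + 0.5)
        elif spec.kind == "constant":
            g = np.full(shape, float(p.get("value", grey_max)))
        elif spec.kind.startswith("sine"):
            freq = float(p.get("frequency", 8.0))
            rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                                 indexing="ij")
            if spec.kind == "sine_horizontal":
                phase = 2 * np.pi * freq * cc / shape[1]
            elif spec.kind == "sine_vertical":
                phase = 2 * np.pi * freq * rr / shape[0]
            else:
                r = np.hypot(rr - (shape[0] - 1) / 2, cc - (shape[1] - 1) / 2)
                phase = 2 * np.pi * freq * r / min(shape)
            g = quantize_grey(np.sin(phase), grey_max)
        elif spec.kind == "surface_fft":
            dim = float(p.get("dim", 2.5))
            if not 2.0 < dim < 3.0:
                raise ValueError("surface dimension must lie in (2, 3)")
            g = quantize_grey(_spectral_field(shape, 8.0 - 2.0 * dim, rng), grey_max)
        elif spec.kind == "surface_mpd":
            dim = float(p.get("dim", 2.5))
            if not 2.0 < dim < 3.0:
                raise ValueError("surface dimension must lie in (2, 3)")
            g = quantize_grey(_diamond_square(max(shape), 3.0 - dim, rng)[
                :shape[0], :shape[1]], grey_max)
        elif spec.kind == "ifs_menger":
            level = p.get("level")
            if level is None:
                level = int(np.floor(np.log(min(shape)) / np.log(3)))
            mask = _menger_carpet_mask(int(level))
            if mask.shape[0] > min(shape):
                raise ValueError("Menger level too large for requested size")
            g = _embed_centered(mask, shape).astype(float) * grey_max
        else:  # ifs_sierpinski
            g = _sierpinski_chaos_game(shape, rng).astype(float) * grey_max
        out.append(GreyGrid(g))
    return out


# ---------------------------------------------------------------------------
# 3D volumes
# ---------------------------------------------------------------------------

def _menger_cube_mask(level: int) -> np.ndarray:
    m = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        side = m.shape[0]
        nxt = np.zeros((3 * side,) * 3, dtype=bool)
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    if (a == 1) + (b == 1) + (c == 1) < 2:
                        nxt[a * side:(a + 1) * side, b * side:(b + 1) * side,
                            c * side:(c + 1) * side] = m
        m = nxt
    return m


def _random_additions_3d(shape: tuple[int, int, int], hurst: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Midpoint-displacement volume via successive random additions."""
    levels = int(np.ceil(np.log2(max(shape))))
    side = 2
    field = rng.standard_normal((side,) * 3)
    sd = 1.0
    for _ in range(levels):
        field = ndimage.zoom(field, 2.0, order=1, grid_mode=True, mode="nearest")
        sd *= 2.0 ** (-hurst)
        field = field + sd * rng.standard_normal(field.shape)
    return field[:shape[0], :shape[1], :shape[2]]


_VOL_KINDS = {"random", "gaussian", "constant", "volume_fft", "volume_mpd",
              "ifs_menger_cube"}

#: refuse to synthesize volumes above this voxel count (memory guard)
MAX_VOXELS = 320 ** 3


def generate_volume(spec: GeneratorSpec) -> GreyGrid:
    """Generate one grey volume of shape ``spec.size`` = (D, H, W).

    ``volume_fft`` uses 3D spectral synthesis with β = 11 − 2·dim for a
    target dimension in (3, 4), giving a grey pattern that is smooth
    along all three axes including depth; ``ifs_menger_cube`` draws the
    level-L Menger sponge on a 3^L-sided cube.
    """
    if spec.kind not in _VOL_KINDS:
        raise ValueError(f"unknown volume kind {spec.kind!r}")
    shape = (spec.size,) * 3 if isinstance(spec.size, int) else tuple(spec.size)
    if len(shape) != 3:
        raise ValueError("volume size must be (depth, height, width)")
    if int(np.prod(shape)) > MAX_VOXELS:
        raise ValueError(f"voxel count {np.prod(shape)} exceeds cap {MAX_VOXELS}")
    rng = _rng(spec.seed)
    p = spec.params
    grey_max = int(p.get("grey_max", 255))
    if spec.kind == "random":
        g = rng.integers(0, grey_max + 1, size=shape).astype(float)
    elif spec.kind == "gaussian":
        g = np.floor(np.clip(rng.normal(grey_max / 2, grey_max / 6, shape),
                             0, grey_max) + 0.5)
    elif spec.kind == "constant":
        g = np.full(shape, float(p.get("value", grey_max)))
    elif spec.kind == "volume_fft":
        dim = float(p.get("dim", 3.5))
        if not 3.0 < dim < 4.0:
            raise ValueError("volume dimension must lie in (3, 4)")
        g = quantize_grey(_spectral_field(shape, 11.0 - 2.0 * dim, rng), grey_max)
    elif spec.kind == "volume_mpd":
        dim = float(p.get("dim", 3.5))
        if not 3.0 < dim < 4.0:
            raise ValueError("volume dimension must lie in (3, 4)")
        g = quantize_grey(_random_additions_3d(shape, 4.0 - dim, rng), grey_max)
    else:  # ifs_menger_cube
        level = p.get("level")
        if level is None:
            level = int(np.floor(np.log(min(shape)) / np.log(3)))
        mask = _menger_cube_mask(int(level))
        if mask.shape[0] > min(shape):
            raise ValueError("Menger level too large for requested size")
        g = _embed_centered(mask, shape).astype(float) * grey_max
    return GreyGrid(g)
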