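"""Surrogate data and noise injection for sequences, images and volumes.

Surrogate analysis builds randomized copies of a dataset that preserve
selected linear properties while destroying others, providing a null
against which a nonlinear statistic can be compared.  Four methods are
offered in any rank (1D/2D/3D):

* ``shuffle`` — uniform random permutation of all samples; preserves the
  value multiset exactly, destroys all correlation.
* ``gaussian`` — iid normal draws matching the data's sample mean and SD;
  destroys both distribution shape and correlation.
* ``random_phase`` — Fourier phase randomization under Hermitian symmetry;
  preserves the power spectrum (hence all linear autocorrelation), the DC
  bin is untouched so the mean is conserved.
* ``aaft`` — amplitude-adjusted Fourier transform (Theiler): rank-remap
  to a Gaussian, phase-randomize, rank-remap back; preserves the value
  multiset exactly and the spectrum approximately.

An ensemble driver evaluates a statistic on the original and on ``count``
surrogates and reports all individual values plus their mean and sample
standard deviation.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .types import GreyGrid, Sequence1D, SurrogateReport

__all__ = ["make_surrogate", "add_noise", "surrogate_ensemble",
           "SURROGATE_METHODS", "NOISE_KINDS"]

SURROGATE_METHODS = ("shuffle", "gaussian", "random_phase", "aaft")
NOISE_KINDS = ("shot", "salt_pepper", "uniform", "gaussian", "rayleigh",
               "exponential")


def _unwrap(data: Sequence1D | GreyGrid) -> tuple[np.ndarray, Callable]:
    if isinstance(data, Sequence1D):
        return data.values, lambda arr: Sequence1D(name=data.name, values=arr)
    if isinstance(data, GreyGrid):
        return data.data, lambda arr: GreyGrid(np.clip(arr, 0.0, 255.0))
    arr = np.asarray(data, dtype=float)
    return arr, lambda out: out


def _random_phase_array(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    f = np.fft.fftn(x)
    w = np.fft.fftn(rng.standard_normal(x.shape))
    mag = np.abs(w)
    mag[mag == 0] = 1.0
    u = w / mag  # unit modulus, exact Hermitian symmetry
    u.flat[0] = 1.0  # leave DC untouched so the mean is conserved
    return np.fft.ifftn(f * u).real


def _aaft_array(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    flat = x.ravel()
    order = np.argsort(flat, kind="stable")
    # rank-remap the data onto sorted Gaussian deviates
    gauss = np.sort(rng.standard_normal(flat.size))
    y = np.empty_like(flat)
    y[order] = gauss
    y_surr = _random_phase_array(y.reshape(x.shape), rng).ravel()
    # rank-remap back onto the original amplitude distribution
    out = np.empty_like(flat)
    out[np.argsort(y_surr, kind="stable")] = np.sort(flat)
    return out.reshape(x.shape)


def make_surrogate(data: Sequence1D | GreyGrid, method: str,
                   seed: int | None = None):
    """Return one surrogate of ``data`` (same type, same shape)."""
    if method not in SURROGATE_METHODS:
        raise ValueError(f"unknown surrogate method {method!r}")
    x, wrap = _unwrap(data)
    if method in ("random_phase", "aaft") and x.size < 4:
        raise ValueError("spectral surrogates need at least 4 samples")
    rng = np.random.default_rng(seed)
    if method == "shuffle":
        out = rng.permutation(x.ravel()).reshape(x.shape)
    elif method == "gaussian":
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        out = rng.normal(x.mean(), sd, size=x.shape)
    elif method == "random_phase":
        out = _random_phase_array(x, rng)
    else:
        out = _aaft_array(x, rng)
    return wrap(out)


def add_noise(data: Sequence1D | GreyGrid, kind: str, level: float,
              seed: int | None = None):
    """Contaminate ``data`` with one of six noise kinds.

    ``level`` is the SD for gaussian, the half-width for uniform, the
    scale for rayleigh/exponential (draws are centered before adding),
    the corrupted fraction p for salt & pepper (each corrupted position
    set to the data minimum or maximum with probability p/2 each), and
    the gain for shot noise (each value v is replaced by
    Poisson(v/level)·level).  Grid outputs are clamped to [0, 255];
    level 0 returns the input unchanged.
    """
    if kind not in NOISE_KINDS:
        raise ValueError(f"unknown noise kind {kind!r}")
    if level < 0:
        raise ValueError("noise level must be >= 0")
    x, wrap = _unwrap(data)
    if level == 0:
        return wrap(x.copy())
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        out = x + rng.normal(0.0, level, x.shape)
    elif kind == "uniform":
        out = x + rng.uniform(-level, level, x.shape)
    elif kind == "rayleigh":
        draws = rng.rayleigh(level, x.shape)
        out = x + draws - level * np.sqrt(np.pi / 2.0)
    elif kind == "exponential":
        draws = rng.exponential(level, x.shape)
        out = x + draws - level
    elif kind == "salt_pepper":
        if level > 1:
            raise ValueError("salt & pepper fraction must be <= 1")
        lo = 0.0
        hi = 255.0 if isinstance(data, GreyGrid) else float(x.max())
        if isinstance(data, Sequence1D):
            lo = float(x.min())
        out = x.copy().ravel()
        u = rng.random(out.size)
        out[u < level / 2.0] = lo
        out[(u >= level / 2.0) & (u < level)] = hi
        out = out.reshape(x.shape)
    else:  # shot
        out = rng.poisson(np.maximum(x, 0.0) / level).astype(float) * level
    return wrap(out)


def surrogate_ensemble(data: Sequence1D | GreyGrid,
                       statistic: Callable[..., float],
                       method: str, count: int,
                       seed: int | None = None) -> SurrogateReport:
    """Evaluate ``statistic`` on the original and on ``count`` surrogates.

    Surrogate seeds are spawned deterministically from ``seed``; the
    report lists every surrogate value plus their mean and sample SD
    (denominator n−1; SD is 0 for a single surrogate).
    """
    if count < 1:
        raise ValueError("surrogate count must be >= 1")
    original = float(statistic(data))
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seed_seq.spawn(count)]
    values = []
    for i, child in enumerate(child_seeds):
        surr = make_surrogate(data, method, seed=child)
        try:
            values.append(float(statistic(surr)))
        except Exception as exc:
            raise RuntimeError(f"statistic failed on surrogate {i + 1}: {exc}") from exc
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if count > 1 else 0.0
    return SurrogateReport(original_value=original, surrogate_values=values,
                           surrogate_mean=float(arr.mean()), surrogate_sd=sd)
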