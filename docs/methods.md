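# Methods

This note records the models behind `fractan`, the numerical choices
that were genuinely open, and what the synthetic benchmarks do and do
not demonstrate.

## The exponent bookkeeping

Everything in the package hangs off one relation between the fractal
dimension *D* of a grey-value graph embedded in rank *E* (signal graph
E = 1, surface E = 2, volume E = 3), the Hurst exponent *H* of the
underlying fractional process, and the spectral exponent *β* of its
power-law spectrum P(f) ∝ f^(−β):

    D = E + 1 − H,        β = 2H + E  =  3E + 2 − 2D.

The three canonical self-tests are D = 1.5 ↔ β = 2 (1D), D = 2.5 ↔ β = 3
(2D) and D = 3.5 ↔ β = 4 (3D). Generators synthesize at a prescribed D
(or H); estimators invert the same relation, so generator–estimator
round trips are exact consistency checks of both sides.

## Generators

* **Weierstrass–Mandelbrot** — x(t) = Σ γ^(−nH) sin(γⁿ t + φₙ) with
  γ = 1.5, H = 2 − D, φₙ uniform, t on [0, 2π] sampled N times. The term
  range n is chosen so γⁿ spans [1/N, N]: below that the terms are flat
  over the window, above they alias. γ itself is a free convention; any
  γ ∈ (1, 2) gives dense frequency coverage and the recovered dimension
  is insensitive to it.
* **fGn (Davies–Harte)** — exact circulant embedding of the fGn
  autocovariance ρ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}); the
  embedding eigenvalues are checked for nonnegativity (tolerance 1e−8)
  and the method fails loudly rather than clipping meaningful negative
  mass. Sampling is exact — the benchmark autocovariance test holds to
  Monte-Carlo error with no asymptotic argument.
* **fBm / fractal surfaces / volumes (spectral synthesis)** — the target
  amplitude |f|^(−β/2) is multiplied by a unit-modulus random-phase
  field obtained as W/|W| with W the FFT of white Gaussian noise. This
  yields *exactly* the prescribed amplitude spectrum with uniform random
  phases and exact Hermitian symmetry in any rank, with no per-bin
  conjugate bookkeeping and no parity special cases. The 1D trace is
  synthesized directly at β = 2H + 1 (the motion scale), which is what
  the PSD-recovery benchmark measures.
* **Midpoint displacement** — 2D uses classic diamond-square with
  per-level displacement SD ratio 2^(−H), H = 3 − D; 3D uses successive
  random additions (×2 linear upsampling plus level-scaled noise), the
  natural rank-3 analogue.
* **IFS sets** — Menger carpet/cube are constructed by exact recursion
  on 3^L grids (foreground counts 8^L and 20^L exactly); when the
  requested canvas is larger the set is centered. Sierpinski uses the
  chaos game.
* **Chaotic maps** — logistic (a = 4), Henon (a = 1.4, b = 0.3, x
  emitted), cubic x ← a·x(1 − x²) (a = 3), Spence x ← |ln x|; 100
  transient steps are discarded and initial conditions are drawn from
  each map's basin.
* **Grey quantization** — images/volumes are min-max scaled to
  [0, grey_max] and rounded half-up before estimation, mirroring an
  8-bit acquisition pipeline; the quantization noise floor is part of
  what the recovery benchmarks absorb.

Defaults (N = 1024 sequences, 512² surfaces, 256³ volumes, grey_max
255, target dimensions 1.5/2.5/3.5) are the canonical walkthrough
conditions and are used verbatim by `scripts/acceptance.py`.

## Estimators: numerical choices

* **Log-log regression** — every scaling estimator funnels through one
  OLS of ln(measure) on ln(scale) with a 1-based inclusive index window
  ("Regression Min/Max" convention). Non-positive measures raise unless
  `skip_zero` is enabled; fewer than two usable points is a degenerate
  regression error, never a sentinel value.
* **Radial spectrum averaging** — power is binned by rounded radial
  wavenumber (in cycles per shortest side), bins 1..⌊min side/2⌋, DC
  excluded; the Hann window (separable, applied after mean subtraction
  to suppress DC leakage) controls spectral leakage of the non-periodic
  field. The FFT dimension fits the full bin range by default.
* **Raster scales** — box counting, generalized dimensions and default
  lacunarity sizes use the divisors of the shortest side (≤ side/2), so
  every box tiles the grid exactly; partial-box inflation at the far
  edge otherwise biases the slope low. On power-of-two sides this is
  exactly the dyadic ladder; on 3^L sides it is the triadic ladder on
  which exact self-similar sets count exactly. Prime-ish sides fall
  back to dyadic scales with origin-anchored partial boxes. Box-scale
  estimators fit the central scaling region by default (smallest and
  largest scale dropped when ≥ 4 scales exist) to reduce finite-size
  bias; the FFI is the exception (see below).
* **Minkowski dimension** — dilation by Chebyshev balls; the regression
  runs against the structuring-element diameter 2r+1 rather than the
  radius, which makes the point/line/area limiting cases exact at small
  r (A = (2r+1)², (2r+1)·length, constant).
* **2D/3D Higuchi, direct differences** — the mean absolute k-spaced
  grey difference δ(k) is normalized to M(k) = δ(k)/k^(E+1), fixed by a
  calibration constraint: a smooth plane ramp (δ ∝ k) must give
  M ∝ k^(−E), hence D = E, and iid noise (δ ≈ const) gives D = E + 1.
  For a fractal graph with Hölder exponent H, δ(k) ∝ k^H recovers
  D = E + 1 − H. The profile variant averages the genuine 1D Higuchi
  length curves over all rows and columns and adds 1 to map the profile
  dimension into the surface range.
* **FFI** — boundary = foreground minus its 4-connected erosion
  (4-connectivity gives the thinner boundary). FFI fits box counts over
  the *full* scale range: at coarse scales a fractal's boundary occupies
  the same boxes as its area, so a central-window fit would drive FFI of
  any thin fractal to 0 and the index would carry no information.
* **ApEn/SampEn** — Chebyshev metric; tolerance r defaults to 0.2 ×
  sample SD (ddof = 1). ApEn includes self-matches (Pincus), SampEn
  excludes them and restricts both template sets to the common N − m
  count (Richman–Moorman); zero match counts raise rather than return 0.
* **Permutation entropy** — ordinal patterns with ties broken by
  earlier index (stable argsort), reported raw (nats), per symbol
  (/(order−1)) or normalized (/ln order!).
* **PSD Hurst** — Hann periodogram, DC dropped, fit over the lowest
  half of the frequency bins by default (the scaling regime of interest
  is low-frequency); β ∈ (−1, 1) ⇒ fGn with H = (β+1)/2, β ∈ [1, 3) ⇒
  fBm with H = (β−1)/2, the boundary β = 1 classified fBm by the
  half-open convention.
* **Surrogates** — random-phase surrogates reuse the unit-modulus
  phase-field trick, leaving the DC coefficient untouched so the mean
  is conserved to machine precision while all other phases randomize;
  self-conjugate (Nyquist) bins may flip sign, which preserves power and
  realness. AAFT is Theiler's single-pass scheme (rank-remap to
  Gaussian, phase-randomize, rank-remap back); the value multiset is
  preserved exactly, the spectrum only approximately. Ensemble
  sub-seeds are spawned deterministically from the base seed.
* **Kolmogorov complexity** — canonical serialization (8-byte IEEE
  doubles for sequences, row-major 8-bit grey for grids), zlib or gzip
  at level 9. Logical depth (median decompression wall time) is
  reported with an explicit hardware-dependence flag and is not used in
  any quantitative check.

## Degenerate inputs

Constant data is rejected wherever the estimate is undefined (Higuchi,
DFA, Sevcik, spectral estimators raise flat-spectrum/degenerate errors;
Petrosian legitimately returns 1). Two-point sequences, empty
foregrounds, empty boundaries and all-coincident point sets raise named
errors; nothing returns NaN silently.

## What the benchmarks show — and what they don't

The synthetic workloads are *monofractal, stationary, isotropic* fields
with exactly prescribed power-law structure, plus exact IFS sets. They
demonstrate that each estimator inverts its own generative model at
realistic sizes (N = 1024–8192, 512², 128³–256³), that independent
estimators agree (FFT vs Higuchi dimension within 0.3 on shared
surfaces), and that the implementations match brute-force references
exactly. They do not exercise nonstationarity, anisotropy,
multifractality beyond the D_q inequality checks, measurement noise
other than the six synthetic kinds, or the short, gappy records typical
of real biological data — on such data the usual caveats (scaling-range
selection, finite-size bias) apply and the regression windows should be
inspected via the returned `ScalingFit`, not trusted blindly.

## Known limitations

* The Sevcik estimate converges to the ideal dimension only
  logarithmically (a straight line reads ≈ 1.035 at N = 10⁴); it is a
  fast rough estimate, as is Katz.
* Spectral surrogates of 8-bit grids are clipped back to [0, 255], so
  their power spectrum is preserved only approximately (exactly for
  sequences).
* Lacunarity and correlation dimension are 2D-only in this release;
  Minkowski uses the dilation method only (no blanket/variation).
* The logical-depth proxy is wall-clock based and machine dependent by
  construction.
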