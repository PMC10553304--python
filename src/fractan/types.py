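"""Core domain types shared across the toolkit.

The toolkit operates uniformly on three kinds of data: named 1D signals
(:class:`Sequence1D`), grey-value grids of rank 2 or 3 (:class:`GreyGrid`),
and binary masks derived from them (:class:`BinaryMask`).  Estimator output
is collected in :class:`ResultTable` rows, and regression-based dimension
estimates carry their log-log fit in a :class:`DimensionResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd


class DegenerateRegressionError(ValueError):
    """Fewer than two usable points remain for a log-log regression."""


class FlatSpectrumError(ValueError):
    """All spectral power sits in the DC bin (constant input)."""


class RaggedColumnError(ValueError):
    """A CSV column contains internal (non-trailing) NaN values."""


@dataclass
class Sequence1D:
    """A named column of real samples.

    Parameters
    ----------
    name
        Column header label.
    values
        Ordered real samples, length >= 1, unit-free.  NaN is not allowed:
        trailing NaN padding is stripped by the CSV reader before
        construction.
    """

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("Sequence1D requires a 1D array of length >= 1")
        if np.isnan(self.values).any():
            raise ValueError("Sequence1D must not contain NaN")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class GreyGrid:
    """A 2D image or 3D volume of grey values in [0, 255].

    Axis order is (row, column) for rank 2 and (slice, row, column) for
    rank 3.  Values are stored as float64 internally even though file
    storage is 8-bit.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError("GreyGrid rank must be 2 or 3")
        if min(self.data.shape) < 1:
            raise ValueError("all grid dimensions must be >= 1")
        if self.data.min() < 0 or self.data.max() > 255:
            raise ValueError("grey values must lie in [0, 255]")

    @property
    def rank(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A {0,1} mask with the shape of its source grid."""

    data: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim not in (2, 3):
            raise ValueError("BinaryMask rank must be 2 or 3")

    @property
    def rank(self) -> int:
        return self.data.ndim

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())


class ResultTable:
    """A labelled table of analysis results, one row per analyzed input.

    Thin wrapper around a :class:`pandas.DataFrame`; the index holds the
    row labels that become the first CSV column on write.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    @classmethod
    def from_records(cls, records: list[Mapping[str, Any]],
                     labels: list[str] | None = None) -> "ResultTable":
        frame = pd.DataFrame.from_records(records)
        if labels is not None:
            frame.index = pd.Index(labels)
        return cls(frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ResultTable({len(self.frame)} rows x {len(self.frame.columns)} cols)"


@dataclass
class AnalysisSpec:
    """Windowing and surrogate options shared by the 1D analysis drivers."""

    range_mode: str = "entire"          # entire | subsequent_boxes | sliding_box
    box_length: int = 100
    surrogate_method: str = "none"      # none | shuffle | gaussian | random_phase | aaft
    surrogate_count: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.range_mode not in ("entire", "subsequent_boxes", "sliding_box"):
            raise ValueError(f"unknown range mode {self.range_mode!r}")
        if self.range_mode != "entire" and self.box_length < 1:
            raise ValueError("box_length must be positive")
        if self.surrogate_method != "none" and self.surrogate_count < 1:
            raise ValueError("surrogate_count must be >= 1")


@dataclass
class ScalingFit:
    """Least-squares fit of ln(measure) on ln(scale) over an index window."""

    slope: float
    intercept: float
    r_squared: float
    reg_min: int  # 1-based inclusive
    reg_max: int


@dataclass
class ScaleSeries:
    """Paired (scale, measure) points feeding a log-log regression."""

    scales: np.ndarray
    measures: np.ndarray

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.measures = np.asarray(self.measures, dtype=float)
        if self.scales.shape != self.measures.shape or self.scales.ndim != 1:
            raise ValueError("scales and measures must be 1D arrays of equal length")
        if len(self.scales) < 2:
            raise ValueError("a ScaleSeries needs at least 2 points")
        if (self.scales <= 0).any():
            raise ValueError("scales must be positive")
        if np.diff(self.scales).min() <= 0:
            raise ValueError("scales must be strictly increasing")

    def __len__(self) -> int:
        return int(self.scales.size)


@dataclass
class DimensionResult:
    """A dimension (or exponent) estimate plus its regression diagnostics."""

    dimension: float
    fit: ScalingFit | None
    method: str
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def r_squared(self) -> float | None:
        return None if self.fit is None else self.fit.r_squared


@dataclass
class SurrogateReport:
    """Per-surrogate statistic values with their ensemble mean and SD."""

    original_value: float
    surrogate_values: list[float]
    surrogate_mean: float
    surrogate_sd: float


@dataclass
class LacunaritySeries:
    """Lacunarity Λ(r) per box size; mode is 'raster' or 'gliding'."""

    box_sizes: np.ndarray
    lacunarity: np.ndarray
    mode: str


@dataclass
class ProbDist:
    """A discrete probability distribution (histogram probabilities)."""

    probabilities: np.ndarray
    source: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 1 or self.probabilities.size < 1:
            raise ValueError("probabilities must be a 1D array of length >= 1")
        if (self.probabilities < -1e-12).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")


@dataclass
class GeneratorSpec:
    """Recipe for one batch of synthetic sequences, images or volumes."""

    kind: str
    size: int | tuple[int, ...]
    count: int = 1
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
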