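"""Readers and writers for the sequence CSV dialect, images and volumes.

Sequence files are comma-separated text: the first row holds column
headers, the first column holds row headers (typically sample numbers),
data cells are real numbers with a point decimal, and shorter columns
are padded at the bottom with the literal token ``NaN`` so that every
column has the same length.

Images are 8-bit grey (or 24-bit RGB, converted on load) PNG/TIFF;
volumes are multi-page TIFF stacks with the page index as slice axis.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .types import BinaryMask, GreyGrid, RaggedColumnError, ResultTable, Sequence1D

__all__ = ["read_sequences_csv", "write_sequences_csv", "write_table_csv",
           "read_table_csv", "read_grid", "write_grid", "binarize"]

#: BT.709 luminance weights for RGB to grey conversion
_LUMA = (0.2126, 0.7152, 0.0722)


def read_sequences_csv(path: str | os.PathLike) -> list[Sequence1D]:
    """Load every data column of a sequence CSV as a :class:`Sequence1D`.

    The first row is treated as headers and the first column as row
    headers (skipped as data).  Trailing runs of NaN are stripped per
    column; an internal NaN raises :class:`RaggedColumnError`, and a
    malformed number raises a parse error naming its row and column.
    """
    frame = pd.read_csv(path, index_col=0, dtype=str, skipinitialspace=True)
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise ValueError(f"{path}: no data columns found")
    sequences = []
    for col in frame.columns:
        raw = frame[col].to_numpy()
        values = np.empty(len(raw))
        for i, cell in enumerate(raw):
            text = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                else str(cell).strip()
            if text == "" or text.lower() == "nan":
                values[i] = np.nan
                continue
            try:
                values[i] = float(text)
            except ValueError:
                raise ValueError(
                    f"{path}: malformed number {text!r} at row "
                    f"{frame.index[i]!r}, column {col!r}") from None
        isnan = np.isnan(values)
        n = len(values)
        while n > 0 and isnan[n - 1]:
            n -= 1
        if n == 0:
            raise ValueError(f"{path}: column {col!r} is entirely NaN")
        if isnan[:n].any():
            raise RaggedColumnError(
                f"{path}: ragged column {col!r} has internal NaN")
        sequences.append(Sequence1D(name=str(col), values=values[:n]))
    return sequences


def write_sequences_csv(sequences: list[Sequence1D],
                        path: str | os.PathLike) -> None:
    """Write sequences as the CSV dialect, padding short columns with NaN."""
    if not sequences:
        raise ValueError("no sequences to write")
    n = max(len(s) for s in sequences)
    data = {}
    for seq in sequences:
        col = np.full(n, np.nan)
        col[:len(seq)] = seq.values
        data[seq.name] = col
    frame = pd.DataFrame(data, index=np.arange(1, n + 1))
    frame.index.name = "Row"
    frame.to_csv(path, na_rep="NaN", float_format="%.17g")


def write_table_csv(table: ResultTable, path: str | os.PathLike) -> None:
    """Write a result table: header row first, row labels in column one."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    frame = table.frame.copy()
    frame.index.name = frame.index.name or "Row"
    frame.to_csv(path, na_rep="NaN", float_format="%.17g")


def read_table_csv(path: str | os.PathLike) -> ResultTable:
    """Read back a result table written by :func:`write_table_csv`."""
    return ResultTable(pd.read_csv(path, index_col=0,
                                   float_precision="round_trip"))


def _to_grey(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(float)
        grey = rgb @ np.asarray(_LUMA)
        return np.floor(grey + 0.5)
    return arr.astype(float)


def read_grid(path: str | os.PathLike) -> GreyGrid:
    """Read a PNG/TIFF image or a multi-page TIFF volume as a grey grid.

    RGB input is converted to grey by BT.709 luminance (rounded half-up);
    multi-page TIFFs become rank-3 grids with page index as slice axis.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.size == 0:
        raise ValueError(f"{path}: zero-size image")
    if arr.dtype not in (np.uint8, np.dtype(bool)):
        raise ValueError(f"{path}: unsupported bit depth {arr.dtype} (8-bit expected)")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = _to_grey(arr)
    elif arr.ndim == 4 and arr.shape[-1] in (3, 4):  # RGB volume
        arr = np.stack([_to_grey(page) for page in arr])
    elif arr.ndim not in (2, 3):
        raise ValueError(f"{path}: unsupported image rank {arr.ndim}")
    return GreyGrid(arr.astype(float))


def write_grid(grid: GreyGrid, path: str | os.PathLike) -> None:
    """Write a grey grid as 8-bit PNG/TIFF (rank 2) or multi-page TIFF."""
    arr = np.floor(grid.data + 0.5).astype(np.uint8)
    ext = os.path.splitext(str(path))[1].lower()
    if grid.rank == 3 or ext in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def binarize(grid: GreyGrid, threshold: float = 0.0) -> BinaryMask:
    """Foreground mask: 1 where grey > threshold, else 0."""
    return BinaryMask(data=grid.data > threshold, threshold=threshold)
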