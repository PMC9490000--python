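"""Fixed window grids and per-window read-depth matrices.

Copy-number inference from short-read coverage starts from a fixed grid of
non-overlapping windows (default 800 bp) tiled across each chromosome.
Per-individual mean depth in every window is then rescaled so that the
diploid baseline sits at 1.0: a heterozygous deletion is expected near
0.5, a single-copy gain near 1.5.

All coordinates are 0-based, half-open. Depth matrices are exchanged as
plain TSV with header ``chrom  start  end  <id1> ... <idN>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import InputDataError, ParameterError

__all__ = [
    "GenomeLayout",
    "WindowGrid",
    "RawDepthMatrix",
    "NormalizedDepthMatrix",
    "make_window_grid",
    "read_genome_layout",
    "read_depth_matrix",
    "write_depth_matrix",
    "normalize_depth",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in bp."""

    names: tuple[str, ...]
    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise InputDataError("duplicate chromosome names in genome layout")
        for name in self.names:
            length = self.lengths[name]
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise InputDataError(
                    f"chromosome {name!r} has non-positive length {length!r}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeLayout":
        pairs = list(pairs)
        return cls(tuple(n for n, _ in pairs), {n: int(l) for n, l in pairs})

    @property
    def total_length(self) -> int:
        return sum(self.lengths[n] for n in self.names)

    def __len__(self) -> int:
        return len(self.names)


def read_genome_layout(path: str | Path) -> GenomeLayout:
    """Read a two-column ``chrom length`` TSV (.fai files work: extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputDataError(f"{path}: expected at least 2 columns (chrom, length)")
    try:
        lengths = df.iloc[:, 1].astype(int)
    except ValueError as exc:
        raise InputDataError(f"{path}: non-integer chromosome length: {exc}") from exc
    return GenomeLayout.from_pairs(zip(df.iloc[:, 0], lengths))


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping fixed-width windows sorted by (chromosome order, start)."""

    windows: pd.DataFrame = field(repr=False)  # columns: chrom, start, end
    window_size: int

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def index_lookup(self) -> dict[tuple[str, int], int]:
        """Map (chrom, start) -> row index."""
        return {
            (c, int(s)): i
            for i, (c, s) in enumerate(
                zip(self.windows["chrom"], self.windows["start"])
            )
        }

    def windows_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of grid windows overlapping [start, end) on ``chrom``."""
        w = self.windows
        mask = (w["chrom"] == chrom) & (w["start"] < end) & (w["end"] > start)
        return np.flatnonzero(mask.to_numpy())

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous row ranges per chromosome (grid is sorted)."""
        out: dict[str, slice] = {}
        chroms = self.windows["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out


def make_window_grid(genome: GenomeLayout, window_size: int = 800) -> WindowGrid:
    """Tile each chromosome with ``window_size`` windows; trailing remainder dropped.

    Chromosomes shorter than one window contribute no windows.
    """
    if window_size < 1:
        raise ParameterError(f"window_size must be >= 1, got {window_size}")
    if len(genome) == 0:
        raise InputDataError("empty genome layout")
    chroms: list[str] = []
    starts: list[int] = []
    for name in genome.names:
        n = genome.lengths[name] // window_size
        chroms.extend([name] * n)
        starts.extend(range(0, n * window_size, window_size))
    starts_arr = np.asarray(starts, dtype=np.int64)
    df = pd.DataFrame(
        {"chrom": chroms, "start": starts_arr, "end": starts_arr + window_size}
    )
    return WindowGrid(df, window_size)


def _check_matrix(grid: WindowGrid, individuals: tuple[str, ...], values: np.ndarray):
    if values.shape != (grid.n_windows, len(individuals)):
        raise InputDataError(
            f"depth matrix shape {values.shape} does not match "
            f"({grid.n_windows} windows, {len(individuals)} individuals)"
        )
    if not np.all(np.isfinite(values)):
        raise InputDataError("depth matrix contains non-finite values")
    if np.any(values < 0):
        raise InputDataError("depth matrix contains negative values")


@dataclass(frozen=True)
class RawDepthMatrix:
    """Per-window mean raw depth (reads-per-base equivalents), windows x individuals."""

    grid: WindowGrid
    individuals: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_matrix(self.grid, self.individuals, self.values)

    def column(self, individual: str) -> np.ndarray:
        return self.values[:, self.individuals.index(individual)]


@dataclass(frozen=True)
class NormalizedDepthMatrix:
    """Copy-number-scaled depth: each individual's diploid baseline is 1.0.

    ``stdev`` is the plain (ddof=0) standard deviation of each normalized
    column; it drives the statistical half of the calling criterion.
    """

    grid: WindowGrid
    individuals: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    scale_factors: np.ndarray = field(repr=False)
    stdev: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_matrix(self.grid, self.individuals, self.values)

    def column(self, individual: str) -> np.ndarray:
        return self.values[:, self.individuals.index(individual)]

    def columns_for(self, individuals: Iterable[str]) -> np.ndarray:
        idx = [self.individuals.index(i) for i in individuals]
        return self.values[:, idx]


def read_depth_matrix(path: str | Path, grid: WindowGrid) -> RawDepthMatrix:
    """Load a depth TSV and align it to ``grid``; every grid window must be present."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ("chrom", "start", "end")
    if tuple(df.columns[:3]) != required:
        raise InputDataError(
            f"{path}: first three columns must be {required}, got {tuple(df.columns[:3])}"
        )
    individuals = tuple(df.columns[3:])
    if not individuals:
        raise InputDataError(f"{path}: no individual columns")
    lookup = {(c, int(s)): i for i, (c, s) in enumerate(zip(df["chrom"], df["start"]))}
    rows = np.empty(grid.n_windows, dtype=np.int64)
    for gi, (c, s) in enumerate(zip(grid.windows["chrom"], grid.windows["start"])):
        key = (c, int(s))
        if key not in lookup:
            raise InputDataError(f"{path}: missing grid window {c}:{s}-{s + grid.window_size}")
        rows[gi] = lookup[key]
    try:
        values = df.iloc[:, 3:].to_numpy(dtype=float)[rows]
    except ValueError as exc:
        raise InputDataError(f"{path}: malformed depth value: {exc}") from exc
    return RawDepthMatrix(grid, individuals, values)


def write_depth_matrix(matrix: RawDepthMatrix | NormalizedDepthMatrix, path: str | Path) -> None:
    """Write the documented depth TSV dialect (round-trips bit-exactly)."""
    df = matrix.grid.windows.copy()
    for j, ind in enumerate(matrix.individuals):
        df[ind] = matrix.values[:, j]
    df.to_csv(path, sep="\t", index=False)


def normalize_depth(
    raw: RawDepthMatrix,
    mode: Literal["global-median", "per-chromosome-median"] = "global-median",
) -> NormalizedDepthMatrix:
    """Divide each individual's column by its median depth (global or per chromosome).

    The median is robust to the CNV windows themselves, so the diploid bulk
    of the genome lands at 1.0. Per-chromosome mode supports sex-chromosome
    analyses where a whole chromosome sits at a different baseline.
    """
    values = raw.values.astype(float).copy()
    scale = np.median(values, axis=0)
    if mode == "global-median":
        for j, ind in enumerate(raw.individuals):
            if scale[j] <= 0:
                raise InputDataError(f"individual {ind!r} has zero median depth")
        normalized = values / scale
    elif mode == "per-chromosome-median":
        normalized = np.empty_like(values)
        for chrom, sl in raw.grid.chromosome_slices().items():
            med = np.median(values[sl], axis=0)
            for j, ind in enumerate(raw.individuals):
                if med[j] <= 0:
                    raise InputDataError(
                        f"individual {ind!r} has zero median depth on {chrom}"
                    )
            normalized[sl] = values[sl] / med
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    stdev = normalized.std(axis=0, ddof=0)
    return NormalizedDepthMatrix(raw.grid, raw.individuals, normalized, scale, stdev)
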