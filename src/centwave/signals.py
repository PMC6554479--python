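"""Windowed density profiles over a chromosome.

Every downstream stage (wavelet landscapes, centromere calling, co-evolution
profiles) consumes per-window feature counts over a grid of non-overlapping
windows tiling a chromosome (10 kb by default). This module builds those
profiles from point features (SNP positions), interval features (mapped
reads, genes, BLAST hits) and raw sequence (assembly-gap 'N' runs).

Coordinates are 0-based half-open throughout; format-specific conversions
happen in :mod:`centwave.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("centwave")

PROFILE_KINDS = ("snp", "reads", "coverage", "gap", "blast_hits", "corr_snp")

DEFAULT_WINDOW_SIZE = 10_000


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping windows tiling ``[0, chrom_length)``.

    All windows have length ``window_size`` except possibly the last, which
    is truncated at the chromosome end and kept (counts are raw, never
    length-normalized here; window lengths are available for callers that
    want to normalize).
    """

    chrom: str
    chrom_length: int
    window_size: int

    def __post_init__(self) -> None:
        if self.chrom_length < 1:
            raise ValueError(f"chrom_length must be >= 1, got {self.chrom_length}")
        if self.window_size < 1:
            raise ValueError(f"window_size must be >= 1, got {self.window_size}")

    @property
    def n_windows(self) -> int:
        return -(-self.chrom_length // self.window_size)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows, dtype=np.int64) * self.window_size

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.window_size, self.chrom_length)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def windows(self) -> list[tuple[int, int]]:
        return list(zip(self.starts.tolist(), self.ends.tolist()))

    def window_of(self, pos: int) -> int:
        """Index of the window containing bp position ``pos``."""
        if not 0 <= pos < self.chrom_length:
            raise ValueError(f"position {pos} outside [0, {self.chrom_length})")
        return pos // self.window_size


@dataclass
class DensityProfile:
    """Per-window feature counts on a :class:`WindowGrid`."""

    grid: WindowGrid
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_windows,):
            raise ValueError(
                f"values length {self.values.shape} does not match "
                f"{self.grid.n_windows} windows"
            )
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")
        if self.kind in ("coverage", "gap") and np.any(self.values > self.grid.lengths):
            raise ValueError(f"{self.kind} counts exceed window lengths")


@dataclass
class IntervalSet:
    """0-based half-open intervals on one chromosome (reads, genes, hits)."""

    chrom: str
    intervals: np.ndarray  # shape (n, 2)
    merged: bool = field(default=False)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if len(self.intervals) and np.any(self.intervals[:, 0] >= self.intervals[:, 1]):
            raise ValueError("every interval must satisfy start < end")

    def __len__(self) -> int:
        return len(self.intervals)

    def merge(self) -> "IntervalSet":
        """Union of the intervals as a sorted, disjoint set."""
        if len(self.intervals) == 0:
            return IntervalSet(self.chrom, self.intervals, merged=True)
        ivs = self.intervals[np.argsort(self.intervals[:, 0])]
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return IntervalSet(self.chrom, np.array(out), merged=True)


def make_windows(
    chrom_length: int,
    window_size: int = DEFAULT_WINDOW_SIZE,
    chrom: str = "chr",
) -> WindowGrid:
    """Tile ``[0, chrom_length)`` with non-overlapping windows."""
    return WindowGrid(chrom=chrom, chrom_length=int(chrom_length), window_size=int(window_size))


def _check_range(positions: np.ndarray, grid: WindowGrid, out_of_range: str) -> np.ndarray:
    in_range = (positions >= 0) & (positions < grid.chrom_length)
    n_bad = int((~in_range).sum())
    if n_bad:
        if out_of_range == "error":
            raise ValueError(f"{n_bad} positions outside [0, {grid.chrom_length})")
        logger.warning("%d of %d positions outside [0, %d) dropped",
                       n_bad, positions.size, grid.chrom_length)
    return positions[in_range]


def point_density(positions, grid: WindowGrid, out_of_range: str = "warn") -> DensityProfile:
    """Count point features (e.g. SNP sites) per window.

    ``out_of_range``: "warn" drops out-of-range positions with a logged
    count; "error" raises.
    """
    positions = np.asarray(positions, dtype=np.int64).ravel()
    positions = _check_range(positions, grid, out_of_range)
    counts = np.bincount(positions // grid.window_size, minlength=grid.n_windows)
    return DensityProfile(grid, "snp", counts.astype(float))


def _clip_intervals(ivs: IntervalSet, grid: WindowGrid, out_of_range: str) -> np.ndarray:
    arr = ivs.intervals
    if len(arr) == 0:
        return arr
    ok = (arr[:, 0] < grid.chrom_length) & (arr[:, 1] > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        if out_of_range == "error":
            raise ValueError(f"{n_bad} intervals entirely outside [0, {grid.chrom_length})")
        logger.warning("%d of %d intervals outside chromosome dropped", n_bad, len(arr))
    return np.clip(arr[ok], 0, grid.chrom_length)


def read_count_density(
    reads: IntervalSet,
    grid: WindowGrid,
    mode: str = "overlap",
    out_of_range: str = "warn",
) -> DensityProfile:
    """Count read intervals per window.

    ``mode="overlap"`` (default, bedtools-intersect-count semantics): a read
    increments every window it overlaps by >= 1 bp, so a boundary-spanning
    read is counted in each window it touches. ``mode="midpoint"`` assigns
    each read once, to the window containing its midpoint.
    """
    ivs = _clip_intervals(reads, grid, out_of_range)
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    if len(ivs):
        w = grid.window_size
        if mode == "overlap":
            first = ivs[:, 0] // w
            last = (ivs[:, 1] - 1) // w
            # difference-array: +1 at first touched window, -1 past the last
            diff = np.zeros(grid.n_windows + 1, dtype=np.int64)
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
            counts = np.cumsum(diff[:-1])
        elif mode == "midpoint":
            mid = (ivs[:, 0] + ivs[:, 1] - 1) // 2
            counts = np.bincount(mid // w, minlength=grid.n_windows)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return DensityProfile(grid, "reads", counts.astype(float))


def positional_coverage_density(
    features: IntervalSet,
    grid: WindowGrid,
    kind: str = "coverage",
    out_of_range: str = "warn",
) -> DensityProfile:
    """Per-window bp covered by the union of the intervals.

    A position inside two overlapping features counts once (gene-body union
    semantics for gene density; same rule for BLAST-hit density).
    """
    clipped = IntervalSet(features.chrom, _clip_intervals(features, grid, out_of_range)) \
        if len(features) else features
    merged = clipped.merge() if len(clipped) else clipped
    vals = np.zeros(grid.n_windows, dtype=np.int64)
    w = grid.window_size
    for s, e in merged.intervals:
        w0, w1 = s // w, (e - 1) // w
        if w0 == w1:
            vals[w0] += e - s
        else:
            vals[w0] += (w0 + 1) * w - s
            vals[w1] += e - w1 * w
            if w1 > w0 + 1:
                vals[w0 + 1:w1] += w
    return DensityProfile(grid, kind, vals.astype(float))


def gap_density(sequence: str, grid: WindowGrid) -> DensityProfile:
    """Count assembly-gap characters ('N'/'n') per window."""
    if len(sequence) != grid.chrom_length:
        raise ValueError(
            f"sequence length {len(sequence)} != chrom_length {grid.chrom_length}"
        )
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_n = (arr == ord("N")) | (arr == ord("n"))
    counts = np.add.reduceat(is_n.astype(np.int64), grid.starts)
    return DensityProfile(grid, "gap", counts.astype(float))
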