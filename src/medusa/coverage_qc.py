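"""Windowed coverage, RPM normalisation, strand tracks and library QC.

Fragments are assigned to windows by their midpoint ("point data"): with
non-overlapping tiles each fragment is counted exactly once, so window
counts conserve the library size.  QC statistics follow common MeDIP
practice: Pearson correlation of replicate RPM over 500 bp windows sliding
in 250 bp increments (windows with a combined raw count below 5 excluded),
the proportion of reference CpG sites covered at increasing depth, and a
saturation curve built by correlating growing subsamples of one half of a
library against the other half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fragments_io import FragmentSet
from .genome import GenomeSpec

__all__ = [
    "WindowGrid",
    "CoverageTrack",
    "tile_genome",
    "count_fragments",
    "rpm",
    "strand_tracks",
    "replicate_correlation",
    "cpg_coverage",
    "saturation_curve",
]


@dataclass
class WindowGrid:
    """Fixed-width tiles (width ``width``, step ``step``) over a genome.

    Stored as flat arrays over all chromosomes; ``chrom_offsets`` gives the
    slice of each chromosome's windows.
    """

    chrom_names: list[str]
    starts: np.ndarray
    ends: np.ndarray
    chrom_offsets: dict[str, tuple[int, int]]
    width: int
    step: int

    def __len__(self) -> int:
        return len(self.starts)

    def chrom_slice(self, chrom: str) -> slice:
        lo, hi = self.chrom_offsets[chrom]
        return slice(lo, hi)

    def chrom_of_window(self) -> np.ndarray:
        out = np.empty(len(self), dtype=object)
        for chrom, (lo, hi) in self.chrom_offsets.items():
            out[lo:hi] = chrom
        return out


@dataclass
class CoverageTrack:
    grid: WindowGrid
    values: np.ndarray  # RPM or raw counts per window
    strand_mode: str = "total"  # total | forward | reverse

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.grid):
            raise ValueError("values length must match grid")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("track values must be finite and >= 0")


def tile_genome(genome: GenomeSpec, window: int = 500, step: int | None = None) -> WindowGrid:
    """Tile every chromosome with fixed windows; the last tile is truncated."""
    if step is None:
        step = window
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if step > window:
        raise ValueError("step > window would leave gaps between tiles")
    starts_all: list[np.ndarray] = []
    ends_all: list[np.ndarray] = []
    offsets: dict[str, tuple[int, int]] = {}
    n = 0
    for chrom in genome.chrom_names:
        length = genome.chrom_lengths[chrom]
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        starts_all.append(starts)
        ends_all.append(ends)
        offsets[chrom] = (n, n + len(starts))
        n += len(starts)
    return WindowGrid(
        chrom_names=list(genome.chrom_names),
        starts=np.concatenate(starts_all) if starts_all else np.empty(0, dtype=np.int64),
        ends=np.concatenate(ends_all) if ends_all else np.empty(0, dtype=np.int64),
        chrom_offsets=offsets,
        width=window,
        step=step,
    )


def _count_midpoints(grid: WindowGrid, chroms: np.ndarray, mids: np.ndarray) -> np.ndarray:
    """Count midpoints per window; overlapping grids count a midpoint in
    every window containing it."""
    counts = np.zeros(len(grid), dtype=np.int64)
    w, t = grid.width, grid.step
    n_phases = math.ceil(w / t)
    for chrom in grid.chrom_names:
        lo, hi = grid.chrom_offsets[chrom]
        mask = chroms == chrom
        if not mask.any():
            continue
        m = mids[mask]
        base = m // t  # index of right-most window whose start <= m
        for d in range(n_phases):
            j = base - d
            valid = (j >= 0) & (j < hi - lo) & (j * t + w > m)
            if valid.any():
                counts[lo:hi] += np.bincount(j[valid], minlength=hi - lo)
    return counts


def count_fragments(grid: WindowGrid, fragset: FragmentSet) -> np.ndarray:
    """Midpoint counts per window (raw integer counts)."""
    return _count_midpoints(grid, fragset.chroms, fragset.midpoints)


def rpm(counts: np.ndarray, library_size: int, grid: WindowGrid | None = None) -> CoverageTrack | np.ndarray:
    """Reads-per-million normalisation: count * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    values = np.asarray(counts, dtype=float) * 1e6 / library_size
    if grid is None:
        return values
    return CoverageTrack(grid=grid, values=values)


def strand_tracks(
    fragset: FragmentSet, grid: WindowGrid
) -> tuple[CoverageTrack, CoverageTrack, CoverageTrack]:
    """Raw-count coverage split by strand; forward + reverse == total."""
    fwd_mask = fragset.strands == "+"
    fwd = _count_midpoints(grid, fragset.chroms[fwd_mask], fragset.midpoints[fwd_mask])
    rev = _count_midpoints(grid, fragset.chroms[~fwd_mask], fragset.midpoints[~fwd_mask])
    total = fwd + rev
    return (
        CoverageTrack(grid, total.astype(float), "total"),
        CoverageTrack(grid, fwd.astype(float), "forward"),
        CoverageTrack(grid, rev.astype(float), "reverse"),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 2:
        return None
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return None  # undefined, never silently 0
    return float(np.corrcoef(x, y)[0, 1])


def replicate_correlation(
    fragset_a: FragmentSet,
    fragset_b: FragmentSet,
    genome: GenomeSpec,
    window: int = 500,
    step: int = 250,
    min_reads: int = 5,
    log2: bool = False,
) -> float | None:
    """Pearson correlation of replicate RPM over qualifying windows.

    Windows qualify when the two samples' combined raw count is at least
    ``min_reads``.  Returns None when fewer than 2 windows qualify or a
    track has zero variance (undefined correlation).
    """
    grid = tile_genome(genome, window=window, step=step)
    ca = count_fragments(grid, fragset_a)
    cb = count_fragments(grid, fragset_b)
    keep = (ca + cb) >= min_reads
    if keep.sum() < 2:
        return None
    xa = rpm(ca[keep], fragset_a.library_size)
    xb = rpm(cb[keep], fragset_b.library_size)
    if log2:
        xa, xb = np.log2(xa + 1), np.log2(xb + 1)
    return _pearson(xa, xb)


def cpg_coverage(
    fragset: FragmentSet,
    genome: GenomeSpec,
    min_depth_thresholds: tuple[int, ...] = (1, 5, 10),
) -> dict[int, float]:
    """Proportion of reference CpG sites covered by >= d fragments, per d."""
    if genome.cpg_positions is None or genome.n_cpgs() == 0:
        raise ValueError("genome has no CpG positions")
    total = genome.n_cpgs()
    covered = {d: 0 for d in min_depth_thresholds}
    for chrom in genome.chrom_names:
        pos = genome.cpg_positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        mask = fragset.chroms == chrom
        starts = np.sort(fragset.starts[mask])
        ends = np.sort(fragset.ends[mask])
        # depth at p = #starts <= p  -  #ends <= p
        depth = np.searchsorted(starts, pos, side="right") - np.searchsorted(
            ends, pos, side="right"
        )
        for d in min_depth_thresholds:
            covered[d] += int(np.sum(depth >= d))
    return {d: covered[d] / total for d in min_depth_thresholds}


def saturation_curve(
    fragset: FragmentSet,
    genome: GenomeSpec,
    fractions: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0),
    seed: int = 0,
    window: int = 500,
) -> list[tuple[float, float | None]]:
    """Correlate growing subsamples of one half-library against the other.

    The library is split into two random halves; for each fraction f the
    windowed RPM of an f-subsample of half 1 is correlated (Pearson) with
    the full half 2.  The curve rises towards its asymptote as f -> 1 when
    the library has saturated the methylome.
    """
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    n = len(fragset)
    if n < 4:
        raise ValueError("library too small to split for saturation analysis")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half1, half2 = perm[: n // 2], perm[n // 2 :]
    grid = tile_genome(genome, window=window)
    set2 = fragset.subset(half2)
    c2 = count_fragments(grid, set2)
    x2 = rpm(c2, len(half2))
    out: list[tuple[float, float | None]] = []
    for f in fractions:
        k = max(1, int(round(f * len(half1))))
        sub = fragset.subset(half1[:k])
        x1 = rpm(count_fragments(grid, sub), k)
        out.append((f, _pearson(x1, x2)))
    return out
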