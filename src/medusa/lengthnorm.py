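"""Fragment-length normalisation by sub-sampling.

Differences in fragment-length distributions between MeDIP libraries bias
window counts, because the length bias arises during immunoprecipitation
and cannot be corrected by trimming aligned fragments afterwards.  The fix
is to equalize the distributions by removing fragments: a common target
distribution is built as the per-bin minimum of the samples' length
proportions (renormalised), and each sample is sub-sampled without
replacement to match it.  This is the maximal distribution dominated by
every sample, i.e. the choice that removes the fewest fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragments_io import FragmentSet

__all__ = [
    "LengthDistribution",
    "length_histogram",
    "joint_histograms",
    "target_distribution",
    "subsample_to_target",
    "equalize_lengths",
]

DEFAULT_BIN_WIDTH = 5  # bp; 1 bp grids are noisy at small library sizes


@dataclass
class LengthDistribution:
    """Histogram of fragment lengths on a fixed bin grid."""

    bin_edges: np.ndarray  # length n_bins + 1
    counts: np.ndarray  # length n_bins, >= 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have one more entry than counts")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        t = self.total
        if t == 0:
            return np.zeros_like(self.counts)
        return self.counts / t


def _bin_index(lengths: np.ndarray, lo: int, bin_width: int) -> np.ndarray:
    return (lengths - lo) // bin_width


def length_histogram(
    fragset: FragmentSet,
    bin_width: int = 1,
    bin_range: tuple[int, int] | None = None,
) -> LengthDistribution:
    """Histogram of fragment lengths; sum of counts equals library size.

    ``bin_range`` (lo, hi) forces a common grid across samples; by default
    the grid spans [min_len, max_len] of this sample.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    lengths = fragset.lengths
    if len(lengths) == 0:
        edges = np.array([0, bin_width], dtype=np.int64)
        return LengthDistribution(edges, np.zeros(1))
    if bin_range is None:
        lo, hi = int(lengths.min()), int(lengths.max())
    else:
        lo, hi = bin_range
    n_bins = (hi - lo) // bin_width + 1
    edges = lo + bin_width * np.arange(n_bins + 1, dtype=np.int64)
    idx = _bin_index(lengths, lo, bin_width)
    if np.any(idx < 0) or np.any(idx >= n_bins):
        raise ValueError("fragment length outside bin_range")
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return LengthDistribution(edges, counts)


def joint_histograms(
    fragsets: list[FragmentSet], bin_width: int = DEFAULT_BIN_WIDTH
) -> list[LengthDistribution]:
    """Length histograms for several samples on one common bin grid."""
    non_empty = [fs for fs in fragsets if len(fs)]
    if not non_empty:
        raise ValueError("all fragment sets are empty")
    lo = min(int(fs.lengths.min()) for fs in non_empty)
    hi = max(int(fs.lengths.max()) for fs in non_empty)
    return [length_histogram(fs, bin_width, (lo, hi)) for fs in fragsets]


def target_distribution(dists: list[LengthDistribution]) -> LengthDistribution:
    """Per-bin minimum of the samples' proportions, renormalised to sum 1.

    The result is expressed as a LengthDistribution whose counts hold the
    target *proportions* (total 1).
    """
    if len(dists) < 2:
        raise ValueError("need at least 2 distributions")
    edges = dists[0].bin_edges
    for d in dists[1:]:
        if len(d.bin_edges) != len(edges) or np.any(d.bin_edges != edges):
            raise ValueError("distributions must share a common bin grid")
    props = np.vstack([d.proportions for d in dists])
    q = props.min(axis=0)
    total = q.sum()
    if total == 0:
        raise ValueError("no common fragment-length support")
    return LengthDistribution(edges, q / total)


def subsample_to_target(
    fragset: FragmentSet, target: LengthDistribution, seed: int
) -> FragmentSet:
    """Sub-sample a library so its length distribution matches ``target``.

    The retained total is ``n_s = floor(min over target bins of c_l / q_l)``
    — the largest size at which every bin can be filled.  Per bin,
    ``round(n_s * q_l)`` fragments are kept (round-half-even), chosen
    uniformly without replacement with a seeded generator; residual
    off-by-totals are corrected on the largest bins.  Fragments in
    zero-target bins are always removed.
    """
    q = target.proportions
    lo = int(target.bin_edges[0])
    bin_width = int(target.bin_edges[1] - target.bin_edges[0])
    n_bins = len(q)
    lengths = fragset.lengths
    idx = _bin_index(lengths, lo, bin_width)
    in_grid = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[in_grid], minlength=n_bins).astype(np.int64)
    pos = q > 0
    if not pos.any():
        raise ValueError("target distribution is empty")
    n_s = int(np.floor((counts[pos] / q[pos]).min()))
    if n_s == 0:
        raise ValueError("sample has insufficient fragments in target support")
    keep_per_bin = np.minimum(counts, np.round(n_s * q).astype(np.int64))
    keep_per_bin[~pos] = 0
    # correct rounding residue on the largest target bins, deterministically
    diff = int(keep_per_bin.sum()) - n_s
    order = np.argsort(-q, kind="stable")
    k = 0
    while diff != 0 and k < n_bins:
        b = order[k]
        if diff > 0 and keep_per_bin[b] > 0:
            take = min(diff, int(keep_per_bin[b]))
            keep_per_bin[b] -= take
            diff -= take
        elif diff < 0 and keep_per_bin[b] < counts[b]:
            add = min(-diff, int(counts[b] - keep_per_bin[b]))
            keep_per_bin[b] += add
            diff += add
        k += 1
    rng = np.random.default_rng(seed)
    keep_indices: list[np.ndarray] = []
    for b in np.nonzero(keep_per_bin)[0]:
        members = np.nonzero(in_grid & (idx == b))[0]
        chosen = rng.choice(members, size=int(keep_per_bin[b]), replace=False)
        keep_indices.append(np.sort(chosen))
    if not keep_indices:
        raise ValueError("no fragments retained")
    return fragset.subset(np.sort(np.concatenate(keep_indices)))


def equalize_lengths(
    fragsets: list[FragmentSet], bin_width: int = DEFAULT_BIN_WIDTH, seed: int = 0
) -> list[FragmentSet]:
    """Joint length normalisation of a cohort set: build the common target
    from all samples and sub-sample each against it (one derived seed per
    sample for reproducibility)."""
    dists = joint_histograms(fragsets, bin_width=bin_width)
    target = target_distribution(dists)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(fragsets))]
    return [
        subsample_to_target(fs, target, child)
        for fs, child in zip(fragsets, child_seeds)
    ]
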