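"""DMR validation against bisulfite CpG calls, and interval overlap stats.

Two independent checks of called DMRs:

* **Δms concordance** — per-CpG bisulfite methylation scores from the two
  cell states are depth-filtered (default >= 10 reads), quantile
  normalised to remove global-methylation offsets, and averaged per DMR
  as Δms = mean(score_A − score_B) over shared CpGs.  A DMR is
  *supported* when the sign of Δms matches its called direction.  DMRs
  with fewer than 10 CpGs or any simple-repeat overlap are excluded
  first (repeat and non-CpG methylation signals are invisible to CpG
  bisulfite calls).  Empirical p-values come from permutations over
  random regions.
* **Observed/expected overlap** — base-pair overlap between two interval
  sets (e.g. DMRs vs low-methylated regions), with the expectation under
  independent uniform placement: E = bp_a * bp_b / genome_bp.  The null
  distribution of O/E is built from random 500 bp region sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import FeatureSet, _merge_intervals, _overlap_bp
from .dmr_core import DMR
from .genome import GenomeSpec

__all__ = [
    "CpGCallSet",
    "DeltaResult",
    "read_cpg_calls",
    "filter_depth",
    "quantile_normalize",
    "dmr_validation_filter",
    "delta_ms",
    "concordance",
    "permutation_pvalue",
    "random_regions",
    "oe_overlap",
]


@dataclass
class CpGCallSet:
    """Per-CpG bisulfite counts: chrom, 0-based pos, methylated, total."""

    table: pd.DataFrame  # chrom, pos, meth, total

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "meth", "total"}
        if not required <= set(self.table.columns):
            raise ValueError("call table needs chrom/pos/meth/total columns")
        t = self.table
        if len(t) and (np.any(t["meth"] < 0) or np.any(t["meth"] > t["total"])):
            raise ValueError("need 0 <= methylated <= total")
        self.table = t.sort_values(["chrom", "pos"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def scores(self) -> pd.Series:
        """Methylation score ms = methylated/total (defined when total > 0)."""
        t = self.table
        return t["meth"] / t["total"].where(t["total"] > 0)

    def with_scores(self, values: np.ndarray) -> "CpGCallSet":
        out = self.table.copy()
        out["score"] = values
        return CpGCallSet(out)


def read_cpg_calls(path: str) -> CpGCallSet:
    """Read 'chrom pos meth_count total_count' TSV (header optional)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "pos", "meth", "total"], header=None,
        dtype={"chrom": str, "pos": np.int64, "meth": np.int64, "total": np.int64},
    )
    if len(df) and df.iloc[0]["chrom"] == "chrom":
        df = df.iloc[1:].reset_index(drop=True)
    return CpGCallSet(df)


def filter_depth(calls: CpGCallSet, min_depth: int = 10) -> CpGCallSet:
    """Keep CpGs with read depth >= min_depth."""
    return CpGCallSet(calls.table[calls.table["total"] >= min_depth].reset_index(drop=True))


def quantile_normalize(scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample quantile normalisation on a shared CpG set.

    Each value is replaced by the mean of the two samples' order
    statistics at its rank (ties get the average rank, so tied inputs map
    to equal outputs); the two normalised vectors then have identical
    sorted values.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and of equal length")
    n = len(a)
    if n == 0:
        return a.copy(), b.copy()
    mean_sorted = (np.sort(a) + np.sort(b)) / 2.0
    grid = np.arange(1, n + 1, dtype=float)
    out = []
    for x in (a, b):
        ranks = stats.rankdata(x, method="average")
        out.append(np.interp(ranks, grid, mean_sorted))
    return out[0], out[1]


def _calls_in_region(calls: CpGCallSet, chrom: str, start: int, end: int) -> pd.DataFrame:
    t = calls.table
    sub = t[t["chrom"] == chrom]
    return sub[(sub["pos"] >= start) & (sub["pos"] < end)]


def dmr_validation_filter(
    dmrs: Sequence[DMR],
    calls: CpGCallSet,
    repeats: FeatureSet | None = None,
    min_cpgs: int = 10,
) -> list[DMR]:
    """Eligible DMRs: >= min_cpgs qualifying CpGs inside, and zero overlap
    with annotated simple repeats.  ``calls`` should already be
    depth-filtered."""
    out: list[DMR] = []
    for d in dmrs:
        if len(_calls_in_region(calls, d.chrom, d.start, d.end)) < min_cpgs:
            continue
        if repeats is not None:
            m_starts, m_ends = repeats.merged(d.chrom)
            if _overlap_bp(d.start, d.end, m_starts, m_ends) > 0:
                continue
        out.append(d)
    return out


@dataclass
class DeltaResult:
    """Aggregated bisulfite methylation change over one DMR."""

    dmr: DMR
    n_cpgs: int
    delta_ms: float | None  # mean per-CpG (score_A − score_B); None if no shared CpGs
    supported: bool | None  # sign(delta) agrees with the DMR's direction


def delta_ms(
    dmr: DMR,
    calls_a: CpGCallSet,
    calls_b: CpGCallSet,
    score_col: str = "score",
) -> DeltaResult:
    """Unweighted mean per-CpG score difference (A − B) over shared CpGs.

    Direction convention: the DMR's ``hyper``/``hypo`` is cohort B
    relative to A on the same orientation, so a hyper DMR is supported by
    Δms < 0 and a hypo DMR by Δms > 0.
    """
    sub_a = _calls_in_region(calls_a, dmr.chrom, dmr.start, dmr.end)
    sub_b = _calls_in_region(calls_b, dmr.chrom, dmr.start, dmr.end)
    merged = sub_a.merge(sub_b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if len(merged) == 0:
        return DeltaResult(dmr, 0, None, None)
    if f"{score_col}_a" in merged.columns:
        sa = merged[f"{score_col}_a"].values
        sb = merged[f"{score_col}_b"].values
    else:
        sa = (merged["meth_a"] / merged["total_a"]).values
        sb = (merged["meth_b"] / merged["total_b"]).values
    delta = float(np.mean(sa - sb))
    if delta == 0:
        supported = False
    else:
        supported = (delta < 0) == (dmr.direction == "hyper")
    return DeltaResult(dmr, len(merged), delta, supported)


def concordance(results: Sequence[DeltaResult], strong_threshold: float = 0.1) -> dict:
    """Support counts per direction, overall supported fraction.

    ``strong`` counts DMRs whose |Δms| exceeds ``strong_threshold`` in the
    concordant direction; ``contradicted_strong`` the same in the
    discordant direction.
    """
    table: dict[str, dict[str, int]] = {
        d: {"n": 0, "supported": 0, "strong": 0, "contradicted_strong": 0}
        for d in ("hyper", "hypo")
    }
    undefined = 0
    for r in results:
        if r.delta_ms is None:
            undefined += 1
            continue
        row = table[r.dmr.direction]
        row["n"] += 1
        if r.supported:
            row["supported"] += 1
        concordant_sign = -1 if r.dmr.direction == "hyper" else 1
        if r.delta_ms * concordant_sign > strong_threshold:
            row["strong"] += 1
        elif -r.delta_ms * concordant_sign > strong_threshold:
            row["contradicted_strong"] += 1
    n_defined = sum(row["n"] for row in table.values())
    n_supported = sum(row["supported"] for row in table.values())
    return {
        "per_direction": table,
        "n_total": len(results),
        "n_defined": n_defined,
        "n_undefined": undefined,
        "supported_fraction": (n_supported / n_defined) if n_defined else None,
    }


def permutation_pvalue(
    observed: float,
    null_sampler: Callable[[np.random.Generator], float],
    n_perm: int = 1000,
    tail: str = "ge",
    seed: int = 0,
) -> float:
    """Add-one empirical p-value: (1 + #{null beyond observed}) / (n + 1).

    ``tail='ge'`` counts null draws >= observed, ``'le'`` counts <=.
    The add-one estimator never returns 0, matching the convention of
    reporting p < 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("ge", "le"):
        raise ValueError("tail must be 'ge' or 'le'")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        x = null_sampler(rng)
        if (tail == "ge" and x >= observed) or (tail == "le" and x <= observed):
            count += 1
    return (1 + count) / (n_perm + 1)


def random_regions(
    genome: GenomeSpec,
    n: int,
    size: int = 500,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """n random intervals of exactly ``size`` bp, chromosome chosen with
    probability proportional to length, start uniform over valid
    positions.  No overlap rejection (duplicates possible at tiny
    probability)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = np.array([genome.chrom_lengths[c] for c in genome.chrom_names], dtype=float)
    if size > lengths.min():
        raise ValueError("size exceeds the smallest chromosome")
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=n, p=probs)
    starts = np.empty(n, dtype=np.int64)
    for i, ci in enumerate(chrom_idx):
        starts[i] = rng.integers(0, int(lengths[ci]) - size + 1)
    return pd.DataFrame(
        {
            "chrom": [genome.chrom_names[ci] for ci in chrom_idx],
            "start": starts,
            "end": starts + size,
        }
    )


def _regions_to_merged(regions) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    if isinstance(regions, FeatureSet):
        return {c: regions.merged(c) for c in regions.table["chrom"].unique()}
    if isinstance(regions, pd.DataFrame):
        df = regions
    else:  # sequence of DMRs or (chrom, start, end) triples
        rows = []
        for r in regions:
            if isinstance(r, DMR):
                rows.append((r.chrom, r.start, r.end))
            else:
                rows.append(tuple(r[:3]))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out = {}
    for chrom, sub in df.groupby("chrom"):
        out[str(chrom)] = _merge_intervals(
            sub["start"].values.astype(np.int64), sub["end"].values.astype(np.int64)
        )
    return out


def oe_overlap(regions_a, regions_b, genome: GenomeSpec) -> tuple[int, float, float | None]:
    """Observed vs expected base-pair overlap of two interval sets.

    Observed is the intersection of the two interval unions; expected is
    (bp_a * bp_b) / genome_bp, the mean overlap under independent uniform
    placement.  Returns (observed_bp, expected_bp, ratio); ratio is None
    when expected is 0.
    """
    merged_a = _regions_to_merged(regions_a)
    merged_b = _regions_to_merged(regions_b)
    bp_a = sum(int((e - s).sum()) for s, e in merged_a.values())
    bp_b = sum(int((e - s).sum()) for s, e in merged_b.values())
    observed = 0
    for chrom, (sa, ea) in merged_a.items():
        if chrom not in merged_b:
            continue
        sb, eb = merged_b[chrom]
        for s, e in zip(sa, ea):
            observed += _overlap_bp(int(s), int(e), sb, eb)
    expected = bp_a * bp_b / genome.total_length
    ratio = observed / expected if expected > 0 else None
    return observed, expected, ratio
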