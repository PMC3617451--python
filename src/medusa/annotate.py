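"""Genomic-context annotation of DMRs.

Feature intersection (BED/GFF), single-label classification under an
explicit priority order, strand-aware nearest-gene association, CpG
density and per-feature tallies.  Interval arithmetic is done on sorted
numpy arrays; overlaps count the *union* of feature bases (no double
counting where features overlap each other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmr_core import DMR
from .genome import GenomeSpec

__all__ = [
    "FeatureSet",
    "load_features",
    "intersect_bp",
    "classify_dmr",
    "nearest_gene",
    "cpg_density",
    "feature_tally",
    "annotate_dmrs",
    "DEFAULT_PRIORITY",
]

DEFAULT_PRIORITY = ("cpg_island", "promoter", "exon", "intron")


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping sorted intervals into a disjoint union."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


@dataclass
class FeatureSet:
    """Named genomic intervals (0-based half-open), sorted per chromosome."""

    name: str
    table: pd.DataFrame  # chrom, start, end [, gene_id, strand]
    _merged: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required <= set(self.table.columns):
            raise ValueError("feature table needs chrom/start/end columns")
        if len(self.table) and np.any(self.table["end"].values <= self.table["start"].values):
            raise ValueError("feature end must exceed start")
        self.table = self.table.sort_values(["chrom", "start"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def merged(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._merged:
            sub = self.table[self.table["chrom"] == chrom]
            self._merged[chrom] = _merge_intervals(
                sub["start"].values.astype(np.int64), sub["end"].values.astype(np.int64)
            )
        return self._merged[chrom]

    @property
    def total_bp(self) -> int:
        return int(
            sum(
                (e - s).sum()
                for chrom in self.table["chrom"].unique()
                for s, e in [self.merged(chrom)]
            )
        )


def load_features(path: str, name: str) -> FeatureSet:
    """Load a FeatureSet from BED3+ or GFF3.

    GFF coordinates (1-based closed) are converted to 0-based half-open;
    a ``gene_id``/``ID``/``Name`` attribute, when present, populates the
    gene_id column.
    """
    is_gff = path.endswith((".gff", ".gff3", ".gtf"))
    rows: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if is_gff:
                    if len(parts) < 8:
                        raise ValueError("GFF needs >= 8 columns")
                    start = int(parts[3]) - 1  # 1-based closed -> 0-based half-open
                    end = int(parts[4])
                    strand = parts[6] if parts[6] in ("+", "-") else None
                    gene_id = None
                    if len(parts) > 8:
                        for kv in parts[8].replace("; ", ";").split(";"):
                            for key in ("gene_id=", "ID=", "Name="):
                                if kv.startswith(key):
                                    gene_id = kv[len(key):].strip('"')
                                    break
                            if gene_id:
                                break
                    rows.append(
                        {"chrom": parts[0], "start": start, "end": end,
                         "gene_id": gene_id, "strand": strand}
                    )
                else:
                    if len(parts) < 3:
                        raise ValueError("BED needs >= 3 columns")
                    rows.append(
                        {
                            "chrom": parts[0],
                            "start": int(parts[1]),
                            "end": int(parts[2]),
                            "gene_id": parts[3] if len(parts) > 3 and parts[3] != "." else None,
                            "strand": parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else None,
                        }
                    )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed feature line ({exc})") from exc
            if rows and rows[-1]["end"] <= rows[-1]["start"]:
                raise ValueError(f"{path}:{lineno}: end <= start")
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])
    return FeatureSet(name=name, table=table)


def _overlap_bp(start: int, end: int, m_starts: np.ndarray, m_ends: np.ndarray) -> int:
    if len(m_starts) == 0:
        return 0
    lo = np.searchsorted(m_ends, start, side="right")
    hi = np.searchsorted(m_starts, end, side="left")
    if hi <= lo:
        return 0
    s = np.maximum(m_starts[lo:hi], start)
    e = np.minimum(m_ends[lo:hi], end)
    return int(np.maximum(e - s, 0).sum())


def intersect_bp(dmr: DMR, features: FeatureSet, window: int = 0) -> tuple[int, list[str]]:
    """Base pairs of a DMR covered by the union of a feature set, plus the
    ids of overlapping features.  ``window`` extends the query by N bp on
    each side (windowBed-style proximity search)."""
    qs, qe = dmr.start - window, dmr.end + window
    m_starts, m_ends = features.merged(dmr.chrom)
    bp = _overlap_bp(max(qs, 0), qe, m_starts, m_ends)
    sub = features.table[features.table["chrom"] == dmr.chrom]
    hit = sub[(sub["start"] < qe) & (sub["end"] > qs)]
    ids = [g for g in hit.get("gene_id", pd.Series(dtype=object)) if g]
    return bp, ids


def classify_dmr(
    dmr: DMR,
    feature_sets: dict[str, FeatureSet],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> str:
    """Single feature label: highest-priority feature with >= 1 bp overlap;
    ``intergenic`` when nothing overlaps."""
    for name in priority:
        fs = feature_sets.get(name)
        if fs is None:
            continue
        bp, _ = intersect_bp(dmr, fs)
        if bp > 0:
            return name
    return "intergenic"


def nearest_gene(
    dmr: DMR,
    genes: FeatureSet,
    max_upstream: int = 10_000,
    max_downstream: int = 5_000,
) -> tuple[str, int] | None:
    """Associate a DMR with its nearest gene within a strand-aware window.

    A gene is a candidate when the DMR overlaps the gene span extended by
    ``max_upstream`` bp upstream of its TSS and ``max_downstream`` bp past
    its 3' end (directions follow gene strand).  Among candidates, the one
    with the smallest distance to the gene body wins (0 if inside; ties ->
    first in coordinate order).  Returns (gene_id, distance) or None.
    """
    sub = genes.table[genes.table["chrom"] == dmr.chrom]
    best: tuple[int, str] | None = None
    for _, g in sub.iterrows():
        strand = g.get("strand") or "+"
        if strand == "+":
            lo, hi = g["start"] - max_upstream, g["end"] + max_downstream
        else:
            lo, hi = g["start"] - max_downstream, g["end"] + max_upstream
        if dmr.end <= lo or dmr.start >= hi:
            continue
        if dmr.end > g["start"] and dmr.start < g["end"]:
            dist = 0
        elif dmr.end <= g["start"]:
            dist = int(g["start"] - dmr.end)
        else:
            dist = int(dmr.start - g["end"])
        gene_id = g.get("gene_id") or f"{dmr.chrom}:{g['start']}-{g['end']}"
        if best is None or dist < best[0]:
            best = (dist, gene_id)
    if best is None:
        return None
    return best[1], best[0]


def cpg_density(dmr: DMR, genome: GenomeSpec) -> tuple[int, float]:
    """CpG count within the DMR and per-bp density."""
    if genome.cpg_positions is None:
        raise ValueError("genome has no CpG positions")
    pos = genome.cpg_positions.get(dmr.chrom, np.empty(0, dtype=np.int64))
    count = int(np.searchsorted(pos, dmr.end, "left") - np.searchsorted(pos, dmr.start, "left"))
    return count, count / (dmr.end - dmr.start)


def feature_tally(labels: list[str], directions: list[str]) -> pd.DataFrame:
    """Per-feature, per-direction DMR counts; grand total = #DMRs."""
    if len(labels) != len(directions):
        raise ValueError("labels and directions must align")
    if not labels:
        return pd.DataFrame(columns=["hyper", "hypo"])
    df = pd.DataFrame({"label": labels, "direction": directions})
    tally = df.pivot_table(index="label", columns="direction", aggfunc="size", fill_value=0)
    for col in ("hyper", "hypo"):
        if col not in tally.columns:
            tally[col] = 0
    return tally[["hyper", "hypo"]]


def annotate_dmrs(
    dmrs: list[DMR],
    feature_sets: dict[str, FeatureSet],
    genome: GenomeSpec | None = None,
    genes: FeatureSet | None = None,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    max_upstream: int = 10_000,
    max_downstream: int = 5_000,
) -> pd.DataFrame:
    """Full annotation table: label, nearest gene, CpG count/density."""
    rows = []
    for d in dmrs:
        row: dict = {
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "direction": d.direction,
            "label": classify_dmr(d, feature_sets, priority),
        }
        if genes is not None:
            hit = nearest_gene(d, genes, max_upstream, max_downstream)
            row["nearest_gene"] = hit[0] if hit else None
            row["gene_distance"] = hit[1] if hit else None
        if genome is not None and genome.cpg_positions is not None:
            count, dens = cpg_density(d, genome)
            row["cpg_count"] = count
            row["cpg_density"] = dens
        rows.append(row)
    return pd.DataFrame(rows)
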