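"""Read, filter and write MeDIP fragments.

A *fragment* is the sequenced DNA insert inferred from a properly mapped
read pair; it is the atomic unit of MeDIP signal.  This module turns raw
paired-end alignments (SAM/BAM or BEDPE) into filtered, deduplicated
:class:`FragmentSet` objects, and round-trips fragments through BED6.
Coverage tracks go out as fixedStep wig.

Filtering rules:

* pairs failing to map as a proper pair are removed;
* pairs in which neither read reaches the alignment-score threshold
  (default 10) are removed;
* fragments sharing the exact same chromosome, start and stop are
  collapsed to one (first encountered wins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "RawPair",
    "Fragment",
    "FragmentSet",
    "read_pairs",
    "filter_pairs",
    "deduplicate",
    "read_bed",
    "write_bed",
    "write_wig",
]


@dataclass(frozen=True)
class RawPair:
    """One paired-end alignment, 0-based half-open per read."""

    chrom: str
    start_1: int
    end_1: int
    start_2: int
    end_2: int
    proper_pair: bool
    score_1: int
    score_2: int
    strand: str  # strand of read 1

    def __post_init__(self) -> None:
        if self.end_1 <= self.start_1 or self.end_2 <= self.start_2:
            raise ValueError("read end must exceed read start")


@dataclass(frozen=True)
class Fragment:
    """A uniquely mapped, filtered insert (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str  # strand of the sequenced first read

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FragmentSet:
    """All filtered fragments of one sample, as parallel numpy arrays."""

    sample_id: str
    chroms: np.ndarray  # object dtype, chromosome per fragment
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    strands: np.ndarray  # '<U1', '+' or '-'
    cohort_label: str | None = None

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype="<U1")
        n = len(self.starts)
        if not (len(self.chroms) == len(self.ends) == len(self.strands) == n):
            raise ValueError("fragment arrays must have equal length")
        if n and np.any(self.ends <= self.starts):
            raise ValueError("fragment end must exceed start")

    @classmethod
    def from_fragments(
        cls,
        fragments: Iterable[Fragment],
        sample_id: str = "sample",
        cohort_label: str | None = None,
    ) -> "FragmentSet":
        frags = list(fragments)
        return cls(
            sample_id=sample_id,
            chroms=np.array([f.chrom for f in frags], dtype=object),
            starts=np.array([f.start for f in frags], dtype=np.int64),
            ends=np.array([f.end for f in frags], dtype=np.int64),
            strands=np.array([f.strand for f in frags], dtype="<U1"),
            cohort_label=cohort_label,
        )

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def library_size(self) -> int:
        return len(self)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def __iter__(self) -> Iterator[Fragment]:
        for c, s, e, st in zip(self.chroms, self.starts, self.ends, self.strands):
            yield Fragment(str(c), int(s), int(e), str(st))

    def subset(self, index: np.ndarray) -> "FragmentSet":
        return FragmentSet(
            sample_id=self.sample_id,
            chroms=self.chroms[index],
            starts=self.starts[index],
            ends=self.ends[index],
            strands=self.strands[index],
            cohort_label=self.cohort_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "strand": self.strands,
            }
        )

    def validate_against(self, genome: GenomeSpec) -> None:
        for chrom in pd.unique(self.chroms):
            if not genome.has_chrom(str(chrom)):
                raise ValueError(f"fragment on unknown chromosome {chrom!r}")
            mask = self.chroms == chrom
            if np.any(self.starts[mask] < 0) or np.any(
                self.ends[mask] > genome.chrom_lengths[str(chrom)]
            ):
                raise ValueError(f"fragment out of bounds on {chrom!r}")


def _read_pairs_sam(path: str, genome: GenomeSpec) -> Iterator[RawPair]:
    import pysam

    pending: dict[str, object] = {}
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.mate_is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name
            if name is None:
                raise ValueError(f"{path}: alignment record without query name")
            mate = pending.pop(name, None)
            if mate is None:
                pending[name] = rec
                continue
            r1, r2 = (rec, mate) if rec.is_read1 else (mate, rec)
            chrom = r1.reference_name
            if chrom != r2.reference_name:
                continue  # inter-chromosomal, never a proper pair
            if not genome.has_chrom(chrom):
                raise ValueError(f"{path}: record {name!r} on unknown chromosome {chrom!r}")
            yield RawPair(
                chrom=chrom,
                start_1=r1.reference_start,
                end_1=r1.reference_end,
                start_2=r2.reference_start,
                end_2=r2.reference_end,
                proper_pair=bool(r1.is_proper_pair),
                score_1=r1.mapping_quality,
                score_2=r2.mapping_quality,
                strand="-" if r1.is_reverse else "+",
            )


def _read_pairs_bedpe(path: str, genome: GenomeSpec) -> Iterator[RawPair]:
    # BEDPE: chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2
    # score is taken as the shared alignment score; an 11th/12th column, if
    # present, overrides with per-read scores.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}:{lineno}: BEDPE needs >= 10 columns")
            chrom1, chrom2 = parts[0], parts[3]
            if chrom1 != chrom2:
                continue
            if not genome.has_chrom(chrom1):
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom1!r}")
            try:
                s1, e1, s2, e2 = int(parts[1]), int(parts[2]), int(parts[4]), int(parts[5])
                score = int(parts[7])
                sc1 = int(parts[10]) if len(parts) > 10 else score
                sc2 = int(parts[11]) if len(parts) > 11 else score
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable BEDPE record") from exc
            yield RawPair(
                chrom=chrom1,
                start_1=s1,
                end_1=e1,
                start_2=s2,
                end_2=e2,
                proper_pair=True,
                score_1=sc1,
                score_2=sc2,
                strand=parts[8],
            )


def read_pairs(path: str, genome: GenomeSpec) -> Iterator[RawPair]:
    """Stream read pairs from SAM/BAM or BEDPE, as 0-based half-open."""
    if path.endswith((".sam", ".bam")):
        return _read_pairs_sam(path, genome)
    return _read_pairs_bedpe(path, genome)


def filter_pairs(pairs: Iterable[RawPair], min_score: int = 10) -> Iterator[Fragment]:
    """Keep proper pairs where at least one read scores >= ``min_score``.

    A kept pair is emitted as its insert ``[min(starts), max(ends))`` with
    the strand of read 1.  Pairs where *neither* read reaches the threshold
    are removed.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    for pair in pairs:
        if not pair.proper_pair:
            continue
        if pair.score_1 < min_score and pair.score_2 < min_score:
            continue
        yield Fragment(
            chrom=pair.chrom,
            start=min(pair.start_1, pair.start_2),
            end=max(pair.end_1, pair.end_2),
            strand=pair.strand,
        )


def deduplicate(
    fragments: Iterable[Fragment],
    sample_id: str = "sample",
    cohort_label: str | None = None,
) -> FragmentSet:
    """Collapse fragments sharing (chrom, start, end) to the first seen.

    Strand is intentionally ignored in the duplicate key: duplicates are
    defined by identical start and stop on the same chromosome.
    """
    seen: set[tuple[str, int, int]] = set()
    kept: list[Fragment] = []
    for frag in fragments:
        key = (frag.chrom, frag.start, frag.end)
        if key in seen:
            continue
        seen.add(key)
        kept.append(frag)
    return FragmentSet.from_fragments(kept, sample_id=sample_id, cohort_label=cohort_label)


def write_bed(fragset: FragmentSet, path: str) -> None:
    """Write a FragmentSet as BED6 (name '.', score 0)."""
    with open(path, "w") as fh:
        for c, s, e, st in zip(fragset.chroms, fragset.starts, fragset.ends, fragset.strands):
            fh.write(f"{c}\t{s}\t{e}\t.\t0\t{st}\n")


def read_bed(
    path: str,
    genome: GenomeSpec | None = None,
    sample_id: str | None = None,
    cohort_label: str | None = None,
) -> FragmentSet:
    """Read fragments from BED6 (strand column required)."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            if genome is not None and not genome.has_chrom(parts[0]):
                raise ValueError(f"{path}:{lineno}: unknown chromosome {parts[0]!r}")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            strands.append(parts[5])
    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].removesuffix(".bed")
    return FragmentSet(
        sample_id=sample_id,
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        strands=np.array(strands, dtype="<U1"),
        cohort_label=cohort_label,
    )


def write_wig(track, path: str, track_name: str) -> None:
    """Write a coverage track as fixedStep wig (1-based, per the standard).

    ``track`` must expose ``grid`` (a WindowGrid with uniform step equal to
    span) and ``values``.  One fixedStep declaration is written per
    chromosome; values are formatted with 4 decimal places.
    """
    grid = track.grid
    values = np.asarray(track.values, dtype=float)
    if grid.step > grid.width:
        raise ValueError("wig output requires step <= window (no gaps)")
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        for chrom in grid.chrom_names:
            idx = grid.chrom_slice(chrom)
            starts = grid.starts[idx]
            if len(starts) == 0:
                continue
            if np.any(np.diff(starts) != grid.step):
                raise ValueError("windows must be sorted with uniform step")
            fh.write(
                f"fixedStep chrom={chrom} start={int(starts[0]) + 1} "
                f"step={grid.step} span={grid.step}\n"
            )
            for v in values[idx]:
                fh.write(f"{v:.4f}\n")
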