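"""Reference coordinate system: chromosome names, lengths and CpG positions.

All coordinates in this package are 0-based half-open (BED-native).  Wig
output converts to 1-based on the way out, GFF input converts from 1-based
closed on the way in; nothing else touches the convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeSpec", "read_chrom_sizes", "write_chrom_sizes"]


@dataclass
class GenomeSpec:
    """A reference genome: ordered chromosomes, lengths, optional CpG sites.

    Parameters
    ----------
    chrom_names:
        Ordered chromosome identifiers.
    chrom_lengths:
        Mapping chromosome -> length in bp (> 0).
    cpg_positions:
        Optional mapping chromosome -> strictly increasing array of 0-based
        start positions of CpG dinucleotides (each < length - 1).
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    cpg_positions: dict[str, np.ndarray] | None = field(default=None)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            if name not in self.chrom_lengths:
                raise ValueError(f"chromosome {name!r} has no length")
            if self.chrom_lengths[name] <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.cpg_positions is not None:
            for name, pos in self.cpg_positions.items():
                pos = np.asarray(pos, dtype=np.int64)
                self.cpg_positions[name] = pos
                if pos.size == 0:
                    continue
                if name not in self.chrom_lengths:
                    raise ValueError(f"CpG positions given for unknown chromosome {name!r}")
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"CpG positions on {name!r} not strictly increasing")
                if pos[0] < 0 or pos[-1] >= self.chrom_lengths[name] - 1:
                    raise ValueError(f"CpG position out of bounds on {name!r}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    def has_chrom(self, name: str) -> bool:
        return name in self.chrom_lengths

    def n_cpgs(self) -> int:
        if self.cpg_positions is None:
            return 0
        return sum(len(v) for v in self.cpg_positions.values())


def read_chrom_sizes(path: str) -> GenomeSpec:
    """Read a UCSC-style ``chrom<TAB>length`` file."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            name, length = parts[0], int(parts[1])
            names.append(name)
            lengths[name] = length
    return GenomeSpec(names, lengths)


def write_chrom_sizes(genome: GenomeSpec, path: str) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f"{name}\t{genome.chrom_lengths[name]}\n")
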