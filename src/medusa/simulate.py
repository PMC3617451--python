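"""Synthetic genomes, methylomes, MeDIP fragments and bisulfite calls.

The generator lets every pipeline stage run without external data.  Its
model of MeDIP enrichment is deliberately minimal: a fragment's sampling
weight is a small background ``epsilon`` per base plus the methylation
level at each CpG it covers, making coverage a monotone function of
methylated-CpG content (the operating assumption of MeDIP DMR calling).
Antibody saturation and CpG-density non-linearities are *not* modelled.

A methylome is a per-base methylation level in [0, 1]: CpG islands low
(default 0.1), background high (default 0.8).  Planted DMRs perturb the
level in one cohort so that the emission-intensity ratio approximates the
requested fold change while levels stay in [0, 1]; planted strand-
asymmetric regions force the strand of fragments whose midpoint falls
inside them (emulating a single-strand, non-CpG-like signal).  Bisulfite
calls draw per-CpG read depth from a Poisson and methylated counts from a
Binomial at the local level.

Per-replicate Gamma multipliers on tiled intensities are available to
create negative-binomial overdispersion between replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bisulfite_validate import CpGCallSet
from .fragments_io import FragmentSet
from .genome import GenomeSpec

__all__ = [
    "MethylomeSpec",
    "simulate_genome",
    "make_methylome",
    "plant_dmrs",
    "plant_asym",
    "simulate_fragments",
    "simulate_bisulfite",
    "simulate_dmr_study",
]

BACKGROUND_LEVEL = 0.8  # methylated genomic background
ISLAND_LEVEL = 0.1  # CpG islands largely unmethylated
DEFAULT_EPSILON = 2e-4  # per-base background pull-down rate


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class MethylomeSpec:
    """Ground-truth methylome: per-base levels plus planted intervals."""

    genome: GenomeSpec
    levels: dict[str, np.ndarray]  # float32 per base, in [0, 1]
    strand_force: dict[str, np.ndarray]  # int8: 0 free, 1 forward, 2 reverse
    islands: pd.DataFrame  # chrom, start, end
    planted_dmrs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "direction", "fold"])
    )
    planted_asym: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    )

    def __post_init__(self) -> None:
        for chrom, lv in self.levels.items():
            if lv.min() < 0 or lv.max() > 1:
                raise ValueError(f"methylation levels on {chrom!r} outside [0, 1]")

    def copy(self) -> "MethylomeSpec":
        return MethylomeSpec(
            genome=self.genome,
            levels={c: v.copy() for c, v in self.levels.items()},
            strand_force={c: v.copy() for c, v in self.strand_force.items()},
            islands=self.islands.copy(),
            planted_dmrs=self.planted_dmrs.copy(),
            planted_asym=self.planted_asym.copy(),
        )


def _place_nonoverlapping(
    length: int, n: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """n non-overlapping interval starts, uniform via the gap construction."""
    slack = length - n * size
    if slack < 0:
        raise ValueError(f"cannot pack {n} intervals of {size} bp into {length} bp")
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    return gaps + size * np.arange(n)


def simulate_genome(
    n_chrom: int = 1,
    chrom_length: int = 1_000_000,
    island_rate: float = 0.01,
    island_size: int = 1_000,
    cpg_bg_rate: float = 0.01,
    cpg_island_rate: float = 0.1,
    seed: int = 0,
) -> tuple[GenomeSpec, pd.DataFrame]:
    """Simulate chromosomes with CpG islands and per-base CpG positions.

    ``island_rate`` is the fraction of each chromosome covered by islands;
    islands are placed uniformly without overlap.  CpG dinucleotide starts
    are Bernoulli per base: ``cpg_island_rate`` inside islands,
    ``cpg_bg_rate`` outside.  Returns (genome, island table).
    """
    for rate in (island_rate, cpg_bg_rate, cpg_island_rate):
        if not 0 < rate < 1:
            raise ValueError("rates must lie in (0, 1)")
    if island_size >= chrom_length:
        raise ValueError("island_size must be below chrom_length")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    lengths = {name: chrom_length for name in names}
    cpgs: dict[str, np.ndarray] = {}
    island_rows = []
    n_islands = int(round(island_rate * chrom_length / island_size))
    for name in names:
        starts = _place_nonoverlapping(chrom_length, n_islands, island_size, rng)
        in_island = np.zeros(chrom_length, dtype=bool)
        for s in starts:
            in_island[s : s + island_size] = True
            island_rows.append({"chrom": name, "start": int(s), "end": int(s + island_size)})
        rate_per_base = np.where(in_island, cpg_island_rate, cpg_bg_rate)
        draws = rng.random(chrom_length) < rate_per_base
        draws[-1] = False  # a CpG start needs a following base
        cpgs[name] = np.nonzero(draws)[0].astype(np.int64)
    genome = GenomeSpec(names, lengths, cpgs)
    return genome, pd.DataFrame(island_rows, columns=["chrom", "start", "end"])


def make_methylome(
    genome: GenomeSpec,
    islands: pd.DataFrame,
    background_level: float = BACKGROUND_LEVEL,
    island_level: float = ISLAND_LEVEL,
) -> MethylomeSpec:
    """Baseline methylome: methylated background, hypomethylated islands."""
    levels = {}
    strand_force = {}
    for chrom in genome.chrom_names:
        n = genome.chrom_lengths[chrom]
        lv = np.full(n, background_level, dtype=np.float32)
        for _, row in islands[islands["chrom"] == chrom].iterrows():
            lv[int(row["start"]) : int(row["end"])] = island_level
        levels[chrom] = lv
        strand_force[chrom] = np.zeros(n, dtype=np.int8)
    return MethylomeSpec(genome=genome, levels=levels, strand_force=strand_force, islands=islands)


def _sample_free_intervals(
    spec: MethylomeSpec,
    n: int,
    width: int,
    rng: np.random.Generator,
    margin: int,
    align: int | None = None,
) -> list[tuple[str, int, int]]:
    """Place n intervals avoiding islands, existing planted intervals and
    each other (with ``margin`` bp of clearance), by rejection sampling."""
    genome = spec.genome
    busy: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    for df in (spec.islands, spec.planted_dmrs, spec.planted_asym):
        for _, row in df.iterrows():
            busy[row["chrom"]].append((int(row["start"]) - margin, int(row["end"]) + margin))
    lengths = np.array([genome.chrom_lengths[c] for c in genome.chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    placed: list[tuple[str, int, int]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > 10_000 * max(n, 1):
            raise ValueError(f"cannot place {n} non-overlapping intervals of {width} bp")
        ci = rng.choice(len(lengths), p=probs)
        chrom = genome.chrom_names[ci]
        hi = genome.chrom_lengths[chrom] - width
        start = int(rng.integers(0, hi + 1))
        if align:
            start = (start // align) * align
        end = start + width
        if any(start < e and end > s for s, e in busy[chrom]):
            continue
        busy[chrom].append((start - margin, end + margin))
        placed.append((chrom, start, end))
    return placed


def plant_dmrs(
    spec: MethylomeSpec,
    n_dmrs: int,
    fold: float = 4.0,
    width: int = 500,
    direction_mix: float = 0.5,
    seed: int = 0,
    background_level: float = BACKGROUND_LEVEL,
    align_to_windows: bool = True,
) -> tuple[MethylomeSpec, MethylomeSpec]:
    """Plant differential regions; returns (cohort-A law, cohort-B law).

    Inside a *hyper* region (B above A) cohort A's level is lowered to
    ``background_level / fold`` while B keeps the background level;
    *hypo* regions are the mirror image.  ``direction_mix`` is the hyper
    fraction.  ``fold = 1`` leaves the two laws identical (null harness).
    Placements avoid islands and previously planted intervals.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rng = np.random.default_rng(seed)
    placed = _sample_free_intervals(
        spec, n_dmrs, width, rng, margin=2 * width, align=width if align_to_windows else None
    )
    spec_a, spec_b = spec.copy(), spec.copy()
    lo = np.float32(background_level / fold)
    hi = np.float32(background_level)
    rows = []
    for chrom, start, end in placed:
        hyper = rng.random() < direction_mix
        if hyper:  # B above A
            spec_a.levels[chrom][start:end] = lo
            spec_b.levels[chrom][start:end] = hi
        else:
            spec_a.levels[chrom][start:end] = hi
            spec_b.levels[chrom][start:end] = lo
        rows.append(
            {"chrom": chrom, "start": start, "end": end,
             "direction": "hyper" if hyper else "hypo", "fold": fold}
        )
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "fold"])
    spec_a.planted_dmrs = truth.copy()
    spec_b.planted_dmrs = truth.copy()
    return spec_a, spec_b


def plant_asym(
    spec: MethylomeSpec,
    n_regions: int,
    width: int = 500,
    seed: int = 0,
) -> MethylomeSpec:
    """Plant regions whose MeDIP signal is confined to one strand
    (alternating forward/reverse), emulating non-CpG-like methylation."""
    rng = np.random.default_rng(seed)
    placed = _sample_free_intervals(spec, n_regions, width, rng, margin=2 * width)
    out = spec.copy()
    rows = []
    for i, (chrom, start, end) in enumerate(placed):
        code = 1 if i % 2 == 0 else 2
        out.strand_force[chrom][start:end] = code
        rows.append(
            {"chrom": chrom, "start": start, "end": end, "strand": "+" if code == 1 else "-"}
        )
    out.planted_asym = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return out


def simulate_fragments(
    spec: MethylomeSpec,
    n_fragments: int,
    len_min: int = 50,
    len_max: int = 350,
    select_min: int = 150,
    select_max: int = 200,
    epsilon: float = DEFAULT_EPSILON,
    seed: int = 0,
    sample_id: str = "sim",
    cohort_label: str | None = None,
    gamma_alpha: float | None = None,
    gamma_tile: int = 500,
) -> FragmentSet:
    """Draw MeDIP fragments from a methylome.

    Fragment length is uniform on the sonication range truncated to the
    size-selection window; an anchor base is drawn with probability
    proportional to ``epsilon + level(x) * cpg(x)`` and the fragment is
    placed uniformly over positions covering the anchor, so a fragment's
    overall weight is proportional to its background plus methylated-CpG
    content.  Strand is the forced strand of the region containing the
    midpoint, or fair-coin otherwise.  ``gamma_alpha`` applies per-tile
    Gamma(1/alpha, alpha) intensity multipliers (mean 1) to create NB
    overdispersion between replicates.
    """
    lo = max(len_min, select_min)
    hi = min(len_max, select_max)
    if lo > hi:
        raise ValueError("size-selection window does not intersect sonication range")
    rng = np.random.default_rng(seed)
    genome = spec.genome
    weights = []
    for chrom in genome.chrom_names:
        n = genome.chrom_lengths[chrom]
        w = np.full(n, epsilon, dtype=np.float64)
        pos = genome.cpg_positions.get(chrom) if genome.cpg_positions else None
        if pos is not None and len(pos):
            w[pos] += spec.levels[chrom][pos]
        if gamma_alpha:
            n_tiles = -(-n // gamma_tile)
            mult = rng.gamma(1.0 / gamma_alpha, gamma_alpha, size=n_tiles)
            w *= np.repeat(mult, gamma_tile)[:n]
        weights.append(w)
    flat = np.concatenate(weights)
    total = flat.sum()
    if total <= 0:
        raise ValueError("zero total emission weight")
    cum = np.cumsum(flat)
    offsets = np.cumsum([0] + [genome.chrom_lengths[c] for c in genome.chrom_names])
    anchors = np.searchsorted(cum, rng.random(n_fragments) * total, side="right")
    chrom_idx = np.searchsorted(offsets, anchors, side="right") - 1
    local = anchors - offsets[chrom_idx]
    lengths = rng.integers(lo, hi + 1, size=n_fragments)
    starts = local - rng.integers(0, lengths)
    chrom_lengths = np.array([genome.chrom_lengths[c] for c in genome.chrom_names])
    starts = np.clip(starts, 0, chrom_lengths[chrom_idx] - lengths)
    ends = starts + lengths
    mids = (starts + ends) // 2
    strands = np.where(rng.random(n_fragments) < 0.5, "+", "-").astype("<U1")
    for ci, chrom in enumerate(genome.chrom_names):
        mask = chrom_idx == ci
        if not mask.any():
            continue
        forced = spec.strand_force[chrom][mids[mask]]
        sub = strands[mask]
        sub[forced == 1] = "+"
        sub[forced == 2] = "-"
        strands[mask] = sub
    chroms = np.array(genome.chrom_names, dtype=object)[chrom_idx]
    return FragmentSet(
        sample_id=sample_id,
        chroms=chroms,
        starts=starts.astype(np.int64),
        ends=ends.astype(np.int64),
        strands=strands,
        cohort_label=cohort_label,
    )


def simulate_bisulfite(
    spec: MethylomeSpec, depth_mean: float = 30.0, seed: int = 0
) -> CpGCallSet:
    """Bisulfite CpG calls: depth ~ Poisson(depth_mean), methylated ~
    Binomial(depth, level at the CpG)."""
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    genome = spec.genome
    for chrom in genome.chrom_names:
        pos = genome.cpg_positions.get(chrom) if genome.cpg_positions else None
        if pos is None or len(pos) == 0:
            continue
        totals = rng.poisson(depth_mean, size=len(pos))
        meth = rng.binomial(totals, spec.levels[chrom][pos].astype(np.float64))
        rows.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth, "total": totals})
        )
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chrom", "pos", "meth", "total"])
    )
    return CpGCallSet(table)


def simulate_dmr_study(
    seed: int = 0,
    n_replicates: int = 3,
    n_fragments: int = 200_000,
    n_chrom: int = 1,
    chrom_length: int = 1_000_000,
    n_dmrs: int = 100,
    fold: float = 4.0,
    dmr_width: int = 500,
    direction_mix: float = 0.5,
    n_asym: int = 0,
    island_rate: float = 0.01,
    island_size: int = 1_000,
    cpg_bg_rate: float = 0.01,
    cpg_island_rate: float = 0.1,
    epsilon: float = DEFAULT_EPSILON,
    gamma_alpha: float | None = None,
) -> dict:
    """One full two-cohort study: genome, planted truth and replicate
    fragment sets.  Defaults mirror the study design the pipeline targets:
    3 replicates per cohort, ~2e5 fragments per sample on a 1 Mb genome
    with 100 planted 4-fold 500 bp regions."""
    seeds = _child_seeds(seed, 4 + 2 * n_replicates)
    genome, islands = simulate_genome(
        n_chrom=n_chrom,
        chrom_length=chrom_length,
        island_rate=island_rate,
        island_size=island_size,
        cpg_bg_rate=cpg_bg_rate,
        cpg_island_rate=cpg_island_rate,
        seed=seeds[0],
    )
    base = make_methylome(genome, islands)
    if n_asym:
        base = plant_asym(base, n_asym, width=dmr_width, seed=seeds[1])
    if n_dmrs:
        spec_a, spec_b = plant_dmrs(
            base, n_dmrs, fold=fold, width=dmr_width,
            direction_mix=direction_mix, seed=seeds[2],
        )
    else:
        spec_a, spec_b = base.copy(), base.copy()
    fragsets_a = [
        simulate_fragments(
            spec_a, n_fragments, epsilon=epsilon, seed=seeds[3 + i],
            sample_id=f"A{i + 1}", cohort_label="A", gamma_alpha=gamma_alpha,
        )
        for i in range(n_replicates)
    ]
    fragsets_b = [
        simulate_fragments(
            spec_b, n_fragments, epsilon=epsilon, seed=seeds[3 + n_replicates + i],
            sample_id=f"B{i + 1}", cohort_label="B", gamma_alpha=gamma_alpha,
        )
        for i in range(n_replicates)
    ]
    return {
        "genome": genome,
        "islands": islands,
        "spec_a": spec_a,
        "spec_b": spec_b,
        "fragsets_a": fragsets_a,
        "fragsets_b": fragsets_b,
        "truth": spec_a.planted_dmrs,
        "asym_truth": spec_a.planted_asym,
    }
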