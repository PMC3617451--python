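import numpy as np
import pytest

from medusa import FragmentSet, GenomeSpec
from medusa.dmr_core import WindowCountMatrix


@pytest.fixture
def toy_genome() -> GenomeSpec:
    return GenomeSpec(
        chrom_names=["chr1", "chr2"],
        chrom_lengths={"chr1": 10_000, "chr2": 5_000},
        cpg_positions={
            "chr1": np.arange(100, 9_000, 100, dtype=np.int64),
            "chr2": np.arange(50, 4_000, 200, dtype=np.int64),
        },
    )


def random_fragset(
    genome: GenomeSpec,
    n: int,
    seed: int = 0,
    sample_id: str = "s",
    cohort_label: str | None = None,
    len_range: tuple[int, int] = (150, 200),
) -> FragmentSet:
    """Uniformly placed random fragments (no methylation structure)."""
    rng = np.random.default_rng(seed)
    names = genome.chrom_names
    lengths = np.array([genome.chrom_lengths[c] for c in names], dtype=float)
    ci = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    flen = rng.integers(len_range[0], len_range[1] + 1, size=n)
    starts = np.array(
        [rng.integers(0, genome.chrom_lengths[names[c]] - fl) for c, fl in zip(ci, flen)]
    )
    return FragmentSet(
        sample_id=sample_id,
        chroms=np.array([names[c] for c in ci], dtype=object),
        starts=starts,
        ends=starts + flen,
        strands=np.where(rng.random(n) < 0.5, "+", "-").astype("<U1"),
        cohort_label=cohort_label,
    )


def matrix_from_counts(counts: np.ndarray, n_a: int = 3, window: int = 500) -> WindowCountMatrix:
    """Wrap a raw count matrix as consecutive chr1 windows, cohorts A|B."""
    counts = np.asarray(counts)
    n, m = counts.shape
    return WindowCountMatrix(
        chrom=np.array(["chr1"] * n, dtype=object),
        start=np.arange(n) * window,
        end=np.arange(n) * window + window,
        window_index=np.arange(n),
        counts=counts,
        sample_ids=[f"s{i}" for i in range(m)],
        cohort_labels=["A"] * n_a + ["B"] * (m - n_a),
        library_sizes=counts.sum(axis=0),
        window_size=window,
    )


def nb_null_matrix(
    seed: int,
    n_windows: int = 10_000,
    alpha: float = 0.2,
    n_per_cohort: int = 3,
    mean_range: tuple[float, float] = (5, 500),
) -> WindowCountMatrix:
    """Both cohorts drawn from the same NB law (gamma-Poisson mixture)."""
    rng = np.random.default_rng(seed)
    m = 2 * n_per_cohort
    mu = rng.uniform(*mean_range, n_windows)
    if alpha > 0:
        lam = mu[:, None] * rng.gamma(1 / alpha, alpha, size=(n_windows, m))
    else:
        lam = np.repeat(mu[:, None], m, axis=1)
    return matrix_from_counts(rng.poisson(lam), n_a=n_per_cohort)
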