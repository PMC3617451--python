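"""Windowed negative-binomial differential methylation testing.

The statistical engine: fragment counts in fixed genomic windows are
compared between two cohorts of replicates under a negative-binomial model
in the style of the classic DESeq exact test:

* per-sample *size factors* by median-of-ratios to the per-window
  geometric mean, correcting sequencing depth without being driven by a
  handful of highly covered windows;
* per-window *raw dispersions* by method of moments on normalised counts,
  then a mean–dispersion local regression (lowess on log mean), the test
  using the maximum of raw and fitted dispersion (conservative sharing,
  appropriate for the 2–3 replicates typical of MeDIP designs);
* a *conditioned exact test*: given the total count of a window, the
  probability of a split at least as extreme as the observed one, summing
  P(a)P(b) over all splits a + b = k_total with probability not exceeding
  the observed split's;
* Benjamini–Hochberg adjustment over all tested windows, and merging of
  runs of significant same-direction windows into DMRs, recording the
  best (lowest-p) window of each region.

Counts enter the test raw; size factors enter through the NB means.
Windows whose combined depth over all samples is below a threshold
(default 10) are excluded before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coverage_qc import count_fragments, tile_genome
from .fragments_io import FragmentSet
from .genome import GenomeSpec

__all__ = [
    "WindowCountMatrix",
    "DispersionFit",
    "DMR",
    "build_count_matrix",
    "estimate_size_factors",
    "fit_dispersion",
    "nb_conditioned_test",
    "test_windows",
    "bh_adjust",
    "merge_significant_windows",
    "strand_asymmetry",
    "call_dmrs",
    "dmrs_to_dataframe",
]

DISPERSION_FLOOR = 1e-8


@dataclass
class WindowCountMatrix:
    """Integer fragment counts per window per sample, with cohort labels.

    ``window_index`` is the ordinal of each retained window in the original
    genome-wide grid (used to measure gaps after depth filtering).
    """

    chrom: np.ndarray  # object, per window
    start: np.ndarray
    end: np.ndarray
    window_index: np.ndarray
    counts: np.ndarray  # (n_windows, n_samples) int64
    sample_ids: list[str]
    cohort_labels: list[str]  # per sample
    library_sizes: np.ndarray
    window_size: int = 500
    n_windows_filtered: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative integers")
        if self.counts.shape[1] != len(self.sample_ids):
            raise ValueError("counts columns must match sample_ids")
        if len(self.cohort_labels) != len(self.sample_ids):
            raise ValueError("one cohort label per sample required")

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def cohorts(self) -> list[str]:
        seen: list[str] = []
        for c in self.cohort_labels:
            if c not in seen:
                seen.append(c)
        return seen

    def cohort_columns(self, label: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.cohort_labels) if c == label])


def build_count_matrix(
    cohort_a: list[FragmentSet],
    cohort_b: list[FragmentSet],
    genome: GenomeSpec,
    window: int = 500,
    depth_threshold: int = 10,
    label_a: str = "A",
    label_b: str = "B",
) -> WindowCountMatrix:
    """Count fragment midpoints per window and drop low-depth windows.

    Windows whose total count over *all* samples is below
    ``depth_threshold`` are removed (their number is recorded).
    """
    if not cohort_a or not cohort_b:
        raise ValueError("each cohort needs at least one sample")
    ids_a = {fs.sample_id for fs in cohort_a}
    ids_b = {fs.sample_id for fs in cohort_b}
    if ids_a & ids_b:
        raise ValueError(f"cohorts share sample ids: {sorted(ids_a & ids_b)}")
    grid = tile_genome(genome, window=window)
    fragsets = list(cohort_a) + list(cohort_b)
    counts = np.column_stack([count_fragments(grid, fs) for fs in fragsets])
    total = counts.sum(axis=1)
    keep = total >= depth_threshold
    return WindowCountMatrix(
        chrom=grid.chrom_of_window()[keep],
        start=grid.starts[keep],
        end=grid.ends[keep],
        window_index=np.nonzero(keep)[0],
        counts=counts[keep],
        sample_ids=[fs.sample_id for fs in fragsets],
        cohort_labels=[label_a] * len(cohort_a) + [label_b] * len(cohort_b),
        library_sizes=np.array([fs.library_size for fs in fragsets], dtype=np.int64),
        window_size=window,
        n_windows_filtered=int((~keep).sum()),
    )


def estimate_size_factors(matrix: WindowCountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    s_j = median over windows i (restricted to windows positive in every
    sample) of k_ij / geometric_mean_i.
    """
    counts = matrix.counts if isinstance(matrix, WindowCountMatrix) else np.asarray(matrix)
    if counts.ndim != 2 or counts.shape[0] == 0:
        raise ValueError("count matrix must be 2-D and non-empty")
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no window has positive counts in all samples; "
            "consider a pseudo-reference fallback"
        )
    logs = np.log(counts[positive].astype(float))
    log_geomeans = logs.mean(axis=1, keepdims=True)
    return np.exp(np.median(logs - log_geomeans, axis=0))


@dataclass
class DispersionFit:
    """Raw per-window dispersions plus a fitted mean->dispersion function."""

    raw: np.ndarray  # per window, NaN where undefined
    fit_x: np.ndarray = field(repr=False)  # log means used in the fit
    fit_y: np.ndarray = field(repr=False)  # fitted dispersions at fit_x
    floor: float = DISPERSION_FLOOR
    sharing: str = "maximum"  # maximum | fit-only

    def fitted(self, q: np.ndarray | float) -> np.ndarray:
        q = np.atleast_1d(np.asarray(q, dtype=float))
        out = np.full(len(q), self.floor)
        ok = q > 0
        if len(self.fit_x):
            out[ok] = np.interp(np.log(q[ok]), self.fit_x, self.fit_y)
        return np.maximum(out, self.floor)

    def for_test(self, q: np.ndarray) -> np.ndarray:
        """Dispersion used by the test at pooled mean q (per window)."""
        fitted = self.fitted(q)
        if self.sharing == "fit-only":
            return fitted
        raw = np.where(np.isnan(self.raw), -np.inf, self.raw)
        return np.maximum(raw, fitted)


def fit_dispersion(
    matrix: WindowCountMatrix,
    size_factors: np.ndarray,
    lowess_frac: float = 0.3,
    sharing: str = "maximum",
) -> DispersionFit:
    """Method-of-moments dispersion with a lowess mean–dispersion fit.

    Per window: q_i = mean normalised count, v_i = within-cohort pooled
    sample variance of normalised counts, xi = mean(1/s_j); the raw
    dispersion is alpha_i = max(0, (v_i − q_i·xi) / q_i²) — the excess of
    the observed variance over the shot-noise expectation, on the NB scale
    variance = mu + alpha·mu².  The fitted curve alpha(q) is a lowess of
    raw alpha against log q, floored at a small positive value.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    size_factors = np.asarray(size_factors, dtype=float)
    normed = matrix.counts / size_factors
    q = normed.mean(axis=1)
    cohorts = matrix.cohorts
    reps = {c: matrix.cohort_columns(c) for c in cohorts}
    replicated = [c for c in cohorts if len(reps[c]) >= 2]
    raw = np.full(matrix.n_windows, np.nan)
    if replicated:
        ss = np.zeros(matrix.n_windows)
        df = 0
        inv_s: list[float] = []
        for c in replicated:
            cols = reps[c]
            sub = normed[:, cols]
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df += len(cols) - 1
            inv_s.extend(1.0 / size_factors[cols])
        v = ss / df
        xi = float(np.mean(inv_s))
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(q > 0, np.maximum(0.0, (v - q * xi) / q**2), np.nan)
    else:
        warnings.warn(
            "no cohort has >= 2 replicates; dispersion fitted from pooled "
            "across-cohort variance (treat results with caution)",
            stacklevel=2,
        )
        sub = normed
        v = sub.var(axis=1, ddof=1)
        xi = float(np.mean(1.0 / size_factors))
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(q > 0, np.maximum(0.0, (v - q * xi) / q**2), np.nan)
    ok = ~np.isnan(raw) & (q > 0)
    if ok.sum() >= 10 and np.ptp(raw[ok]) > 0:
        x = np.log(q[ok])
        span = x.max() - x.min()
        fitted = lowess(
            raw[ok], x, frac=lowess_frac, it=2,
            delta=0.01 * span if span > 0 else 0.0, return_sorted=True,
        )
        fit_x, fit_y = fitted[:, 0], np.maximum(fitted[:, 1], DISPERSION_FLOOR)
        # de-duplicate x for interpolation
        fit_x, idx = np.unique(fit_x, return_index=True)
        fit_y = fit_y[idx]
    else:
        # too few windows for a regression: constant fit at the mean raw
        level = float(np.nanmean(raw)) if ok.any() else 0.0
        fit_x = np.array([0.0])
        fit_y = np.array([max(level, DISPERSION_FLOOR)])
    return DispersionFit(raw=raw, fit_x=fit_x, fit_y=fit_y, sharing=sharing)


def _nb_pmf(k: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    """NB pmf with mean mu and variance mu + alpha*mu²; Poisson at alpha=0."""
    if mu <= 0:
        return np.where(k == 0, 1.0, 0.0)
    if alpha < 1e-12:
        return stats.poisson.pmf(k, mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return stats.nbinom.pmf(k, r, p)


def nb_conditioned_test(
    k_a: int,
    k_b: int,
    s_a: float,
    s_b: float,
    q_hat: float,
    alpha: float,
) -> float:
    """Exact conditional NB test of a cohort count split.

    With A-count ~ NB(mean q_hat·s_a, dispersion alpha) and B analogously,
    conditioning on the total k_s = k_a + k_b, the p-value sums the joint
    probabilities P(a)P(b) of all splits a + b = k_s that are no more
    likely than the observed split, normalised by the total over all
    splits.  alpha = 0 is the Poisson limit (conditional law Binomial).
    """
    if k_a < 0 or k_b < 0 or int(k_a) != k_a or int(k_b) != k_b:
        raise ValueError("counts must be non-negative integers")
    if s_a <= 0 or s_b <= 0:
        raise ValueError("summed size factors must be > 0")
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    k_a, k_b = int(k_a), int(k_b)
    ks = k_a + k_b
    if ks == 0:
        return 1.0
    a = np.arange(ks + 1)
    pa = _nb_pmf(a, q_hat * s_a, alpha) * _nb_pmf(ks - a, q_hat * s_b, alpha)
    total = pa.sum()
    if total <= 0:
        return 1.0
    p_obs = pa[k_a]
    # tolerance guards float noise on mathematically tied splits
    p = pa[pa <= p_obs * (1.0 + 1e-12)].sum() / total
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_windows(
    matrix: WindowCountMatrix,
    size_factors: np.ndarray | None = None,
    dispersion: DispersionFit | None = None,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Per-window NB conditioned test with BH adjustment.

    Returns a DataFrame with one row per tested window: coordinates,
    ``base_mean`` (pooled mean normalised count), cohort count sums
    ``k_a``/``k_b``, ``log2_fold_change`` (B over A, display pseudo-count
    0.5 on normalised sums; never entering the test), ``p_value`` and
    BH-``adjusted_p``.
    """
    if matrix.n_windows == 0:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "window_index", "base_mean",
                "k_a", "k_b", "log2_fold_change", "p_value", "adjusted_p",
            ]
        )
    if size_factors is None:
        size_factors = estimate_size_factors(matrix)
    if dispersion is None:
        dispersion = fit_dispersion(matrix, size_factors)
    cohorts = matrix.cohorts
    if len(cohorts) != 2:
        raise ValueError(f"exactly two cohorts required, got {cohorts}")
    cols_a = matrix.cohort_columns(cohorts[0])
    cols_b = matrix.cohort_columns(cohorts[1])
    k_a = matrix.counts[:, cols_a].sum(axis=1)
    k_b = matrix.counts[:, cols_b].sum(axis=1)
    s_a = float(size_factors[cols_a].sum())
    s_b = float(size_factors[cols_b].sum())
    normed = matrix.counts / size_factors
    q = normed.mean(axis=1)
    alphas = dispersion.for_test(q)
    p = np.empty(matrix.n_windows)
    for i in range(matrix.n_windows):
        p[i] = nb_conditioned_test(int(k_a[i]), int(k_b[i]), s_a, s_b, float(q[i]), float(alphas[i]))
    lfc = np.log2((k_b / s_b + pseudo_count) / (k_a / s_a + pseudo_count))
    return pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "start": matrix.start,
            "end": matrix.end,
            "window_index": matrix.window_index,
            "base_mean": q,
            "k_a": k_a,
            "k_b": k_b,
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": bh_adjust(p),
        }
    )


@dataclass
class DMR:
    """A merged run of significant same-direction windows."""

    chrom: str
    start: int
    end: int
    direction: str  # hyper | hypo (cohort B relative to A)
    n_windows: int
    k_a: int
    k_b: int
    log2_fold_change: float  # of the best window
    best_window_start: int
    best_window_end: int
    best_window_p: float
    region_fdr: float  # best member window's BH-adjusted p

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("DMR end must exceed start")
        if not (self.start <= self.best_window_start < self.end):
            raise ValueError("best window must lie inside the region")


def merge_significant_windows(
    results: pd.DataFrame,
    max_fdr: float = 0.05,
    max_gap_windows: int = 1,
) -> list[DMR]:
    """Merge runs of significant same-direction windows into DMRs.

    A run extends across up to ``max_gap_windows`` consecutive
    non-significant (or depth-filtered) window slots; member windows must
    share the fold-change sign.  The best window is the member with the
    lowest raw p (ties -> leftmost); the region FDR is its adjusted p.
    """
    dmrs: list[DMR] = []
    if len(results) == 0:
        return dmrs
    sig = results[
        (results["adjusted_p"] <= max_fdr) & (results["log2_fold_change"] != 0)
    ]
    for chrom, group in sig.groupby("chrom", sort=False):
        group = group.sort_values("start")
        run: list[pd.Series] = []
        prev_idx = None
        prev_sign = 0
        for _, row in group.iterrows():
            sign = 1 if row["log2_fold_change"] > 0 else -1
            idx = int(row["window_index"])
            if run and (idx - prev_idx - 1 > max_gap_windows or sign != prev_sign):
                dmrs.append(_finalize_dmr(str(chrom), run))
                run = []
            run.append(row)
            prev_idx, prev_sign = idx, sign
        if run:
            dmrs.append(_finalize_dmr(str(chrom), run))
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs


def _finalize_dmr(chrom: str, run: list[pd.Series]) -> DMR:
    best = min(run, key=lambda r: (r["p_value"], r["start"]))
    sign = 1 if best["log2_fold_change"] > 0 else -1
    return DMR(
        chrom=chrom,
        start=int(run[0]["start"]),
        end=int(run[-1]["end"]),
        direction="hyper" if sign > 0 else "hypo",
        n_windows=len(run),
        k_a=int(sum(r["k_a"] for r in run)),
        k_b=int(sum(r["k_b"] for r in run)),
        log2_fold_change=float(best["log2_fold_change"]),
        best_window_start=int(best["start"]),
        best_window_end=int(best["end"]),
        best_window_p=float(best["p_value"]),
        region_fdr=float(best["adjusted_p"]),
    )


def dmrs_to_dataframe(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "direction": d.direction,
                "n_windows": d.n_windows,
                "k_a": d.k_a,
                "k_b": d.k_b,
                "log2_fold_change": d.log2_fold_change,
                "best_window_start": d.best_window_start,
                "best_window_end": d.best_window_end,
                "best_window_p": d.best_window_p,
                "region_fdr": d.region_fdr,
            }
            for d in dmrs
        ],
        columns=[
            "chrom", "start", "end", "direction", "n_windows", "k_a", "k_b",
            "log2_fold_change", "best_window_start", "best_window_end",
            "best_window_p", "region_fdr",
        ],
    )


def call_dmrs(
    cohort_a: list[FragmentSet],
    cohort_b: list[FragmentSet],
    genome: GenomeSpec,
    window: int = 500,
    depth_threshold: int = 10,
    max_fdr: float = 0.05,
    max_gap_windows: int = 1,
    sharing: str = "maximum",
) -> tuple[list[DMR], pd.DataFrame]:
    """End-to-end DMR calling: count, normalise, test, adjust, merge."""
    matrix = build_count_matrix(
        cohort_a, cohort_b, genome, window=window, depth_threshold=depth_threshold
    )
    if matrix.n_windows == 0:
        return [], test_windows(matrix)
    size_factors = estimate_size_factors(matrix)
    disp = fit_dispersion(matrix, size_factors, sharing=sharing)
    results = test_windows(matrix, size_factors, disp)
    return merge_significant_windows(results, max_fdr=max_fdr, max_gap_windows=max_gap_windows), results


def strand_asymmetry(
    dmr: DMR,
    fragsets: list[FragmentSet],
    p_threshold: float = 0.01,
    min_fraction: float = 0.8,
) -> tuple[float | None, float | None, bool]:
    """Strand bias of fragments within a DMR: potential non-CpG methylation.

    Symmetric CpG methylation pulls down both strands equally, so a strong
    imbalance of fragment strand-of-origin (exact binomial test against
    0.5, plus a majority-fraction threshold) flags the region as a
    candidate for non-CpG methylation.  Fragment membership is by
    midpoint.  Returns (forward_fraction, two_sided_p, flagged); the first
    two are None when the region contains no fragments.
    """
    f = r = 0
    for fs in fragsets:
        mask = (fs.chroms == dmr.chrom) & (fs.midpoints >= dmr.start) & (fs.midpoints < dmr.end)
        f += int(np.sum(fs.strands[mask] == "+"))
        r += int(np.sum(fs.strands[mask] == "-"))
    n = f + r
    if n == 0:
        return None, None, False
    frac = f / n
    p = stats.binomtest(f, n, 0.5).pvalue
    flagged = (p < p_threshold) and (max(frac, 1 - frac) >= min_fraction)
    return frac, float(p), flagged
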