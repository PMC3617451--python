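"""Bisulfite Δms validation and observed/expected overlap statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medusa import (
    CpGCallSet,
    GenomeSpec,
    concordance,
    delta_ms,
    dmr_validation_filter,
    filter_depth,
    oe_overlap,
    permutation_pvalue,
    quantile_normalize,
    random_regions,
)
from medusa.annotate import FeatureSet
from medusa.dmr_core import DMR


def calls(rows):
    return CpGCallSet(pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"]))


def make_dmr(start, end, direction="hyper", chrom="chr1"):
    return DMR(chrom, start, end, direction, 1, 0, 0, 1.0, start, end, 1e-3, 1e-2)


class TestDepthFilter:
    def test_boundary_at_ten(self):
        cs = calls([("chr1", i, 1, d) for i, d in enumerate((9, 10, 11))])
        assert len(filter_depth(cs, 10)) == 2

    def test_empty(self):
        assert len(filter_depth(calls([]), 10)) == 0

    def test_idempotent(self):
        cs = calls([("chr1", i, 0, d) for i, d in enumerate((5, 15, 25))])
        once = filter_depth(cs, 10)
        assert filter_depth(once, 10).table.equals(once.table)


class TestQuantileNormalize:
    def test_hand_worked_example(self):
        a, b = quantile_normalize(np.array([3.0, 1.0, 2.0]), np.array([40.0, 60.0, 50.0]))
        np.testing.assert_allclose(a, [31.5, 20.5, 26.0])
        np.testing.assert_allclose(b, [20.5, 31.5, 26.0])

    def test_identical_inputs_unchanged(self):
        x = np.array([0.1, 0.7, 0.4])
        a, b = quantile_normalize(x, x.copy())
        np.testing.assert_allclose(a, x)
        np.testing.assert_allclose(b, x)

    def test_ties_map_to_equal_outputs(self):
        a, b = quantile_normalize(np.array([1.0, 1.0, 5.0]), np.array([2.0, 4.0, 6.0]))
        assert a[0] == a[1]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30))
    def test_sorted_vectors_identical(self, values):
        rng = np.random.default_rng(0)
        a = np.asarray(values)
        b = rng.permutation(a) * 0.5 + 0.1
        qa, qb = quantile_normalize(a, b)
        np.testing.assert_allclose(np.sort(qa), np.sort(qb), atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.array([1.0]), np.array([1.0, 2.0]))


class TestValidationFilter:
    def _calls_n(self, n, start=0, spacing=10):
        return calls([("chr1", start + i * spacing, 5, 20) for i in range(n)])

    def test_nine_cpgs_excluded_ten_retained(self):
        d = make_dmr(0, 500)
        assert dmr_validation_filter([d], self._calls_n(9)) == []
        assert dmr_validation_filter([d], self._calls_n(10)) == [d]

    def test_single_bp_repeat_overlap_excludes(self):
        d = make_dmr(0, 500)
        repeats = FeatureSet(
            "simple_repeat",
            pd.DataFrame([{"chrom": "chr1", "start": 499, "end": 600}]),
        )
        assert dmr_validation_filter([d], self._calls_n(10), repeats) == []
        repeats_clear = FeatureSet(
            "simple_repeat",
            pd.DataFrame([{"chrom": "chr1", "start": 500, "end": 600}]),
        )
        assert dmr_validation_filter([d], self._calls_n(10), repeats_clear) == [d]


class TestDeltaMs:
    def test_full_swing(self):
        a = calls([("chr1", i * 10, 20, 20) for i in range(10)])
        b = calls([("chr1", i * 10, 0, 20) for i in range(10)])
        r = delta_ms(make_dmr(0, 500, "hypo"), a, b)
        assert r.delta_ms == pytest.approx(1.0)
        assert r.supported  # A above B backs a B-hypomethylated call

    def test_identical_calls_zero_delta(self):
        a = calls([("chr1", i * 10, 7, 20) for i in range(10)])
        r = delta_ms(make_dmr(0, 500), a, a)
        assert r.delta_ms == 0.0 and r.supported is False

    def test_mean_aggregation(self):
        diffs = [0.2, 0.4, 0.0, 0.3, 0.1, 0.0, 0.2, 0.1, 0.1, 0.1]  # mean 0.15
        a = calls([("chr1", i * 10, int(round((0.5 + d) * 100)), 100) for i, d in enumerate(diffs)])
        b = calls([("chr1", i * 10, 50, 100) for i in range(10)])
        r = delta_ms(make_dmr(0, 500, "hypo"), a, b)
        assert r.delta_ms == pytest.approx(0.15)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a = calls([("chr1", i * 10, int(m), 50) for i, m in enumerate(rng.integers(0, 51, 10))])
        b = calls([("chr1", i * 10, int(m), 50) for i, m in enumerate(rng.integers(0, 51, 10))])
        d = make_dmr(0, 500)
        assert delta_ms(d, a, b).delta_ms == pytest.approx(-delta_ms(d, b, a).delta_ms)

    def test_no_shared_cpgs_undefined(self):
        a = calls([("chr1", 10, 5, 20)])
        b = calls([("chr1", 20, 5, 20)])
        r = delta_ms(make_dmr(0, 500), a, b)
        assert r.delta_ms is None and r.supported is None


class TestConcordance:
    def test_counts_and_strong_threshold(self):
        a_scores = [-0.3, -0.05, 0.2]
        results = []
        for i, dm in enumerate(a_scores):
            d = make_dmr(i * 1000, i * 1000 + 500, "hypo")
            from medusa.bisulfite_validate import DeltaResult

            results.append(DeltaResult(d, 10, dm, dm > 0))
        out = concordance(results)
        row = out["per_direction"]["hypo"]
        assert row["n"] == 3 and row["supported"] == 1
        assert row["strong"] == 1  # only +0.2 clears the 0.1 bar concordantly
        assert row["contradicted_strong"] == 1  # -0.3

    def test_partition_conservation(self):
        from medusa.bisulfite_validate import DeltaResult

        results = [
            DeltaResult(make_dmr(0, 500), 10, -0.2, True),
            DeltaResult(make_dmr(1000, 1500), 0, None, None),
        ]
        out = concordance(results)
        assert out["n_defined"] + out["n_undefined"] == out["n_total"]


class TestPermutationP:
    def test_observed_above_all_null(self):
        p = permutation_pvalue(10.0, lambda rng: rng.random(), n_perm=1000, tail="ge", seed=1)
        assert p == pytest.approx(1 / 1001)

    def test_observed_below_all_null(self):
        p = permutation_pvalue(-1.0, lambda rng: rng.random(), n_perm=1000, tail="ge", seed=1)
        assert p == 1.0

    def test_seed_reproducible(self):
        sampler = lambda rng: rng.normal()
        assert permutation_pvalue(0.5, sampler, 200, "ge", seed=3) == permutation_pvalue(
            0.5, sampler, 200, "ge", seed=3
        )

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            permutation_pvalue(0.0, lambda rng: 0.0, n_perm=0)


class TestRandomRegions:
    def test_exact_size_and_count(self):
        genome = GenomeSpec(["chr1", "chr2"], {"chr1": 100_000, "chr2": 50_000})
        df = random_regions(genome, n=1000, size=500, seed=5)
        assert len(df) == 1000
        assert set((df["end"] - df["start"]).tolist()) == {500}

    def test_within_bounds(self):
        genome = GenomeSpec(["chr1"], {"chr1": 10_000})
        df = random_regions(genome, n=500, size=500, seed=6)
        assert df["start"].min() >= 0 and df["end"].max() <= 10_000

    def test_deterministic(self):
        genome = GenomeSpec(["chr1"], {"chr1": 10_000})
        a = random_regions(genome, 100, seed=7)
        b = random_regions(genome, 100, seed=7)
        assert a.equals(b)


class TestOeOverlap:
    def test_worked_ratio(self):
        genome = GenomeSpec(["chr1"], {"chr1": 10_000})
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [700], "end": [1700]})
        observed, expected, ratio = oe_overlap(a, b, genome)
        assert observed == 300
        assert expected == pytest.approx(100.0)
        assert ratio == pytest.approx(3.0)

    def test_disjoint_zero_ratio(self):
        genome = GenomeSpec(["chr1"], {"chr1": 10_000})
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [6000]})
        assert oe_overlap(a, b, genome)[2] == 0.0

    def test_whole_genome_saturation(self):
        genome = GenomeSpec(["chr1"], {"chr1": 10_000})
        a = pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [3000]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        observed, expected, ratio = oe_overlap(a, b, genome)
        assert observed == 1000 and ratio == pytest.approx(1.0)
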