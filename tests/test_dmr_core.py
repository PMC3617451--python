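"""The NB testing engine: size factors, dispersion, exact test, merging."""

import numpy as np
import pandas as pd
import pytest

from medusa import (
    bh_adjust,
    build_count_matrix,
    estimate_size_factors,
    fit_dispersion,
    merge_significant_windows,
    nb_conditioned_test,
    strand_asymmetry,
)
from medusa import test_windows as run_window_tests
from medusa.dmr_core import DMR
from medusa.fragments_io import FragmentSet
from medusa.genome import GenomeSpec

from conftest import matrix_from_counts, nb_null_matrix
from oracle import conditioned_test_enumeration


def fragset_at(midpoints, chrom="chr1", sample_id="s", cohort=None, strand="+"):
    mids = np.asarray(midpoints)
    return FragmentSet(
        sample_id=sample_id,
        chroms=np.array([chrom] * len(mids), dtype=object),
        starts=mids - 50,
        ends=mids + 50,
        strands=np.array([strand] * len(mids), dtype="<U1"),
        cohort_label=cohort,
    )


class TestBuildCountMatrix:
    def test_combined_depth_boundary(self):
        genome = GenomeSpec(["chr1"], {"chr1": 500})
        # 9 fragments total in the single window -> excluded; 10 -> included
        a = [fragset_at([100] * 3, sample_id=f"a{i}") for i in range(2)]
        b = [fragset_at([100] * 3, sample_id="b0")]
        mat = build_count_matrix(a, b, genome, depth_threshold=10)
        assert mat.n_windows == 0 and mat.n_windows_filtered == 1
        b = [fragset_at([100] * 4, sample_id="b0")]
        mat = build_count_matrix(a, b, genome, depth_threshold=10)
        assert mat.n_windows == 1
        assert mat.counts.tolist() == [[3, 3, 4]]

    def test_shared_sample_id_rejected(self):
        genome = GenomeSpec(["chr1"], {"chr1": 500})
        fs = fragset_at([100] * 5, sample_id="dup")
        with pytest.raises(ValueError, match="share sample ids"):
            build_count_matrix([fs], [fs], genome)

    def test_empty_genome_gives_empty_matrix(self):
        genome = GenomeSpec(["chr1"], {"chr1": 2000})
        a = [fragset_at([], sample_id="a")]
        b = [fragset_at([], sample_id="b")]
        mat = build_count_matrix(a, b, genome)
        assert mat.n_windows == 0


class TestSizeFactors:
    def test_median_of_ratios_hand_value(self):
        counts = np.tile([2, 8], (20, 1))  # geometric mean 4 per window
        np.testing.assert_allclose(
            estimate_size_factors(matrix_from_counts(counts, n_a=1)), [0.5, 2.0]
        )

    def test_identical_samples_unit_factors(self):
        counts = np.tile([7, 7, 7], (15, 1))
        np.testing.assert_allclose(
            estimate_size_factors(matrix_from_counts(counts, n_a=2)), [1, 1, 1]
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson([20, 40, 80], size=(200, 3)) + 1
        s = estimate_size_factors(matrix_from_counts(counts, n_a=2))
        perm = [2, 0, 1]
        s_perm = estimate_size_factors(matrix_from_counts(counts[:, perm], n_a=2))
        np.testing.assert_allclose(s_perm, s[perm])

    def test_no_allpositive_window_errors(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="positive"):
            estimate_size_factors(matrix_from_counts(counts, n_a=1))


class TestDispersion:
    def test_poisson_counts_fit_near_zero(self):
        mat = nb_null_matrix(seed=11, n_windows=2_000, alpha=0.0)
        sf = estimate_size_factors(mat)
        fit = fit_dispersion(mat, sf)
        q = (mat.counts / sf).mean(axis=1)
        assert np.median(fit.fitted(q)) < 0.01

    def test_nb_dispersion_recovered(self):
        mat = nb_null_matrix(seed=12, n_windows=2_000, alpha=0.2)
        sf = estimate_size_factors(mat)
        fit = fit_dispersion(mat, sf)
        q = (mat.counts / sf).mean(axis=1)
        fitted = fit.fitted(q)
        assert 0.1 <= np.median(fitted) <= 0.4
        # across the mean range, not just at the centre
        for lo, hi in [(5, 50), (50, 500)]:
            band = fitted[(q >= lo) & (q < hi)]
            assert 0.1 <= np.median(band) <= 0.4

    def test_constant_replicates_zero_raw(self):
        counts = np.tile([10, 10, 10, 10, 10, 10], (30, 1))
        mat = matrix_from_counts(counts)
        fit = fit_dispersion(mat, np.ones(6))
        assert np.all(fit.raw[~np.isnan(fit.raw)] == 0.0)


class TestConditionedTest:
    def test_balanced_split_has_p_one(self):
        # conditional law Binomial(4, 1/2); the observed split is the mode
        assert nb_conditioned_test(2, 2, 1.0, 1.0, 2.0, 0.0) == 1.0

    def test_three_one_split(self):
        # Binomial(4, 1/2) probs (1,4,6,4,1)/16; mass <= 4/16 sums to 10/16
        assert nb_conditioned_test(3, 1, 1.0, 1.0, 2.0, 0.0) == pytest.approx(0.625, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.1, 1.0])
    @pytest.mark.parametrize("s_a,s_b", [(1.0, 1.0), (2.0, 1.0)])
    def test_matches_enumeration_oracle(self, alpha, s_a, s_b):
        for ks in range(0, 31, 3):
            for k_a in range(ks + 1):
                q = max(ks, 1) / (s_a + s_b)
                got = nb_conditioned_test(k_a, ks - k_a, s_a, s_b, q, alpha)
                want = conditioned_test_enumeration(k_a, ks - k_a, s_a, s_b, q, alpha)
                assert got == pytest.approx(want, abs=1e-12)

    def test_rejects_non_integer_counts(self):
        with pytest.raises(ValueError, match="integer"):
            nb_conditioned_test(1.5, 2, 1.0, 1.0, 2.0, 0.0)

    def test_p_in_unit_interval_and_positive(self):
        p = nb_conditioned_test(500, 0, 1.0, 1.0, 250.0, 0.5)
        assert 0 < p <= 1


class TestWindowTesting:
    def test_label_swap_flips_fold_change_preserves_p(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(30, size=(300, 6)) + 1
        mat = matrix_from_counts(counts, n_a=3)
        swapped = matrix_from_counts(counts[:, [3, 4, 5, 0, 1, 2]], n_a=3)
        res = run_window_tests(mat, np.ones(6))
        res_sw = run_window_tests(swapped, np.ones(6))
        np.testing.assert_allclose(res["p_value"], res_sw["p_value"], rtol=1e-10)
        np.testing.assert_allclose(
            res["log2_fold_change"], -res_sw["log2_fold_change"], rtol=1e-10
        )

    def test_extreme_window_called_hyper(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(30, size=(200, 6)) + 1
        counts[0, :3] = 0
        counts[0, 3:] = 150
        mat = matrix_from_counts(counts, n_a=3)
        res = run_window_tests(mat, np.ones(6))
        assert res.loc[0, "adjusted_p"] < 1e-6
        assert res.loc[0, "log2_fold_change"] > 0

    def test_null_pvalues_not_anticonservative(self):
        mat = nb_null_matrix(seed=21, n_windows=10_000, alpha=0.1)
        sf = estimate_size_factors(mat)
        res = run_window_tests(mat, sf, fit_dispersion(mat, sf))
        # the conditioned test is discrete and conservative; the rejection
        # rate at any cut must not exceed the nominal level by more than
        # Monte-Carlo noise
        for cut in (0.01, 0.05, 0.1):
            assert float(np.mean(res["p_value"] <= cut)) <= cut + 0.01

    def test_empty_matrix_empty_result(self):
        counts = np.empty((0, 4), dtype=int)
        mat = matrix_from_counts(counts, n_a=2)
        assert len(run_window_tests(mat, np.ones(4))) == 0


class TestBH:
    def test_step_up_hand_value(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04]
        )

    def test_single_and_tied(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])
        np.testing.assert_allclose(bh_adjust(np.full(5, 0.03)), np.full(5, 0.03))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.2]))


def _results_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "window_index", "base_mean",
                 "k_a", "k_b", "log2_fold_change", "p_value", "adjusted_p"],
    )


class TestMerging:
    def test_adjacent_same_direction_merge(self):
        res = _results_frame([
            ("chr1", 0, 500, 0, 10, 5, 40, 2.0, 0.001, 0.001),
            ("chr1", 500, 1000, 1, 10, 5, 35, 1.8, 0.002, 0.002),
        ])
        dmrs = merge_significant_windows(res)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end) == (0, 1000)
        assert d.best_window_start == 0 and d.region_fdr == 0.001
        assert d.direction == "hyper"

    def test_opposite_directions_split(self):
        res = _results_frame([
            ("chr1", 0, 500, 0, 10, 5, 40, 2.0, 0.001, 0.001),
            ("chr1", 500, 1000, 1, 10, 40, 5, -2.0, 0.001, 0.001),
        ])
        assert len(merge_significant_windows(res)) == 2

    def test_gap_rule(self):
        res = _results_frame([
            ("chr1", 0, 500, 0, 10, 5, 40, 2.0, 0.001, 0.001),
            ("chr1", 1500, 2000, 3, 10, 5, 40, 2.0, 0.001, 0.001),
        ])
        # 2 missing window slots between them; max_gap 1 -> two DMRs
        assert len(merge_significant_windows(res, max_gap_windows=1)) == 2
        assert len(merge_significant_windows(res, max_gap_windows=2)) == 1

    def test_nonsignificant_never_member(self):
        res = _results_frame([
            ("chr1", 0, 500, 0, 10, 5, 40, 2.0, 0.001, 0.2),
        ])
        assert merge_significant_windows(res) == []


class TestStrandAsymmetry:
    def _dmr(self):
        return DMR("chr1", 0, 500, "hyper", 1, 0, 20, 2.0, 0, 500, 1e-4, 1e-3)

    def test_symmetric_not_flagged(self):
        fs = [fragset_at([100] * 10, strand="+"), fragset_at([200] * 10, strand="-")]
        frac, p, flag = strand_asymmetry(self._dmr(), fs)
        assert frac == 0.5 and p == pytest.approx(1.0, abs=0.3) and not flag

    def test_all_forward_flagged(self):
        frac, p, flag = strand_asymmetry(self._dmr(), [fragset_at([100] * 20, strand="+")])
        assert frac == 1.0 and flag

    def test_exact_binomial_18_2(self):
        fs = [fragset_at([100] * 18, strand="+"), fragset_at([200] * 2, strand="-")]
        frac, p, flag = strand_asymmetry(self._dmr(), fs)
        assert p == pytest.approx(422 / 2**20, rel=1e-9)
        assert flag

    def test_empty_region_undefined(self):
        frac, p, flag = strand_asymmetry(self._dmr(), [fragset_at([], strand="+")])
        assert frac is None and p is None and not flag
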