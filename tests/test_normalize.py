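"""Normalization chain: pTPM scaling, TMM factors against a literal oracle,
median-of-ratios size factors, and centered log expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cellrep import normalize as norm
from cellrep.matrix import ExpressionMatrix

from conftest import make_matrix


def tmm_factor_oracle(x, r, logratio_trim=0.3, abs_intensity_trim=0.05,
                      do_weighting=True):
    """Literal, unoptimized transcription of the trimmed-mean-of-M formula.

    Plain Python loops; rank-based two-sided trims on M and A (stable order
    for ties), inverse delta-method binomial variance weights.
    """
    N = 1.0e6
    pairs = [(xi, ri) for xi, ri in zip(x, r) if xi > 0 and ri > 0]
    M = [np.log2(xi / ri) for xi, ri in pairs]
    A = [0.5 * np.log2(xi * ri / (N * N)) for xi, ri in pairs]
    n = len(M)

    def keep(vals, trim):
        order = sorted(range(n), key=lambda i: (vals[i], i))
        rank = [0] * n
        for pos, i in enumerate(order, start=1):
            rank[i] = pos
        lo = int(np.floor(n * trim)) + 1
        hi = n + 1 - lo
        return [lo <= rank[i] <= hi for i in range(n)]

    km = keep(M, logratio_trim)
    ka = keep(A, abs_intensity_trim)
    kept = [i for i in range(n) if km[i] and ka[i]]
    if len(kept) < 10:
        kept = list(range(n))
    num = den = 0.0
    for i in kept:
        xi, ri = pairs[i]
        if do_weighting:
            w = 1.0 / ((N - xi) / (N * xi) + (N - ri) / (N * ri))
        else:
            w = 1.0
        num += w * M[i]
        den += w
    return 2.0 ** (num / den)


class TestPtpm:
    def test_rescales_coding_genes_to_one_million(self):
        tpm = make_matrix([[3e5], [1e5], [6e5]], unit="TPM")
        out = norm.to_ptpm(tpm, ["g0", "g1"])
        assert out.unit == "pTPM"
        np.testing.assert_allclose(out.data["s0"].to_numpy(), [7.5e5, 2.5e5])

    def test_identity_when_coding_sum_already_one_million(self):
        tpm = make_matrix([[4e5], [6e5]], unit="TPM")
        out = norm.to_ptpm(tpm, ["g0", "g1"])
        np.testing.assert_allclose(out.data["s0"].to_numpy(), [4e5, 6e5])

    def test_proportional_rescale(self):
        tpm = make_matrix([[1.0], [1.0], [2.0]], unit="TPM")
        out = norm.to_ptpm(tpm, ["g0", "g1", "g2"])
        np.testing.assert_allclose(out.data["s0"].to_numpy(),
                                   [2.5e5, 2.5e5, 5e5])

    def test_all_zero_sample_names_the_sample(self):
        tpm = make_matrix([[1.0, 0.0], [1.0, 0.0]], unit="TPM")
        with pytest.raises(ValueError, match="s1"):
            norm.to_ptpm(tpm, ["g0", "g1"])

    @given(st.lists(st.floats(0.01, 1e5), min_size=2, max_size=20),
           st.integers(1, 5))
    @settings(max_examples=30, deadline=None)
    def test_columns_sum_to_one_million(self, col, n_samples):
        vals = np.tile(np.asarray(col)[:, None], (1, n_samples))
        vals *= np.arange(1, n_samples + 1)
        tpm = make_matrix(vals, unit="TPM")
        out = norm.to_ptpm(tpm, tpm.gene_ids)
        np.testing.assert_allclose(out.data.sum(axis=0), 1e6, rtol=1e-9)


class TestReferenceSelection:
    def test_single_sample(self):
        m = make_matrix([[1.0], [2.0]], unit="pTPM")
        assert norm.select_tmm_reference(m) == "s0"

    def test_median_upper_quartile(self):
        # upper quartiles 5, 9, 20 -> the middle sample wins
        cols = {"a": [5.0, 5, 5, 5], "b": [9.0, 9, 9, 9], "c": [20.0, 20, 20, 20]}
        m = ExpressionMatrix(pd.DataFrame(cols, index=["g0", "g1", "g2", "g3"]),
                             "pTPM")
        assert norm.select_tmm_reference(m) == "b"

    def test_tie_goes_to_lexicographically_smallest(self):
        vals = np.ones((5, 3))
        m = make_matrix(vals, samples=["z", "m", "a"], unit="pTPM")
        assert norm.select_tmm_reference(m) == "a"


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(1, 100, size=40)
        vals = np.tile(col[:, None], (1, 4))
        m = make_matrix(vals * 1e6 / col.sum(), unit="pTPM")
        f = norm.tmm_factors(m)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-12)

    def test_agrees_with_literal_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            vals = rng.lognormal(3, 1, size=(50, 10))
            vals = vals / vals.sum(axis=0) * 1e6
            m = make_matrix(vals, unit="pTPM")
            ref = norm.select_tmm_reference(m)
            f = norm.tmm_factors(m, ref=ref)
            raw = np.array([
                1.0 if sid == ref else
                tmm_factor_oracle(m.data[sid].to_numpy(),
                                  m.data[ref].to_numpy())
                for sid in m.sample_ids])
            expected = raw / np.exp(np.mean(np.log(raw)))
            np.testing.assert_allclose(f.to_numpy(), expected, atol=1e-10)

    def test_single_doubled_gene_matches_oracle(self):
        # a single doubled gene is an extreme log-ratio: the 30% trim discards
        # it, so the factor equals the oracle's trimmed mean (here exactly 1)
        rng = np.random.default_rng(7)
        col = rng.uniform(10, 100, size=60)
        other = col.copy()
        other[0] *= 2
        vals = np.column_stack([col, other]) * 1e6 / col.sum()
        m = make_matrix(vals, unit="pTPM")
        f = norm.tmm_factors(m, ref="s0")
        raw = tmm_factor_oracle(m.data["s1"].to_numpy(), m.data["s0"].to_numpy())
        expected = np.array([1.0, raw])
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(f.to_numpy(), expected, atol=1e-10)

    def test_partial_upshift_gives_factor_between_one_and_two(self):
        # with a mild trim, doubling a quarter of the genes pulls the trimmed
        # weighted mean strictly into (0, 1) on the log2 scale
        rng = np.random.default_rng(8)
        col = rng.uniform(10, 100, size=80)
        other = col * (1 + rng.normal(0, 0.01, 80))
        other[:20] *= 2
        # no per-column renormalization here: the doubled genes must stay an
        # upshift rather than becoming a compositional downshift of the rest
        vals = np.column_stack([col, other])
        m = make_matrix(vals, unit="pTPM")
        params = norm.TmmParams(logratio_trim=0.1)
        f = norm.tmm_factors(m, ref="s0", params=params)
        # undo geometric-mean rescale to inspect the raw s1-vs-s0 factor
        raw = f["s1"] / f["s0"]
        assert 1.0 < raw < 2.0

    def test_factor_product_is_one(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(2, 1.2, size=(80, 6))
        vals = vals / vals.sum(axis=0) * 1e6
        f = norm.tmm_factors(make_matrix(vals, unit="pTPM"))
        assert abs(np.prod(f.to_numpy()) - 1.0) < 1e-9

    def test_untrimmed_fallback_warns_with_few_genes(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 10, size=(6, 2))
        vals = vals / vals.sum(axis=0) * 1e6
        m = make_matrix(vals, unit="pTPM")
        with pytest.warns(RuntimeWarning, match="untrimmed"):
            norm.tmm_factors(m, ref="s0")

    def test_no_coexpressed_genes_is_an_error(self):
        vals = np.array([[1e6, 0.0], [0.0, 1e6]])
        m = make_matrix(vals, unit="pTPM")
        with pytest.raises(ValueError, match="shares no expressed genes"):
            norm.tmm_factors(m, ref="s0")


class TestApplyTmm:
    def test_unit_factors_are_identity(self):
        m = make_matrix([[10.0, 20.0], [30.0, 40.0]], unit="pTPM")
        f = pd.Series([1.0, 1.0], index=m.sample_ids)
        out = norm.apply_tmm(m, f)
        assert out.unit == "nTPM"
        np.testing.assert_array_equal(out.data.to_numpy(), m.data.to_numpy())

    def test_factor_two_halves_the_sample(self):
        m = make_matrix([[10.0, 20.0]], unit="pTPM")
        f = pd.Series([1.0, 2.0], index=m.sample_ids)
        out = norm.apply_tmm(m, f)
        np.testing.assert_allclose(out.data.to_numpy(), [[10.0, 10.0]])

    def test_round_trip_fixed_point_uniform_weights(self):
        # with uniform weights and a pinned reference the trimmed gene set is
        # invariant under rescaling, so recomputed factors are exactly 1
        rng = np.random.default_rng(5)
        vals = rng.lognormal(3, 1, size=(60, 5)) * [1.0, 2.0, 0.5, 1.5, 3.0]
        vals = vals / vals.sum(axis=0) * 1e6
        m = make_matrix(vals, unit="pTPM")
        params = norm.TmmParams(do_weighting=False)
        f = norm.tmm_factors(m, ref="s0", params=params)
        ntpm = norm.apply_tmm(m, f)
        again = ExpressionMatrix(ntpm.data, "pTPM")
        f2 = norm.tmm_factors(again, ref="s0", params=params)
        np.testing.assert_allclose(f2.to_numpy(), 1.0, atol=1e-9)

    def test_round_trip_near_fixed_point_with_weighting(self):
        # inverse-variance weights change slightly after rescaling, so the
        # fixed point is only approximate under the default weighting
        rng = np.random.default_rng(5)
        base = rng.lognormal(3, 1, size=60)
        vals = base[:, None] * 2 ** rng.normal(0, 0.1, size=(60, 5))
        vals = vals / vals.sum(axis=0) * 1e6
        m = make_matrix(vals, unit="pTPM")
        f = norm.tmm_factors(m, ref="s0")
        ntpm = norm.apply_tmm(m, f)
        f2 = norm.tmm_factors(ExpressionMatrix(ntpm.data, "pTPM"), ref="s0")
        np.testing.assert_allclose(f2.to_numpy(), 1.0, atol=0.02)

    def test_nonpositive_factor_rejected(self):
        m = make_matrix([[1.0, 2.0]], unit="pTPM")
        f = pd.Series([1.0, 0.0], index=m.sample_ids)
        with pytest.raises(ValueError, match="nonpositive"):
            norm.apply_tmm(m, f)

    def test_preserves_within_sample_rank_order(self):
        rng = np.random.default_rng(9)
        vals = rng.lognormal(2, 1, size=(40, 4))
        vals = vals / vals.sum(axis=0) * 1e6
        m = make_matrix(vals, unit="pTPM")
        out = norm.apply_tmm(m, norm.tmm_factors(m))
        for sid in m.sample_ids:
            a = m.data[sid].rank().to_numpy()
            b = out.data[sid].rank().to_numpy()
            np.testing.assert_array_equal(a, b)


class TestSizeFactors:
    def test_identical_columns(self):
        vals = np.tile(np.arange(1.0, 11.0)[:, None], (1, 3))
        f = norm.size_factors_median_of_ratios(make_matrix(vals, unit="counts"))
        np.testing.assert_allclose(f.to_numpy(), 1.0)

    def test_doubled_sample_splits_sqrt2(self):
        a = np.arange(1.0, 21.0)
        vals = np.column_stack([a, 2 * a])
        f = norm.size_factors_median_of_ratios(make_matrix(vals, unit="counts"))
        np.testing.assert_allclose(f.to_numpy(),
                                   [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_single_sample_gets_factor_one(self):
        f = norm.size_factors_median_of_ratios(
            make_matrix([[5.0], [7.0]], unit="counts"))
        np.testing.assert_allclose(f.to_numpy(), [1.0])

    def test_no_universally_positive_gene_is_an_error(self):
        vals = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="positive in all samples"):
            norm.size_factors_median_of_ratios(make_matrix(vals, unit="counts"))


class TestLogCenter:
    def test_constant_gene_becomes_zero_row(self):
        m = make_matrix([[7.0, 7.0, 7.0]], unit="counts")
        f = pd.Series(1.0, index=m.sample_ids)
        out = norm.log_center(m, f)
        assert out.unit == "centered-log"
        np.testing.assert_allclose(out.data.to_numpy(), 0.0, atol=1e-12)

    def test_mean_subtraction(self):
        # log2(x + 1) values of 1 and 3 -> centered to -1, +1
        m = make_matrix([[1.0, 7.0]], unit="counts")
        f = pd.Series(1.0, index=m.sample_ids)
        out = norm.log_center(m, f)
        np.testing.assert_allclose(out.data.to_numpy(), [[-1.0, 1.0]])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rows_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 1000, size=(15, 6)).astype(float)
        m = make_matrix(vals, unit="counts")
        f = pd.Series(rng.uniform(0.5, 2.0, 6), index=m.sample_ids)
        out = norm.log_center(m, f)
        np.testing.assert_allclose(out.data.sum(axis=1), 0.0, atol=1e-9)
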