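"""Cell-line prioritization: fold-change ranking, preranked GSEA against a
direct running-sum oracle, rank integration, and recovery of planted best
lines."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cellrep import classify as cls
from cellrep import normalize as norm
from cellrep import prioritize as pri
from cellrep import synthetic as syn

from conftest import make_matrix


def es_oracle(stats, gene_set, weight_exponent=1.0):
    """Direct transcription of the weighted running-sum enrichment score."""
    genes = list(stats.index)
    in_set = [g in gene_set for g in genes]
    m = sum(in_set)
    n = len(genes)
    hit_total = sum(abs(s) ** weight_exponent
                    for s, h in zip(stats.to_numpy(), in_set) if h)
    running = 0.0
    best = 0.0
    for s, h in zip(stats.to_numpy(), in_set):
        if h:
            if hit_total > 0:
                running += abs(s) ** weight_exponent / hit_total
            else:
                running += 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


class TestBaselineAndRanking:
    def test_cohort_mean_of_one_sample_is_itself(self):
        m = make_matrix([[3.0], [5.0]])
        np.testing.assert_allclose(pri.cohort_mean_profile(m).to_numpy(),
                                   [3.0, 5.0])

    def test_disease_baseline_is_mean_over_clds(self):
        clds = make_matrix([[2.0, 4.0]])
        assert pri.disease_baseline(clds)["g0"] == 3.0

    def test_unequal_disease_sizes_differ_from_grand_mean(self):
        # CLD means [2] (one line) and [6] (three lines at 6): baseline 4,
        # but the grand mean over the four lines is 5
        lines = make_matrix([[2.0, 6.0, 6.0, 6.0]])
        import cellrep.matrix as mx
        ann = mx.SampleAnnotation(pd.DataFrame(
            {"disease": ["a", "b", "b", "b"]}, index=lines.sample_ids))
        clds = cls.aggregate_cld(lines, ann)
        baseline = pri.disease_baseline(clds)
        assert baseline["g0"] == 4.0
        assert lines.data.loc["g0"].mean() == 5.0

    def test_fold_change_arithmetic_and_ordering(self):
        line = pd.Series({"a": 7.0, "b": 0.0, "c": 3.0})
        base = pd.Series({"a": 3.0, "b": 0.0, "c": 3.0})
        ranked = pri.ranked_fold_changes(line, base)
        assert ranked["a"] == pytest.approx(1.0)   # log2(8/4)
        assert ranked["b"] == 0.0                  # pseudocount guard
        assert list(ranked.index) == ["a", "b", "c"]  # ties broken by ID

    def test_equal_profiles_give_all_zero_stats(self):
        v = pd.Series({"a": 5.0, "b": 1.0})
        ranked = pri.ranked_fold_changes(v, v)
        np.testing.assert_allclose(ranked.to_numpy(), 0.0)


class TestCorrelationMetric:
    def test_identical_line_has_rho_one(self):
        rng = np.random.default_rng(0)
        prof = rng.uniform(0, 50, 200)
        lines = make_matrix(prof[:, None])
        rho = pri.correlation_metric(lines, pd.Series(prof, index=lines.gene_ids))
        assert rho["s0"] == pytest.approx(1.0)

    def test_monotone_transform_keeps_rho_one(self):
        rng = np.random.default_rng(1)
        prof = rng.uniform(1, 50, 150)
        lines = make_matrix(np.exp(prof / 20)[:, None])
        rho = pri.correlation_metric(lines, pd.Series(prof, index=lines.gene_ids))
        assert rho["s0"] == pytest.approx(1.0)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(2)
        lines = make_matrix(rng.uniform(0, 10, (20000, 1)))
        ref = pd.Series(rng.uniform(0, 10, 20000), index=lines.gene_ids)
        rho = pri.correlation_metric(lines, ref)
        assert abs(rho["s0"]) < 0.05

    def test_small_intersection_rejected(self):
        lines = make_matrix(np.ones((10, 1)) * 2)
        ref = pd.Series(np.ones(10), index=lines.gene_ids)
        with pytest.raises(ValueError, match="shared genes"):
            pri.correlation_metric(lines, ref, min_common_genes=100)


class TestGseaPreranked:
    def _ranked(self, n, seed=0):
        rng = np.random.default_rng(seed)
        stats = pd.Series(rng.normal(0, 1, n),
                          index=[f"g{i:04d}" for i in range(n)])
        return stats.sort_values(ascending=False)

    def test_single_top_gene_es_is_one(self):
        stats = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0],
                          index=list("abcde"))
        es, nes, p = pri.gsea_preranked(stats, {"a"})
        assert es == pytest.approx(1.0)
        assert nes > 0

    def test_es_matches_direct_oracle(self):
        params = pri.GseaParams(n_permutations=100, seed=0)
        for seed in range(5):
            stats = self._ranked(200, seed=seed)
            rng = np.random.default_rng(seed + 100)
            gene_set = set(rng.choice(stats.index, size=20, replace=False))
            es, _, _ = pri.gsea_preranked(stats, gene_set, params)
            assert es == pytest.approx(es_oracle(stats, gene_set), abs=1e-12)

    def test_nes_stable_against_independent_null(self):
        # two long permutation runs with different seeds agree within MC error
        stats = self._ranked(200, seed=3)
        top = set(stats.index[:15])
        _, nes1, _ = pri.gsea_preranked(
            stats, top, pri.GseaParams(n_permutations=10000, seed=1))
        _, nes2, _ = pri.gsea_preranked(
            stats, top, pri.GseaParams(n_permutations=10000, seed=2))
        assert nes1 == pytest.approx(nes2, rel=0.05)

    def test_reversed_ranking_flips_es_sign(self):
        stats = self._ranked(100, seed=4)
        top = set(stats.index[:10])
        es_fwd, _, _ = pri.gsea_preranked(stats, top)
        rev = (-stats)[::-1]
        es_rev, _, _ = pri.gsea_preranked(rev, top)
        assert es_fwd > 0 > es_rev

    def test_null_pvalues_approximately_uniform(self):
        stats = self._ranked(300, seed=5)
        rng = np.random.default_rng(6)
        pvals = []
        for i in range(150):
            # an independent null per draw: a shared null would correlate the
            # p-values and distort the empirical distribution
            params = pri.GseaParams(n_permutations=500, seed=1000 + i)
            gene_set = set(rng.choice(stats.index, size=15, replace=False))
            _, nes, p = pri.gsea_preranked(stats, gene_set, params)
            pvals.append(p)
        # smoothed permutation p-values are stochastically slightly larger
        # than uniform (+1/(n+1) shift, sign-conditioned pools), so the bound
        # allows mild conservatism
        ks = sps.kstest(pvals, "uniform").statistic
        assert ks < 0.15
        assert 0.40 < np.mean(pvals) < 0.62

    def test_empty_or_full_set_rejected(self):
        stats = self._ranked(50)
        with pytest.raises(ValueError):
            pri.gsea_preranked(stats, set())
        with pytest.raises(ValueError):
            pri.gsea_preranked(stats, set(stats.index))


class TestIntegrateRanks:
    def _rec(self, name, rho, nes):
        return pri.PrioritizationRecord(name, "c", rho=rho, nes=nes)

    def test_double_winner_is_first(self):
        recs = [self._rec("a", 0.9, 3.0), self._rec("b", 0.5, 1.0)]
        out = pri.integrate_ranks(recs)
        assert out[0].cell_line_id == "a" and out[0].final_rank == 1

    def test_average_rank_arithmetic(self):
        # rank pairs (1,3), (2,1), (3,2) -> averages 2.0, 1.5, 2.5
        recs = [self._rec("x", 0.9, 1.0), self._rec("y", 0.8, 3.0),
                self._rec("z", 0.7, 2.0)]
        out = pri.integrate_ranks(recs)
        assert [r.cell_line_id for r in out] == ["y", "x", "z"]
        assert [r.combined_rank for r in out] == [1.5, 2.0, 2.5]

    def test_ties_at_fifth_select_six(self):
        recs = [self._rec(f"l{i}", 1.0 - 0.1 * i, 5.0 - i) for i in range(5)]
        recs += [self._rec("l5", 1.0 - 0.45, 5.0 - 4.5),
                 self._rec("l6", 0.1, 0.0)]
        out = pri.integrate_ranks(recs, top_k=5)
        tied = [r for r in out if r.combined_rank == out[4].combined_rank]
        assert all(r.selected for r in out[:5])
        assert all(r.selected for r in tied)

    def test_rank_only_dependence(self):
        # a strictly monotone transform of the metrics leaves ranks unchanged
        recs1 = [self._rec("a", 0.9, 2.0), self._rec("b", 0.4, 3.0),
                 self._rec("c", 0.1, 1.0)]
        recs2 = [self._rec("a", np.tanh(0.9), np.exp(2.0)),
                 self._rec("b", np.tanh(0.4), np.exp(3.0)),
                 self._rec("c", np.tanh(0.1), np.exp(1.0))]
        out1 = pri.integrate_ranks(recs1)
        out2 = pri.integrate_ranks(recs2)
        assert [r.cell_line_id for r in out1] == [r.cell_line_id for r in out2]

    def test_missing_metric_rejected(self):
        rec = pri.PrioritizationRecord("a", "c", rho=0.5)
        with pytest.raises(ValueError, match="missing"):
            pri.integrate_ranks([rec])


class TestRecovery:
    def test_best_line_wins_and_metrics_agree(self, small_panel_ntpm):
        d = small_panel_ntpm
        truth, ann = d["truth"], d["ann"]
        cohort_calls = cls.classify_matrix(d["cohort_clds"])
        rank_corr_all, rank_gsea_all = [], []
        hits = 0
        for disease, cohort_id in truth.disease_cohort.items():
            lines = d["ntpm"].subset_samples(ann.groups("disease")[disease])
            members = d["cohort_ann"].groups("cohort")[cohort_id]
            cohort = d["cohort_ntpm"].subset_samples(members)
            sig = cls.elevated_set(cohort_calls, cohort_id)
            recs = pri.prioritize_cohort(
                lines, cohort, d["clds"], sig, cohort_id=cohort_id,
                params=pri.GseaParams(n_permutations=1000, seed=11),
                min_common_genes=100)
            hits += recs[0].cell_line_id == truth.cohort_best_line[cohort_id]
            rank_corr_all.extend(r.rank_corr for r in recs)
            rank_gsea_all.extend(r.rank_gsea for r in recs)
        assert hits == len(truth.disease_cohort)
        # the two metrics broadly agree on synthetic panels
        rho = sps.spearmanr(rank_corr_all, rank_gsea_all).statistic
        assert rho > 0

    def test_stage_prioritization_recovers_planted_stage(self, small_panel_ntpm):
        d = small_panel_ntpm
        truth = d["truth"]
        disease = "D00"
        cohort_id = truth.disease_cohort[disease]
        members = d["cohort_ann"].groups("cohort")[cohort_id]
        cohort = d["cohort_ntpm"].subset_samples(members)
        labels = {s: d["cohort_ann"].table.loc[s, "stage"] for s in members}
        lines = d["ntpm"].subset_samples(d["ann"].groups("disease")[disease])
        with pytest.warns(UserWarning) if False else np.errstate():
            out = pri.prioritize_stage_or_subtype(
                lines, cohort, labels, d["clds"],
                params=pri.GseaParams(n_permutations=300, seed=1),
                min_common_genes=100)
        assert set(out) == {"stage1", "stage2", "stage3"}
        # the stage carrying the planted signature ranks the best line first
        assert out["stage1"][0].cell_line_id == truth.cohort_best_line[cohort_id]

    def test_identical_stage_means_fall_back_to_correlation(self):
        rng = np.random.default_rng(1)
        prof = rng.uniform(1, 50, 300)
        cohort = make_matrix(np.tile(prof[:, None], (1, 4)),
                             samples=["t0", "t1", "t2", "t3"])
        labels = {"t0": "s1", "t1": "s1", "t2": "s2", "t3": "s2"}
        lines = make_matrix(
            np.column_stack([prof, prof[::-1]]), samples=["a", "b"])
        clds = make_matrix(np.column_stack([prof, prof * 1.1]),
                           samples=["d1", "d2"])
        out = pri.prioritize_stage_or_subtype(
            lines, cohort, labels, clds, min_common_genes=100)
        for label, recs in out.items():
            assert recs[0].cell_line_id == "a"  # correlation-only ranking
            assert np.isnan(recs[0].nes)
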