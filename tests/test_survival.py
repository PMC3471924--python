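import itertools

import numpy as np
import pytest

from ldsig import (
    SurvivalCohort,
    coa_refine,
    gen_cohort,
    km_estimate,
    logrank_test,
    median_split,
    signature_score,
)
from ldsig.survival import survival_pipeline
from ldsig import OrthologTable

from conftest import small_config


def _cohort(expr, time=None, event=None, genes=None):
    n = expr.shape[1]
    return SurvivalCohort(
        patient_ids=[f"P{i}" for i in range(n)],
        gene_ids=genes or [f"G{i}" for i in range(expr.shape[0])],
        expression=expr,
        time=np.arange(1, n + 1, dtype=float) if time is None else np.asarray(time, float),
        event=np.ones(n, bool) if event is None else np.asarray(event, bool),
    )


class TestSignatureScore:
    def test_single_gene_zscore_is_standardized(self):
        rng = np.random.default_rng(0)
        cohort = _cohort(rng.normal(5, 2, (1, 50)))
        s = signature_score(cohort, ["G0"])
        assert s.mean() == pytest.approx(0.0, abs=1e-12)
        assert s.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_all_negative_directions_negate_score(self):
        rng = np.random.default_rng(1)
        cohort = _cohort(rng.normal(size=(4, 30)))
        genes = [f"G{i}" for i in range(4)]
        s = signature_score(cohort, genes)
        s_neg = signature_score(cohort, genes, directions={g: -1 for g in genes})
        np.testing.assert_array_equal(s_neg, -s)

    def test_constant_gene_contributes_zero(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(size=(2, 20))
        expr[1] = 3.14
        cohort = _cohort(expr)
        s_both = signature_score(cohort, ["G0", "G1"])
        s_one = signature_score(cohort, ["G0"])
        np.testing.assert_allclose(s_both, s_one)

    def test_all_genes_missing_is_error(self):
        cohort = _cohort(np.zeros((1, 5)) + np.arange(5))
        with pytest.raises(ValueError):
            signature_score(cohort, ["Nope"])

    def test_zscore_invariant_under_affine_gene_transforms(self):
        rng = np.random.default_rng(3)
        expr = rng.normal(size=(5, 40))
        cohort = _cohort(expr)
        scaled = _cohort(expr * rng.uniform(0.5, 4, (5, 1)) + rng.normal(0, 10, (5, 1)))
        genes = [f"G{i}" for i in range(5)]
        np.testing.assert_allclose(
            signature_score(cohort, genes), signature_score(scaled, genes), atol=1e-9
        )


class TestMedianSplit:
    @pytest.mark.parametrize(
        "scores,cut,n_above",
        [([1, 2, 3, 4], 2.5, 2), ([1, 2, 2, 3], 2.0, 1), ([1, 2, 3], 2.0, 1)],
    )
    def test_cut_and_tie_rule(self, scores, cut, n_above):
        split = median_split(scores)
        assert split.cut == cut
        assert split.n_above == n_above

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            median_split([2.0, 2.0, 2.0])


class TestKaplanMeier:
    def test_all_events_no_ties(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert len(km.event_times) == 0
        assert km.survival_at(10.0) == 1.0

    def test_hand_computed_worked_example(self):
        # times 1, 2+, 3, 4, 5+, 6 -> S = 5/6, 5/8, 5/12, 0
        km = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        np.testing.assert_allclose(km.survival, [5 / 6, 5 / 8, 5 / 12, 0.0], atol=1e-12)
        np.testing.assert_array_equal(km.at_risk, [6, 4, 3, 1])

    def test_no_censoring_equals_empirical_survivor_function(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 40).round(2)
        km = km_estimate(t, np.ones(40))
        for et, s in zip(km.event_times, km.survival):
            assert s == pytest.approx((t > et).mean(), abs=1e-12)

    def test_matches_lifelines_with_censoring(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(6)
        t = rng.exponential(1, 60)
        e = rng.random(60) < 0.7
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = [km.survival_at(x) for x in km.event_times]
        theirs = [float(kmf.predict(x)) for x in km.event_times]
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        g = ([1, 2, 3, 4], [1, 0, 1, 1])
        res = logrank_test(g, g)
        assert res.chi_sq == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_relabeling_invariance_and_nonnegativity(self):
        rng = np.random.default_rng(7)
        g1 = (rng.exponential(1, 30), rng.random(30) < 0.8)
        g2 = (rng.exponential(2, 25), rng.random(25) < 0.8)
        r12 = logrank_test(g1, g2)
        r21 = logrank_test(g2, g1)
        assert r12.chi_sq == pytest.approx(r21.chi_sq, rel=1e-12)
        assert r12.chi_sq >= 0

    def test_zero_events_flagged(self):
        res = logrank_test(([1, 2], [0, 0]), ([3, 4], [0, 0]))
        assert res.p_value == 1.0 and res.flagged

    def test_matches_lifelines_with_ties(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(8)
        t1 = rng.integers(1, 8, 40).astype(float)  # heavy ties
        t2 = rng.integers(1, 10, 35).astype(float)
        e1 = rng.random(40) < 0.8
        e2 = rng.random(35) < 0.8
        ours = logrank_test((t1, e1), (t2, e2))
        theirs = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert ours.chi_sq == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-9)

    def test_agrees_with_exact_permutation_small_arms(self):
        time = np.array([3.0, 5.0, 7.0, 2.0, 4.0, 9.0, 1.0, 8.0, 6.0, 10.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1], bool)
        obs = logrank_test((time[:5], event[:5]), (time[5:], event[5:]))
        count = total = 0
        for idx in itertools.combinations(range(10), 5):
            sel = np.zeros(10, bool)
            sel[list(idx)] = True
            stat = logrank_test((time[sel], event[sel]), (time[~sel], event[~sel])).chi_sq
            count += stat >= obs.chi_sq - 1e-12
            total += 1
        assert abs(obs.p_value - count / total) < 0.1


class TestCOARefine:
    def test_gene_equal_to_score_is_coa_higher_in_above(self):
        rng = np.random.default_rng(9)
        expr = rng.normal(size=(3, 60))
        cohort = _cohort(expr)
        score = signature_score(cohort, ["G0", "G1", "G2"])
        cohort2 = _cohort(np.vstack([expr, score]), genes=["G0", "G1", "G2", "Gscore"])
        split = median_split(score)
        res = coa_refine(cohort2, split, ["G0", "G1", "G2", "Gscore"])
        row = res.table.set_index("gene").loc["Gscore"]
        assert row["p_value"] < 1e-6
        assert row["direction"] == "higher_in_above"
        assert "Gscore" in res.coa_genes

    def test_direction_labels_flip_with_score_sign(self):
        rng = np.random.default_rng(10)
        expr = rng.normal(size=(4, 50))
        cohort = _cohort(expr)
        genes = [f"G{i}" for i in range(4)]
        score = signature_score(cohort, genes)
        up = coa_refine(cohort, median_split(score), genes, alpha=1.0)
        down = coa_refine(cohort, median_split(-score), genes, alpha=1.0)
        flip = {"higher_in_above": "lower_in_above", "lower_in_above": "higher_in_above"}
        assert list(down.table["direction"]) == [
            flip[d] for d in up.table["direction"]
        ]

    def test_coa_cannot_exceed_gene_count(self):
        rng = np.random.default_rng(11)
        cohort = _cohort(rng.normal(size=(6, 40)))
        genes = [f"G{i}" for i in range(6)]
        res = coa_refine(cohort, median_split(signature_score(cohort, genes)), genes)
        assert len(res.coa_genes) <= 6

    def test_strong_latent_factor_makes_every_gene_coa(self):
        cfg = small_config(seed=21, cohort_loading=3.0, n_cohort_genes=30)
        sig = [f"S{i}" for i in range(20)]
        cohort, _ = gen_cohort(cfg, sig)
        score = signature_score(cohort, sig)
        res = coa_refine(cohort, median_split(score), sig)
        assert set(res.coa_genes) == set(sig)

    def test_small_group_rejected(self):
        cohort = _cohort(np.arange(3.0)[None, :] + np.zeros((2, 3)))
        split = median_split(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            coa_refine(cohort, split, ["G0"])


class TestSurvivalPipeline:
    def test_planted_risk_lowers_above_median_survival(self):
        cfg = small_config(seed=31)
        sig_mouse = [f"Siggene{i}" for i in range(30)]
        table = OrthologTable(pairs={g: [g.upper()] for g in sig_mouse})
        cohort, _ = gen_cohort(cfg, [g.upper() for g in sig_mouse])
        rep = survival_pipeline(cohort, sig_mouse, table)
        t_last = min(rep["km_above"].event_times[-1], rep["km_below"].event_times[-1])
        assert rep["km_above"].survival_at(t_last) < rep["km_below"].survival_at(t_last)
        assert rep["logrank"].p_value < 0.01

    def test_directed_negation_identity(self):
        # a subset scored with -1 signs reproduces the negated undirected score
        rng = np.random.default_rng(12)
        cohort = _cohort(rng.normal(size=(5, 30)))
        genes = [f"G{i}" for i in range(3)]
        undirected = signature_score(cohort, genes)
        directed = signature_score(cohort, genes, directions={g: -1 for g in genes})
        np.testing.assert_allclose(directed, -undirected, atol=1e-12)
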