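import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ldsig import (
    classify_dose_response,
    contrast,
    gene_list,
    magnitude_comparison,
    welch_t,
)
from ldsig.de import FC_CUT, classify_calls


class TestWelchT:
    def test_identical_samples(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([3.0, 4.0, 5.0, 6.0])
        # Welch-Satterthwaite, computed from the defining formulas
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_ref = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_ref = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
        t, df, p = welch_t(x, y)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == pytest.approx(df_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_agrees_with_exact_permutation_when_variances_equal(self):
        x = [4.1, 5.2, 3.9, 4.8]
        y = [5.9, 6.4, 5.1, 6.6]
        pooled = sorted(x + y)
        t_obs, _, p_t = welch_t(x, y)
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            xs = [pooled[i] for i in idx]
            ys = [pooled[i] for i in range(8) if i not in idx]
            t_perm, _, _ = welch_t(xs, ys)
            count += abs(t_perm) >= abs(t_obs) - 1e-12
            total += 1
        assert abs(p_t - count / total) < 0.1

    def test_fewer_than_two_observations_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_zero_variance_conventions(self):
        t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_t([3.0, 3.0], [2.0, 2.0])
        assert p == 0.0 and t == math.inf


class TestContrast:
    def test_identical_groups_have_zero_fold_change(self, small_study):
        study, _ = small_study
        mask = study.select(tissue="blood", strain="sensitive", dose="sham", time="early")
        cols = np.flatnonzero(mask)
        a = np.zeros(study.n_samples, bool)
        b = np.zeros(study.n_samples, bool)
        a[cols[:2]] = True
        b[cols[2:4]] = True
        import ldsig

        study2 = ldsig.ExpressionStudy(
            gene_ids=study.gene_ids,
            values=np.concatenate([study.values[:, a], study.values[:, a]], axis=1),
            sample_meta=pd.concat(
                [study.sample_meta[a], study.sample_meta[a].set_axis(["c1", "c2"])]
            ),
        )
        c = contrast(study2, [True, True, False, False], [False, False, True, True])
        assert np.allclose(c["log2_fc"], 0.0)

    def test_group_swap_antisymmetry(self, small_study):
        study, _ = small_study
        ga = {"tissue": "mammary", "strain": "sensitive", "dose": "sham"}
        gb = {"tissue": "mammary", "strain": "resistant", "dose": "sham"}
        ab = contrast(study, ga, gb)
        ba = contrast(study, gb, ga)
        np.testing.assert_array_equal(ab["log2_fc"].to_numpy(), -ba["log2_fc"].to_numpy())
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], rtol=1e-12)

    def test_gene_count_preserved(self, small_study):
        study, _ = small_study
        c = contrast(
            study,
            {"strain": "sensitive", "dose": "sham"},
            {"strain": "resistant", "dose": "sham"},
        )
        assert len(c) == study.n_genes

    def test_planted_baseline_genes_recovered(self, small_study):
        study, truth = small_study
        c = contrast(
            study,
            {"tissue": "mammary", "strain": "sensitive", "dose": "sham"},
            {"tissue": "mammary", "strain": "resistant", "dose": "sham"},
        )
        planted = c[c["gene"].isin(truth.baseline_signature)]
        hit = (planted["p_value"] <= 0.05) & (planted["log2_fc"].abs() >= FC_CUT)
        assert hit.mean() >= 0.9

    def test_overlapping_and_empty_selections_rejected(self, small_study):
        study, _ = small_study
        with pytest.raises(ValueError, match="overlap"):
            contrast(study, {"dose": "sham"}, {"strain": "sensitive"})
        with pytest.raises(ValueError, match="empty"):
            contrast(study, {"dose": "sham"}, {"dose": "no-such"})


def _fake_contrasts(rows):
    return pd.DataFrame(rows, columns=["gene", "log2_fc", "t_stat", "p_value"]).assign(
        direction=lambda d: np.sign(d["log2_fc"]).astype(int)
    )


class TestGeneList:
    table = _fake_contrasts(
        [
            ("Up1", 0.60, 2.0, 0.05),
            ("Down1", -0.70, -3.0, 0.005),
            ("WeakFc", 0.50, 4.0, 0.001),
            ("WeakP", 1.20, 1.0, 0.50),
        ]
    )

    def test_ld_criteria(self):
        gl = gene_list(self.table, "LD")
        assert "Up1" in gl.up  # 0.60 >= log2 1.5 ~ 0.585, p 0.05 <= 0.1
        assert gl.down == ["Down1"]
        assert "WeakFc" not in gl.all and "WeakP" not in gl.all

    def test_hd_criteria_excludes_p_between_cutoffs(self):
        gl = gene_list(self.table, "HD")
        assert "Up1" not in gl.all  # p = 0.05 > 0.01
        assert "Down1" in gl.down

    def test_unknown_dose_class(self):
        with pytest.raises(ValueError):
            gene_list(self.table, "XL")

    @given(
        p_loose=st.floats(0.01, 0.2),
        fc_tight=st.floats(0.585, 1.5),
        seed=st.integers(0, 50),
    )
    def test_monotone_in_both_thresholds(self, p_loose, fc_tight, seed):
        rng = np.random.default_rng(seed)
        table = _fake_contrasts(
            [
                (f"G{i}", fc, 0.0, p)
                for i, (fc, p) in enumerate(
                    zip(rng.normal(0, 1, 60), rng.uniform(0, 1, 60))
                )
            ]
        )
        tight = set(gene_list(table, "LD", p_cutoff=0.01, fc_cutoff=fc_tight).all)
        loose = set(gene_list(table, "LD", p_cutoff=p_loose, fc_cutoff=0.585).all)
        assert tight <= loose


class TestDoseResponseClassification:
    def test_thresholded_pattern_from_printed_row(self):
        # sensitive LD -1.23 / HD -1.84 both significant; resistant LD ns, HD -1.25
        fc = {"ld_sensitive": -1.23, "hd_sensitive": -1.84,
              "ld_resistant": 0.0, "hd_resistant": -1.25}
        sig = {"ld_sensitive": True, "hd_sensitive": True,
               "ld_resistant": False, "hd_resistant": True}
        assert classify_calls(fc, sig) == "thresholded"

    def test_opposite_pattern(self):
        fc = {"ld_sensitive": 0.9, "hd_sensitive": -1.1,
              "ld_resistant": 0.0, "hd_resistant": 0.0}
        sig = {"ld_sensitive": True, "hd_sensitive": True,
               "ld_resistant": False, "hd_resistant": False}
        assert classify_calls(fc, sig) == "opposite"

    def test_plateau_pattern(self):
        fc = {"ld_sensitive": 0.70, "hd_sensitive": 0.72,
              "ld_resistant": 0.0, "hd_resistant": 0.0}
        sig = {"ld_sensitive": True, "hd_sensitive": True,
               "ld_resistant": False, "hd_resistant": False}
        assert classify_calls(fc, sig) == "plateau"

    def test_classes_rederivable_from_stored_flags(self, small_study):
        study, _ = small_study
        conds = {}
        for key, strain, dose in (
            ("ld_sensitive", "sensitive", "LD"),
            ("hd_sensitive", "sensitive", "HD"),
            ("ld_resistant", "resistant", "LD"),
            ("hd_resistant", "resistant", "HD"),
        ):
            conds[key] = contrast(
                study,
                {"tissue": "mammary", "strain": strain, "dose": dose, "time": "early"},
                {"tissue": "mammary", "strain": strain, "dose": "sham", "time": "early"},
            )
        out = classify_dose_response(conds)
        for row in out.sample(n=100, random_state=0).to_dict("records"):
            rederived = classify_calls(
                {c: row[f"fc_{c}"] for c in conds},
                {c: bool(row[f"sig_{c}"]) for c in conds},
            )
            assert rederived == row["dose_class"]

    def test_planted_patterns_dominate_their_classes(self, small_study):
        study, truth = small_study
        conds = {
            key: contrast(
                study,
                {"tissue": "mammary", "strain": strain, "dose": dose, "time": "early"},
                {"tissue": "mammary", "strain": strain, "dose": "sham", "time": "early"},
            )
            for key, strain, dose in (
                ("ld_sensitive", "sensitive", "LD"),
                ("hd_sensitive", "sensitive", "HD"),
                ("ld_resistant", "resistant", "LD"),
                ("hd_resistant", "resistant", "HD"),
            )
        }
        out = classify_dose_response(conds).set_index("gene")
        thr = out.loc[list(truth.thresholded_genes), "dose_class"]
        assert (thr == "thresholded").mean() >= 0.7
        opp = out.loc[list(truth.opposite_genes), "dose_class"]
        assert (opp == "opposite").mean() >= 0.7

    def test_missing_condition_rejected(self, small_study):
        with pytest.raises(ValueError, match="missing"):
            classify_dose_response({"ld_sensitive": None})


class TestMagnitudeComparison:
    def test_identical_vectors(self):
        assert magnitude_comparison([0.5, -1.0, 2.0], [0.5, -1.0, 2.0]) == 1.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        b = rng.normal(1.0, 0.1, 28)
        a = b + 0.5
        assert magnitude_comparison(a, b) < 1e-6

    def test_agrees_with_sign_flip_permutation(self):
        rng = np.random.default_rng(4)
        a = np.abs(rng.normal(1.2, 0.3, 8))
        b = np.abs(rng.normal(1.0, 0.3, 8))
        p = magnitude_comparison(a, b, paired=True)
        d = np.abs(a) - np.abs(b)
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        count = 0
        for signs in itertools.product([1, -1], repeat=8):
            ds = d * np.array(signs)
            t = ds.mean() / (ds.std(ddof=1) / np.sqrt(len(ds)))
            count += abs(t) >= abs(t_obs) - 1e-12
        assert abs(p - count / 256) < 0.1

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            magnitude_comparison([1.0, 2.0], [1.0], paired=True)
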