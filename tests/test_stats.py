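"""Behavioral statistics: within-subject ANOVA, Tukey HSD, BIC Bayes
factor, regression adjustment, ICC and its permutation test, max-|Z|
outliers, correlations, and the familiarity covariate model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from multicue.stats import (
    bic_bayes_factor,
    compare_outlier_scores,
    familiarity_covariate_analysis,
    icc_oneway,
    icc_with_permutation,
    max_abs_z,
    regress_out_presleep,
    repetition_benefit_correlation,
    rm_anova,
    subsample_robustness,
    tukey_hsd,
)


def two_way_within_frame(rng, n_subj=6, effect_a=0.0, effect_b=0.0, noise=1.0):
    rows = []
    for s in range(n_subj):
        base = rng.normal()
        for ai, a in enumerate(("c", "n")):
            for bi, b in enumerate((1, 2, 6)):
                rows.append(
                    {
                        "subject": f"s{s}",
                        "A": a,
                        "B": b,
                        "y": base + effect_a * ai + effect_b * bi + rng.normal(scale=noise),
                    }
                )
    return pd.DataFrame(rows)


def ss_oracle_two_way(df):
    """Literal sums-of-squares oracle: explicit loops over the textbook
    partitioning of a two-factor fully-within design."""
    subjects = sorted(df["subject"].unique())
    A = sorted(df["A"].unique())
    B = sorted(df["B"].unique())
    y = {
        (r.subject, r.A, r.B): r.y for r in df.itertuples()
    }
    gm = np.mean(list(y.values()))
    def m_s(s): return np.mean([y[(s, a, b)] for a in A for b in B])
    def m_a(a): return np.mean([y[(s, a, b)] for s in subjects for b in B])
    def m_b(b): return np.mean([y[(s, a, b)] for s in subjects for a in A])
    def m_sa(s, a): return np.mean([y[(s, a, b)] for b in B])
    def m_sb(s, b): return np.mean([y[(s, a, b)] for a in A])
    def m_ab(a, b): return np.mean([y[(s, a, b)] for s in subjects])
    nS, nA, nB = len(subjects), len(A), len(B)
    ss_a = nS * nB * sum((m_a(a) - gm) ** 2 for a in A)
    ss_as = nB * sum((m_sa(s, a) - m_s(s) - m_a(a) + gm) ** 2 for s in subjects for a in A)
    ss_b = nS * nA * sum((m_b(b) - gm) ** 2 for b in B)
    ss_bs = nA * sum((m_sb(s, b) - m_s(s) - m_b(b) + gm) ** 2 for s in subjects for b in B)
    ss_ab = nS * sum((m_ab(a, b) - m_a(a) - m_b(b) + gm) ** 2 for a in A for b in B)
    ss_abs = sum(
        (
            y[(s, a, b)]
            - m_sa(s, a)
            - m_sb(s, b)
            - m_ab(a, b)
            + m_s(s)
            + m_a(a)
            + m_b(b)
            - gm
        )
        ** 2
        for s in subjects
        for a in A
        for b in B
    )
    out = {}
    for name, ss, df1, ss_e, df2 in [
        ("A", ss_a, nA - 1, ss_as, (nA - 1) * (nS - 1)),
        ("B", ss_b, nB - 1, ss_bs, (nB - 1) * (nS - 1)),
        ("A:B", ss_ab, (nA - 1) * (nB - 1), ss_abs, (nA - 1) * (nB - 1) * (nS - 1)),
    ]:
        F = (ss / df1) / (ss_e / df2)
        out[name] = (F, df1, df2, sps.f.sf(F, df1, df2), ss / (ss + ss_e))
    return out


class TestRmAnova:
    def test_all_equal_cells_give_zero_f(self):
        df = two_way_within_frame(np.random.default_rng(0), noise=0.0)
        df["y"] = 1.0
        res = rm_anova(df, "y", ["A", "B"], "subject")
        assert all(e.F == 0.0 and e.p == 1.0 for e in res.effects.values())

    def test_matches_sums_of_squares_oracle(self, rng):
        df = two_way_within_frame(rng, effect_a=0.7, effect_b=0.2)
        res = rm_anova(df, "y", ["A", "B"], "subject")
        oracle = ss_oracle_two_way(df)
        for name in ("A", "B", "A:B"):
            F, df1, df2, p, pes = oracle[name]
            e = res[name]
            assert e.F == pytest.approx(F)
            assert (e.df1, e.df2) == (df1, df2)
            assert e.p == pytest.approx(p)
            assert e.partial_eta_sq == pytest.approx(pes)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = two_way_within_frame(rng, effect_a=0.5, effect_b=0.1)
        res = rm_anova(df, "y", ["A", "B"], "subject")
        tab = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subject", effsize="np2")
        tab = tab.set_index("Source")
        for mine, theirs in [("A", "A"), ("B", "B"), ("A:B", "A * B")]:
            assert res[mine].F == pytest.approx(tab.loc[theirs, "F"])
            assert res[mine].p == pytest.approx(tab.loc[theirs, "p_unc"])
            assert res[mine].partial_eta_sq == pytest.approx(tab.loc[theirs, "np2"])

    def test_subject_constant_shifts_are_absorbed(self, rng):
        df = two_way_within_frame(rng, noise=0.0)  # y = subject base only
        res = rm_anova(df, "y", ["A", "B"], "subject")
        assert res["A"].F == pytest.approx(0.0, abs=1e-18)

    def test_missing_cell_rejected(self, rng):
        df = two_way_within_frame(rng).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(df, "y", ["A", "B"], "subject")

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(300):
            df = two_way_within_frame(rng, n_subj=8)
            ps.append(rm_anova(df, "y", ["A", "B"], "subject")["A"].p)
        assert sps.kstest(ps, "uniform").pvalue > 1e-3


class TestTukeyHsd:
    def test_identical_means_give_p_one(self):
        out = tukey_hsd(pd.Series([5.0, 5.0, 5.0]), 10, 2.0, 27)
        assert (out["p"] == 1.0).all()
        assert (out["q"] == 0.0).all()

    def test_q_matches_direct_formula(self):
        means = pd.Series([1.0, 3.0, 6.0], index=list("abc"))
        out = tukey_hsd(means, n_per_level=8, ms_error=4.0, df_error=14)
        se = np.sqrt(4.0 / 8)
        want = {(a, b): abs(means[a] - means[b]) / se for a, b in [("a", "b"), ("a", "c"), ("b", "c")]}
        for row in out.itertuples():
            assert row.q == pytest.approx(want[(row.level_a, row.level_b)])
            assert row.p == pytest.approx(
                sps.studentized_range.sf(row.q, 3, 14), abs=1e-10
            )

    def test_larger_gap_never_larger_p(self):
        a = tukey_hsd(pd.Series([0.0, 1.0]), 5, 1.0, 8)["p"][0]
        b = tukey_hsd(pd.Series([0.0, 3.0]), 5, 1.0, 8)["p"][0]
        assert b <= a

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd(pd.Series([1.0, 2.0]), 5, 1.0, 0)


class TestBicBayesFactor:
    def test_equal_bics_give_unity(self):
        assert bic_bayes_factor(10.0, 10.0) == 1.0

    def test_two_point_difference_gives_e(self):
        assert bic_bayes_factor(10.0, 12.0) == pytest.approx(np.e)

    def test_reciprocal_identity(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=2) * 50
            assert bic_bayes_factor(a, b) * bic_bayes_factor(b, a) == pytest.approx(1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bic_bayes_factor(np.inf, 1.0)


class TestRegressOutPresleep:
    def test_zero_slope_returns_raw(self, rng):
        pre = rng.uniform(10, 100, 30)
        fg = np.full(30, 4.0)  # no relation, no variance in forgetting
        assert np.allclose(regress_out_presleep(pre, fg), fg)

    def test_perfect_line_collapses_to_mean(self):
        pre = np.linspace(10, 100, 20)
        fg = 2.0 * pre
        adj = regress_out_presleep(pre, fg)
        assert np.allclose(adj, fg.mean())

    def test_matches_normal_equations_oracle(self, rng):
        pre = rng.uniform(0, 200, 50)
        fg = 0.3 * pre + rng.normal(scale=5, size=50)
        X = np.column_stack([np.ones(50), pre])
        beta = np.linalg.solve(X.T @ X, X.T @ fg)
        expected = fg - X @ beta + fg.mean()
        assert np.allclose(regress_out_presleep(pre, fg), expected)

    def test_zero_variance_pre_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = regress_out_presleep(np.full(5, 3.0), np.arange(5.0))
        assert np.allclose(out, np.arange(5.0))


class TestIcc:
    def test_perfect_within_set_agreement(self):
        groups = [np.full(6, v) for v in (1.0, 5.0, 9.0)]
        assert icc_oneway(groups) == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_oneway([np.full(6, 2.0), np.full(6, 2.0)])

    def test_permutation_p_never_zero_and_diff_zero_for_identical(self, rng):
        sets = []
        for flag in (True, False):
            for g in range(4):
                v = np.full(6, float(g)) + (0.0 if flag else 0.1)
                sets.append(
                    pd.DataFrame(
                        {"set_id": f"{flag}{g}", "cued": flag, "benefit": v + rng.normal(0, 1e-6, 6)}
                    )
                )
        df = pd.concat(sets)
        res = icc_with_permutation(df, n_perm=500, rng_seed=0)
        assert res.p_perm > 0.0
        assert abs(res.diff) < 0.01

    def test_needs_two_sets_per_condition(self):
        df = pd.DataFrame({"set_id": ["a"] * 6, "cued": True, "benefit": np.arange(6.0)})
        with pytest.raises(ValueError):
            icc_with_permutation(df, n_perm=10, rng_seed=0)


class TestMaxAbsZ:
    def test_hand_computed_example(self):
        assert max_abs_z([1, 1, 1, 1, 1, 7]) == pytest.approx(5 / np.sqrt(6))

    def test_degenerate_set_scores_zero(self):
        with pytest.warns(UserWarning, match="zero within-set SD"):
            assert max_abs_z([2.0] * 6) == 0.0

    def test_affine_invariance(self, rng):
        v = rng.normal(size=6)
        assert max_abs_z(v) == pytest.approx(max_abs_z(3.0 * v + 11.0))

    def test_requires_six_values(self):
        with pytest.raises(ValueError):
            max_abs_z([1.0, 2.0])

    def test_condition_comparison_runs(self, rng):
        t, df, p, d = compare_outlier_scores(rng.normal(2, 1, 40), rng.normal(2, 1, 40))
        assert df == 78 and 0 <= p <= 1


class TestCorrelations:
    def test_perfect_line(self):
        r, p = repetition_benefit_correlation(2 * np.arange(5.0) + 1, np.arange(5.0))
        assert r == pytest.approx(1.0)

    def test_matches_closed_form(self):
        x = np.array([1.0, 3.0, 4.0, 8.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        r, _ = repetition_benefit_correlation(y, x)
        want = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(want)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            repetition_benefit_correlation(np.ones(5), np.arange(5.0))

    def test_transform_variant(self):
        from multicue.behavior import reactivation_probability

        reps = np.array([2.0, 5.0, 8.0, 11.0, 20.0])
        benefit = np.array([1.0, 2.0, 2.5, 3.0, 3.2])
        r, _ = repetition_benefit_correlation(
            benefit, reps, transform=lambda n: reactivation_probability(6, int(n))
        )
        assert r > 0.9


class TestFamiliarityCovariate:
    def _frame(self, rng, confound=False):
        rows = []
        for s in range(10):
            for cued in (True, False):
                for k in (1, 2, 6):
                    fam = rng.normal(10 * k, 2)
                    benefit = (
                        0.5 * fam + rng.normal() if confound
                        else (3.0 if cued else 0.0) + rng.normal()
                    )
                    rows.append(
                        {"cued": cued, "size_k": k, "familiarity": fam, "benefit": benefit}
                    )
        return pd.DataFrame(rows)

    def test_orthogonal_covariate_leaves_cuing_effect(self, rng):
        df = self._frame(rng)
        with_cov = familiarity_covariate_analysis(df)
        assert with_cov["p_cued"] < 0.01

    def test_familiarity_driven_benefit_shows_no_cuing_effect(self, rng):
        df = self._frame(rng, confound=True)
        res = familiarity_covariate_analysis(df)
        assert res["p_cued"] > 0.05

    def test_coefficients_match_normal_equations(self, rng):
        df = self._frame(rng)
        res = familiarity_covariate_analysis(df)
        X = np.column_stack(
            [
                np.ones(len(df)),
                df["cued"].astype(float),
                (df["size_k"] == 2).astype(float),
                (df["size_k"] == 6).astype(float),
                df["cued"].astype(float) * (df["size_k"] == 2),
                df["cued"].astype(float) * (df["size_k"] == 6),
                df["familiarity"],
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ df["benefit"].to_numpy())
        assert res["params"]["familiarity"] == pytest.approx(beta[-1])
        assert res["params"]["C(cued)[T.True]"] == pytest.approx(beta[1])

    def test_constant_familiarity_dropped_with_warning(self, rng):
        df = self._frame(rng)
        df["familiarity"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            res = familiarity_covariate_analysis(df)
        assert np.isnan(res["p_familiarity"])


class TestSubsampleRobustness:
    def _scored(self, rng, n_subj=8, delta=0.0):
        rows = []
        for s in range(n_subj):
            for k, n_items in ((1, 18), (2, 36), (6, 36)):
                cued = np.arange(n_items) % 2 == 0
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": f"p{s}",
                            "size_k": k,
                            "cued": cued,
                            "err_pre": rng.normal(60, 10, n_items),
                            "benefit": delta * cued + rng.normal(0, 8, n_items),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def test_strong_cuing_always_detected_in_kept_datasets(self, rng):
        rep = subsample_robustness(self._scored(rng, delta=15.0), n_datasets=25, rng_seed=0)
        assert rep.n_kept == 25
        assert rep.all_cued_above_noncued
        assert rep.pct_cuing_significant > 90.0

    def test_symmetric_p_distribution_has_small_skew(self, rng):
        rep = subsample_robustness(self._scored(rng, delta=0.0), n_datasets=40, rng_seed=1)
        assert abs(rep.skew_p_interaction) < 1.5  # near-uniform p's: mild skew

    def test_hopeless_screen_aborts(self, rng):
        scored = self._scored(rng)
        # make pre-sleep error strongly size-dependent so the screen never passes
        scored["err_pre"] += 40.0 * scored["size_k"]
        with pytest.raises(RuntimeError, match="acceptance rate"):
            subsample_robustness(scored, n_datasets=10, rng_seed=0, max_attempts=300)
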