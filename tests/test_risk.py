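"""Risk statistics: t-tests, logistic odds ratios, cutpoint search,
model selection — each against an independent oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nucmorph as nm
from nucmorph.risk import SeparationError

from conftest import cohort_from_2x2


class TestTTest:
    def test_fixture_group_means(self, table1):
        r = nm.two_group_ttest(table1, "mean_nuclear_area")
        assert r.group_stats["negative"][0] == pytest.approx(73.2, abs=0.3)
        assert r.group_stats["positive"][0] == pytest.approx(97.6, abs=0.3)
        assert r.p < 0.001 and r.significant

    def test_identical_groups_give_t0_p1(self):
        cohort = cohort_from_2x2(5, 5, 5, 5)  # same areas in both groups
        r = nm.two_group_ttest(cohort, "mean_nuclear_area")
        assert r.t == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_zero_variance_is_an_error(self):
        cohort = cohort_from_2x2(10, 0, 0, 10)
        with pytest.raises(ValueError, match="variance"):
            nm.two_group_ttest(cohort, "nacv")  # nacv constant everywhere

    def test_welch_variant_differs_under_unequal_variance(self, table1):
        pooled = nm.two_group_ttest(table1, "mean_nuclear_area", equal_var=True)
        welch = nm.two_group_ttest(table1, "mean_nuclear_area", equal_var=False)
        assert pooled.df == pytest.approx(86.0)
        assert welch.df < pooled.df  # Welch-Satterthwaite shrinks df here

    def test_type_i_error_calibration(self):
        """Pooled t on 1000 null two-group draws rejects at 0.05 within
        [0.03, 0.07]."""
        rng = np.random.default_rng(101)
        a = rng.normal(73.2, 19.6, (1000, 42))
        b = rng.normal(73.2, 19.6, (1000, 46))
        p = stats.ttest_ind(a, b, axis=1).pvalue
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.07


class TestUnivariateLogistic:
    def test_continuous_fixture_rows(self, table1):
        area = nm.univariate_logistic(table1, "mean_nuclear_area")
        assert round(area.odds_ratio, 2) == 1.04
        assert round(area.ci_low, 2) == 1.02 and round(area.ci_high, 2) == 1.07
        age = nm.univariate_logistic(table1, "age")
        assert round(age.odds_ratio, 2) == 0.97

    def test_against_sklearn_oracle(self, table1):
        """Unpenalized sklearn LogisticRegression reproduces the statsmodels
        ML coefficient (independent optimizer, same likelihood)."""
        from sklearn.linear_model import LogisticRegression

        x = np.array([r.mean_nuclear_area for r in table1]).reshape(-1, 1)
        y = np.array([r.pn_status for r in table1])
        ref = LogisticRegression(C=np.inf, max_iter=5000, tol=1e-10).fit(x, y)
        ours = nm.univariate_logistic(table1, "mean_nuclear_area")
        assert ours.odds_ratio == pytest.approx(float(np.exp(ref.coef_[0, 0])), rel=1e-5)

    def test_categorical_levels_and_overall_test(self, table1):
        rows = nm.univariate_logistic(table1, "site")
        by_level = {r.level: r for r in rows}
        assert by_level["lower_gingiva"].reference_level == "tongue"
        assert round(by_level["lower_gingiva"].odds_ratio, 2) == 2.20
        assert round(by_level["upper_gingiva"].odds_ratio, 2) == 0.50
        assert rows[0].overall_p > 0.1  # site not associated with pN status

    def test_scaling_transforms_or_as_power(self, table1):
        """Rescaling the increment by k raises the OR to the k-th power."""
        per1 = nm.univariate_logistic(table1, "mean_nuclear_area", scaling=1.0)
        per10 = nm.univariate_logistic(table1, "mean_nuclear_area", scaling=10.0)
        assert per10.odds_ratio == pytest.approx(per1.odds_ratio**10, rel=1e-9)

    def test_record_order_invariance(self, table1):
        shuffled = nm.Cohort(list(table1.records[::-1]), provenance="reversed")
        a = nm.univariate_logistic(table1, "nacv")
        b = nm.univariate_logistic(shuffled, "nacv")
        assert a.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-10)

    def test_permuted_outcome_ci_covers_one(self, table1):
        rng = np.random.default_rng(77)
        perm = rng.permutation([r.pn_status for r in table1])
        frame = table1.to_frame()
        records = []
        for rec, new_status in zip(table1.records, perm):
            from dataclasses import replace

            records.append(
                replace(
                    rec,
                    pn_status=int(new_status),
                    pn_class="1" if new_status else "0",
                    n_positive_nodes=int(new_status),
                    node_levels=("II",) if new_status else (),
                )
            )
        permuted = nm.Cohort(records, "permuted")
        r = nm.univariate_logistic(permuted, "mean_nuclear_area")
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_separation_is_diagnosed_not_silent(self):
        cohort = cohort_from_2x2(20, 0, 0, 20)
        with pytest.raises(SeparationError):
            nm.univariate_logistic(cohort, "mean_nuclear_area")


class TestDichotomizedOR:
    def test_fixture_area_cutoff(self, table1):
        counts, r = nm.dichotomized_or(table1, "mean_nuclear_area", 80.3)
        assert counts.tolist() == [[33, 9], [15, 31]]
        assert r.odds_ratio == pytest.approx(31 * 33 / (15 * 9), abs=1e-6)
        assert round(r.odds_ratio, 2) == 7.58

    def test_fixture_perimeter_cutoff(self, table1):
        counts, r = nm.dichotomized_or(table1, "mean_perimeter", 32.7)
        assert counts.tolist() == [[26, 16], [8, 38]]
        assert round(r.odds_ratio, 2) == 7.72

    def test_balanced_table_gives_or_exactly_one(self):
        _, r = nm.dichotomized_or(cohort_from_2x2(7, 7, 9, 9), "mean_nuclear_area", 100.0)
        assert r.odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_logistic_equals_cross_product_on_random_tables(self):
        """On 100 random zero-cell-free 2x2 tables the logistic-fit OR equals
        the closed-form cross-product ratio to 1e-6 and the Wald CI equals
        exp(log OR ± 1.96*sqrt(1/a+1/b+1/c+1/d))."""
        rng = np.random.default_rng(404)
        checked = 0
        while checked < 100:
            a, b, c, d = rng.integers(2, 40, size=4)
            counts, r = nm.dichotomized_or(
                cohort_from_2x2(int(a), int(b), int(c), int(d)),
                "mean_nuclear_area", 100.0,
            )
            cross = d * a / (b * c)
            assert abs(r.odds_ratio - cross) < 1e-6
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert r.ci_low == pytest.approx(cross * np.exp(-1.96 * se), rel=1e-4)
            assert r.ci_high == pytest.approx(cross * np.exp(1.96 * se), rel=1e-4)
            checked += 1

    def test_zero_cell_reported_with_haldane_flag(self):
        counts, r = nm.dichotomized_or(
            cohort_from_2x2(20, 0, 10, 10), "mean_nuclear_area", 100.0
        )
        assert r.corrected
        expected = (10.5 * 20.5) / (0.5 * 10.5)
        assert r.odds_ratio == pytest.approx(expected, rel=1e-9)

    def test_cutoff_outside_range_rejected(self, table1):
        with pytest.raises(ValueError, match="outside"):
            nm.dichotomized_or(table1, "mean_nuclear_area", 500.0)


class TestMinPCutoff:
    def test_fixture_area_reproduces_published_partition(self, table1):
        """The scan selects the midpoint between 80.3 and 82.5 — the same
        dichotomy as the published 'area > 80.3' (80.3 is an observed value
        and lands in the lower arm) — and its 2x2 matches the published
        counts."""
        res = nm.minp_cutoff_search(table1, "mean_nuclear_area")
        assert 80.3 <= res.cutoff < 82.5
        assert res.counts.tolist() == [[33, 9], [15, 31]]
        assert res.direction == "greater"
        assert "optimism" in res.note

    def test_fixture_perimeter_reproduces_published_partition(self, table1):
        res = nm.minp_cutoff_search(table1, "mean_perimeter")
        assert 32.7 <= res.cutoff < 32.9
        assert res.counts.tolist() == [[26, 16], [8, 38]]

    def test_matches_exhaustive_scan_oracle(self, table1):
        """Brute-force re-scan of every midpoint with scipy directly."""
        x = np.array([r.mean_nuclear_area for r in table1])
        y = np.array([r.pn_status for r in table1])
        distinct = np.unique(x)
        best = (np.inf, None)
        for cut in (distinct[:-1] + distinct[1:]) / 2:
            ind = x > cut
            if min(ind.sum(), (~ind).sum()) < 5:
                continue
            tab = [[np.sum((y == g) & (ind == i)) for i in (0, 1)] for g in (0, 1)]
            p = stats.chi2_contingency(tab, correction=False).pvalue
            if p < best[0]:
                best = (p, cut)
        res = nm.minp_cutoff_search(table1, "mean_nuclear_area")
        assert res.cutoff == pytest.approx(best[1])
        assert res.min_p == pytest.approx(best[0])

    def test_profile_is_exposed(self, table1):
        res = nm.minp_cutoff_search(table1, "mean_nuclear_area")
        assert {"cutoff", "p"} <= set(res.profile.columns)
        assert (res.profile.p >= res.min_p).all()

    def test_perfectly_separating_factor(self):
        cohort = cohort_from_2x2(15, 0, 0, 15)
        res = nm.minp_cutoff_search(cohort, "mean_nuclear_area")
        assert res.counts.tolist() == [[15, 0], [0, 15]]
        assert res.min_p < 1e-6

    def test_fisher_variant(self, table1):
        res = nm.minp_cutoff_search(table1, "mean_nuclear_area", test="fisher")
        assert 80.3 <= res.cutoff < 82.5

    def test_degenerate_inputs_rejected(self):
        cohort = cohort_from_2x2(10, 0, 10, 0)  # single distinct value
        with pytest.raises(ValueError, match="distinct"):
            nm.minp_cutoff_search(cohort, "mean_nuclear_area")

    def test_binarizer_transform(self, table1):
        binar = nm.MinPCutpointBinarizer()
        x = np.array([r.mean_nuclear_area for r in table1])
        y = np.array([r.pn_status for r in table1])
        out = binar.fit(x, y).transform(x)
        assert out.shape == (88, 1)
        assert out.sum() == 40  # 9 + 31 cases above the cutoff


class TestModelSelection:
    def test_screen_keeps_published_candidates(self, table1):
        sel = nm.RiskModelSelector(candidates=nm.risk.DEFAULT_CANDIDATES)
        sel.fit(table1.to_frame(), [r.pn_status for r in table1])
        assert set(sel.screened_) == {
            "age", "mean_nuclear_area", "mean_perimeter", "circular_rate", "nacv",
        }

    def test_two_families_and_anchors_never_coincluded(self, table1):
        models = nm.select_risk_models(table1)
        assert [m.name for m in models] == ["Model 1", "Model 2"]
        for m in models:
            assert not {"mean_nuclear_area", "mean_perimeter"} <= set(m.factors)
        assert "mean_nuclear_area" in models[0].factors
        assert "mean_perimeter" in models[1].factors

    def test_model2_reproduces_published_terms(self, table1):
        m2 = nm.select_risk_models(table1)[1]
        assert set(m2.factors) == {"age", "mean_perimeter"}
        t = m2.term("mean_perimeter")
        assert round(t.odds_ratio, 2) == 1.23
        assert round(t.ci_low, 2) == 1.11 and round(t.ci_high, 2) == 1.36

    def test_model1_adjusted_area_or(self, table1):
        """The AIC-selected area model keeps the adjusted area OR at the
        published 1.05; the directly specified age+area model matches it."""
        m1 = nm.select_risk_models(table1)[0]
        assert round(m1.term("mean_nuclear_area").odds_ratio, 2) in (1.04, 1.05)
        published = nm.fit_logistic_model(table1, ["age", "mean_nuclear_area"])
        t = published.term("mean_nuclear_area")
        assert round(t.odds_ratio, 2) == 1.05
        assert round(t.ci_low, 2) == 1.02 and round(t.ci_high, 2) == 1.07

    def test_aic_of_selection_is_minimal_over_trace(self, table1):
        sel = nm.RiskModelSelector(candidates=nm.risk.DEFAULT_CANDIDATES)
        sel.fit(table1.to_frame(), [r.pn_status for r in table1])
        for model in sel.models_:
            searched = sel.trace_[model.name]
            assert model.aic <= min(aic for _, aic in searched) + 1e-9
            assert len(searched) == 2 ** len(
                [f for f in sel.screened_ if f not in sel.anchors]
            )

    def test_intercept_always_present(self, table1):
        for m in nm.select_risk_models(table1):
            assert m.terms[0].factor == "intercept"

    def test_empty_screen_returns_intercept_only(self, table1):
        sel = nm.RiskModelSelector(screen_alpha=1e-9, candidates=("sex",))
        sel.fit(table1.to_frame(), [r.pn_status for r in table1])
        assert sel.models_[0].factors == ()
        assert "no factor passed the screen" in sel.models_[0].note

    def test_predict_proba_rounds_trip_fitted_probabilities(self, table1):
        frame = table1.to_frame()
        y = np.array([r.pn_status for r in table1])
        sel = nm.RiskModelSelector(candidates=nm.risk.DEFAULT_CANDIDATES).fit(frame, y)
        p = sel.predict_proba(frame)
        assert p.shape == (88, 2)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert ((sel.predict(frame) == 1) == (p[:, 1] >= 0.5)).all()

    def test_screen_type_i_error_calibration(self):
        """Null single-factor screens at alpha = 0.1 fire within
        [0.07, 0.13] over 1000 replicates."""
        import statsmodels.api as sm

        rng = np.random.default_rng(202)
        y = np.r_[np.zeros(42), np.ones(46)]
        hits = 0
        for _ in range(1000):
            x = rng.normal(0, 1, 88)
            res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            wald_p = 2 * stats.norm.sf(abs(res.params[1] / res.bse[1]))
            hits += wald_p < 0.1
        assert 0.07 <= hits / 1000 <= 0.13

    def test_selection_recovers_single_true_predictor(self):
        """One strong predictor (log-OR 1 per SD) plus two null covariates
        at n = 88: the screen+AIC pipeline returns exactly the true support
        in >= 80 of 100 replicates."""
        rng = np.random.default_rng(2014)
        exact = 0
        for _ in range(100):
            X = rng.normal(0, 1, (88, 3))
            eta = -0.1 + 1.0 * X[:, 0]
            y = (rng.random(88) < 1 / (1 + np.exp(-eta))).astype(float)
            sel = nm.RiskModelSelector(candidates=("x0", "x1", "x2"), anchors=())
            try:
                sel.fit(pd.DataFrame(X, columns=["x0", "x1", "x2"]), y)
            except SeparationError:
                continue
            exact += set(sel.models_[0].factors) == {"x0"}
        assert exact >= 80


class TestTable3Report:
    def test_layout_and_published_rows(self, table1):
        rep = nm.table3_report(table1)
        assert rep.factor.nunique() == 9
        row = rep[(rep.factor == "sex") & (rep.level == "M")].iloc[0]
        assert round(row.odds_ratio, 2) == 1.15
        nacv = rep[rep.factor == "nacv"].iloc[0]
        assert round(nacv.odds_ratio, 2) == 1.06
        circ = rep[rep.factor == "circular_rate"].iloc[0]
        assert round(circ.odds_ratio, 2) == 0.44  # per 0.1 increment
        site_overall = rep[rep.factor == "site"].overall_p.iloc[0]
        assert site_overall > 0.1

    def test_dichotomized_blocks_present(self, table1):
        rep = nm.table3_report(table1)
        dich = rep[rep.level == ">80.3"].iloc[0]
        assert round(dich.odds_ratio, 2) == 7.58
        assert rep[rep.level == ">32.7"].iloc[0].odds_ratio == pytest.approx(7.72, abs=0.005)

    def test_no_correction_note_attached(self, table1):
        rep = nm.table3_report(table1)
        assert "correction" in rep.attrs["note"]
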