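"""Statistics battery: score derivations, elementary tests against
extended-precision oracles, longitudinal models, prediction, FDR."""

import mpmath
import numpy as np
import pandas as pd
import pytest

import glymkit as gk
from glymkit import stats as st

mpmath.mp.dps = 50


# ---------------------------------------------------------------------------
# extended-precision oracles


def t_sf_two_sided(t: float, df: float) -> float:
    """Two-sided p for a t statistic via the regularized incomplete beta."""
    x = df / (df + t * t)
    p = mpmath.betainc(df / 2, mpmath.mpf(1) / 2, 0, x, regularized=True)
    return float(p)


def welch_oracle(x, y):
    x = [mpmath.mpf(v) for v in x]
    y = [mpmath.mpf(v) for v in y]
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / mpmath.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(t), float(df), t_sf_two_sided(float(t), float(df))


def chi2_oracle(table):
    table = [[mpmath.mpf(v) for v in row] for row in table]
    n = sum(sum(row) for row in table)
    rows = [sum(row) for row in table]
    cols = [sum(table[i][j] for i in range(len(table))) for j in range(len(table[0]))]
    stat = mpmath.mpf(0)
    for i in range(len(table)):
        for j in range(len(table[0])):
            e = rows[i] * cols[j] / n
            stat += (table[i][j] - e) ** 2 / e
    df = (len(table) - 1) * (len(table[0]) - 1)
    p = mpmath.gammainc(mpmath.mpf(df) / 2, stat / 2, mpmath.inf, regularized=True)
    return float(stat), df, float(p)


def pearson_oracle(x, y):
    x = [mpmath.mpf(v) for v in x]
    y = [mpmath.mpf(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / mpmath.sqrt(sxx * syy)
    t = r * mpmath.sqrt((n - 2) / (1 - r * r))
    return float(r), t_sf_two_sided(float(t), n - 2)


def fdr_oracle(p):
    """adj_(i) = min_{j >= i} m * p_(j) / j, in the sorted order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        tail = [m * p[order[j - 1]] / j for j in range(rank_i, m + 1)]
        adj[idx] = min(1.0, min(tail))
    return adj


def auc_oracle(scores, labels):
    """Exhaustive pairwise concordance with ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------


class TestSymptomSummaries:
    @pytest.mark.parametrize(
        "items, total, n_symp",
        [
            ([0] * 22, 0, 0),
            ([4] * 22, 88, 22),
            ([2, 1] + [0] * 20, 3, 1),
        ],
    )
    def test_totals_and_counts(self, items, total, n_symp):
        rpq_total, n, flags, _ = st.derive_symptom_summaries(items)
        assert rpq_total == total
        assert n == n_symp
        assert flags.sum() == n_symp

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ValueError, match="22"):
            st.derive_symptom_summaries([0] * 21)

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError, match="0..4"):
            st.derive_symptom_summaries([5] + [0] * 21)


class TestWelch:
    def test_identical_samples(self):
        res = st.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_extended_precision_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(5, 30))
            y = rng.normal(0.3, 1.5, size=rng.integers(5, 30))
            res = st.welch_t_test(x, y)
            t0, df0, p0 = welch_oracle(x, y)
            assert res.statistic == pytest.approx(t0, abs=1e-10)
            assert res.df == pytest.approx(df0, abs=1e-8)
            assert res.p_value == pytest.approx(p0, abs=1e-10)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            st.welch_t_test([1.0], [1.0, 2.0])


class TestChiSquared:
    def test_balanced_table(self):
        res = st.chi_squared_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # expected counts all 15 -> stat = 4 * 25/15 = 100/15
        res = st.chi_squared_test([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(100.0 / 15.0, abs=1e-12)
        assert res.df == 1

    def test_2x3_df(self):
        res = st.chi_squared_test([[10, 10, 10], [10, 10, 10]])
        assert res.df == 2

    def test_matches_oracle(self, rng):
        for _ in range(20):
            table = rng.integers(1, 40, size=(2, rng.integers(2, 5)))
            res = st.chi_squared_test(table)
            s0, df0, p0 = chi2_oracle(table)
            assert res.statistic == pytest.approx(s0, abs=1e-10)
            assert res.p_value == pytest.approx(p0, abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            st.chi_squared_test([[0, 0], [5, 5]])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert st.pearson_correlation(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert st.pearson_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=20)
            y = 0.4 * x + rng.normal(size=20)
            res = st.pearson_correlation(x, y)
            r0, p0 = pearson_oracle(x, y)
            assert res.statistic == pytest.approx(r0, abs=1e-10)
            assert res.p_value == pytest.approx(p0, abs=1e-10)

    def test_p_against_permutation_null(self, rng):
        x = rng.normal(size=20)
        y = 0.55 * x + rng.normal(size=20)
        res = st.pearson_correlation(x, y)
        n_perm = 100_000
        perms = np.array([rng.permutation(y) for _ in range(n_perm)])
        xc = x - x.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        rs = (pc @ xc) / np.sqrt((xc**2).sum() * (pc**2).sum(axis=1))
        p_perm = (np.abs(rs) >= abs(res.statistic)).mean()
        mc_err = 2 * np.sqrt(max(p_perm, 1 / n_perm) / n_perm)
        assert abs(res.p_value - p_perm) < max(2 * mc_err, 0.002)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            st.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAdjustedAssociation:
    def test_orthogonal_covariates_leave_slope(self, rng):
        n = 64
        marker = np.tile([1.0, -1.0], n // 2)
        cov = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)  # orthogonal to marker
        y = 2.0 * marker + 0.5 * cov + rng.normal(size=n)
        adj = st.adjusted_association(y, marker, covariates=[cov])
        simple = st.adjusted_association(y, marker, covariates=None)
        assert adj.estimate == pytest.approx(simple.estimate, abs=1e-10)

    def test_duplicated_marker_rejected(self, rng):
        m = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank"):
            st.adjusted_association(rng.normal(size=30), m, covariates=[m])

    def test_recovers_generative_slope(self):
        rng = np.random.default_rng(0)
        n = 2000
        age = rng.uniform(18, 60, n)
        sex = rng.integers(0, 2, n).astype(float)
        marker = rng.normal(size=n)
        y = 1.5 * marker + 0.05 * age - 0.3 * sex + rng.normal(size=n)
        res = st.adjusted_association(y, marker, covariates=[age, sex])
        se = (res.ci[1] - res.ci[0]) / (2 * 1.96)
        assert abs(res.estimate - 1.5) < 3 * se


class TestLmm:
    def _make_long(self, rng, n_subj, visit_effect, tau, sigma=0.3):
        rows = []
        for i in range(n_subj):
            age = rng.uniform(18, 60)
            sex = float(rng.integers(0, 2))
            b = rng.normal(0, tau)
            for visit, eff in (("14Day", 0.0), ("6-12Mon", visit_effect)):
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "visit": visit,
                        "age": age,
                        "sex": sex,
                        "y": 1.0 + eff + 0.01 * age + b + rng.normal(0, sigma),
                    }
                )
        return pd.DataFrame(rows)

    def test_tau_zero_matches_ols(self, rng):
        df = self._make_long(rng, 80, visit_effect=0.2, tau=0.0)
        lmm = st.fit_lmm_visit(df, "y")
        import statsmodels.api as sm

        X = sm.add_constant(
            np.column_stack(
                [
                    (df["visit"] == "6-12Mon").astype(float),
                    df["age"],
                    df["sex"],
                ]
            )
        )
        ols = sm.OLS(df["y"], X).fit()
        key = [k for k in lmm if k.startswith("visit_")][0]
        assert lmm[key].estimate == pytest.approx(ols.params.iloc[1], abs=1e-6)

    def test_balanced_paired_equals_mean_difference(self, rng):
        df = self._make_long(rng, 40, visit_effect=0.15, tau=0.4)
        lmm = st.fit_lmm_visit(df, "y", covariates=())
        wide = df.pivot(index="subject_id", columns="visit", values="y")
        paired = (wide["6-12Mon"] - wide["14Day"]).mean()
        key = [k for k in lmm if k.startswith("visit_")][0]
        assert lmm[key].estimate == pytest.approx(paired, abs=1e-8)

    def test_recovers_visit_effect(self, rng):
        df = self._make_long(rng, 200, visit_effect=0.1, tau=0.25)
        lmm = st.fit_lmm_visit(df, "y")
        key = [k for k in lmm if k.startswith("visit_")][0]
        res = lmm[key]
        assert abs(res.estimate - 0.1) < 3 * res.extra["se"]
        assert res.extra["converged"]


class TestRatioChange:
    def test_constant_marker_is_degenerate(self, small_cohort):
        df = small_cohort.copy()
        df["const_marker"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            st.ratio_change_correlation(df[df["group"] == "mTBI"], "const_marker", "psqi")

    def test_missing_followup_excluded(self, small_cohort):
        mtbi = small_cohort[small_cohort["group"] == "mTBI"].copy()
        drop_sid = mtbi["subject_id"].iloc[0]
        mtbi = mtbi[~((mtbi["subject_id"] == drop_sid) & (mtbi["visit"] == "6-12Mon"))]
        res = st.ratio_change_correlation(mtbi, "alps_index", "psqi")
        assert res.extra["n_pairs"] == mtbi["subject_id"].nunique() - 1
        assert res.extra["n_excluded"] >= 1


class TestStepwise:
    def test_all_zero_outcome_rejected(self, rng):
        df = pd.DataFrame({"y": np.zeros(50), "x": rng.normal(size=50)})
        with pytest.raises(ValueError, match="both classes"):
            st.stepwise_logistic(df, ["x"], "y")

    def test_strong_predictor_selected(self, rng):
        hits = 0
        n_rep, n = 200, 300
        for _ in range(n_rep):
            X = rng.normal(size=(n, 6))
            lp = 1.5 * X[:, 0] - 0.5
            y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
            df = pd.DataFrame(X, columns=[f"x{j}" for j in range(6)])
            df["y"] = y
            _, selected, _ = st.stepwise_logistic(df, [f"x{j}" for j in range(6)], "y")
            hits += "x0" in selected
        assert hits / n_rep > 0.90

    def test_all_null_modal_selection_is_empty(self, rng):
        empty = 0
        n_rep, n = 60, 500
        sizes = []
        for _ in range(n_rep):
            X = rng.normal(size=(n, 5))
            y = rng.integers(0, 2, n).astype(float)
            df = pd.DataFrame(X, columns=[f"x{j}" for j in range(5)])
            df["y"] = y
            _, selected, _ = st.stepwise_logistic(df, [f"x{j}" for j in range(5)], "y")
            sizes.append(len(selected))
            empty += len(selected) == 0
        # intercept-only is the modal outcome under the null
        assert empty >= max(np.bincount(sizes)[1:].max(initial=0), n_rep * 0.4)


class TestRoc:
    def test_worked_example(self):
        curve = st.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert st.roc_auc([0, 0, 1, 1], [0, 0, 1, 1]).auc == 1.0

    def test_all_tied_scores(self):
        assert st.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]).auc == 0.5

    def test_matches_exhaustive_concordance(self, rng):
        for _ in range(30):
            n = rng.integers(6, 25)
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert st.roc_auc(scores, labels).auc == pytest.approx(
                auc_oracle(scores, labels), abs=1e-12
            )

    def test_curve_monotone(self, rng):
        curve = st.roc_auc(rng.normal(size=50), rng.integers(0, 2, 50))
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            st.roc_auc([0.1, 0.2], [1, 1])


class TestBootstrapAuc:
    def test_identical_models(self, rng):
        y = rng.integers(0, 2, 40)
        y[:3] = [0, 1, 0]
        s = rng.normal(size=40)
        res = st.compare_auc_bootstrap(s, s, y, n_boot=300, seed=1)
        assert res.estimate == 0.0
        assert res.p_value >= 0.9

    def test_seed_reproducibility(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        a, b = rng.normal(size=60), rng.normal(size=60)
        r1 = st.compare_auc_bootstrap(a, b, y, n_boot=300, seed=7)
        r2 = st.compare_auc_bootstrap(a, b, y, n_boot=300, seed=7)
        assert r1.p_value == r2.p_value

    def test_seed_mandatory(self, rng):
        with pytest.raises(ValueError, match="seed"):
            st.compare_auc_bootstrap([1.0, 2.0], [2.0, 1.0], [0, 1], seed=None)


class TestFdr:
    def test_single_p_unchanged(self):
        assert st.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_arithmetic_sequence(self):
        adj = st.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            p = rng.random(rng.integers(1, 15))
            assert np.allclose(st.fdr_adjust(p), fdr_oracle(p), atol=1e-12)

    def test_readjustment_never_decreases(self, rng):
        # step-up adjustment is monotone and dominates its input, so a
        # second application can only move values up (it is not idempotent
        # in general: re-ranking ties can raise earlier entries)
        p = rng.random(10)
        once = st.fdr_adjust(p)
        twice = st.fdr_adjust(once)
        assert np.all(twice >= once - 1e-12)
        assert np.all(once >= p)

    def test_permutation_equivariant(self, rng):
        p = rng.random(12)
        perm = rng.permutation(12)
        assert np.allclose(st.fdr_adjust(p)[perm], st.fdr_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.fdr_adjust([0.5, 1.2])
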