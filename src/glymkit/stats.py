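"""Cohort statistics: score derivations, group tests, associations,
longitudinal models, prediction and multiplicity control.

Conventions (documented once, applied throughout):

* two-sample t-tests are Welch (unequal variances, Satterthwaite df);
* chi-squared tests are Pearson without continuity correction;
* marker-symptom associations adjust for age and sex by OLS and report the
  partial correlation of outcome and marker given the covariates;
* the longitudinal model is a random-intercept linear mixed model fitted by
  REML with Wald fixed-effect tests;
* stepwise logistic selection is bidirectional on AIC from the
  intercept-only model;
* AUCs are tie-corrected pairwise concordance probabilities, and two models'
  AUCs are compared with a paired bootstrap normal-approximation test;
* multiplicity control is Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger("glymkit")

__all__ = [
    "TestResult",
    "RocCurve",
    "derive_symptom_summaries",
    "welch_t_test",
    "chi_squared_test",
    "pearson_correlation",
    "adjusted_association",
    "fit_lmm_visit",
    "ratio_change_correlation",
    "stepwise_logistic",
    "roc_auc",
    "compare_auc_bootstrap",
    "fdr_adjust",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    estimate: float | None = None
    ci: tuple[float, float] | None = None
    method: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC out of range: {self.auc}")


# ---------------------------------------------------------------------------
# score derivations

N_RPQ = 22
SYMPTOMATIC_RATING = 2  # "at least a mild problem"


def derive_symptom_summaries(rpq_items, psqi_items=None):
    """RPQ total (0-88), symptom count (items rated >= 2), per-item
    symptomatic flags, and the PSQI global score (sum of its components).

    ``rpq_items`` is a length-22 sequence of ordinal ratings 0-4.
    """
    items = np.asarray(rpq_items, dtype=float)
    if items.shape != (N_RPQ,):
        raise ValueError(f"expected {N_RPQ} RPQ items, got shape {items.shape}")
    if np.any((items < 0) | (items > 4)):
        raise ValueError("RPQ ratings must lie in 0..4")
    flags = items >= SYMPTOMATIC_RATING
    rpq_total = int(items.sum())
    n_symptoms = int(flags.sum())
    psqi_global = None
    if psqi_items is not None:
        psqi_global = float(np.asarray(psqi_items, dtype=float).sum())
        if not (0.0 <= psqi_global <= 21.0):
            raise ValueError(f"PSQI global score out of range: {psqi_global}")
    return rpq_total, n_symptoms, flags, psqi_global


# ---------------------------------------------------------------------------
# elementary tests


def welch_t_test(x, y) -> TestResult:
    """Welch two-sample t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return TestResult(statistic=0.0, p_value=1.0, df=float(x.size + y.size - 2),
                          estimate=0.0, method="welch-t")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples degenerate with different means")
    res = sps.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(df),
        estimate=float(x.mean() - y.mean()),
        method="welch-t",
    )


def chi_squared_test(table) -> TestResult:
    """Pearson chi-squared test on an r x k count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal row/column")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(stat), p_value=float(p), df=float(df), method="chi2")


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with the t-transform p-value on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(r), p_value=float(p), df=float(x.size - 2),
        estimate=float(r), method="pearson",
    )


def adjusted_association(outcome, marker, covariates=None) -> TestResult:
    """OLS of outcome on marker + covariates (default age/sex adjustment).

    Returns the marker slope, its t-test p-value, and (in ``extra``) the
    partial correlation of outcome and marker given the covariates.
    """
    outcome = np.asarray(outcome, dtype=float)
    marker = np.asarray(marker, dtype=float)
    if covariates is None:
        cov = np.empty((outcome.size, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        elif cov.shape[0] != outcome.size and cov.shape[1] == outcome.size:
            cov = cov.T  # given as a sequence of covariate vectors
    n, p_cov = outcome.size, cov.shape[1]
    if n <= p_cov + 2:
        raise ValueError("too few observations for the requested adjustment")
    X = sm.add_constant(np.column_stack([marker, cov]) if p_cov else marker[:, None])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear marker/covariates)")
    fit = sm.OLS(outcome, X).fit()
    t_marker = float(fit.tvalues[1])
    df_resid = float(fit.df_resid)
    partial_r = t_marker / np.sqrt(t_marker**2 + df_resid)
    ci = tuple(np.asarray(fit.conf_int())[1])
    return TestResult(
        statistic=t_marker,
        p_value=float(fit.pvalues[1]),
        df=df_resid,
        estimate=float(fit.params[1]),
        ci=(float(ci[0]), float(ci[1])),
        method="ols-adjusted",
        extra={"partial_r": float(partial_r)},
    )


# ---------------------------------------------------------------------------
# longitudinal


def fit_lmm_visit(
    df: pd.DataFrame,
    outcome: str,
    visit_col: str = "visit",
    subject_col: str = "subject_id",
    covariates: tuple[str, ...] = ("age", "sex"),
    reference_visit: str = "14Day",
) -> dict[str, TestResult]:
    """Random-intercept linear mixed model: outcome ~ visit + covariates,
    (1 | subject), fitted by REML with Wald fixed-effect tests.

    Returns one :class:`TestResult` per fixed effect; each carries the
    convergence flag and variance components in ``extra``.
    """
    data = df[[outcome, visit_col, subject_col, *covariates]].dropna().copy()
    if data[subject_col].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    visits = sorted(data[visit_col].unique(), key=lambda v: v != reference_visit)
    dummies = pd.get_dummies(data[visit_col], prefix="visit", dtype=float)
    keep = [f"visit_{v}" for v in visits[1:]]
    X = pd.concat([dummies[keep], data[list(covariates)].astype(float)], axis=1)
    X = sm.add_constant(X)
    model = sm.MixedLM(
        data[outcome].astype(float), X, groups=data[subject_col]
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    converged = bool(getattr(fit, "converged", True))
    if not converged:
        logger.warning("mixed model did not converge for outcome %s", outcome)
    out: dict[str, TestResult] = {}
    tau2 = float(np.asarray(fit.cov_re).ravel()[0])
    for name in fit.fe_params.index:
        out[name] = TestResult(
            statistic=float(fit.tvalues[name]),
            p_value=float(fit.pvalues[name]),
            estimate=float(fit.fe_params[name]),
            method="lmm-reml",
            extra={
                "converged": converged,
                "tau2": tau2,
                "sigma2": float(fit.scale),
                "se": float(fit.bse[name]),
            },
        )
    return out


def ratio_change_correlation(
    df: pd.DataFrame,
    marker: str,
    score: str,
    visit_col: str = "visit",
    subject_col: str = "subject_id",
    baseline: str = "14Day",
    followup: str = "6-12Mon",
) -> TestResult:
    """Pearson correlation of per-subject follow-up/baseline ratios of a
    marker and an assessment score.

    Subjects lacking either visit, or with a zero baseline value, are
    excluded with a logged count.
    """
    base = df[df[visit_col] == baseline].set_index(subject_col)
    late = df[df[visit_col] == followup].set_index(subject_col)
    common = base.index.intersection(late.index)
    n_excluded = df[subject_col].nunique() - len(common)
    ratios = []
    for sid in common:
        b_m, l_m = base.loc[sid, marker], late.loc[sid, marker]
        b_s, l_s = base.loc[sid, score], late.loc[sid, score]
        if b_m == 0 or b_s == 0 or any(pd.isna([b_m, l_m, b_s, l_s])):
            n_excluded += 1
            continue
        ratios.append((l_m / b_m, l_s / b_s))
    if n_excluded:
        logger.warning("ratio correlation: excluded %d subjects without complete pairs", n_excluded)
    if len(ratios) < 3:
        raise ValueError(f"only {len(ratios)} complete ratio pairs (need >= 3)")
    arr = np.asarray(ratios)
    res = pearson_correlation(arr[:, 0], arr[:, 1])
    res.method = "ratio-pearson"
    res.extra["n_pairs"] = len(ratios)
    res.extra["n_excluded"] = n_excluded
    return res


# ---------------------------------------------------------------------------
# prediction


def _fit_logit(y: np.ndarray, X: np.ndarray):
    model = sm.Logit(y, X)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # singular design / perfect separation
        raise RuntimeError(f"separation or singular fit: {exc}") from None
    if not fit.mle_retvals.get("converged", True) or np.any(np.abs(fit.params) > 50):
        raise RuntimeError("separation")
    return fit


def stepwise_logistic(
    df: pd.DataFrame,
    candidates: list[str],
    outcome: str,
    direction: str = "both",
    penalized: bool = False,
):
    """Bidirectional AIC stepwise logistic regression from the intercept-only
    model.

    Returns ``(fitted model, selected variable list, selection path)``.  The
    final fit's coefficient table is in ``model.summary()`` /
    ``model.params``.  Complete separation raises with advice to retry with
    ``penalized=True`` (L2-regularized refit of the selected terms).
    """
    data = df[[outcome, *candidates]].dropna()
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")

    def fit_aic(terms: list[str]):
        X = sm.add_constant(data[terms].to_numpy(dtype=float)) if terms else np.ones((len(y), 1))
        fit = _fit_logit(y, X)
        return fit, float(fit.aic)

    selected: list[str] = []
    path: list[str] = []
    try:
        best_fit, best_aic = fit_aic(selected)
        improved = True
        while improved:
            improved = False
            moves = []
            if direction in ("both", "forward"):
                moves += [("+", c) for c in candidates if c not in selected]
            if direction in ("both", "backward"):
                moves += [("-", c) for c in selected]
            for op, term in moves:
                trial = selected + [term] if op == "+" else [t for t in selected if t != term]
                try:
                    fit, aic = fit_aic(trial)
                except RuntimeError:
                    continue
                if aic < best_aic - 1e-9:
                    best_aic, best_fit, best_move = aic, fit, (op, term, trial)
                    improved = True
            if improved:
                op, term, selected = best_move
                path.append(f"{op}{term} (AIC={best_aic:.3f})")
    except RuntimeError:
        if not penalized:
            raise RuntimeError(
                "complete separation in logistic fit; retry with penalized=True"
            ) from None
        best_fit, selected, path = None, list(candidates), ["penalized: all candidates"]

    if penalized and best_fit is None:
        X = sm.add_constant(data[selected].to_numpy(dtype=float))
        best_fit = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0)
    logger.info("stepwise path: %s", " -> ".join(path) or "(intercept only)")
    return best_fit, selected, path


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and tie-corrected AUC (pairwise concordance probability).

    The AUC equals the Mann-Whitney U statistic normalized by n1*n0, with
    ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # monotone curve over descending unique thresholds
    order = np.argsort(-scores, kind="mergesort")
    tp = np.cumsum(pos[order])
    fp = np.cumsum(~pos[order])
    distinct = np.r_[np.where(np.diff(scores[order]) != 0)[0], scores.size - 1]
    tpr = np.r_[0.0, tp[distinct] / n1]
    fpr = np.r_[0.0, fp[distinct] / n0]
    thresholds = np.r_[np.inf, scores[order][distinct]]
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc))


def _auc_from_ranks(scores: np.ndarray, pos: np.ndarray) -> float:
    n1 = int(pos.sum())
    n0 = pos.size - n1
    ranks = sps.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def compare_auc_bootstrap(
    scores_a, scores_b, labels, n_boot: int = 2000, seed: int | None = None
) -> TestResult:
    """Paired bootstrap comparison of two models' AUCs on the same subjects.

    Subjects are resampled with replacement; the observed AUC difference is
    standardized by the bootstrap sd of the difference and referred to a
    standard normal (two-sided).  Resamples with a single class are redrawn
    (count logged).  Identical score vectors give dAUC = 0 and p = 1.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap comparison")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    n = labels.size
    obs = _auc_from_ranks(scores_a, pos) - _auc_from_ranks(scores_b, pos)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    redraws = 0
    while True:
        bad = np.where(~(pos[idx].any(axis=1) & (~pos[idx]).any(axis=1)))[0]
        if bad.size == 0:
            break
        redraws += bad.size
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
    p = pos[idx]  # (n_boot, n)
    n1 = p.sum(axis=1)
    n0 = n - n1
    ra = sps.rankdata(scores_a[idx], axis=1)
    rb = sps.rankdata(scores_b[idx], axis=1)
    auc_a = ((ra * p).sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    auc_b = ((rb * p).sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    diffs = auc_a - auc_b
    if redraws:
        logger.warning("bootstrap: redrew %d single-class resamples", redraws)
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        p_val = 1.0
        z = 0.0
    else:
        z = obs / sd
        p_val = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(
        statistic=float(z),
        p_value=p_val,
        estimate=float(obs),
        ci=(float(np.quantile(diffs, 0.025)), float(np.quantile(diffs, 0.975))),
        method="bootstrap-auc",
        extra={"n_boot": n_boot, "n_redraws": redraws},
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
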