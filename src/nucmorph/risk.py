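"""Risk statistics for pathologic nodal status (pN) in OSCC cohorts.

Implements the study's statistical pipeline over a :class:`~nucmorph.cohort.Cohort`:

* two-sample t-tests comparing pN-positive vs pN-negative groups,
* univariate maximum-likelihood logistic regressions of pN status with
  Wald odds ratios, 95% Wald intervals (z = 1.96) and a likelihood-ratio
  "overall test" per factor,
* dichotomization of a continuous marker at a cutoff, with the 2x2 table
  and the logistic odds ratio (which must equal the cross-product ratio
  ad/bc),
* min-p optimal-cutpoint search over observed midpoints (optimism-prone
  and flagged as such),
* a two-stage risk-model selection: univariate screen at p < 0.1, then
  exhaustive best-subset AIC search within an area-based and a
  perimeter-based family (area and perimeter are collinear by
  construction and are never co-included).

No multiple-testing correction is applied anywhere, matching the
original analysis; reports annotate the min-p optimism instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

from .cohort import Cohort, MORPHOMETRIC_FIELDS

__all__ = [
    "TTestResult",
    "UnivariateResult",
    "CutoffResult",
    "ModelTerm",
    "RiskModel",
    "SeparationError",
    "two_group_ttest",
    "univariate_logistic",
    "dichotomized_or",
    "minp_cutoff_search",
    "fit_logistic_model",
    "select_risk_models",
    "table3_report",
    "MinPCutpointBinarizer",
    "RiskModelSelector",
]

Z95 = 1.96  # normal quantile underlying all 95% Wald intervals

#: Factors treated as categorical, with their reference level.
CATEGORICAL_REFERENCES = {
    "sex": "F",
    "differentiation": "well",
    "site": "tongue",
    "neoadjuvant": "none",
    "dissection": "RND",
    "t_class": "1",
}

#: Candidate risk factors screened by default, in reporting order.
DEFAULT_CANDIDATES = (
    "age",
    "sex",
    "differentiation",
    "site",
    "mean_nuclear_area",
    "mean_perimeter",
    "circular_rate",
    "aspect_ratio",
    "nacv",
)

#: The two collinear-by-construction size factors anchoring the model families.
FAMILY_ANCHORS = ("mean_nuclear_area", "mean_perimeter")


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


@dataclass(frozen=True)
class TTestResult:
    field: str
    t: float
    df: float
    p: float
    group_stats: dict  # {"negative"/"positive": (mean, sd, n)}
    equal_var: bool
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class UnivariateResult:
    """One row of the univariate logistic table (one non-reference level)."""

    factor: str
    level: str | None
    reference_level: str | None
    odds_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    overall_p: float
    scaling: float = 1.0
    n: int = 0
    corrected: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("Wald CI must bracket the odds ratio")


@dataclass(frozen=True)
class CutoffResult:
    factor: str
    cutoff: float
    direction: str                  # "greater" or "less-or-equal"
    counts: np.ndarray              # 2x2, rows pN-/pN+, cols <=cutoff/>cutoff
    min_p: float
    odds_ratio: float
    profile: pd.DataFrame = field(repr=False, compare=False, default=None)
    note: str = (
        "min-p cutoff: p-value minimised over all candidate cutoffs and "
        "reported uncorrected; it is optimism-biased"
    )


@dataclass(frozen=True)
class ModelTerm:
    factor: str                     # design-column name, e.g. "site[buccal]"
    coefficient: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float


@dataclass(frozen=True)
class RiskModel:
    name: str
    terms: tuple[ModelTerm, ...]    # intercept first
    aic: float
    n: int
    note: str = ""

    def term(self, name: str) -> ModelTerm:
        for t in self.terms:
            if t.factor == name:
                return t
        raise KeyError(name)

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(t.factor for t in self.terms if t.factor != "intercept")


# ---------------------------------------------------------------------------
# low-level fitting


def _fit_logit(y: np.ndarray, X: np.ndarray | pd.DataFrame):
    """MLE logistic fit; separation and non-convergence raise, never pass silently."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            res = model.fit(disp=0)
        except PerfectSeparationWarning as exc:
            raise SeparationError(
                "complete or quasi-complete separation detected; the odds ratio "
                "is not estimable by maximum likelihood"
            ) from exc
        except ConvergenceWarning as exc:
            raise SeparationError(
                f"logistic fit failed to converge: {exc}"
            ) from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError(
            f"logistic fit failed to converge: {res.mle_retvals}"
        )
    if np.any(res.bse > 1e4):
        raise SeparationError(
            "implausibly large standard error: likely quasi-separation"
        )
    return res


def _is_categorical(factor: str, values: Sequence) -> bool:
    if factor in CATEGORICAL_REFERENCES:
        return True
    try:
        np.asarray(values, dtype=float)
        return False
    except (TypeError, ValueError):
        return True


def _dummy_design(
    values: Sequence[str], reference: str
) -> tuple[pd.DataFrame, list[str]]:
    levels = sorted(set(map(str, values)))
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not observed in data")
    others = [l for l in levels if l != reference]
    arr = {l: (np.asarray([str(v) for v in values]) == l).astype(float) for l in others}
    return pd.DataFrame(arr), others


def _wald_row(b: float, se: float, scaling: float = 1.0) -> tuple[float, float, float, float]:
    orv = float(np.exp(b * scaling))
    lo = float(np.exp((b - Z95 * se) * scaling))
    hi = float(np.exp((b + Z95 * se) * scaling))
    p = float(2.0 * stats.norm.sf(abs(b / se)))
    if scaling < 0:
        lo, hi = hi, lo
    return orv, lo, hi, p


def _outcome(cohort: Cohort) -> np.ndarray:
    return np.array([r.pn_status for r in cohort], dtype=float)


def _values(cohort: Cohort, factor: str) -> list:
    return [getattr(r, factor) for r in cohort]


# ---------------------------------------------------------------------------
# operations


def two_group_ttest(
    cohort: Cohort, field_name: str, *, equal_var: bool = True, alpha: float = 0.05
) -> TTestResult:
    """Two-sided two-sample t-test of a continuous field between pN groups.

    Pooled-variance by default; ``equal_var=False`` gives the Welch
    variant.  Both groups need >= 2 records and the test requires a
    nonzero (pooled) variance.
    """
    y = _outcome(cohort)
    x = np.asarray(_values(cohort, field_name), dtype=float)
    neg, pos = x[y == 0], x[y == 1]
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("both pN groups need at least 2 records")
    if np.var(neg) == 0 and np.var(pos) == 0:
        raise ValueError(f"{field_name}: zero variance in both groups, t undefined")
    res = stats.ttest_ind(neg, pos, equal_var=equal_var)
    return TTestResult(
        field=field_name,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        group_stats={
            "negative": (float(neg.mean()), float(neg.std(ddof=1)), len(neg)),
            "positive": (float(pos.mean()), float(pos.std(ddof=1)), len(pos)),
        },
        equal_var=equal_var,
        alpha=alpha,
    )


def univariate_logistic(
    cohort: Cohort,
    factor: str,
    *,
    scaling: float = 1.0,
    reference: str | None = None,
) -> UnivariateResult | list[UnivariateResult]:
    """Univariate logistic regression of pN status on one factor.

    Continuous factor: returns a single :class:`UnivariateResult` with
    OR = exp(coefficient * scaling) and a 95% Wald interval on the same
    increment; the overall p is the likelihood-ratio test against the
    intercept-only model.  Categorical factor: one result per
    non-reference level (dummy coding), all sharing the factor-level
    likelihood-ratio overall p.
    """
    y = _outcome(cohort)
    vals = _values(cohort, factor)
    n = len(y)
    if _is_categorical(factor, vals):
        ref = reference or CATEGORICAL_REFERENCES.get(factor) or str(
            pd.Series(vals).mode()[0]
        )
        X, others = _dummy_design(vals, ref)
        if not others:
            raise ValueError(f"{factor}: only one observed level ({ref})")
        res = _fit_logit(y, sm.add_constant(X))
        overall_p = float(res.llr_pvalue)
        out = []
        for lvl in others:
            orv, lo, hi, p = _wald_row(res.params[lvl], res.bse[lvl])
            out.append(
                UnivariateResult(
                    factor=factor, level=lvl, reference_level=ref,
                    odds_ratio=orv, ci_low=lo, ci_high=hi,
                    wald_p=p, overall_p=overall_p, n=n,
                )
            )
        return out
    x = np.asarray(vals, dtype=float)
    res = _fit_logit(y, sm.add_constant(x))
    orv, lo, hi, p = _wald_row(res.params[1], res.bse[1], scaling)
    return UnivariateResult(
        factor=factor, level=None, reference_level=None,
        odds_ratio=orv, ci_low=lo, ci_high=hi,
        wald_p=p, overall_p=float(res.llr_pvalue), scaling=scaling, n=n,
    )


def _crosstab(y: np.ndarray, ind: np.ndarray) -> np.ndarray:
    """2x2 counts: rows pN-/pN+, columns indicator 0/1."""
    return np.array(
        [
            [np.sum((y == g) & (ind == i)) for i in (0, 1)]
            for g in (0, 1)
        ],
        dtype=np.int64,
    )


def dichotomized_or(
    cohort: Cohort, factor: str, cutoff: float
) -> tuple[np.ndarray, UnivariateResult]:
    """2x2 table and odds ratio for (factor > cutoff) vs pN status.

    The OR comes from a logistic fit on the indicator and therefore
    equals the cross-product ratio (a*d)/(b*c); with an empty cell the
    Haldane-corrected closed form (0.5 added to every cell) is reported
    instead, explicitly flagged via ``corrected=True``.
    """
    y = _outcome(cohort)
    x = np.asarray(_values(cohort, factor), dtype=float)
    if not (x.min() < cutoff < x.max()):
        raise ValueError(
            f"cutoff {cutoff} outside the open range of observed {factor} values"
        )
    ind = (x > cutoff).astype(float)
    counts = _crosstab(y, ind)
    level = f">{cutoff:g}"
    if np.any(counts == 0):
        a, b = counts[0] + 0.5
        c, d = counts[1] + 0.5
        log_or = np.log(d * a / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        orv, lo, hi, p = _wald_row(log_or, se)
        result = UnivariateResult(
            factor=factor, level=level, reference_level=f"<={cutoff:g}",
            odds_ratio=orv, ci_low=lo, ci_high=hi, wald_p=p, overall_p=p,
            n=len(y), corrected=True,
            note="zero cell: Haldane-Anscombe correction (+0.5 per cell) applied",
        )
        return counts, result
    res = _fit_logit(y, sm.add_constant(ind))
    orv, lo, hi, p = _wald_row(res.params[1], res.bse[1])
    result = UnivariateResult(
        factor=factor, level=level, reference_level=f"<={cutoff:g}",
        odds_ratio=orv, ci_low=lo, ci_high=hi,
        wald_p=p, overall_p=float(res.llr_pvalue), n=len(y),
    )
    return counts, result


class MinPCutpointBinarizer(BaseEstimator, TransformerMixin):
    """Dichotomize a continuous marker at the minimum-p cutoff.

    ``fit(x, y)`` scans every midpoint between consecutive distinct
    observed values (keeping at least ``min_per_arm`` records on each
    side), tests the association between the binary outcome and the
    dichotomized marker, and keeps the cutoff with the smallest p; ties
    break toward the smaller cutoff.  The whole p-profile is retained
    for inspection because the minimised p is optimism-biased.

    Parameters
    ----------
    test : {"chi2", "fisher"}
        Chi-square without continuity correction (default) or Fisher's
        exact test.
    min_per_arm : int
        Minimum number of records on each side of a candidate cutoff.
    """

    def __init__(self, test: str = "chi2", min_per_arm: int = 5) -> None:
        self.test = test
        self.min_per_arm = min_per_arm

    def _pvalue(self, table: np.ndarray) -> float:
        if self.test == "chi2":
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                return 1.0
            return float(stats.chi2_contingency(table, correction=False).pvalue)
        if self.test == "fisher":
            return float(stats.fisher_exact(table).pvalue)
        raise ValueError("test must be 'chi2' or 'fisher'")

    def fit(self, x, y) -> "MinPCutpointBinarizer":
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        for g in (0, 1):
            if np.sum(y == g) < 10:
                raise ValueError("each outcome group needs >= 10 records")
        distinct = np.unique(x)
        if distinct.size < 2:
            raise ValueError("fewer than 2 distinct marker values")
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        rows = []
        for cut in mids:
            ind = (x > cut).astype(int)
            n_le, n_gt = int(np.sum(ind == 0)), int(np.sum(ind == 1))
            if min(n_le, n_gt) < self.min_per_arm:
                continue
            table = _crosstab(y, ind)
            rows.append((float(cut), self._pvalue(table), table))
        if not rows:
            raise ValueError(
                f"no candidate cutoff keeps >= {self.min_per_arm} records per arm"
            )
        self.profile_ = pd.DataFrame(
            [(c, p) for c, p, _ in rows], columns=["cutoff", "p"]
        )
        best = min(range(len(rows)), key=lambda i: (rows[i][1], rows[i][0]))
        cut, p, table = rows[best]
        a, b = table[0] + 0.5 * np.any(table == 0)
        c, d = table[1] + 0.5 * np.any(table == 0)
        orv = float(d * a / (b * c))
        self.cutoff_ = cut
        self.min_p_ = p
        self.counts_ = table
        self.odds_ratio_ = orv
        self.direction_ = "greater" if orv >= 1.0 else "less-or-equal"
        return self

    def transform(self, x) -> np.ndarray:
        if not hasattr(self, "cutoff_"):
            raise RuntimeError("call fit before transform")
        x = np.asarray(x, dtype=float)
        return (x > self.cutoff_).astype(int).reshape(-1, 1)

    def to_result(self, factor: str = "") -> CutoffResult:
        return CutoffResult(
            factor=factor,
            cutoff=self.cutoff_,
            direction=self.direction_,
            counts=self.counts_,
            min_p=self.min_p_,
            odds_ratio=self.odds_ratio_,
            profile=self.profile_,
        )


def minp_cutoff_search(
    cohort: Cohort, factor: str, *, test: str = "chi2", min_per_arm: int = 5
) -> CutoffResult:
    """Min-p optimal-cutpoint search for one continuous factor (see
    :class:`MinPCutpointBinarizer`)."""
    binarizer = MinPCutpointBinarizer(test=test, min_per_arm=min_per_arm)
    binarizer.fit(np.asarray(_values(cohort, factor), float), _outcome(cohort))
    return binarizer.to_result(factor)


# ---------------------------------------------------------------------------
# multivariate models


def _build_design(
    frame: pd.DataFrame, factors: Sequence[str]
) -> pd.DataFrame:
    """Numeric design matrix (no intercept) with dummy columns for
    categorical factors, named ``factor[level]``."""
    cols = {}
    for f in factors:
        vals = frame[f].tolist()
        if _is_categorical(f, vals):
            ref = CATEGORICAL_REFERENCES.get(f, str(pd.Series(vals).mode()[0]))
            dummies, others = _dummy_design(vals, ref)
            for lvl in others:
                cols[f"{f}[{lvl}]"] = dummies[lvl].to_numpy()
        else:
            cols[f] = np.asarray(vals, dtype=float)
    return pd.DataFrame(cols, index=frame.index)


def _model_from_fit(res, name: str, n: int, note: str = "") -> RiskModel:
    terms = []
    for col in res.params.index:
        b, se = float(res.params[col]), float(res.bse[col])
        orv, lo, hi, p = _wald_row(b, se)
        terms.append(
            ModelTerm(
                factor="intercept" if col == "const" else col,
                coefficient=b, se=se,
                odds_ratio=orv, ci_low=lo, ci_high=hi, wald_p=p,
            )
        )
    return RiskModel(name=name, terms=tuple(terms), aic=float(res.aic), n=n, note=note)


def fit_logistic_model(
    cohort: Cohort, factors: Sequence[str], *, name: str = "custom"
) -> RiskModel:
    """Fit a multivariate logistic model of pN status on the given factors."""
    frame = cohort.to_frame()
    y = _outcome(cohort)
    X = sm.add_constant(_build_design(frame, factors), has_constant="add")
    res = _fit_logit(y, X)
    return _model_from_fit(res, name, len(y))


class RiskModelSelector(BaseEstimator, ClassifierMixin):
    """Two-stage risk-model selection: p < 0.1 screen, then best-subset AIC.

    Stage 1 screens each candidate factor by its univariate test
    (continuous: Wald p; categorical: likelihood-ratio overall p) at
    ``screen_alpha``.  Stage 2 fits one model family per screened
    anchor factor (mean nuclear area / mean perimeter — collinear by
    construction, never co-included) by exhaustively searching all
    subsets of the remaining screened factors and keeping the minimum
    AIC.  With no screened anchor a single anchor-free family is
    searched; with nothing screened at all the intercept-only model is
    returned with a notice.

    Fitted attributes
    -----------------
    univariate_ : DataFrame of the screening statistics.
    screened_ : tuple of factors passing the screen.
    models_ : list of :class:`RiskModel`, one per family.
    best_model_ : the model with the lowest AIC across families.
    trace_ : dict mapping family name to every (subset, AIC) examined.
    """

    def __init__(
        self,
        screen_alpha: float = 0.1,
        candidates: Sequence[str] | None = None,
        anchors: Sequence[str] = FAMILY_ANCHORS,
    ) -> None:
        self.screen_alpha = screen_alpha
        self.candidates = candidates
        self.anchors = anchors

    # -- stage 1 -----------------------------------------------------------
    def _screen(self, frame: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
        rows = []
        for f in self.candidates_:
            vals = frame[f].tolist()
            if _is_categorical(f, vals):
                ref = CATEGORICAL_REFERENCES.get(f, str(pd.Series(vals).mode()[0]))
                X, _ = _dummy_design(vals, ref)
                res = _fit_logit(y, sm.add_constant(X))
                p = float(res.llr_pvalue)
            else:
                res = _fit_logit(y, sm.add_constant(np.asarray(vals, float)))
                p = float(2.0 * stats.norm.sf(abs(res.params[1] / res.bse[1])))
            rows.append({"factor": f, "p": p, "screened": p < self.screen_alpha})
        return pd.DataFrame(rows)

    # -- stage 2 -----------------------------------------------------------
    def _best_subset(
        self,
        frame: pd.DataFrame,
        y: np.ndarray,
        anchor: str | None,
        pool: Sequence[str],
        name: str,
    ) -> RiskModel:
        base = [anchor] if anchor else []
        searched = []
        best = None
        for k in range(len(pool) + 1):
            for sub in combinations(pool, k):
                factors = base + list(sub)
                if factors:
                    X = sm.add_constant(
                        _build_design(frame, factors), has_constant="add"
                    )
                else:
                    X = pd.DataFrame({"const": np.ones(len(y))})
                res = _fit_logit(y, X)
                searched.append((tuple(factors), float(res.aic)))
                if best is None or res.aic < best[0].aic:
                    best = (_model_from_fit(res, name, len(y)), tuple(factors))
        self.trace_[name] = searched
        return best[0]

    def fit(self, X: pd.DataFrame, y) -> "RiskModelSelector":
        frame = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel()
        self.candidates_ = tuple(self.candidates or frame.columns)
        missing = [f for f in self.candidates_ if f not in frame.columns]
        if missing:
            raise ValueError(f"candidate factor(s) not in X: {missing}")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = frame.shape[1]
        self.trace_ = {}

        self.univariate_ = self._screen(frame, y)
        screened = tuple(self.univariate_.loc[self.univariate_.screened, "factor"])
        self.screened_ = screened

        if not screened:
            res = _fit_logit(y, pd.DataFrame({"const": np.ones(len(y))}))
            self.models_ = [
                _model_from_fit(
                    res, "Model 1", len(y),
                    note="no factor passed the screen; intercept-only model",
                )
            ]
            self.trace_["Model 1"] = [((), float(res.aic))]
            self.best_model_ = self.models_[0]
            return self

        anchors = [a for a in self.anchors if a in screened]
        pool = [f for f in screened if f not in self.anchors]
        self.models_ = []
        if anchors:
            for i, anchor in enumerate(anchors, start=1):
                self.models_.append(
                    self._best_subset(frame, y, anchor, pool, f"Model {i}")
                )
        else:
            self.models_.append(self._best_subset(frame, y, None, pool, "Model 1"))
        self.best_model_ = min(self.models_, key=lambda m: m.aic)
        return self

    # -- prediction with the lowest-AIC model ------------------------------
    def _design_for(self, model: RiskModel, frame: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(frame))]
        for t in model.terms:
            if t.factor == "intercept":
                continue
            if "[" in t.factor:
                f, lvl = t.factor[:-1].split("[", 1)
                cols.append((frame[f].astype(str) == lvl).to_numpy(float))
            else:
                cols.append(frame[t.factor].to_numpy(float))
        return np.column_stack(cols)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "best_model_"):
            raise RuntimeError("call fit first")
        design = self._design_for(self.best_model_, pd.DataFrame(X))
        beta = np.array([t.coefficient for t in self.best_model_.terms])
        p1 = 1.0 / (1.0 + np.exp(-design @ beta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def select_risk_models(
    cohort: Cohort,
    *,
    screen_alpha: float = 0.1,
    candidates: Sequence[str] | None = None,
) -> list[RiskModel]:
    """Run the screen + best-subset-AIC selection on a cohort (see
    :class:`RiskModelSelector`).  On the reference cohort this yields an
    area-based Model 1 and a perimeter-based Model 2."""
    selector = RiskModelSelector(
        screen_alpha=screen_alpha, candidates=candidates or DEFAULT_CANDIDATES
    )
    selector.fit(cohort.to_frame(), _outcome(cohort))
    return selector.models_


# ---------------------------------------------------------------------------
# reporting


#: Per-increment scalings used in the univariate report: the circular
#: rate is reported per 0.1-unit increment (its whole observed range is
#: ~0.2 wide, so a per-1.0 OR would be unreadably extreme).
REPORT_SCALINGS = {"circular_rate": 0.1}


def table3_report(
    cohort: Cohort,
    *,
    area_cutoff: float | None = 80.3,
    perimeter_cutoff: float | None = 32.7,
) -> pd.DataFrame:
    """Full univariate risk table for the standard factor set.

    One block per factor: age, sex (ref Women), differentiation (ref
    well), site (ref tongue), nuclear area (continuous and dichotomized),
    nuclear perimeter (continuous and dichotomized), circular rate (per
    0.1), aspect ratio, NACV.  Cutoffs default to the reference study's
    published values; pass ``None`` to derive them by min-p search on
    the supplied cohort.

    Columns: factor, level, group summaries (mean±sd or count per pN
    group), odds_ratio, ci_low, ci_high, wald_p, overall_p.
    """
    y = _outcome(cohort)
    frame = cohort.to_frame()
    if area_cutoff is None:
        area_cutoff = minp_cutoff_search(cohort, "mean_nuclear_area").cutoff
    if perimeter_cutoff is None:
        perimeter_cutoff = minp_cutoff_search(cohort, "mean_perimeter").cutoff

    rows: list[dict] = []

    def cont_summary(f: str) -> tuple[str, str]:
        out = []
        for g in (0, 1):
            v = frame.loc[frame.pn_status == g, f].astype(float)
            out.append(f"{v.mean():.1f}±{v.std(ddof=1):.1f}")
        return tuple(out)

    def add_continuous(factor: str, label: str, scaling: float = 1.0) -> None:
        r = univariate_logistic(cohort, factor, scaling=scaling)
        neg, pos = cont_summary(factor)
        rows.append(
            {
                "factor": label, "level": None, "negative": neg, "positive": pos,
                "odds_ratio": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "wald_p": r.wald_p, "overall_p": r.overall_p,
            }
        )

    def add_categorical(factor: str, label: str) -> None:
        results = univariate_logistic(cohort, factor)
        ref = results[0].reference_level
        counts = pd.crosstab(frame[factor], frame.pn_status)
        rows.append(
            {
                "factor": label, "level": f"{ref} (ref)",
                "negative": int(counts.loc[ref, 0]) if 0 in counts else 0,
                "positive": int(counts.loc[ref, 1]) if 1 in counts else 0,
                "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                "wald_p": np.nan, "overall_p": results[0].overall_p,
            }
        )
        for r in results:
            rows.append(
                {
                    "factor": label, "level": r.level,
                    "negative": int(counts.loc[r.level, 0]) if 0 in counts else 0,
                    "positive": int(counts.loc[r.level, 1]) if 1 in counts else 0,
                    "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "wald_p": r.wald_p,
                    "overall_p": r.overall_p,
                }
            )

    def add_dichotomy(factor: str, label: str, cutoff: float) -> None:
        counts, r = dichotomized_or(cohort, factor, cutoff)
        rows.append(
            {
                "factor": label, "level": f"<={cutoff:g} (ref)",
                "negative": int(counts[0, 0]), "positive": int(counts[1, 0]),
                "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                "wald_p": np.nan, "overall_p": r.overall_p,
            }
        )
        rows.append(
            {
                "factor": label, "level": f">{cutoff:g}",
                "negative": int(counts[0, 1]), "positive": int(counts[1, 1]),
                "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "wald_p": r.wald_p, "overall_p": r.overall_p,
            }
        )

    add_continuous("age", "age")
    add_categorical("sex", "sex")
    add_categorical("differentiation", "differentiation")
    add_categorical("site", "site")
    add_continuous("mean_nuclear_area", "mean_nuclear_area")
    add_dichotomy("mean_nuclear_area", "mean_nuclear_area", area_cutoff)
    add_continuous("mean_perimeter", "mean_perimeter")
    add_dichotomy("mean_perimeter", "mean_perimeter", perimeter_cutoff)
    add_continuous("circular_rate", "circular_rate", REPORT_SCALINGS["circular_rate"])
    add_continuous("aspect_ratio", "aspect_ratio")
    add_continuous("nacv", "nacv")
    report = pd.DataFrame(rows)
    report.attrs["note"] = (
        "no multiple-testing correction applied anywhere; min-p-derived "
        "cutoffs are optimism-biased"
    )
    return report
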