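"""Recurrence-association statistics: 2x2 odds ratios with Wald intervals,
logistic regression, contingency tests, Kaplan-Meier estimation, log-rank
tests and Cox proportional hazards.

The univariate odds ratio of a binary risk factor is the 2x2 cross-product
ratio ``(a d)/(b c)``, identical to the exponentiated coefficient of a
univariate binomial logistic regression; its Wald interval is
``exp(log OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``. The table builder
reproduces the standard recurrence risk-factor analysis: per-variable
univariate odds ratios, with variables showing a tendency of association
(p < 0.25) carried into one multivariate logistic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Raised when logistic/Cox estimates diverge (perfect separation)."""


@dataclass
class TwoByTwoTable:
    """Exposure x outcome counts: a/b exposed with/without the event,
    c/d unexposed with/without the event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be nonnegative")
        if sum(cells) == 0:
            raise ValueError("table is empty")

    @classmethod
    def from_events(cls, exposed_events: int, exposed_total: int,
                    unexposed_events: int, unexposed_total: int) -> "TwoByTwoTable":
        """Build from the 'events/total' pairs printed in clinical tables."""
        return cls(exposed_events, exposed_total - exposed_events,
                   unexposed_events, unexposed_total - unexposed_events)


@dataclass
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    se_log: float
    p: float


def odds_ratio_wald(t: TwoByTwoTable, alpha: float = 0.05,
                    correction: str = "none") -> OddsRatioResult:
    """Cross-product odds ratio with a Wald confidence interval.

    With ``correction='haldane_if_zero'`` 0.5 is added to every cell only
    when some cell is zero; with ``'none'`` a zero cell is an error. The
    p-value is the two-sided Wald test of log OR = 0.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if correction == "haldane_if_zero":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            raise ZeroDivisionError("zero cell; use correction='haldane_if_zero'")
    oddsratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = np.log(oddsratio)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioResult(oddsratio, float(np.exp(log_or - z * se)),
                           float(np.exp(log_or + z * se)), float(se), float(p))


@dataclass
class LogisticFitResult:
    params: pd.Series            # coefficients on the log-odds scale
    conf_int: pd.DataFrame       # Wald CI of exp(beta)
    odds_ratios: pd.Series       # exp(beta)
    pvalues: pd.Series
    converged: bool
    n: int


def logistic_fit(X: pd.DataFrame, y, max_iter: int = 100,
                 tol: float = 1e-8) -> LogisticFitResult:
    """Binomial logistic regression by maximum likelihood (IRLS/Newton).

    An intercept is added automatically. Diverging coefficients
    (|beta| > 15) raise :class:`SeparationError`; a singular design raises a
    rank error from the solver.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("more parameters than observations")
    nunique = X.nunique()
    if (nunique <= 1).any():
        bad = nunique[nunique <= 1].index.tolist()
        raise ValueError(f"constant covariate column(s): {bad}")
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    try:
        res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=False)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular design or separation: {exc}") from exc
    if np.abs(res.params.drop("const", errors="ignore")).max() > 15:
        raise SeparationError("coefficients diverge; data are (quasi-)separated")
    ci = np.exp(res.conf_int())
    ci.columns = ["ci_low", "ci_high"]
    return LogisticFitResult(res.params, ci, np.exp(res.params),
                             res.pvalues, bool(res.mle_retvals["converged"]),
                             int(X.shape[0]))


def contingency_test(table, method: str = "chi_square") -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) or Fisher's exact test.

    Fisher's exact test (two-sided, hypergeometric tail summation) applies
    only to 2x2 tables. Zero-margin rows/columns are dropped with a warning
    for the chi-square test.
    """
    T = np.asarray(table, dtype=float)
    if (T < 0).any():
        raise ValueError("counts must be nonnegative")
    if method == "fisher_2x2":
        if T.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        _, p = stats.fisher_exact(T, alternative="two-sided")
        return float("nan"), float(p)
    if method != "chi_square":
        raise ValueError(f"unknown method {method!r}")
    keep_r = T.sum(axis=1) > 0
    keep_c = T.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("dropping %d zero-margin rows and %d columns",
                       (~keep_r).sum(), (~keep_c).sum())
        T = T[keep_r][:, keep_c]
    chi2, p, _, _ = stats.chi2_contingency(T, correction=False)
    return float(chi2), float(p)


def km_estimate(time, event, group=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group, with median survival.

    Returns per-group DataFrames of step coordinates (``time``,
    ``survival``) plus the median under key metadata columns. Censored
    observations never drop the curve.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time <= 0).any():
        raise ValueError("times must be positive")
    groups = np.asarray(group) if group is not None else np.zeros(len(time), dtype=int)
    curves: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            logger.warning("empty group %r skipped", g)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        df.attrs["median"] = float(kmf.median_survival_time_)
        df.attrs["n"] = int(mask.sum())
        curves[str(g)] = df
    return curves


def logrank_test(time, event, group) -> tuple[float, int, float]:
    """Log-rank test across groups; returns (chi-square, df, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if event.sum() == 0:
        raise ValueError("no events observed")
    if pd.unique(group).size < 2:
        raise ValueError("need at least two groups")
    res = multivariate_logrank_test(time, group, event)
    df = int(pd.unique(group).size - 1)
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class CoxFitResult:
    params: pd.Series
    hazard_ratios: pd.Series
    conf_int: pd.DataFrame      # CI of exp(beta)
    pvalues: pd.Series
    log_likelihood: float
    n: int


def cox_fit(time, event, X: pd.DataFrame, ties: str = "efron") -> CoxFitResult:
    """Cox proportional-hazards regression (partial likelihood, Newton).

    ``ties`` selects Efron (default) or Breslow handling of tied event
    times. All-censored data or non-convergence raise errors.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time <= 0).any():
        raise ValueError("times must be positive")
    if event.sum() == 0:
        raise ValueError("all observations are censored")
    X = pd.DataFrame(X).astype(float)
    model = PHReg(time, X, status=event, ties=ties)
    try:
        res = model.fit()
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"Cox fit failed: {exc}") from exc
    if not np.isfinite(res.params).all() or np.abs(res.params).max() > 15:
        raise SeparationError("Cox coefficients diverge (monotone likelihood)")
    params = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    z = stats.norm.ppf(0.975)
    ci = pd.DataFrame({"ci_low": np.exp(params - z * se),
                       "ci_high": np.exp(params + z * se)})
    pvals = pd.Series(res.pvalues, index=X.columns)
    return CoxFitResult(params, np.exp(params), ci, pvals,
                        float(model.loglike(res.params)), int(len(time)))


# ---------------------------------------------------------------------------
# recurrence risk-factor table

AGGRESSIVE_VARIANTS = {"tall cell variant", "columnar variant", "hobnail variant",
                       "tall cell", "columnar", "hobnail"}

TABLE2_ROWS = [
    ("age_ge55", "Age >= 55 years"),
    ("male", "Male sex"),
    ("aggressive_variant", "Aggressive histologic variant"),
    ("extrathyroidal_extension", "Extrathyroidal extension"),
    ("pt34", "pT3-4"),
    ("pn1", "pN1"),
    ("braf_like", "BRAF-like"),
    ("high_mutation", "> 11 nonsynonymous mutations"),
    ("nmf3", "NMF cluster 3"),
]


def dichotomize_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Binary risk-factor columns from a clinical table.

    Expects columns ``age, sex, histologic_variant, extrathyroidal_extension,
    pT, pN, driver_class, mutation_count, cluster, recurrence``; rows with a
    missing entry for a given variable are dropped for that variable only.
    """
    required = ["age", "sex", "histologic_variant", "extrathyroidal_extension",
                "pT", "pN", "driver_class", "mutation_count", "cluster",
                "recurrence"]
    missing = [c for c in required if c not in clinical.columns]
    if missing:
        raise KeyError(f"clinical table lacks required column(s): {missing}")
    out = pd.DataFrame(index=clinical.index)
    out["age_ge55"] = (clinical["age"].astype(float) >= 55).astype(int)
    out["male"] = (clinical["sex"].astype(str).str.lower() == "male").astype(int)
    out["aggressive_variant"] = clinical["histologic_variant"].astype(str).str.lower().isin(
        AGGRESSIVE_VARIANTS).astype(int)
    out["extrathyroidal_extension"] = clinical["extrathyroidal_extension"].astype(int)
    out["pt34"] = clinical["pT"].astype(str).isin(["pT3", "pT4"]).astype(int)
    out["pn1"] = (clinical["pN"].astype(str) == "pN1").astype(int)
    driver = clinical["driver_class"].astype(str)
    out["braf_like"] = (driver == "BRAF-like").astype(int)
    out.loc[~driver.isin(["BRAF-like", "RAS-like"]), "braf_like"] = np.nan
    out["high_mutation"] = (clinical["mutation_count"].astype(float) > 11).astype(int)
    out["nmf3"] = (clinical["cluster"].astype(str) == "NMF3").astype(int)
    out["recurrence"] = clinical["recurrence"].astype(int)
    return out


def build_table2(clinical: pd.DataFrame, enter_threshold: float = 0.25,
                 alpha: float = 0.05) -> dict:
    """Univariate odds ratios per risk factor plus one multivariate model.

    Each variable is dichotomized per the standard recurrence risk-factor
    layout, analysed on its complete cases with :func:`odds_ratio_wald`, and
    variables with univariate p below ``enter_threshold`` enter a single
    multivariate logistic regression on their joint complete cases.
    """
    binary = dichotomize_clinical(clinical)
    rows = []
    for var, pretty in TABLE2_ROWS:
        sub = binary[[var, "recurrence"]].dropna()
        a = int(((sub[var] == 1) & (sub["recurrence"] == 1)).sum())
        b = int(((sub[var] == 1) & (sub["recurrence"] == 0)).sum())
        c = int(((sub[var] == 0) & (sub["recurrence"] == 1)).sum())
        d = int(((sub[var] == 0) & (sub["recurrence"] == 0)).sum())
        try:
            res = odds_ratio_wald(TwoByTwoTable(a, b, c, d), alpha=alpha,
                                  correction="haldane_if_zero")
        except ValueError as exc:
            logger.warning("variable %r skipped: %s", var, exc)
            continue
        rows.append({"variable": var, "description": pretty,
                     "events_exposed": a, "total_exposed": a + b,
                     "events_unexposed": c, "total_unexposed": c + d,
                     "odds_ratio": res.oddsratio, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p": res.p})
    univariate = pd.DataFrame(rows).set_index("variable")

    selected = univariate.index[univariate["p"] < enter_threshold].tolist()
    multivariate = None
    if len(selected) >= 1:
        complete = binary[selected + ["recurrence"]].dropna()
        usable = [v for v in selected if complete[v].nunique() > 1]
        if usable and complete["recurrence"].nunique() > 1:
            try:
                multivariate = logistic_fit(complete[usable], complete["recurrence"])
            except (SeparationError, ValueError) as exc:
                logger.warning("multivariate model not fitted: %s", exc)
    return {"univariate": univariate, "selected": selected,
            "multivariate": multivariate}
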