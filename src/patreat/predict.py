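"""Statistical stage: group tests, correlation, regression and response
prediction.

This module implements the analysis chain that turns per-animal growth
and StO2 features into a treatment-response prediction:

1. per-day unpaired t-tests between control and treated groups;
2. a Spearman rank-correlation matrix over growth and StO2 features;
3. a multivariate linear model for the Gompertz growth rate,

       beta = b0 + b1*pretreatment volume + b2*dStO2(D7-D10)
                 + b3*dStO2(D10-D14),

   with forward selection (VIF-gated), plus k-fold and repeated
   random-subsampling cross-validation of the coefficients;
4. responder labeling (growth rate below the 25th percentile of the
   untreated group), multiple logistic regression, Hosmer-Lemeshow
   goodness of fit, ROC analysis with the Youden-optimal cutoff, and the
   resulting confusion metrics.

Ordinary model fits are delegated to statsmodels; the ROC machinery,
Hosmer-Lemeshow statistic, VIF screen, forward selection and both CV
schemes are implemented here (sklearn/scipy equivalents serve as
independent cross-checks in the test suite, not as the implementation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "per_day_group_tests",
    "CorrelationMatrix",
    "spearman_matrix",
    "RegressionResult",
    "fit_linear",
    "variance_inflation_factors",
    "forward_select",
    "kfold_cv",
    "subsample_cv",
    "label_responders",
    "LogisticResult",
    "fit_logistic",
    "hosmer_lemeshow",
    "ROCResult",
    "roc_analysis",
    "youden_threshold",
    "confusion_metrics",
    "ConfusionMetrics",
    "GrowthRateModel",
    "ResponderModel",
    "ResponderResults",
]


# --------------------------------------------------------------------------
# group tests


def per_day_group_tests(
    cohort: pd.DataFrame,
    variable: str,
    days: Sequence[float] | None = None,
    welch: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-tailed unpaired t-test between groups 0 and 1 on each day.

    Days on which only one group was measured are skipped with a warning.
    The Student (pooled-variance) test is the default; ``welch=True``
    switches to the unequal-variance form.
    """
    if days is None:
        days = sorted(cohort["day"].unique())
    rows = []
    for day in days:
        sub = cohort[cohort["day"] == day]
        a = sub.loc[sub["group"] == 0, variable].dropna().to_numpy()
        b = sub.loc[sub["group"] == 1, variable].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"day {day}: fewer than two observations in a group; skipped",
                stacklevel=2,
            )
            continue
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            dict(
                day=float(day), n_control=len(a), n_treated=len(b),
                t=float(t), p=float(p), significant=bool(p < alpha),
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rank correlations with p-values.

    ``rho`` and ``p`` are symmetric DataFrames over the same variables;
    constant variables produce NaN entries (flagged with a warning at
    construction).
    """

    rho: pd.DataFrame
    p: pd.DataFrame

    @property
    def variables(self) -> list[str]:
        return list(self.rho.columns)


def spearman_matrix(
    table: pd.DataFrame, variables: Sequence[str] | None = None
) -> CorrelationMatrix:
    """Spearman correlation matrix (average-rank ties, t-approximation p).

    Requires >= 5 complete pairs per variable pair.
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    variables = list(variables)
    k = len(variables)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[variables[i], variables[j]]].dropna()
            if len(sub) < 5:
                raise InsufficientDataError(
                    f"need >= 5 complete pairs for ({variables[i]}, {variables[j]})"
                )
            x = sub.iloc[:, 0].to_numpy(dtype=float)
            y = sub.iloc[:, 1].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant variable in pair ({variables[i]}, {variables[j]}); "
                    "correlation undefined",
                    stacklevel=2,
                )
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=variables, columns=variables),
        p=pd.DataFrame(pmat, index=variables, columns=variables),
    )


# --------------------------------------------------------------------------
# linear regression, VIF, forward selection, cross-validation


@dataclass
class RegressionResult:
    """A fitted (or cross-validated) linear growth-rate model.

    ``scheme`` is "full", "kfold" or "subsample".  For CV schemes the
    coefficients are fold/repeat averages, standard errors are the
    across-fold dispersion of the coefficient means, and ``r_squared``
    is the held-out validation R^2.
    """

    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    std_errors: np.ndarray
    r_squared: float
    adj_r_squared: float
    model_p: float
    coef_p: np.ndarray
    vifs: dict[str, float]
    scheme: str = "full"
    n_obs: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def param_names(self) -> list[str]:
        return ["intercept", *self.predictors]

    def summary(self) -> str:
        lines = [
            f"Linear growth-rate model ({self.scheme}), n = {self.n_obs}",
            "=" * 62,
            f"{'term':<22}{'coef':>12}{'std err':>12}{'p':>10}",
        ]
        for name, c, se, p in zip(
            self.param_names, self.coefficients, self.std_errors, self.coef_p
        ):
            lines.append(f"{name:<22}{c:>12.5g}{se:>12.3g}{p:>10.3g}")
        lines += [
            "-" * 62,
            f"R^2 = {self.r_squared:.4f}   adj R^2 = {self.adj_r_squared:.4f}   "
            f"model p = {self.model_p:.4g}",
        ]
        if self.vifs:
            vifstr = ", ".join(f"{k}: {v:.2f}" for k, v in self.vifs.items())
            lines.append(f"VIF: {vifstr}")
        lines.append("=" * 62)
        return "\n".join(lines)


def _design(table: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    x = table[list(predictors)].to_numpy(dtype=float)
    return sm.add_constant(x, has_constant="add")


def variance_inflation_factors(
    table: pd.DataFrame, predictors: Sequence[str]
) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2_j) of predictor j regressed on the others.

    A single predictor has VIF 1 by convention; an exactly collinear
    predictor returns ``inf``.
    """
    predictors = list(predictors)
    out: dict[str, float] = {}
    for j, name in enumerate(predictors):
        others = [p for p in predictors if p != name]
        if not others:
            out[name] = 1.0
            continue
        res = sm.OLS(
            table[name].to_numpy(dtype=float), _design(table, others)
        ).fit()
        r2 = min(res.rsquared, 1.0)
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def fit_linear(
    table: pd.DataFrame, predictors: Sequence[str], response: str
) -> RegressionResult:
    """Ordinary least squares of ``response`` on ``predictors`` + intercept."""
    predictors = tuple(predictors)
    y = table[response].to_numpy(dtype=float)
    x = _design(table, predictors)
    if len(y) <= len(predictors) + 1:
        raise ValidationError("need n > #predictors + 1 observations")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    res = sm.OLS(y, x).fit()
    return RegressionResult(
        predictors=predictors,
        coefficients=np.asarray(res.params, dtype=float),
        std_errors=np.asarray(res.bse, dtype=float),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        model_p=float(res.f_pvalue),
        coef_p=np.asarray(res.pvalues, dtype=float),
        vifs=variance_inflation_factors(table, predictors),
        scheme="full",
        n_obs=int(res.nobs),
    )


def forward_select(
    table: pd.DataFrame,
    candidates: Sequence[str],
    response: str,
    max_k: int = 3,
    vif_cutoff: float = 3.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> tuple[list[str], list[dict]]:
    """Greedy forward selection of predictors.

    At each step the admissible candidate that most increases R^2
    (adjusted R^2 with ``use_adjusted``) is added; a candidate is
    admissible when its coefficient p-value is below ``alpha`` and every
    VIF in the augmented set stays <= ``vif_cutoff``.  Selection stops at
    ``max_k`` predictors or when no candidate is admissible.

    Returns the selected predictor list and a full trace (one record per
    step with the per-candidate scores and rejection reasons).
    """
    selected: list[str] = []
    remaining = list(candidates)
    trace: list[dict] = []
    while remaining and len(selected) < max_k:
        step: dict = {"step": len(selected) + 1, "candidates": {}, "chosen": None}
        best_name, best_score = None, -np.inf
        for name in remaining:
            trial = [*selected, name]
            try:
                res = fit_linear(table, trial, response)
            except ValidationError as err:
                # exact collinearity: the VIF of the new predictor is infinite
                step["candidates"][name] = {
                    "rejected": f"singular design (VIF infinite): {err}"
                }
                continue
            score = res.adj_r_squared if use_adjusted else res.r_squared
            new_p = float(res.coef_p[-1])
            max_vif = max(res.vifs.values())
            rec = {"r2": res.r_squared, "adj_r2": res.adj_r_squared,
                   "coef_p": new_p, "max_vif": max_vif}
            if new_p >= alpha:
                rec["rejected"] = f"coefficient p {new_p:.3g} >= {alpha}"
            elif max_vif > vif_cutoff:
                rec["rejected"] = f"VIF {max_vif:.3g} > {vif_cutoff}"
            elif score > best_score:
                best_name, best_score = name, score
            step["candidates"][name] = rec
        if best_name is None:
            trace.append(step)
            break
        step["chosen"] = best_name
        step["score"] = best_score
        trace.append(step)
        selected.append(best_name)
        remaining.remove(best_name)
    return selected, trace


def _cv_result(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str,
    splits: list[tuple[np.ndarray, np.ndarray]],
    scheme: str,
    seed: int,
) -> RegressionResult:
    """Shared machinery for k-fold and subsampling CV."""
    predictors = tuple(predictors)
    y = table[response].to_numpy(dtype=float)
    coefs, preds, truth = [], [], []
    for train_idx, val_idx in splits:
        sub = table.iloc[train_idx]
        res = sm.OLS(sub[response].to_numpy(dtype=float), _design(sub, predictors)).fit()
        coefs.append(np.asarray(res.params, dtype=float))
        xval = _design(table.iloc[val_idx], predictors)
        preds.append(xval @ res.params)
        truth.append(y[val_idx])
    coefs = np.asarray(coefs)
    mean_coef = coefs.mean(axis=0)
    # dispersion of the across-split coefficient mean
    se_coef = (
        coefs.std(axis=0, ddof=1) / math.sqrt(len(splits))
        if len(splits) > 1
        else np.zeros_like(mean_coef)
    )
    preds = np.concatenate(preds)
    truth = np.concatenate(truth)
    ss_res = float(((truth - preds) ** 2).sum())
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    val_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    full = fit_linear(table, predictors, response)
    return RegressionResult(
        predictors=predictors,
        coefficients=mean_coef,
        std_errors=se_coef,
        r_squared=float(val_r2),
        adj_r_squared=float(
            1.0 - (1.0 - val_r2) * (len(y) - 1) / (len(y) - len(predictors) - 1)
        ),
        model_p=full.model_p,
        coef_p=full.coef_p,
        vifs=full.vifs,
        scheme=scheme,
        n_obs=len(y),
        extra={"n_splits": len(splits), "seed": seed,
               "per_split_coefficients": coefs},
    )


def kfold_cv(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str,
    k: int = 5,
    seed: int = 0,
) -> RegressionResult:
    """k-fold cross-validation of the linear model (seeded partition)."""
    n = len(table)
    if k > n:
        raise ValidationError(f"k = {k} exceeds n = {n}")
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    splits = [
        (np.concatenate([f for j, f in enumerate(folds) if j != i]), folds[i])
        for i in range(k)
    ]
    return _cv_result(table, predictors, response, splits, "kfold", seed)


def subsample_cv(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str,
    train_frac: float = 0.8,
    repeats: int = 100,
    seed: int = 0,
) -> RegressionResult:
    """Repeated random-subsampling (train/validation split) CV."""
    if not 0.0 < train_frac < 1.0:
        raise ValidationError("train_frac must lie in (0, 1)")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    n = len(table)
    n_train = int(round(train_frac * n))
    if n_train < len(list(predictors)) + 2:
        raise ValidationError("training split too small for the model")
    if n_train >= n:
        n_train = n - 1
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        splits.append((perm[:n_train], perm[n_train:]))
    return _cv_result(table, predictors, response, splits, "subsample", seed)


# --------------------------------------------------------------------------
# responder labeling and logistic regression


def label_responders(
    betas: Sequence[float],
    control_mask: Sequence[bool],
    percentile: float = 25.0,
) -> tuple[np.ndarray, float]:
    """Label animals whose growth rate fell below the control distribution.

    The threshold is the ``percentile``-th percentile (linear-interpolation
    quantile) of the control group's fitted growth rates; an animal is a
    responder (label 1) iff its rate is strictly below the threshold.

    Returns ``(labels, threshold)``.
    """
    betas = np.asarray(betas, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if betas.shape != control_mask.shape:
        raise ValidationError("betas and control_mask must align")
    control = betas[control_mask]
    if control.size < 4:
        raise InsufficientDataError(
            "need >= 4 control animals for a meaningful percentile"
        )
    threshold = float(np.percentile(control, percentile))
    return (betas < threshold).astype(int), threshold


@dataclass
class LogisticResult:
    """A fitted multiple logistic regression."""

    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    probabilities: np.ndarray
    converged: bool
    separation: bool
    log_likelihood: float

    @property
    def param_names(self) -> list[str]:
        return ["intercept", *self.predictors]


def fit_logistic(
    table: pd.DataFrame, predictors: Sequence[str], labels: Sequence[int]
) -> LogisticResult:
    """Maximum-likelihood logistic regression of binary labels.

    Fit by iteratively reweighted least squares (Newton scoring).
    Complete separation is detected and flagged; in that case a lightly
    ridge-penalized refit supplies finite coefficients and probabilities
    (the likelihood itself is unbounded under separation).
    """
    predictors = tuple(predictors)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("labels must contain both classes")
    x = _design(table, predictors)

    separation = False
    converged = False
    params = None
    llf = float("nan")
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, x).fit(method="newton", disp=0, maxiter=100)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", True))
            llf = float(res.llf)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True

    if params is not None:
        probs = 1.0 / (1.0 + np.exp(-(x @ params)))
        # quasi-separation: every observation fit essentially perfectly
        if np.all(np.abs(y - probs) < 1e-6):
            separation = True
    if params is None or (separation and not np.all(np.isfinite(params))):
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e3, max_iter=5000)
        clf.fit(x[:, 1:], y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        converged = True
        separation = True
    probs = 1.0 / (1.0 + np.exp(-(x @ params)))
    if not math.isfinite(llf):
        eps = 1e-12
        llf = float(np.sum(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
    return LogisticResult(
        predictors=predictors,
        coefficients=params,
        probabilities=probs,
        converged=converged,
        separation=separation,
        log_likelihood=llf,
    )


def hosmer_lemeshow(
    probs: Sequence[float], labels: Sequence[int], groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow chi^2 goodness-of-fit over deciles of risk.

    Observations are binned into ``groups`` quantile bins of predicted
    probability (degenerate bins are merged, with a warning); the
    statistic sums (O-E)^2/E over events and non-events in each bin and
    is referred to chi^2 with ``groups - 2`` degrees of freedom.

    Returns ``(statistic, df, p)``.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValidationError("probs and labels must align")
    if len(probs) < 2 * groups:
        raise ValidationError("need n >= 2 * groups observations")
    try:
        bins = np.asarray(
            pd.qcut(probs, groups, labels=False, duplicates="drop"), dtype=float
        )
    except ValueError:
        bins = np.full(len(probs), np.nan)
    if np.all(np.isnan(bins)):
        warnings.warn("degenerate probability bins; merged to one", stacklevel=2)
        bins = np.zeros(len(probs), dtype=int)
    else:
        bins = bins.astype(int)
    n_bins = int(np.max(bins)) + 1
    if n_bins < groups:
        warnings.warn(
            f"tied probabilities reduced {groups} bins to {n_bins}", stacklevel=2
        )
    stat = 0.0
    for b in range(n_bins):
        m = bins == b
        n_b = int(m.sum())
        if n_b == 0:
            continue
        o1 = float(labels[m].sum())
        e1 = float(probs[m].sum())
        o0, e0 = n_b - o1, n_b - e1
        for o, e in ((o1, e1), (o0, e0)):
            if e > 0:
                stat += (o - e) ** 2 / e
    df = max(n_bins - 2, 1)
    return float(stat), df, float(stats.chi2.sf(stat, df))


# --------------------------------------------------------------------------
# ROC analysis


@dataclass
class ROCResult:
    """Empirical ROC curve with AUC, its SE/CI, and the Youden cutoff.

    The curve is a step function through (0,0) and (1,1); ``thresholds``
    holds the score cutoffs that generate each operating point (a
    prediction is positive iff score >= cutoff).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    p_value: float
    n_pos: int
    n_neg: int
    se_method: str = "hanley"

    @property
    def youden_cutoff(self) -> float:
        return youden_threshold(self)


def roc_analysis(
    scores: Sequence[float], labels: Sequence[int], se_method: str = "hanley"
) -> ROCResult:
    """Empirical ROC curve and AUC of scores against binary labels.

    The AUC (trapezoid over the tie-aware step curve) equals the
    normalized Mann-Whitney U statistic.  The AUC standard error follows
    Hanley & McNeil by default (``se_method="delong"`` uses the DeLong
    placement-value variance); the 95% CI is normal-theory, clipped to
    [0, 1], and ``p_value`` tests AUC = 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")

    if np.ptp(scores) == 0:
        warnings.warn("constant scores: ROC is the diagonal, AUC = 0.5", stacklevel=2)

    # tie-aware step curve: one operating point per distinct score cutoff
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    cum_tp = np.cumsum(y_sorted == 1)
    cum_fp = np.cumsum(y_sorted == 0)
    idx = np.flatnonzero(np.r_[distinct[1:], True])  # last index of each tie block
    tpr = np.r_[0.0, cum_tp[idx] / n_pos]
    fpr = np.r_[0.0, cum_fp[idx] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]

    auc = float(np.trapezoid(tpr, fpr))

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if se_method == "hanley":
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc**2 / (1.0 + auc)
        var = (
            auc * (1 - auc)
            + (n_pos - 1) * (q1 - auc**2)
            + (n_neg - 1) * (q2 - auc**2)
        ) / (n_pos * n_neg)
        se = math.sqrt(max(var, 0.0))
    elif se_method == "delong":
        # placement values
        v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n_neg for p in pos])
        v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / n_pos for q in neg])
        s10 = v10.var(ddof=1) if n_pos > 1 else 0.0
        s01 = v01.var(ddof=1) if n_neg > 1 else 0.0
        se = math.sqrt(s10 / n_pos + s01 / n_neg)
    else:
        raise ValidationError("se_method must be 'hanley' or 'delong'")

    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    ci = (max(auc - 1.959963984540054 * se, 0.0), min(auc + 1.959963984540054 * se, 1.0))
    return ROCResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc, auc_se=float(se),
        ci95=ci, p_value=p, n_pos=n_pos, n_neg=n_neg, se_method=se_method,
    )


def youden_threshold(roc: ROCResult) -> float:
    """Cutoff maximizing the Youden index J = TPR - FPR.

    Ties are broken toward higher specificity (lower FPR), then toward
    the higher cutoff.  The +inf pseudo-threshold (the predict-nothing
    (0,0) point, J = 0) is returned when no finite cutoff beats it —
    i.e. when the scores carry no positive discrimination.
    """
    j = roc.tpr - roc.fpr
    best = None
    for i in range(len(j)):
        if best is None:
            best = i
            continue
        if j[i] > j[best] + 1e-12:
            best = i
        elif abs(j[i] - j[best]) <= 1e-12:
            if roc.fpr[i] < roc.fpr[best] - 1e-12:
                best = i
            elif (
                abs(roc.fpr[i] - roc.fpr[best]) <= 1e-12
                and roc.thresholds[i] > roc.thresholds[best]
            ):
                best = i
    return float(roc.thresholds[best])


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 classification metrics at one cutoff (NaN where undefined)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    cutoff: float


def confusion_metrics(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> ConfusionMetrics:
    """Sensitivity/specificity/PPV/NPV at a cutoff (positive iff score >= cutoff)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValidationError("both classes must be present")
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))

    def _ratio(num, den):
        return float(num) / den if den > 0 else float("nan")

    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        cutoff=float(cutoff),
    )


# --------------------------------------------------------------------------
# Model-object facade


class GrowthRateModel:
    """Multivariate linear model for the Gompertz growth rate.

    A thin statsmodels-style facade: construct from a feature table,
    ``fit(scheme=...)`` returns a :class:`RegressionResult` for the full
    fit, k-fold CV, or repeated-subsampling CV.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        predictors: Sequence[str],
        response: str = "beta",
    ):
        self.table = table.reset_index(drop=True)
        self.predictors = tuple(predictors)
        self.response = response

    @classmethod
    def from_dataframe(cls, df, predictors, response="beta"):
        return cls(df, predictors, response)

    def fit(
        self,
        scheme: str = "full",
        seed: int = 0,
        k: int = 5,
        train_frac: float = 0.8,
        repeats: int = 100,
    ) -> RegressionResult:
        if scheme == "full":
            return fit_linear(self.table, self.predictors, self.response)
        if scheme == "kfold":
            return kfold_cv(self.table, self.predictors, self.response, k=k, seed=seed)
        if scheme == "subsample":
            return subsample_cv(
                self.table, self.predictors, self.response,
                train_frac=train_frac, repeats=repeats, seed=seed,
            )
        raise ValidationError("scheme must be 'full', 'kfold' or 'subsample'")

    def forward_select(self, candidates=None, **kwargs):
        if candidates is None:
            candidates = self.predictors
        return forward_select(self.table, candidates, self.response, **kwargs)


@dataclass
class ResponderResults:
    """Outputs of the responder classification stage."""

    labels: np.ndarray
    threshold: float
    logistic: LogisticResult
    roc: ROCResult
    cutoff: float
    confusion: ConfusionMetrics
    hl_statistic: float
    hl_df: int
    hl_p: float

    def summary(self) -> str:
        c = self.confusion
        return "\n".join(
            [
                "Responder prediction",
                "=" * 54,
                f"responder threshold (growth rate): {self.threshold:.4g} /day",
                f"responders: {int(self.labels.sum())} / {len(self.labels)}",
                f"separation flagged: {self.logistic.separation}",
                f"ROC AUC = {self.roc.auc:.3f} (SE {self.roc.auc_se:.3f}, "
                f"95% CI {self.roc.ci95[0]:.3f}-{self.roc.ci95[1]:.3f}, "
                f"p = {self.roc.p_value:.3g})",
                f"Youden cutoff = {self.cutoff:.3g}",
                f"sensitivity {100 * c.sensitivity:.1f}%  "
                f"specificity {100 * c.specificity:.1f}%  "
                f"PPV {100 * c.ppv:.1f}%  NPV {100 * c.npv:.1f}%",
                f"Hosmer-Lemeshow chi2 = {self.hl_statistic:.3g} "
                f"(df {self.hl_df}, p = {self.hl_p:.3g})",
                "=" * 54,
            ]
        )


class ResponderModel:
    """Treatment-response classifier built on the growth-rate percentile rule.

    Labels animals as responders when their fitted growth rate falls
    below the 25th percentile (configurable) of the untreated group, fits
    a multiple logistic regression of the labels on the supplied
    predictors, and evaluates it with Hosmer-Lemeshow, ROC/Youden and
    confusion metrics.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        predictors: Sequence[str],
        beta_col: str = "beta",
        group_col: str = "group",
        percentile: float = 25.0,
    ):
        self.table = table.reset_index(drop=True)
        self.predictors = tuple(predictors)
        self.beta_col = beta_col
        self.group_col = group_col
        self.percentile = percentile

    def fit(self, hl_groups: int | None = None) -> ResponderResults:
        betas = self.table[self.beta_col].to_numpy(dtype=float)
        control = self.table[self.group_col].to_numpy() == 0
        labels, threshold = label_responders(betas, control, self.percentile)
        logistic = fit_logistic(self.table, self.predictors, labels)
        roc = roc_analysis(logistic.probabilities, labels)
        cutoff = youden_threshold(roc)
        conf = confusion_metrics(logistic.probabilities, labels, cutoff)
        if hl_groups is None:
            hl_groups = max(2, min(10, len(labels) // 2))
        try:
            hl_stat, hl_df, hl_p = hosmer_lemeshow(
                logistic.probabilities, labels, groups=hl_groups
            )
        except ValidationError:
            hl_stat, hl_df, hl_p = float("nan"), 0, float("nan")
        return ResponderResults(
            labels=labels, threshold=threshold, logistic=logistic, roc=roc,
            cutoff=cutoff, confusion=conf,
            hl_statistic=hl_stat, hl_df=hl_df, hl_p=hl_p,
        )
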