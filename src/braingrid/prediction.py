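"""Symptom and diagnosis prediction models.

* Univariable and forward-conditional multivariable binary logistic
  regression for onset symptoms (seizure, cognitive deficit), reported as
  odds ratios with Wald 95% confidence intervals.
* Baseline-category multinomial logistic regression for the three molecular
  subgroups, with a collinearity (VIF) gate.
* One-vs-rest ROC/AUC and the closed-form prevalence-adjusted positive and
  negative predictive values

      PPV = Se*pi / (Se*pi + (1 - Sp)(1 - pi))
      NPV = Sp*(1 - pi) / (Sp*(1 - pi) + (1 - Se)*pi)

  where pi is the class prevalence.

Fragile fits are flagged rather than silently reported: complete separation
is detected from exploding standardized coefficients or failed convergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve

from .errors import InvalidDesignError, UndefinedMetricError

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorEffect",
    "LogisticFit",
    "MultinomialModel",
    "ROCResult",
    "PredictionMetrics",
    "fit_binary_logistic",
    "forward_conditional_select",
    "check_collinearity",
    "fit_multinomial",
    "roc_auc",
    "ppv_npv",
    "classification_metrics",
]

SEPARATION_COEF_BOUND = 15.0  # |coef| on standardized predictors beyond this -> flagged


@dataclass
class PredictorEffect:
    variable: str
    coef: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    flag: str | None = None


@dataclass
class LogisticFit:
    effects: list[PredictorEffect]
    loglik: float
    selected: list[str] = field(default_factory=list)
    intercept: float | None = None

    def effect(self, variable: str) -> PredictorEffect:
        for e in self.effects:
            if e.variable == variable:
                return e
        raise KeyError(variable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": e.variable,
                    "P": e.p_value,
                    "OR": e.odds_ratio,
                    "CI_low": e.ci_low,
                    "CI_high": e.ci_high,
                    "flag": e.flag or "",
                }
                for e in self.effects
            ]
        )


def _as_design(predictors) -> pd.DataFrame:
    X = pd.DataFrame(predictors).copy()
    X.columns = [str(c) for c in X.columns]
    return X.astype(float)


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant predictor(s): {const}", stacklevel=3)
        X = X.drop(columns=const)
    return X


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        try:
            res = model.fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            # Newton blows up under (near-)complete separation; retry with a
            # gradient method so the fit can be reported flagged, not crashed
            res = model.fit(disp=0, maxiter=500, method="bfgs")
    return res


def _separation_flag(res, X: pd.DataFrame) -> str | None:
    if not res.mle_retvals.get("converged", True):
        return "non-estimable (no convergence; possible separation)"
    sds = X.std(ddof=0).replace(0, 1.0)
    std_coefs = res.params.drop("const") * sds.reindex(res.params.drop("const").index)
    if (std_coefs.abs() > SEPARATION_COEF_BOUND).any():
        return "non-estimable (separation suspected)"
    return None


def _effects_from(res, X: pd.DataFrame, flag: str | None) -> list[PredictorEffect]:
    out = []
    ci = res.conf_int(alpha=0.05)
    for var in X.columns:
        coef = float(res.params[var])
        out.append(
            PredictorEffect(
                variable=var,
                coef=coef,
                odds_ratio=float(np.exp(coef)),
                ci_low=float(np.exp(ci.loc[var, 0])),
                ci_high=float(np.exp(ci.loc[var, 1])),
                p_value=float(res.pvalues[var]),
                flag=flag,
            )
        )
    return out


def fit_binary_logistic(outcome, predictors, univariable: bool = False) -> LogisticFit | list[LogisticFit]:
    """Maximum-likelihood binary logistic regression.

    With ``univariable=True`` each predictor is fit in its own one-predictor
    model (the univariable screen of a symptom table); otherwise a single
    joint model is fit.  Confidence intervals are Wald: exp(coef +- 1.96 SE).
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise InvalidDesignError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise InvalidDesignError("outcome has a single class")
    X = _drop_constant(_as_design(predictors))
    if X.shape[1] == 0:
        raise InvalidDesignError("no usable predictors")

    if univariable:
        fits = []
        for col in X.columns:
            Xc = X[[col]]
            res = _fit_logit(y, Xc)
            flag = _separation_flag(res, Xc)
            fits.append(
                LogisticFit(
                    effects=_effects_from(res, Xc, flag),
                    loglik=float(res.llf),
                    intercept=float(res.params["const"]),
                )
            )
        return fits

    res = _fit_logit(y, X)
    flag = _separation_flag(res, X)
    return LogisticFit(
        effects=_effects_from(res, X, flag),
        loglik=float(res.llf),
        selected=list(X.columns),
        intercept=float(res.params["const"]),
    )


def _score_test_add(y: np.ndarray, X_current: pd.DataFrame, x_new: np.ndarray) -> float:
    """Rao score test p-value for adding one column to a fitted logit.

    Computed at the restricted MLE: U = x'(y - p), V = x'Wx - x'WZ (Z'WZ)^-1 Z'Wx
    with W = diag(p(1-p)) and Z the current design (incl. intercept).
    """
    Z = sm.add_constant(X_current, has_constant="add").to_numpy(float)
    res = _fit_logit(y, X_current) if X_current.shape[1] else None
    if res is None:
        p0 = np.full_like(y, y.mean(), dtype=float)
        Z = np.ones((len(y), 1))
    else:
        p0 = np.asarray(res.predict())
    w = p0 * (1 - p0)
    x = np.asarray(x_new, float)
    U = float(x @ (y - p0))
    ZtWZ = Z.T @ (Z * w[:, None])
    ZtWx = Z.T @ (x * w)
    V = float(x @ (x * w) - ZtWx @ np.linalg.solve(ZtWZ, ZtWx))
    if V <= 1e-10:
        return 1.0  # direction already spanned by the current model
    return float(stats.chi2.sf(U * U / V, df=1))


def _lr_test_drop(y: np.ndarray, X: pd.DataFrame, var: str) -> float:
    full = _fit_logit(y, X)
    reduced = _fit_logit(y, X.drop(columns=[var])) if X.shape[1] > 1 else None
    ll0 = reduced.llf if reduced is not None else sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
    lr = 2 * (full.llf - ll0)
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def forward_conditional_select(
    outcome, candidates, p_enter: float = 0.05, p_remove: float = 0.10
) -> LogisticFit:
    """Forward-conditional stepwise logistic model building.

    Entry by Rao score test (p < ``p_enter``), removal by likelihood-ratio
    test (p > ``p_remove``); ties broken by candidate order.  With no
    admissible candidate the intercept-only model is returned, flagged.
    """
    if p_enter >= p_remove:
        raise InvalidDesignError("require p_enter < p_remove")
    y = np.asarray(outcome, dtype=float)
    X = _drop_constant(_as_design(candidates))
    if X.shape[1] == 0:
        raise InvalidDesignError("no candidates")

    selected: list[str] = []
    while True:
        remaining = [c for c in X.columns if c not in selected]
        entered = False
        if remaining:
            pvals = [
                _score_test_add(y, X[selected], X[c].to_numpy(float)) for c in remaining
            ]
            best = int(np.argmin(pvals))  # first minimum wins the tie
            if pvals[best] < p_enter:
                selected.append(remaining[best])
                entered = True
        removed = False
        while len(selected) > 0:
            drop_p = [_lr_test_drop(y, X[selected], v) for v in selected]
            worst = int(np.argmax(drop_p))
            if drop_p[worst] > p_remove:
                selected.pop(worst)
                removed = True
            else:
                break
        if not entered and not removed:
            break

    if not selected:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        logger.warning("forward selection admitted no candidate; intercept-only model")
        return LogisticFit(
            effects=[], loglik=float(res.llf), selected=[], intercept=float(res.params[0])
        )
    res = _fit_logit(y, X[selected])
    flag = _separation_flag(res, X[selected])
    return LogisticFit(
        effects=_effects_from(res, X[selected], flag),
        loglik=float(res.llf),
        selected=list(selected),
        intercept=float(res.params["const"]),
    )


def check_collinearity(predictors, flag_threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factors; VIF above ``flag_threshold`` is flagged.

    Exactly collinear columns yield infinite VIF and are flagged, not raised.
    """
    X = _as_design(predictors)
    n, p = X.shape
    if p < 2:
        raise InvalidDesignError("collinearity check needs >= 2 predictors")
    if n <= p:
        raise InvalidDesignError("need more observations than predictors")
    rows = []
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]), has_constant="add")
        r2 = sm.OLS(X[col], others).fit().rsquared
        vif = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"variable": col, "vif": float(vif), "flagged": bool(vif > flag_threshold)})
    return pd.DataFrame(rows)


@dataclass
class MultinomialModel:
    reference: str
    classes: list[str]  # reference first
    params: pd.DataFrame  # rows: const + predictors; columns: non-reference classes
    probabilities: pd.DataFrame  # per-patient class probabilities, columns = classes

    def predicted_class(self) -> np.ndarray:
        return self.probabilities.idxmax(axis=1).to_numpy()


def fit_multinomial(class_labels, predictors=None, reference: str | None = None) -> MultinomialModel:
    """Baseline-category multinomial logit; reference-class coefficients are 0."""
    labels = pd.Series(class_labels).astype(str)
    classes = list(pd.unique(labels))
    if len(classes) < 2:
        raise InvalidDesignError("need >= 2 outcome classes")
    if (labels.value_counts() == 0).any():
        raise InvalidDesignError("empty outcome class")
    if reference is None:
        reference = classes[0]
    if reference not in classes:
        raise InvalidDesignError(f"reference class {reference!r} absent from labels")
    ordered = [reference] + [c for c in classes if c != reference]
    codes = labels.map({c: i for i, c in enumerate(ordered)}).to_numpy()

    if predictors is None or (hasattr(predictors, "shape") and np.size(predictors) == 0):
        X = pd.DataFrame(index=range(len(labels)))
    else:
        X = _drop_constant(_as_design(predictors))
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(codes, design).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            res = None
        if res is None or np.isnan(np.asarray(res.params)).any():
            # separation: Newton diverges; a gradient method still yields
            # usable (if extreme) probabilities
            res = sm.MNLogit(codes, design).fit(disp=0, maxiter=1000, method="bfgs")
    params = pd.DataFrame(
        res.params.to_numpy(), index=design.columns, columns=ordered[1:]
    )
    probs = pd.DataFrame(np.asarray(res.predict(design)), columns=ordered)
    return MultinomialModel(
        reference=reference, classes=ordered, params=params, probabilities=probs
    )


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, binary_truth) -> ROCResult:
    """ROC curve and trapezoidal AUC; equals the tie-corrected rank statistic."""
    y = np.asarray(binary_truth, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise InvalidDesignError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return ROCResult(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def ppv_npv(sensitivity: float, specificity: float, prevalence: float) -> tuple[float, float]:
    """Prevalence-adjusted positive and negative predictive values."""
    se, sp, pi = float(sensitivity), float(specificity), float(prevalence)
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise UndefinedMetricError("sensitivity/specificity must lie in [0, 1]")
    if not (0 < pi < 1):
        raise UndefinedMetricError("prevalence must lie strictly in (0, 1)")
    ppv_den = se * pi + (1 - sp) * (1 - pi)
    npv_den = sp * (1 - pi) + (1 - se) * pi
    if ppv_den == 0 or npv_den == 0:
        raise UndefinedMetricError("predictive value undefined (zero denominator)")
    return se * pi / ppv_den, sp * (1 - pi) / npv_den


@dataclass
class PredictionMetrics:
    class_name: str
    sensitivity: float
    specificity: float
    prevalence: float
    auc: float
    ppv: float
    npv: float
    flag: str | None = None


def classification_metrics(model: MultinomialModel, truth) -> list[PredictionMetrics]:
    """One-vs-rest metrics per class from argmax assignment of the model.

    Sensitivity/specificity come from the argmax confusion matrix; AUC from
    the class's predicted probability; PPV/NPV from the closed form at the
    observed class prevalence.  A class the model never predicts is reported
    with sensitivity 0 and flagged.
    """
    y = pd.Series(truth).astype(str).to_numpy()
    if len(y) != len(model.probabilities):
        raise InvalidDesignError("truth and model predictions must align")
    pred = model.predicted_class()
    out = []
    for cls in model.classes:
        pos = y == cls
        hat = pred == cls
        tp = int(np.sum(pos & hat))
        fn = int(np.sum(pos & ~hat))
        fp = int(np.sum(~pos & hat))
        tn = int(np.sum(~pos & ~hat))
        se = tp / (tp + fn) if tp + fn else 0.0
        sp = tn / (tn + fp) if tn + fp else 0.0
        pi = pos.mean()
        auc_val = roc_auc(model.probabilities[cls].to_numpy(), pos.astype(float)).auc
        flag = None
        if hat.sum() == 0:
            flag = "class never predicted by argmax"
        try:
            ppv, npv = ppv_npv(se, sp, pi)
        except UndefinedMetricError:
            ppv, npv = float("nan"), float("nan")
            flag = (flag or "") + " predictive values undefined"
        out.append(
            PredictionMetrics(
                class_name=cls,
                sensitivity=se,
                specificity=sp,
                prevalence=float(pi),
                auc=auc_val,
                ppv=float(ppv),
                npv=float(npv),
                flag=flag,
            )
        )
    return out


def metrics_frame(metrics: list[PredictionMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": m.class_name,
                "Se": m.sensitivity,
                "Sp": m.specificity,
                "prevalence": m.prevalence,
                "AUC": m.auc,
                "PPV": m.ppv,
                "NPV": m.npv,
                "flag": m.flag or "",
            }
            for m in metrics
        ]
    )
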