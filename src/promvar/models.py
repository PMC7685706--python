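"""Single-feature association tests and multi-feature causality predictors.

Single-feature tests: logistic regression of the causal/non-causal label on
one Z-scored feature plus two covariates (library and baseline expression),
with a likelihood-ratio chi-square(1) p-value against the covariate-only
model and q-values over all features.

Prediction: a registry of 112 feature-subset models, each trained with
repeated stratified 10-fold cross-validation on a 90% split (selection
metric Cohen's Kappa for classification, RMSE for regression of the
absolute log fold-change) and evaluated on the held-out 10% (AUC, or
Spearman rho plus full-data R^2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import (
    RepeatedKFold,
    RepeatedStratifiedKFold,
    train_test_split,
)

from .testing import adjust_fdr

N_MODELS = 112


@dataclass
class SingleFeatureResult:
    feature: str
    beta: float
    p: float
    q: float = np.nan
    separation: bool = False


def _loglik_logistic(y: np.ndarray, X: np.ndarray, penalized: bool) -> tuple[float, np.ndarray, bool]:
    """Log-likelihood and coefficients of a logistic fit; falls back to a
    weak ridge penalty when ML fails (perfect separation)."""
    if not penalized:
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if np.isfinite(fit.llf) and fit.mle_retvals.get("converged", True):
                return float(fit.llf), np.asarray(fit.params), False
        except Exception:
            pass
    clf = LogisticRegression(C=100.0, max_iter=2000)
    clf.fit(X[:, 1:], y)  # sklearn adds its own intercept
    prob = np.clip(clf.predict_proba(X[:, 1:])[:, 1], 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return llf, params, True


def single_feature_test(
    labels, feature, covariates: pd.DataFrame
) -> SingleFeatureResult:
    """Likelihood-ratio test of one feature's association with causality,
    adjusting for the library and baseline-expression covariates."""
    y = np.asarray(labels, dtype=float)
    x = np.asarray(feature, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    ok = np.isfinite(x) & np.all(np.isfinite(cov), axis=1)
    y, x, cov = y[ok], x[ok], cov[ok]
    if np.std(x) == 0:
        raise ValueError("constant feature; exclude upstream")
    X_red = np.column_stack([np.ones(len(y)), cov])
    X_full = np.column_stack([X_red, x])
    ll_full, params, sep_full = _loglik_logistic(y, X_full, penalized=False)
    ll_red, _, sep_red = _loglik_logistic(y, X_red, penalized=sep_full)
    lr = max(2.0 * (ll_full - ll_red), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    name = feature.name if hasattr(feature, "name") else "feature"
    return SingleFeatureResult(
        feature=str(name), beta=float(params[-1]), p=max(p, np.finfo(float).tiny),
        separation=sep_full or sep_red,
    )


def single_feature_tests(
    features: pd.DataFrame, labels, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Run the single-feature test for every column; attach q-values."""
    results = [
        single_feature_test(labels, features[col], covariates)
        for col in features.columns
    ]
    out = pd.DataFrame([r.__dict__ for r in results])
    out["q"] = adjust_fdr(out["p"].to_numpy())
    return out


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    non_tf: bool
    contexts: tuple[str, ...]  # subset of (plus, minus, agnostic)
    strengths: tuple[str, ...]  # subset of (strong, weak)
    aggregated: bool
    significant_only: bool
    task: str = "classify"


def build_model_registry(task: str = "classify") -> list[ModelSpec]:
    """Deterministic enumeration of the feature-subset flag axes, trimmed to
    the first 112 valid combinations; a user-supplied registry may replace it."""
    context_subsets = [
        ("plus", "minus", "agnostic"), ("plus", "minus"), ("plus", "agnostic"),
        ("minus", "agnostic"), ("plus",), ("minus",), ("agnostic",), (),
    ]
    strength_subsets = [("strong", "weak"), ("strong",), ("weak",), ()]
    specs = []
    for non_tf, ctx, strength, agg, sig in itertools.product(
        (True, False), context_subsets, strength_subsets, (True, False), (False, True)
    ):
        if (len(ctx) == 0) != (len(strength) == 0):
            continue  # TF features need both a context and a strength choice
        if not ctx and not non_tf and not agg:
            continue  # no features at all
        specs.append(
            ModelSpec(
                model_id=f"m{len(specs):03d}",
                non_tf=non_tf, contexts=ctx, strengths=strength,
                aggregated=agg, significant_only=sig, task=task,
            )
        )
        if len(specs) == N_MODELS:
            break
    return specs


_STRENGTH_OF_METRIC = {
    "best_strong": "strong", "mean_strong": "strong", "n_strong": "strong",
    "best_weak": "weak", "mean_weak": "weak",
}


def _classify_column(col: str, tf_names: set[str]) -> tuple[str, str | None, str | None]:
    """Column kind: ("tf"|"agg"|"nontf", context, strength)."""
    if col.startswith("agg_"):
        parts = col.split("_")
        context = parts[1]
        strength = "strong" if "strong" in parts else ("weak" if "weak" in parts else None)
        return "agg", context, strength or "strong"
    for metric, strength in _STRENGTH_OF_METRIC.items():
        for context in ("plus", "minus", "agnostic"):
            suffix = f"_{context}_{metric}"
            if col.endswith(suffix) and col[: -len(suffix)] in tf_names:
                return "tf", context, strength
    return "nontf", None, None


def select_features(
    spec: ModelSpec,
    columns,
    tf_names,
    significant: set[str] | None = None,
) -> list[str]:
    """Columns of the feature matrix that a model spec selects."""
    tf_names = set(tf_names)
    out = []
    for col in columns:
        kind, context, strength = _classify_column(col, tf_names)
        if kind == "nontf":
            keep = spec.non_tf
        elif kind == "tf":
            keep = context in spec.contexts and strength in spec.strengths
        else:  # aggregated summaries
            keep = spec.aggregated and context in (spec.contexts or ("plus", "minus", "agnostic"))
        if keep and spec.significant_only and significant is not None:
            keep = col in significant
        if keep:
            out.append(col)
    return out


@dataclass
class PredictionResult:
    model_id: str
    n_features: int
    cv_metric: float  # mean Kappa (classify) or RMSE (regress) across folds
    test_auc: float = np.nan
    test_rho: float = np.nan
    full_r2: float = np.nan
    test_index: np.ndarray = field(default=None, repr=False)


def drop_na_features(features: pd.DataFrame) -> pd.DataFrame:
    """Exclude features carrying any NA value (the models use complete
    columns only)."""
    return features.loc[:, features.notna().all(axis=0)]


def fit_and_evaluate(
    spec: ModelSpec,
    features: pd.DataFrame,
    target,
    tf_names,
    split_seed: int = 0,
    significant: set[str] | None = None,
    n_splits: int = 10,
    n_repeats: int = 5,
) -> PredictionResult:
    """Train one registry model and evaluate it on the held-out 10%.

    ``target`` is the boolean causality label for classification or the
    absolute log2 fold-change for regression.
    """
    usable = drop_na_features(features)
    cols = select_features(spec, usable.columns, tf_names, significant)
    if not cols:
        raise ValueError(f"model {spec.model_id} selects no available feature")
    X = usable[cols].to_numpy(dtype=float)
    y = np.asarray(target)

    if spec.task == "classify":
        y = y.astype(int)
        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx, test_size=0.1, stratify=y, random_state=split_seed
        )
        cv = RepeatedStratifiedKFold(
            n_splits=n_splits, n_repeats=n_repeats, random_state=split_seed
        )
        kappas = []
        for tr, va in cv.split(X[train_idx], y[train_idx]):
            model = LogisticRegression(C=1e6, max_iter=2000)
            model.fit(X[train_idx][tr], y[train_idx][tr])
            pred = (model.predict_proba(X[train_idx][va])[:, 1] >= 0.5).astype(int)
            kappas.append(cohen_kappa_score(y[train_idx][va], pred))
        final = LogisticRegression(C=1e6, max_iter=2000)
        final.fit(X[train_idx], y[train_idx])
        auc = roc_auc_score(y[test_idx], final.predict_proba(X[test_idx])[:, 1])
        return PredictionResult(
            model_id=spec.model_id, n_features=len(cols),
            cv_metric=float(np.mean(kappas)), test_auc=float(auc),
            test_index=test_idx,
        )

    if spec.task == "regress":
        y = y.astype(float)
        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx, test_size=0.1, random_state=split_seed
        )
        cv = RepeatedKFold(
            n_splits=n_splits, n_repeats=n_repeats, random_state=split_seed
        )
        rmses = []
        for tr, va in cv.split(X[train_idx]):
            model = LinearRegression()
            model.fit(X[train_idx][tr], y[train_idx][tr])
            resid = y[train_idx][va] - model.predict(X[train_idx][va])
            rmses.append(float(np.sqrt(np.mean(resid**2))))
        final = LinearRegression().fit(X[train_idx], y[train_idx])
        pred = final.predict(X[test_idx])
        rho = stats.spearmanr(y[test_idx], pred).statistic
        full = LinearRegression().fit(X, y)
        r2 = full.score(X, y)
        return PredictionResult(
            model_id=spec.model_id, n_features=len(cols),
            cv_metric=float(np.mean(rmses)), test_rho=float(rho),
            full_r2=float(r2), test_index=test_idx,
        )

    raise ValueError(f"unknown task {spec.task!r}")
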