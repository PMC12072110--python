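"""Logistic-regression and random-forest modelling of MRD status.

Covers the patient-level analysis suite: maximum-likelihood logistic
regression (full "enter" model and forward selection by the efficient
score test), Nagelkerke's pseudo-R², the Hosmer-Lemeshow
goodness-of-fit test on deciles of risk, stratified random-forest
classification with out-of-bag permutation importance (mean decrease
in accuracy, MDA) and total Gini impurity decrease (MDG), and the
agreement statistics used to report classifier performance: exact
Clopper-Pearson confidence intervals, Cohen's kappa and the
continuity-corrected McNemar test.

The logistic MLE is delegated to statsmodels; score-test entry, the
importance metrics and the agreement statistics are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "LogisticFit", "fit_logistic", "nagelkerke_r2", "forward_select",
    "StepwisePath", "StepRecord", "HLTest", "hosmer_lemeshow",
    "RFConfig", "train_rf_eval", "ClassifierEval",
    "cohen_kappa", "mcnemar_cc", "clopper_pearson", "oob_permutation_importance",
]

_Z975 = 1.96  # normal quantile used for reported Wald-type OR intervals


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic model with the reporting-style summaries."""

    coefficients: pd.DataFrame  # index = variables + "const"
    minus2ll: float
    ll: float
    ll_null: float
    nagelkerke: float
    accuracy: float     # classification table at probability cutoff 0.5 (%)
    sensitivity: float
    specificity: float
    converged: bool
    n: int
    variables: tuple[str, ...]
    fitted_probabilities: np.ndarray = field(repr=False, default=None)


def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke's rescaling of the Cox-Snell pseudo-R²."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if ll_full < ll_null - 1e-8:
        raise ValueError("full-model log-likelihood below null log-likelihood")
    r2_cs = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    return float(r2_cs / max_cs) if max_cs > 0 else 0.0


def _prepare(features, labels):
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if features is None:
        X = pd.DataFrame(index=range(len(y)))
    else:
        X = pd.DataFrame(features).reset_index(drop=True)
    if len(X) != len(y):
        raise ValueError("features and labels length mismatch")
    if len(y) < 10:
        raise ValueError("at least 10 observations are required")
    return X, y


def fit_logistic(features, labels, variables: tuple[str, ...] | None = None,
                 tol: float = 1e-8, maxiter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald summaries.

    ``features`` may be None/empty for the intercept-only null model.
    Perfect separation is flagged through ``converged=False`` (a
    quasi-Newton fallback still reports coefficients).
    """
    X, y = _prepare(features, labels)
    if variables is not None:
        X = X[list(variables)]
    names = list(X.columns)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add") \
        if names else np.ones((len(y), 1))
    model = sm.Logit(y, design)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # perfect separation or singular information
            res = model.fit(disp=0, method="bfgs", maxiter=500)
            converged = False
    params = np.atleast_1d(res.params)
    bse = np.atleast_1d(res.bse)
    order = names + ["const"] if names else ["const"]
    # statsmodels puts the constant first when added via add_constant
    idx = list(range(1, len(order))) + [0] if names else [0]
    b, se = params[idx], bse[idx]
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        wald = (b / se) ** 2
        table = pd.DataFrame({
            "B": b, "SE": se, "Wald": wald,
            "p": sps.chi2.sf(wald, df=1),
            "OR": np.exp(b),
            "CI_low": np.exp(b - _Z975 * se),
            "CI_high": np.exp(b + _Z975 * se),
        }, index=order)

    probs = np.asarray(res.predict(design))
    pred = (probs > 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    accuracy = 100.0 * (tp + tn) / len(y)
    sens = 100.0 * tp / (y == 1).sum()
    spec = 100.0 * tn / (y == 0).sum()

    ll = float(res.llf)
    ll_null = float(res.llnull) if names else ll
    return LogisticFit(
        coefficients=table, minus2ll=-2.0 * ll, ll=ll, ll_null=ll_null,
        nagelkerke=nagelkerke_r2(ll_null, ll, len(y)),
        accuracy=accuracy, sensitivity=sens, specificity=spec,
        converged=converged, n=len(y), variables=tuple(names),
        fitted_probabilities=probs,
    )


def _score_test_stat(design: np.ndarray, y: np.ndarray, p_hat: np.ndarray,
                     x_new: np.ndarray) -> tuple[float, float]:
    w = p_hat * (1.0 - p_hat)
    u = float(x_new @ (y - p_hat))
    info = design.T @ (design * w[:, None])
    cross = design.T @ (x_new * w)
    var = float(x_new @ (x_new * w) - cross @ np.linalg.solve(info, cross))
    if var <= 0:
        return 0.0, 1.0
    chi2 = u * u / var
    return chi2, float(sps.chi2.sf(chi2, df=1))


def score_test(features: pd.DataFrame, labels, current: tuple[str, ...],
               candidate: str) -> tuple[float, float]:
    """Efficient score test for adding ``candidate`` to the current model.

    Evaluated at the restricted MLE: U = x'(y - p̂) and the model-based
    variance of U with the current design projected out.
    """
    X, y = _prepare(features, labels)
    base = fit_logistic(X, y, variables=current)
    design = sm.add_constant(X[list(current)].to_numpy(dtype=float),
                             has_constant="add") \
        if current else np.ones((len(y), 1))
    x_new = X[candidate].to_numpy(dtype=float)
    return _score_test_stat(design, y, base.fitted_probabilities, x_new)


@dataclass(frozen=True)
class HLTest:
    """Hosmer-Lemeshow goodness of fit over g risk groups (df = g - 2)."""

    chi2: float
    df: int
    p: float
    g: int
    degenerate: bool = False


def hosmer_lemeshow(probabilities, labels, g: int = 10) -> HLTest:
    """Deciles-of-risk chi-square: sum (O-E)²/(E(1-E/n_g)) over groups.

    Groups are equal-count bins of the sorted probabilities; bins that
    collapse onto identical probability values are merged and the
    result flagged degenerate when fewer than 3 groups survive.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if g < 3:
        raise ValueError("g must be >= 3")
    if p.size < g:
        raise ValueError("need at least g observations")
    order = np.argsort(p, kind="stable")
    bins = [b for b in np.array_split(order, g) if b.size]
    # merge adjacent bins whose probability ranges coincide exactly
    merged: list[np.ndarray] = []
    for b in bins:
        if merged and p[merged[-1]].max() == p[b].min() == p[b].max() == p[merged[-1]].min():
            merged[-1] = np.concatenate([merged[-1], b])
        else:
            merged.append(b)
    g_eff = len(merged)
    chi2 = 0.0
    for b in merged:
        n_g = b.size
        e = p[b].sum()
        o = y[b].sum()
        denom = e * (1.0 - e / n_g)
        if denom > 0:
            chi2 += (o - e) ** 2 / denom
    df = g_eff - 2
    if df < 1:
        return HLTest(float(chi2), df, float("nan"), g_eff, degenerate=True)
    return HLTest(float(chi2), df, float(sps.chi2.sf(chi2, df)), g_eff,
                  degenerate=g_eff < g)


@dataclass(frozen=True)
class StepRecord:
    step: int
    entered: str | None
    removed: tuple[str, ...]
    fit: LogisticFit
    hl: HLTest | None


@dataclass(frozen=True)
class StepwisePath:
    steps: tuple[StepRecord, ...]

    @property
    def minus2ll_path(self) -> list[float]:
        return [s.fit.minus2ll for s in self.steps]

    @property
    def entry_order(self) -> list[str]:
        return [s.entered for s in self.steps if s.entered]

    def final_fit(self) -> LogisticFit | None:
        return self.steps[-1].fit if self.steps else None


def forward_select(features, labels, p_enter: float = 0.05,
                   p_remove: float = 0.10, hl_groups: int = 10) -> StepwisePath:
    """Forward-selection logistic regression with score-test entry.

    At each step the unentered variable with the smallest score-test p
    below ``p_enter`` is added; entered variables whose Wald p exceeds
    ``p_remove`` are then removed.  Each step snapshots the fit and the
    Hosmer-Lemeshow test.  An empty path means no variable qualified.
    """
    X, y = _prepare(features, labels)
    current: list[str] = []
    records: list[StepRecord] = []
    seen_states = {frozenset()}
    step = 0
    while True:
        candidates = [c for c in X.columns if c not in current]
        if not candidates:
            break
        base = fit_logistic(X, y, variables=tuple(current))
        design = sm.add_constant(X[list(current)].to_numpy(dtype=float),
                                 has_constant="add") \
            if current else np.ones((len(y), 1))
        pvals = {c: _score_test_stat(design, y, base.fitted_probabilities,
                                     X[c].to_numpy(dtype=float))[1]
                 for c in candidates}
        best = min(pvals, key=pvals.get)
        if pvals[best] >= p_enter:
            break
        current.append(best)
        removed: list[str] = []
        while True:
            fit = fit_logistic(X, y, variables=tuple(current))
            # NaN Wald p (separation-broken SE) is not evidence for removal
            wald_p = fit.coefficients.loc[current, "p"].astype(float).fillna(0.0)
            worst = wald_p.idxmax()
            if wald_p[worst] <= p_remove or len(current) == 1:
                break
            current.remove(worst)
            removed.append(worst)
        state = frozenset(current)
        if state in seen_states:  # enter/remove cycle: stop at the repeat
            break
        seen_states.add(state)
        step += 1
        hl = hosmer_lemeshow(fit.fitted_probabilities, y, g=hl_groups) \
            if len(y) >= hl_groups else None
        records.append(StepRecord(step, best, tuple(removed), fit, hl))
    return StepwisePath(tuple(records))


# ---------------------------------------------------------------------------
# Random forest importance and classifier agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFConfig:
    """Random-forest configuration: 100 trees, 4 features per split,
    stratified 70/30 train/test split (or stratified k-fold when
    ``cv_folds`` is set)."""

    ntree: int = 100
    mtry: int = 4
    train_fraction: float = 0.7
    seed: int = 0
    cv_folds: int | None = None

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds is not None and self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class ClassifierEval:
    """Test-set confusion summary with agreement statistics."""

    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float            # proportion in [0, 1]
    ci: tuple[float, float]    # exact binomial 95% CI for accuracy
    sensitivity: float
    specificity: float
    kappa: float
    mcnemar_chi2: float
    mcnemar_p: float


def clopper_pearson(successes: int, n: int, conf: float = 0.95
                    ) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if not 0 <= successes <= n or n < 1:
        raise ValueError("require 0 <= successes <= n and n >= 1")
    alpha = 1.0 - conf
    lower = 0.0 if successes == 0 else \
        float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else \
        float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def cohen_kappa(tp: int, fn: int, fp: int, tn: int) -> float:
    """Chance-corrected agreement between prediction and truth."""
    n = tp + fn + fp + tn
    if n < 1:
        raise ValueError("at least one observation is required")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def mcnemar_cc(b: int, c: int) -> tuple[float, float]:
    """Continuity-corrected McNemar test on the discordant cells.

    chi² = max(0, |b-c|-1)²/(b+c); the correction is clamped at zero so
    it can never exceed the uncorrected statistic's sign logic.
    """
    if b + c < 1:
        raise ValueError("at least one discordant observation is required")
    chi2 = max(0.0, abs(b - c) - 1.0) ** 2 / (b + c)
    return chi2, float(sps.chi2.sf(chi2, df=1))


def _bootstrap_oob_masks(forest: RandomForestClassifier, n: int):
    """Out-of-bag masks per tree, replicating the forest's bootstrap draws."""
    for tree in forest.estimators_:
        rng = np.random.RandomState(tree.random_state)
        sampled = rng.randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        yield tree, mask


def oob_permutation_importance(forest: RandomForestClassifier,
                               X: np.ndarray, y: np.ndarray,
                               seed: int = 0) -> np.ndarray:
    """Mean decrease in accuracy (percentage points) per feature.

    For each tree, accuracy on its out-of-bag rows is compared with the
    accuracy after permuting one feature among those rows; the decrease
    is averaged over trees.
    """
    rng = np.random.default_rng(seed)
    n, n_feat = X.shape
    classes = forest.classes_

    def predict(tree, block):  # low-level call avoids per-call validation
        proba = tree.tree_.predict(np.ascontiguousarray(block, np.float32))
        return classes[np.argmax(proba.reshape(len(block), -1), axis=1)]

    decreases = np.zeros(n_feat)
    used = 0
    for tree, oob in _bootstrap_oob_masks(forest, n):
        if not oob.any():
            continue
        used += 1
        X_oob, y_oob = X[oob], y[oob]
        base = (predict(tree, X_oob) == y_oob).mean()
        for j in range(n_feat):
            perm = X_oob.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            decreases[j] += base - (predict(tree, perm) == y_oob).mean()
    if used == 0:
        raise ValueError("no out-of-bag rows; cannot compute MDA")
    return 100.0 * decreases / used


def gini_importance(forest: RandomForestClassifier) -> np.ndarray:
    """Mean total Gini impurity decrease per feature (unnormalized)."""
    n_feat = forest.n_features_in_
    totals = np.zeros(n_feat)
    for est in forest.estimators_:
        t = est.tree_
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:
                continue
            w = t.weighted_n_node_samples
            drop = (w[node] * t.impurity[node]
                    - w[left] * t.impurity[left]
                    - w[right] * t.impurity[right])
            totals[t.feature[node]] += drop
    return totals / len(forest.estimators_)


def _eval_from_confusion(tp: int, fn: int, fp: int, tn: int) -> ClassifierEval:
    n = tp + fn + fp + tn
    chi2, p = mcnemar_cc(fp, fn) if fp + fn >= 1 else (0.0, 1.0)
    return ClassifierEval(
        tp=tp, fn=fn, fp=fp, tn=tn, accuracy=(tp + tn) / n,
        ci=clopper_pearson(tp + tn, n),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        kappa=cohen_kappa(tp, fn, fp, tn),
        mcnemar_chi2=chi2, mcnemar_p=p,
    )


def _train_rf_eval_cv(X: np.ndarray, y: np.ndarray, feature_names: list[str],
                      config: RFConfig) -> tuple[pd.DataFrame, ClassifierEval]:
    """Stratified k-fold evaluation; importances from a full-data forest."""
    from sklearn.model_selection import StratifiedKFold
    tp = fn = fp = tn = 0
    splitter = StratifiedKFold(config.cv_folds, shuffle=True,
                               random_state=config.seed)
    for train_idx, test_idx in splitter.split(X, y):
        forest = RandomForestClassifier(
            n_estimators=config.ntree, max_features=config.mtry,
            bootstrap=True, random_state=config.seed).fit(X[train_idx],
                                                          y[train_idx])
        pred = forest.predict(X[test_idx])
        y_test = y[test_idx]
        tp += int(((pred == 1) & (y_test == 1)).sum())
        fn += int(((pred == 0) & (y_test == 1)).sum())
        fp += int(((pred == 1) & (y_test == 0)).sum())
        tn += int(((pred == 0) & (y_test == 0)).sum())
    full = RandomForestClassifier(
        n_estimators=config.ntree, max_features=config.mtry,
        oob_score=True, bootstrap=True, random_state=config.seed).fit(X, y)
    importance = pd.DataFrame(
        {"MDA": oob_permutation_importance(full, X, y, seed=config.seed),
         "MDG": gini_importance(full)}, index=feature_names)
    return importance, _eval_from_confusion(tp, fn, fp, tn)


def train_rf_eval(cohort: pd.DataFrame, config: RFConfig = RFConfig(),
                  label_column: str = "MRD"
                  ) -> tuple[pd.DataFrame, ClassifierEval]:
    """Stratified split, forest fit, importance table and test-set evaluation."""
    y = cohort[label_column].to_numpy()
    X = cohort.drop(columns=[label_column])
    feature_names = list(X.columns)
    if not 1 <= config.mtry <= len(feature_names):
        raise ValueError("mtry must lie in [1, n_features]")
    if config.cv_folds is not None:
        return _train_rf_eval_cv(X.to_numpy(dtype=float), y, feature_names,
                                 config)
    X_train, X_test, y_train, y_test = train_test_split(
        X.to_numpy(dtype=float), y, train_size=config.train_fraction,
        stratify=y, random_state=config.seed)
    for split_y in (y_train, y_test):
        if min(np.bincount(split_y.astype(int), minlength=2)) < 2:
            raise ValueError("each split needs >= 2 samples of each class")

    forest = RandomForestClassifier(
        n_estimators=config.ntree, max_features=config.mtry,
        oob_score=True, bootstrap=True, random_state=config.seed,
    ).fit(X_train, y_train)

    mda = oob_permutation_importance(forest, X_train, y_train, seed=config.seed)
    mdg = gini_importance(forest)
    importance = pd.DataFrame({"MDA": mda, "MDG": mdg}, index=feature_names)

    pred = forest.predict(X_test)
    tp = int(((pred == 1) & (y_test == 1)).sum())
    fn = int(((pred == 0) & (y_test == 1)).sum())
    fp = int(((pred == 1) & (y_test == 0)).sum())
    tn = int(((pred == 0) & (y_test == 0)).sum())
    return importance, _eval_from_confusion(tp, fn, fp, tn)
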