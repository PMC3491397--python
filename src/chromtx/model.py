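"""The two-step expression model: on/off classifier times level regressor.

Roughly 40% of promoters in a typical dataset are not expressed at all, so a
single regression against log expression is dominated by the point mass at
zero.  The two-step model instead predicts

    yhat_i = C(X_i) * R(X_i)

where ``C`` is a random-forests classifier of expression status (1 = "on",
0 = "off") and ``R`` is a regressor of log2 expression level fitted on the
"on" genes only.  Genes classified off are predicted exactly 0.

The module follows the statsmodels idiom: :class:`TwoStepExpressionModel` is
built from a design matrix and expression vector, and ``fit()`` returns a
:class:`TwoStepResults` carrying the estimates, their uncertainties (for the
linear regressor), diagnostics and a ``summary()`` table.  Thin functional
wrappers (``fit_two_step``, ``predict_two_step``, ``crossvalidate``,
``randomization_test``, ``cross_context_apply``) expose the same machinery for
pipeline use.

Evaluation happens on pooled out-of-fold predictions from a ten-fold
cross-validation of the modeling set (D2); the selection set (D1, one third of
genes) is reserved for bin selection and pseudocount optimization upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score

from .binning import BinnedFeatureMatrix, BinSpec, apply_bin_spec, select_bin_spec
from .transforms import (
    PseudocountSpec,
    log2_with_pseudocount,
    optimize_pseudocount,
)

__all__ = [
    "SplitPlan",
    "make_split",
    "FeatureTransform",
    "TwoStepExpressionModel",
    "TwoStepResults",
    "SingleStepModel",
    "EvaluationResult",
    "CrossValidationResult",
    "evaluate",
    "to_log2_with_zeros",
    "fit_two_step",
    "predict_two_step",
    "crossvalidate",
    "crossvalidate_single_step",
    "randomization_test",
    "cross_context_apply",
    "DEFAULT_N_TREES",
]

DEFAULT_N_TREES = 250
MIN_GENES_FOR_SPLIT = 30


# --------------------------------------------------------------------------- #
# splits

@dataclass
class SplitPlan:
    """D1 (selection) / D2 (modeling) split plus the ten folds of D2."""

    d1_ids: np.ndarray
    d2_ids: np.ndarray
    folds: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        d1, d2 = set(self.d1_ids), set(self.d2_ids)
        if d1 & d2:
            raise ValueError("D1 and D2 overlap")
        fold_union = set().union(*(set(f) for f in self.folds))
        if fold_union != d2:
            raise ValueError("folds do not partition D2")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than 1")


def make_split(
    gene_ids, seed: int, d1_fraction: float = 1 / 3, n_folds: int = 10
) -> SplitPlan:
    """Uniform random D1/D2 split with round-robin folds, reproducible by seed."""
    gene_ids = np.asarray(gene_ids)
    n = len(gene_ids)
    if n < MIN_GENES_FOR_SPLIT:
        raise ValueError(f"need at least {MIN_GENES_FOR_SPLIT} genes, got {n}")
    rng = np.random.default_rng(seed)
    shuffled = gene_ids[rng.permutation(n)]
    n_d1 = int(round(n * d1_fraction))
    d1, d2 = shuffled[:n_d1], shuffled[n_d1:]
    folds = [d2[i::n_folds] for i in range(n_folds)]
    return SplitPlan(d1, d2, folds, seed)


# --------------------------------------------------------------------------- #
# per-feature transform state (bestbin + pseudocount), fitted on D1

class FeatureTransform:
    """Fitted preprocessing state: per-feature summary bin(s) and pseudocount.

    ``fit`` runs on the selection set D1 only, in the pipeline's stated order:
    first the bin strategy chooses the summary bin(s) (on provisionally
    log-transformed signal), then the pseudocount is optimized on the frozen
    bin.  Both use only genes with positive expression, because the level
    regression they serve is fit on "on" genes.
    """

    def __init__(self, strategy: str = "bestbin", grid_size: int = 50):
        self.strategy = strategy
        self.grid_size = grid_size
        self.bin_specs: dict[str, BinSpec] = {}
        self.pseudocounts: dict[str, PseudocountSpec] = {}
        self.feature_names: list[str] = []

    def fit(
        self,
        binned: Mapping[str, BinnedFeatureMatrix | pd.DataFrame],
        y: pd.Series,
        d1_ids,
    ) -> "FeatureTransform":
        d1_ids = pd.Index(d1_ids)
        y1 = y.loc[d1_ids]
        on = y1 > 0
        if on.sum() < 3:
            raise ValueError("need at least 3 expressed genes in D1 to fit transforms")
        y_log = np.log2(y1[on].to_numpy())
        self.feature_names = list(binned)
        for name, mat in binned.items():
            df = mat.values if isinstance(mat, BinnedFeatureMatrix) else mat
            sub = df.loc[d1_ids[on.to_numpy()]]
            spec = select_bin_spec(BinnedFeatureMatrix(name, sub), y_log, self.strategy)
            x = apply_bin_spec(sub, spec).to_numpy()
            pc = optimize_pseudocount(x, y_log, self.grid_size, feature_name=name)
            self.bin_specs[name] = spec
            self.pseudocounts[name] = pc
        return self

    def transform(
        self,
        binned: Mapping[str, BinnedFeatureMatrix | pd.DataFrame],
        gene_ids=None,
        extra: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        """Build the genes x features design matrix ``log2(x_j + a_j)``.

        ``extra`` columns (sequence features such as the normalized CpG score,
        which are not binned signal) are appended untransformed.
        """
        if not self.bin_specs:
            raise RuntimeError("transform is not fitted")
        cols = {}
        for name in self.feature_names:
            mat = binned[name]
            df = mat.values if isinstance(mat, BinnedFeatureMatrix) else mat
            if gene_ids is not None:
                df = df.loc[pd.Index(gene_ids)]
            x = apply_bin_spec(df, self.bin_specs[name])
            cols[name] = log2_with_pseudocount(x.to_numpy(), self.pseudocounts[name].a)
        index = df.index
        X = pd.DataFrame(cols, index=index)
        if extra is not None:
            X = X.join(extra.loc[index])
        return X

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "grid_size": self.grid_size,
            "features": {
                name: {
                    "selected_bins": [int(b) for b in self.bin_specs[name].selected_bins],
                    "selection_correlation": float(
                        self.bin_specs[name].selection_correlation
                    ),
                    "pseudocount": float(self.pseudocounts[name].a),
                    "pseudocount_r": float(self.pseudocounts[name].achieved_r),
                }
                for name in self.feature_names
            },
        }


# --------------------------------------------------------------------------- #
# evaluation

@dataclass
class EvaluationResult:
    """Pooled prediction metrics: correlation, RMSE, and classifier accuracy."""

    pcc_r: float
    rmse: float
    auc: float = float("nan")
    classification_accuracy: float = float("nan")
    n_genes: int = 0

    def as_dict(self) -> dict:
        return {
            "pcc_r": self.pcc_r,
            "rmse": self.rmse,
            "auc": self.auc,
            "classification_accuracy": self.classification_accuracy,
            "n_genes": self.n_genes,
        }


def to_log2_with_zeros(y: np.ndarray | pd.Series) -> np.ndarray:
    """log2 of positive expression, with unexpressed genes kept at exactly 0."""
    y = np.asarray(y, dtype=float)
    out = np.zeros_like(y)
    pos = y > 0
    out[pos] = np.log2(y[pos])
    return out


def evaluate(
    y: np.ndarray | pd.Series,
    y_hat: np.ndarray | pd.Series,
    proba: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    threshold: float = 0.5,
    rmse_normalize: str | None = None,
) -> EvaluationResult:
    """Metrics between measured and predicted values on a common (log2) scale.

    ``pcc_r`` is the Pearson correlation (NaN when either side has zero
    variance — an undefined correlation, not 0); ``rmse`` is
    ``sqrt(sum((y - yhat)^2) / n)``.  With ``rmse_normalize="range"`` the RMSE
    is divided by the range of ``y``; the default reports the plain formula.
    AUC and accuracy are computed when classifier vote fractions ``proba`` are
    given, against ``labels`` (default: ``y != 0``).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must be equal-length vectors of size >= 2")
    resid = y - y_hat
    rmse = float(np.sqrt(np.mean(resid**2)))
    if rmse_normalize == "range":
        span = float(np.ptp(y))
        rmse = rmse / span if span > 0 else float("nan")
    if y.std() == 0 or y_hat.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(y, y_hat)[0, 1])
    auc = acc = float("nan")
    if proba is not None:
        proba = np.asarray(proba, dtype=float)
        labels = (y != 0) if labels is None else np.asarray(labels, dtype=bool)
        if labels.any() and not labels.all():
            auc = float(roc_auc_score(labels, proba))
        acc = float(np.mean((proba >= threshold) == labels))
    return EvaluationResult(r, rmse, auc, acc, int(y.size))


# --------------------------------------------------------------------------- #
# the model / results pair

class TwoStepExpressionModel:
    """Two-step expression model built from a design matrix and expression.

    Parameters
    ----------
    X : genes x features design matrix (already transformed, e.g. by
        :class:`FeatureTransform`).
    y : linear-scale expression (RPM/RPKM-like); zeros mean "off".
    method : regressor for the level step: ``"linear"`` (OLS, with standard
        errors) or ``"rf"`` (random forests).  ``"mars"`` is a recognized but
        unimplemented option (no MARS backend is bundled).
    seed : controls both forests; refitting with the same seed reproduces the
        model exactly.
    n_estimators : trees per forest (default 250).
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series,
        method: str = "linear",
        seed: int = 0,
        n_estimators: int = DEFAULT_N_TREES,
        threshold: float = 0.5,
        transform: FeatureTransform | None = None,
    ):
        if method not in ("linear", "rf", "mars"):
            raise ValueError(f"unknown regression method {method!r}")
        if method == "mars":
            raise NotImplementedError(
                "MARS regression requires an external earth-style backend; "
                "use method='linear' or method='rf'"
            )
        X = pd.DataFrame(X)
        y = pd.Series(y).loc[X.index]
        if not np.isfinite(X.to_numpy()).all():
            raise ValueError("design matrix must be finite")
        if (np.asarray(y, dtype=float) < 0).any():
            raise ValueError("expression must be >= 0")
        self.X = X
        self.y = y
        self.method = method
        self.seed = seed
        self.n_estimators = n_estimators
        self.threshold = threshold
        self.transform = transform
        self.feature_names = list(X.columns)

    def fit(self) -> "TwoStepResults":
        labels = (self.y > 0).to_numpy()
        if not labels.any():
            raise ValueError("no expressed ('on') genes: cannot fit the level regressor")
        Xv = self.X.to_numpy()
        if labels.all():
            warnings.warn(
                "no 'off' genes: classifier degenerates to constant 1", stacklevel=2
            )
            classifier = _ConstantClassifier(1.0)
        else:
            classifier = RandomForestClassifier(
                n_estimators=self.n_estimators,
                random_state=np.random.RandomState(self.seed),
                n_jobs=1,
            ).fit(Xv, labels)

        X_on = self.X.loc[labels]
        y_log_on = np.log2(self.y[labels].to_numpy())
        ols_fit = None
        if self.method == "linear":
            ols_fit = sm.OLS(y_log_on, sm.add_constant(X_on, has_constant="add")).fit()
            regressor = ols_fit
        else:
            regressor = RandomForestRegressor(
                n_estimators=self.n_estimators,
                random_state=np.random.RandomState(self.seed + 1),
                n_jobs=1,
            ).fit(X_on.to_numpy(), y_log_on)
        return TwoStepResults(self, classifier, regressor, ols_fit)


class _ConstantClassifier:
    """Stands in for the forest when the training data has a single class."""

    def __init__(self, value: float):
        self.value = value
        self.feature_importances_ = None

    def predict_proba(self, X):
        p1 = np.full(len(X), self.value)
        return np.column_stack([1 - p1, p1])


class TwoStepResults:
    """Fitted two-step model: classifier, regressor, and their diagnostics.

    Exposes ``params``/``bse``/``rsquared`` for the linear level regressor
    (statsmodels-style), ``predict`` for the combined C(X)*R(X) rule, and
    ``evaluate``/``summary`` for reporting.
    """

    def __init__(self, model, classifier, regressor, ols_fit):
        self.model = model
        self.classifier = classifier
        self.regressor = regressor
        self._ols = ols_fit
        self.feature_names = model.feature_names

    # ---- statsmodels-style accessors (linear regressor only) ----
    @property
    def params(self) -> pd.Series:
        if self._ols is None:
            raise AttributeError("params are only defined for the linear regressor")
        return self._ols.params

    @property
    def bse(self) -> pd.Series:
        if self._ols is None:
            raise AttributeError("bse is only defined for the linear regressor")
        return self._ols.bse

    @property
    def rsquared(self) -> float:
        """Training R^2 of the level regression on 'on' genes."""
        if self._ols is not None:
            return float(self._ols.rsquared)
        on = self.model.y > 0
        return float(
            self.regressor.score(
                self.model.X.loc[on].to_numpy(), np.log2(self.model.y[on].to_numpy())
            )
        )

    # ---- prediction ----
    def _check_features(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                f"feature mismatch: model expects {self.feature_names}, got {list(X.columns)}"
            )
        return X

    def predict_proba(self, X: pd.DataFrame) -> pd.Series:
        """Classifier vote fraction for the 'on' class."""
        X = self._check_features(X)
        proba = self.classifier.predict_proba(X.to_numpy())[:, 1]
        return pd.Series(proba, index=X.index)

    def predict_level(self, X: pd.DataFrame) -> pd.Series:
        """Regressor output R(X) (log2 expression), ignoring the classifier."""
        X = self._check_features(X)
        if self._ols is not None:
            pred = self._ols.predict(sm.add_constant(X, has_constant="add"))
            return pd.Series(np.asarray(pred), index=X.index)
        return pd.Series(self.regressor.predict(X.to_numpy()), index=X.index)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Combined prediction C(X) * R(X); genes classified off get exactly 0."""
        on = self.predict_proba(X) >= self.model.threshold
        level = self.predict_level(X)
        return level.where(on, 0.0)

    def evaluate(self, X: pd.DataFrame, y: pd.Series, **kw) -> EvaluationResult:
        y = pd.Series(y).loc[X.index]
        return evaluate(
            to_log2_with_zeros(y),
            self.predict(X),
            proba=self.predict_proba(X),
            labels=(y > 0).to_numpy(),
            threshold=self.model.threshold,
            **kw,
        )

    def summary(self) -> str:
        lines = [
            "Two-step expression model",
            "=" * 60,
            f"method: {self.model.method}    seed: {self.model.seed}",
            f"genes: {len(self.model.y)}  "
            f"on: {int((self.model.y > 0).sum())}  off: {int((self.model.y == 0).sum())}",
            f"level-regression R^2 (training, on genes): {self.rsquared:.4f}",
        ]
        if self._ols is not None:
            lines.append("-" * 60)
            lines.append(f"{'feature':<20}{'coef':>12}{'std err':>12}")
            for name in self.params.index:
                lines.append(
                    f"{str(name):<20}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                )
        return "\n".join(lines)


# --------------------------------------------------------------------------- #
# functional wrappers and cross-validation

def fit_two_step(
    X: pd.DataFrame,
    y: pd.Series,
    method: str = "linear",
    seed: int = 0,
    **kw,
) -> TwoStepResults:
    return TwoStepExpressionModel(X, y, method=method, seed=seed, **kw).fit()


def predict_two_step(results: TwoStepResults, X: pd.DataFrame) -> pd.Series:
    return results.predict(X)


class SingleStepModel:
    """Baseline: one regressor over all genes, zeros included as target 0.

    This is the comparator for the two-step model: it regresses the same
    pooled target (log2 expression, off genes at 0) without an on/off
    classifier.
    """

    def __init__(self, X, y, method="linear", seed=0, n_estimators=DEFAULT_N_TREES):
        self.X = pd.DataFrame(X)
        self.y = pd.Series(y).loc[self.X.index]
        self.method = method
        self.seed = seed
        self.n_estimators = n_estimators
        self.feature_names = list(self.X.columns)

    def fit(self):
        target = to_log2_with_zeros(self.y)
        if self.method == "linear":
            self._fit = sm.OLS(
                target, sm.add_constant(self.X, has_constant="add")
            ).fit()
        else:
            self._fit = RandomForestRegressor(
                n_estimators=self.n_estimators,
                random_state=np.random.RandomState(self.seed),
                n_jobs=1,
            ).fit(self.X.to_numpy(), target)
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        if self.method == "linear":
            pred = self._fit.predict(sm.add_constant(X, has_constant="add"))
            return pd.Series(np.asarray(pred), index=X.index)
        return pd.Series(self._fit.predict(X.to_numpy()), index=X.index)


@dataclass
class CrossValidationResult:
    """Pooled out-of-fold predictions over D2 plus their metrics."""

    predictions: pd.Series
    proba: pd.Series | None
    result: EvaluationResult
    per_fold: list[EvaluationResult] = field(default_factory=list)


def crossvalidate(
    X: pd.DataFrame,
    y: pd.Series,
    plan: SplitPlan,
    method: str = "linear",
    seed: int = 0,
    n_estimators: int = DEFAULT_N_TREES,
    threshold: float = 0.5,
) -> CrossValidationResult:
    """Ten-fold CV on D2: each gene predicted once by a model not trained on it.

    Metrics are computed on the pooled out-of-fold predictions (correlation,
    RMSE on the log2 scale with zeros included, AUC from the classifier vote
    fractions).
    """
    y = pd.Series(y)
    missing = [g for g in plan.d2_ids if g not in X.index]
    if missing:
        raise ValueError(f"plan covers genes absent from X: {missing[:5]}...")
    preds, probas = {}, {}
    per_fold = []
    d2 = pd.Index(plan.d2_ids)
    for k, fold in enumerate(plan.folds):
        fold = pd.Index(fold)
        train = d2.difference(fold, sort=False)
        y_train = y.loc[train]
        if not (y_train > 0).any():
            warnings.warn(f"fold {k}: no 'on' genes in training split; predicting 0")
            for g in fold:
                preds[g] = 0.0
                probas[g] = 0.0
            continue
        res = TwoStepExpressionModel(
            X.loc[train],
            y_train,
            method=method,
            seed=seed + k,
            n_estimators=n_estimators,
            threshold=threshold,
        ).fit()
        fold_pred = res.predict(X.loc[fold])
        fold_proba = res.predict_proba(X.loc[fold])
        preds.update(fold_pred.to_dict())
        probas.update(fold_proba.to_dict())
        per_fold.append(res.evaluate(X.loc[fold], y.loc[fold]))
    pred = pd.Series(preds).loc[d2]
    proba = pd.Series(probas).loc[d2]
    y_d2 = y.loc[d2]
    result = evaluate(
        to_log2_with_zeros(y_d2),
        pred,
        proba=proba,
        labels=(y_d2 > 0).to_numpy(),
        threshold=threshold,
    )
    return CrossValidationResult(pred, proba, result, per_fold)


def crossvalidate_single_step(
    X: pd.DataFrame,
    y: pd.Series,
    plan: SplitPlan,
    method: str = "linear",
    seed: int = 0,
    n_estimators: int = DEFAULT_N_TREES,
) -> CrossValidationResult:
    """Ten-fold CV of the single-regressor baseline on the same folds."""
    y = pd.Series(y)
    preds = {}
    d2 = pd.Index(plan.d2_ids)
    for k, fold in enumerate(plan.folds):
        fold = pd.Index(fold)
        train = d2.difference(fold, sort=False)
        m = SingleStepModel(
            X.loc[train], y.loc[train], method=method, seed=seed + k,
            n_estimators=n_estimators,
        ).fit()
        preds.update(m.predict(X.loc[fold]).to_dict())
    pred = pd.Series(preds).loc[d2]
    result = evaluate(to_log2_with_zeros(y.loc[d2]), pred)
    return CrossValidationResult(pred, None, result)


def randomization_test(
    X: pd.DataFrame,
    y: pd.Series,
    mode: str,
    plan: SplitPlan,
    seed: int = 0,
    method: str = "linear",
    n_estimators: int = DEFAULT_N_TREES,
) -> EvaluationResult:
    """Negative / structural controls for the whole pipeline.

    ``shuffle_y`` permutes expression across genes once before modeling — the
    fully-broken baseline.  ``shuffle_x_columns`` permutes each feature column
    independently, destroying gene-feature pairing while keeping every
    marginal.  ``swap_x_labels`` fits normally but permutes the
    column-to-feature assignment of the test matrix before prediction, probing
    how much accuracy depends on feature-specific coefficients rather than
    shared signal among correlated features.
    """
    rng = np.random.default_rng(seed)
    if mode == "shuffle_y":
        y_perm = pd.Series(
            y.loc[X.index].to_numpy()[rng.permutation(len(X))], index=X.index
        )
        return crossvalidate(X, y_perm, plan, method, seed, n_estimators).result
    if mode == "shuffle_x_columns":
        Xp = X.copy()
        for col in Xp.columns:
            Xp[col] = Xp[col].to_numpy()[rng.permutation(len(Xp))]
        return crossvalidate(Xp, y, plan, method, seed, n_estimators).result
    if mode == "swap_x_labels":
        perm = _derangement(len(X.columns), rng)
        y = pd.Series(y)
        preds, probas = {}, {}
        d2 = pd.Index(plan.d2_ids)
        for k, fold in enumerate(plan.folds):
            fold = pd.Index(fold)
            train = d2.difference(fold, sort=False)
            res = TwoStepExpressionModel(
                X.loc[train], y.loc[train], method=method, seed=seed + k,
                n_estimators=n_estimators,
            ).fit()
            # relabel the test matrix: column j's values presented as feature perm[j]
            X_test = X.loc[fold]
            swapped = pd.DataFrame(
                X_test.to_numpy()[:, perm], index=X_test.index, columns=X_test.columns
            )
            preds.update(res.predict(swapped).to_dict())
            probas.update(res.predict_proba(swapped).to_dict())
        pred = pd.Series(preds).loc[d2]
        proba = pd.Series(probas).loc[d2]
        y_d2 = y.loc[d2]
        return evaluate(
            to_log2_with_zeros(y_d2), pred, proba=proba, labels=(y_d2 > 0).to_numpy()
        )
    raise ValueError(f"unknown randomization mode {mode!r}")


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A permutation of range(n) with no fixed points."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def cross_context_apply(
    results: TwoStepResults, X_other: pd.DataFrame, y_other: pd.Series
) -> EvaluationResult:
    """Apply a fitted model, unchanged, to another dataset or cell context.

    ``X_other`` must be built with the model's own bin specs and pseudocounts
    (the transform travels with the model); no refitting happens here.
    """
    return results.evaluate(X_other, pd.Series(y_other))
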