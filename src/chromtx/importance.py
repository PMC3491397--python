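"""Per-feature importance: LMG R^2 decomposition, Gini decrease, reporting.

For the linear level regressor, importance is the LMG decomposition: each
feature's share of the model R^2 is its average increase in R^2 over all
orderings in which features can enter the model.  Averaging over orderings
makes the allocation fair for correlated predictors, and the shares sum
exactly to the full-model R^2.  Rather than enumerating all p! orderings, the
shares are computed from the 2^p subset R^2 values with the ordering weights

    w(|S|) = |S|! (p - |S| - 1)! / p!

which is exact and tractable up to p = 20.

For the random-forests classifier (and the optional forest regressor),
importance is the mean decrease in node impurity (Gini).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "lmg_importance",
    "gini_importance",
    "relative_contribution_report",
    "ImportanceReport",
]

_MAX_LMG_FEATURES = 20
_RIDGE_JITTER = 1e-8


def _subset_r2(cov_xx: np.ndarray, cov_xy: np.ndarray, var_y: float) -> np.ndarray:
    """R^2 of every feature subset, indexed by bitmask."""
    p = len(cov_xy)
    r2 = np.zeros(1 << p)
    jittered = False
    for mask in range(1, 1 << p):
        idx = [j for j in range(p) if mask >> j & 1]
        A = cov_xx[np.ix_(idx, idx)]
        b = cov_xy[idx]
        try:
            coef = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            if not jittered:
                warnings.warn("singular design; stabilizing with ridge jitter 1e-8")
                jittered = True
            coef = np.linalg.solve(A + _RIDGE_JITTER * np.eye(len(idx)), b)
        r2[mask] = float(b @ coef) / var_y
    return r2


def lmg_importance(X: pd.DataFrame | np.ndarray, y) -> pd.Series:
    """LMG share of the linear-model R^2 for each feature.

    Feature j's share is the average, over all p! orderings, of the increase
    in R^2 when j enters the model after the features preceding it; computed
    via the 2^p subset decomposition.  Shares are nonnegative up to numerical
    noise and sum to the full-model R^2.
    """
    X = pd.DataFrame(X)
    names = list(X.columns)
    p = len(names)
    n = len(X)
    if p > _MAX_LMG_FEATURES:
        raise ValueError(f"LMG enumeration supports at most {_MAX_LMG_FEATURES} features")
    if n <= p:
        raise ValueError("need more observations than features")
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    Xc = Xv - Xv.mean(axis=0)
    yc = y - y.mean()
    var_y = float(yc @ yc)
    if var_y == 0:
        raise ValueError("y has zero variance")
    cov_xx = Xc.T @ Xc
    cov_xy = Xc.T @ yc
    r2 = _subset_r2(cov_xx, cov_xy, var_y)

    fact = [math.factorial(k) for k in range(p + 1)]
    weights = [fact[k] * fact[p - k - 1] / fact[p] for k in range(p)]
    shares = np.zeros(p)
    full = (1 << p) - 1
    for j in range(p):
        others = [k for k in range(p) if k != j]
        for sub in range(1 << (p - 1)):
            mask = sum(1 << others[i] for i in range(p - 1) if sub >> i & 1)
            size = bin(mask).count("1")
            shares[j] += weights[size] * (r2[mask | (1 << j)] - r2[mask])
    assert abs(shares.sum() - r2[full]) < 1e-6
    return pd.Series(shares, index=names)


def gini_importance(fitted_ensemble, feature_names=None) -> pd.Series:
    """Mean decrease in node impurity per feature, from a fitted forest."""
    imp = getattr(fitted_ensemble, "feature_importances_", None)
    if imp is None:
        raise ValueError("model is not a fitted ensemble with feature_importances_")
    index = feature_names if feature_names is not None else range(len(imp))
    return pd.Series(np.asarray(imp, dtype=float), index=index)


def relative_contribution_report(
    importances: pd.Series, normalize: bool = True
) -> pd.Series:
    """Stacked-share report of nonnegative importances (sums to 1 if normalized)."""
    imp = pd.Series(importances, dtype=float)
    if (imp < 0).any():
        raise ValueError("importances must be nonnegative")
    if not normalize:
        return imp
    total = imp.sum()
    if total == 0:
        raise ValueError("cannot normalize an all-zero importance vector")
    return imp / total


class ImportanceReport:
    """Classifier- and regressor-side importances for one fitted model."""

    def __init__(
        self,
        feature_names,
        classifier_importance: pd.Series | None,
        regressor_importance: pd.Series,
        classifier_method: str = "gini",
        regressor_method: str = "lmg",
    ):
        self.feature_names = list(feature_names)
        self.classifier_importance = classifier_importance
        self.regressor_importance = regressor_importance
        self.classifier_method = classifier_method
        self.regressor_method = regressor_method

    @classmethod
    def from_results(cls, results) -> "ImportanceReport":
        """Build the report from fitted :class:`~chromtx.model.TwoStepResults`.

        The classifier side uses Gini decrease; the regressor side uses LMG
        shares for the linear method and Gini decrease for forests.  (A MARS
        nsubsets criterion would slot in here, but no MARS backend is bundled,
        so it is reported unavailable.)
        """
        clf = results.classifier
        clf_imp = None
        if getattr(clf, "feature_importances_", None) is not None:
            clf_imp = gini_importance(clf, results.feature_names)
        on = results.model.y > 0
        if results.model.method == "linear":
            reg_imp = lmg_importance(
                results.model.X.loc[on], np.log2(results.model.y[on].to_numpy())
            )
            reg_method = "lmg"
        else:
            reg_imp = gini_importance(results.regressor, results.feature_names)
            reg_method = "gini"
        return cls(results.feature_names, clf_imp, reg_imp, "gini", reg_method)

    def to_frame(self, normalize: bool = True) -> pd.DataFrame:
        reg = relative_contribution_report(self.regressor_importance, normalize)
        out = pd.DataFrame(index=pd.Index(self.feature_names, name="feature"))
        if self.classifier_importance is not None:
            out["classifier_share"] = relative_contribution_report(
                self.classifier_importance, normalize
            )
        else:
            out["classifier_share"] = np.nan
        out["regressor_share"] = reg
        return out
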