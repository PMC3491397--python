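"""Context analyses: feature-category models, HCP/LCP strata, expression deciles.

Chromatin features fall into functional groups — promoter marks (H3K4me2,
H3K4me3, H2A.Z, H3K9ac, H3K27ac), structural/elongation marks (H3K36me3,
H3K79me2), repressive marks (H3K27me3, H3K9me3), distal/other marks (H3K4me1,
H4K20me1, H3K9me1), and DNase accessibility.  Fitting the two-step model on
single categories or pairs shows which group carries the predictive signal
for a given expression readout.  Stratifying genes by promoter CpG class
(HCP/LCP) or by expression decile asks the same question across gene groups.

Bin specs and pseudocounts are re-selected per combo/stratum on its own D1,
matching the pipeline's order of operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .importance import ImportanceReport, lmg_importance
from .model import (
    DEFAULT_N_TREES,
    FeatureTransform,
    SplitPlan,
    crossvalidate,
    evaluate,
    fit_two_step,
    make_split,
    to_log2_with_zeros,
)
from .simulate import FEATURE_CATEGORIES

__all__ = [
    "FeatureCategoryMap",
    "run_category_models",
    "stratified_models",
    "cumulative_decile_analysis",
]


@dataclass
class FeatureCategoryMap:
    """Disjoint functional categories of chromatin features."""

    categories: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in FEATURE_CATEGORIES.items()}
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.categories.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"categories overlap on {sorted(overlap)}")
            seen |= set(members)

    def features_for(self, combo: Iterable[str]) -> list[str]:
        """Union of the features of the named categories, in roster order."""
        combo = list(combo)
        unknown = [c for c in combo if c not in self.categories]
        if unknown:
            raise KeyError(f"unknown categories {unknown}; have {list(self.categories)}")
        out: list[str] = []
        for cat in combo:
            out.extend(f for f in self.categories[cat] if f not in out)
        if not out:
            raise ValueError("empty category combo")
        return out

    @classmethod
    def from_yaml(cls, path) -> "FeatureCategoryMap":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.categories, fh)


def _training_r2(X: pd.DataFrame, y: pd.Series, d2_ids) -> float:
    """Training R^2 of the linear level regression on D2's expressed genes."""
    d2 = pd.Index(d2_ids)
    y2 = y.loc[d2]
    on = y2 > 0
    fit = sm.OLS(
        np.log2(y2[on].to_numpy()),
        sm.add_constant(X.loc[d2[on.to_numpy()]], has_constant="add"),
    ).fit()
    return float(fit.rsquared)


def run_category_models(
    binned: Mapping[str, pd.DataFrame],
    y: pd.Series,
    category_map: FeatureCategoryMap,
    combos: Sequence[Iterable[str]],
    plan: SplitPlan,
    method: str = "linear",
    seed: int = 0,
    n_estimators: int = DEFAULT_N_TREES,
    strategy: str = "bestbin",
) -> pd.DataFrame:
    """Cross-validate the two-step model on each category combination.

    Every combo re-selects its transforms (bestbin + pseudocount) on D1 using
    only its own features, then runs the ten-fold CV on D2.  Returns one row
    per combo with the pooled metrics and the linear training R^2 (which is
    monotone under feature-set inclusion for nested combos).
    """
    rows = []
    for combo in combos:
        combo = list(combo)
        features = category_map.features_for(combo)
        sub = {f: binned[f] for f in features}
        ft = FeatureTransform(strategy=strategy).fit(sub, y, plan.d1_ids)
        X = ft.transform(sub)
        cv = crossvalidate(X, y, plan, method=method, seed=seed, n_estimators=n_estimators)
        rows.append(
            {
                "combo": "+".join(combo),
                "n_features": len(features),
                "pcc_r": cv.result.pcc_r,
                "rmse": cv.result.rmse,
                "auc": cv.result.auc,
                "classification_accuracy": cv.result.classification_accuracy,
                "train_r2": _training_r2(X, y, plan.d2_ids),
            }
        )
    return pd.DataFrame(rows).set_index("combo")


def stratified_models(
    binned: Mapping[str, pd.DataFrame],
    y: pd.Series,
    strata: Mapping[str, str] | pd.Series,
    method: str = "linear",
    seed: int = 0,
    n_estimators: int = DEFAULT_N_TREES,
    strategy: str = "bestbin",
) -> dict[str, dict]:
    """Fit the full pipeline independently inside each gene stratum.

    ``strata`` maps gene id to a label (typically "HCP"/"LCP" from the
    normalized CpG score at threshold 0.4).  Each stratum gets its own D1/D2
    split, transform selection, ten-fold CV, and importance report; strata
    share no genes.  Strata smaller than 30 genes raise.
    """
    strata = pd.Series(strata)
    out: dict[str, dict] = {}
    for k, label in enumerate(sorted(strata.unique())):
        ids = strata.index[strata == label]
        plan = make_split(list(ids), seed=seed + 101 * k)
        sub = {f: df.loc[ids] for f, df in binned.items()}
        ft = FeatureTransform(strategy=strategy).fit(sub, y.loc[ids], plan.d1_ids)
        X = ft.transform(sub)
        cv = crossvalidate(
            X, y.loc[ids], plan, method=method, seed=seed + k, n_estimators=n_estimators
        )
        d2 = pd.Index(plan.d2_ids)
        res = fit_two_step(
            X.loc[d2], y.loc[d2], method=method, seed=seed + k,
            n_estimators=n_estimators,
        )
        out[label] = {
            "n_genes": len(ids),
            "plan": plan,
            "transform": ft,
            "result": cv.result,
            "importance": ImportanceReport.from_results(res),
        }
    return out


def cumulative_decile_analysis(
    X: pd.DataFrame,
    y: pd.Series,
    plan: SplitPlan,
    method: str = "linear",
    seed: int = 0,
    n_estimators: int = DEFAULT_N_TREES,
    promoter_class: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Prediction accuracy over cumulative expression deciles.

    D2 genes are sorted by measured expression (descending) and evaluated on
    the top 10%, 20%, ..., 100% using the pooled out-of-fold predictions of a
    single ten-fold CV.  The last row therefore equals the standard full
    evaluation.  When ``promoter_class`` labels are given, the fraction of LCP
    genes per cutoff is reported alongside.
    """
    y = pd.Series(y)
    n_on = int((y.loc[plan.d2_ids] > 0).sum())
    if n_on < 100:
        raise ValueError(f"need at least 100 expressed genes in D2, got {n_on}")
    cv = crossvalidate(X, y, plan, method=method, seed=seed, n_estimators=n_estimators)
    d2 = pd.Index(plan.d2_ids)
    y_d2 = y.loc[d2]
    order = y_d2.sort_values(ascending=False, kind="stable").index
    rows = []
    for pct in range(10, 101, 10):
        top = order[: int(round(len(order) * pct / 100))]
        labels = (y_d2.loc[top] > 0).to_numpy()
        ev = evaluate(
            to_log2_with_zeros(y_d2.loc[top]),
            cv.predictions.loc[top],
            proba=cv.proba.loc[top] if cv.proba is not None else None,
            labels=labels,
        )
        row = {"top_pct": pct, "n_genes": ev.n_genes, "pcc_r": ev.pcc_r,
               "rmse": ev.rmse, "auc": ev.auc}
        if promoter_class is not None:
            pc = pd.Series(promoter_class)
            row["lcp_fraction"] = float((pc.loc[top] == "LCP").mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("top_pct")
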