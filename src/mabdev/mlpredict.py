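"""Prediction of DSC transition temperatures from orthogonal measurements.

The feature table joins light-scattering, SEC and formulation metrics per
sample; the four thermogram-derived temperatures (T_onset, T_m1, T_m2,
T_m3) are targets.  A direct multioutput strategy fits one independent
gradient-boosting regressor per target, evaluated by k-fold
cross-validation repeated with independent random partitions (5 folds x
5 repeats = 25 train/validation splits by default) and summarised by the
mean absolute error over validation folds.  Impurity (Gini-style)
feature importances are collected per split so their across-fold
distribution can be reported, mirroring how tree-ensemble importances
are read in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import ParameterSampler, RepeatedKFold

from .errors import InvalidInputError

__all__ = [
    "DEFAULT_PREDICTORS",
    "DEFAULT_TARGETS",
    "CurationLog",
    "curate_dataset",
    "TargetEvaluation",
    "ModelEvaluation",
    "train_evaluate",
    "feature_importance",
]

DEFAULT_PREDICTORS = ["pH", "nacl_mM", "kd", "kd_se", "d0", "z_average_nm",
                      "pdi", "pct_hmw", "pct_monomer", "pct_lmw", "tagg1", "tagg2"]
DEFAULT_TARGETS = ["tonset", "tm1", "tm2", "tm3"]

_DEFAULT_GBM_PARAMS = dict(n_estimators=300, learning_rate=0.05, max_depth=3,
                           subsample=0.8)

_SEARCH_SPACE = {
    "n_estimators": [100, 200, 300, 500],
    "learning_rate": [0.02, 0.05, 0.1],
    "max_depth": [2, 3, 4],
    "subsample": [0.7, 0.8, 1.0],
}


# ---------------------------------------------------------------------------
# curation

@dataclass
class CurationLog:
    n_input: int
    n_qc_removed: int
    n_missing_removed: int
    dropped_collinear: list[tuple[str, str, float]] = field(default_factory=list)
    kept_predictors: list[str] = field(default_factory=list)

    @property
    def n_final(self) -> int:
        return self.n_input - self.n_qc_removed - self.n_missing_removed


def curate_dataset(raw: pd.DataFrame, predictors=None, targets=None,
                   qc_col: str = "qc_flag",
                   collinearity_r: float = 0.95) -> tuple[pd.DataFrame, CurationLog]:
    """Produce the ML-ready table.

    Order of filters: QC-flagged rows out first, then rows with any
    missing value in predictors or targets, then collinear predictors —
    for every pair with |Pearson r| >= ``collinearity_r`` the member with
    the larger mean absolute correlation to all other predictors is
    dropped (a deterministic, order-independent rule).
    """
    predictors = list(predictors or [c for c in DEFAULT_PREDICTORS if c in raw.columns])
    targets = list(targets or [c for c in DEFAULT_TARGETS if c in raw.columns])
    overlap = set(predictors) & set(targets)
    if overlap:
        raise InvalidInputError(f"targets leak into predictors: {sorted(overlap)}")
    if len(raw) == 0:
        raise InvalidInputError("empty dataset")

    df = raw.copy()
    n_input = len(df)
    if qc_col in df.columns:
        df = df[~df[qc_col].astype(bool)]
    n_qc = n_input - len(df)
    before = len(df)
    df = df.dropna(subset=predictors + targets)
    n_missing = before - len(df)
    if len(df) == 0:
        raise InvalidInputError("empty dataset after filtering")

    kept = list(predictors)
    dropped = []
    while True:
        corr = df[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = corr.stack()
        worst = pairs.idxmax()
        if pairs.loc[worst] < collinearity_r:
            break
        a, b = worst
        mean_abs = corr.mean()
        victim = a if mean_abs[a] > mean_abs[b] else b
        if mean_abs[a] == mean_abs[b]:  # tie: drop the later column
            victim = b if kept.index(b) > kept.index(a) else a
        keeper = b if victim == a else a
        dropped.append((victim, keeper, float(pairs.loc[worst])))
        kept.remove(victim)

    log = CurationLog(n_input=n_input, n_qc_removed=n_qc,
                      n_missing_removed=n_missing,
                      dropped_collinear=dropped, kept_predictors=kept)
    return df[kept + targets].copy(), log


# ---------------------------------------------------------------------------
# training / evaluation

@dataclass
class TargetEvaluation:
    target: str
    mae_mean: float
    mae_splits: np.ndarray  # one MAE per train/validation split
    predictions: pd.DataFrame  # measured, predicted (mean over repeats), sd
    importances: pd.DataFrame  # splits x features
    pearson_r: float
    model_params: dict


@dataclass
class ModelEvaluation:
    per_target: dict[str, TargetEvaluation]
    folds: int
    repeats: int
    predictors: list[str]

    @property
    def n_splits(self) -> int:
        return self.folds * self.repeats


def _cv_run(X, y, folds, repeats, seed, params):
    """One full repeated-CV pass; returns per-split MAE, importances and
    out-of-fold predictions per repeat."""
    n = len(y)
    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    maes, imps = [], []
    preds = np.full((repeats, n), np.nan)
    for split_i, (tr, va) in enumerate(rkf.split(X)):
        model = GradientBoostingRegressor(random_state=seed + split_i, **params)
        model.fit(X[tr], y[tr])
        yhat = model.predict(X[va])
        maes.append(float(np.mean(np.abs(yhat - y[va]))))
        imps.append(model.feature_importances_)
        preds[split_i // folds, va] = yhat
    return np.array(maes), np.array(imps), preds


def train_evaluate(table: pd.DataFrame, targets=None, predictors=None,
                   folds: int = 5, repeats: int = 5, seed: int = 0,
                   model_params: dict | None = None,
                   n_search: int = 0) -> ModelEvaluation:
    """Repeated cross-validated gradient boosting, one regressor per target.

    ``n_search`` > 0 draws that many hyperparameter candidates and keeps
    the one with the best mean cross-validated MAE (same splits), before
    reporting that winner's evaluation.  Split assignment and model
    initialisation are both fully determined by ``seed``.
    """
    targets = list(targets or [c for c in DEFAULT_TARGETS if c in table.columns])
    predictors = list(predictors or [c for c in table.columns
                                     if c not in targets and c != "qc_flag"
                                     and pd.api.types.is_numeric_dtype(table[c])])
    leak = set(predictors) & set(targets)
    if leak:
        raise InvalidInputError(f"targets leak into predictors: {sorted(leak)}")
    if folds > len(table):
        raise InvalidInputError("more folds than samples")
    X = table[predictors].to_numpy(dtype=float)

    per_target = {}
    for ti, target in enumerate(targets):
        y = table[target].to_numpy(dtype=float)
        if np.std(y) == 0:
            warnings.warn(f"target {target!r} is constant")
        tseed = seed + 1000 * ti
        candidates = [dict(model_params or _DEFAULT_GBM_PARAMS)]
        if n_search > 0:
            candidates += list(ParameterSampler(_SEARCH_SPACE, n_iter=n_search,
                                                random_state=tseed))
        best = None
        for params in candidates:
            maes, imps, preds = _cv_run(X, y, folds, repeats, tseed, params)
            if best is None or maes.mean() < best[0].mean():
                best = (maes, imps, preds, params)
        maes, imps, preds, params = best

        pred_mean = np.nanmean(preds, axis=0)
        pred_sd = np.nanstd(preds, axis=0)
        pred_df = pd.DataFrame({"measured": y, "predicted": pred_mean, "sd": pred_sd},
                               index=table.index)
        r = (float(np.corrcoef(y, pred_mean)[0, 1]) if np.std(y) > 0
             and np.std(pred_mean) > 0 else float("nan"))
        per_target[target] = TargetEvaluation(
            target=target, mae_mean=float(maes.mean()), mae_splits=maes,
            predictions=pred_df,
            importances=pd.DataFrame(imps, columns=predictors),
            pearson_r=r, model_params=params,
        )
    return ModelEvaluation(per_target=per_target, folds=folds, repeats=repeats,
                           predictors=predictors)


def feature_importance(evaluation: ModelEvaluation) -> dict[str, pd.DataFrame]:
    """Across-split importance distribution per target, ranked by median.

    Returns one table per target with median, quartiles and mean impurity
    importance for every feature, most important first.
    """
    out = {}
    for target, ev in evaluation.per_target.items():
        imp = ev.importances
        summary = pd.DataFrame({
            "median": imp.median(),
            "q1": imp.quantile(0.25),
            "q3": imp.quantile(0.75),
            "mean": imp.mean(),
        })
        out[target] = summary.sort_values("median", ascending=False)
    return out
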