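"""Nested penalized prediction models with held-out ROC/AUC evaluation.

Four covariate tiers are fit as L1-penalized logistic regressions
(metabolites only; + demographics; + lifestyle/comorbidities; + PRS), each
with one of three metabolite panels (none / certified subset / full panel).
The data are split once into a seeded, case-stratified 80/20
train/evaluation split; the penalty weight is chosen by 5-fold
cross-validated deviance inside the training split, the model is refit on
the full training split at the selected weight, and every reported AUC is
computed on the untouched 20% hold-out. Two models fitted on the same split
are compared with the paired DeLong test on their held-out predicted
probabilities.

The L1 penalty zeroes coefficients, shrinking the metabolite set the model
actually uses; the selection rule is minimum cross-validated deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import CohortTable, covariate_schema
from .preprocess import DesignMatrix, ProbitMatrix, build_design
from .stats import AUCResult, auc_mann_whitney, delong_test

DEFAULT_PENALTY_GRID = np.logspace(-4.0, 4.0, 50)  # grid of inverse penalties (C)


@dataclass
class FittedPredictionModel:
    tier: int
    metabolite_set: str
    coefficients: pd.Series          # named, zeros where the penalty dropped a column
    intercept: float
    penalty_weight: float            # lambda = 1/C at the selected grid point
    train_fraction: float
    folds: int
    seed: int
    train_index: np.ndarray
    test_index: np.ndarray
    heldout_scores: np.ndarray       # predicted case probabilities on the hold-out
    heldout_labels: np.ndarray
    heldout_auc: AUCResult

    @property
    def n_selected(self) -> int:
        return int((self.coefficients != 0.0).sum())

    def to_dict(self) -> dict:
        return {
            "tier": self.tier,
            "metabolite_set": self.metabolite_set,
            "penalty_weight": self.penalty_weight,
            "intercept": self.intercept,
            "n_selected": self.n_selected,
            "coefficients": self.coefficients.to_dict(),
            "heldout_auc": self.heldout_auc.to_dict(),
            "seed": self.seed,
        }


@dataclass
class ModelComparison:
    model_a: FittedPredictionModel
    model_b: FittedPredictionModel
    auc_a: float = field(init=False)
    auc_b: float = field(init=False)
    delong_z: float = field(init=False)
    delong_p: float = field(init=False)


def _stratified_split(y: np.ndarray, train_fraction: float, seed: int):
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=1.0 - train_fraction, stratify=y, random_state=seed)
    return np.sort(train_idx), np.sort(test_idx)


def _cv_folds(y_train: np.ndarray, folds: int, seed: int, max_attempts: int = 10):
    """Seeded stratified folds; re-shuffle (bounded) if a fold loses a class."""
    for attempt in range(max_attempts):
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(kf.split(np.zeros_like(y_train), y_train))
        if all(len(np.unique(y_train[tr])) == 2 and len(np.unique(y_train[te])) == 2
               for tr, te in splits):
            return splits
    raise ValueError("could not build folds containing both classes")


def fit_prediction_model(table: CohortTable, tier: int, metabolite_set: str,
                         seed: int, folds: int = 5, train_fraction: float = 0.8,
                         penalty_grid: np.ndarray = DEFAULT_PENALTY_GRID,
                         probit: ProbitMatrix | None = None,
                         design: DesignMatrix | None = None) -> FittedPredictionModel:
    """Fit one tier/panel combination end to end.

    The table must be imputed. ``design`` may supply a prebuilt design
    matrix (for reuse across tiers); otherwise it is constructed here.
    The same seed reproduces the split, the selected penalty and the
    coefficients exactly.
    """
    if design is None:
        design = build_design(table, tier, metabolite_set, probit=probit)
    X_full = design.frame.drop(columns="intercept")
    y = table.status
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    train_idx, test_idx = _stratified_split(y, train_fraction, seed)
    X_all = X_full.to_numpy(dtype=float)
    y_train = y[train_idx]
    splits = _cv_folds(y_train, folds, seed)

    # Columns are standardized (training moments) before penalized fitting so
    # the L1 penalty treats every predictor symmetrically, and coefficients
    # are reported back on the original scale.
    mu = X_all[train_idx].mean(axis=0)
    sd = X_all[train_idx].std(axis=0)
    sd[sd == 0.0] = 1.0
    X_std = (X_all - mu) / sd

    est = LogisticRegressionCV(
        Cs=penalty_grid, cv=splits, penalty="l1", solver="liblinear",
        scoring="neg_log_loss", refit=True, tol=1e-6, max_iter=2000,
        random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(X_std[train_idx], y_train)

    beta_std = est.coef_[0]
    coefficients = pd.Series(beta_std / sd, index=X_full.columns)
    intercept = float(est.intercept_[0] - np.sum(beta_std * mu / sd))
    heldout_scores = est.predict_proba(X_std[test_idx])[:, 1]
    heldout_labels = y[test_idx]
    heldout_auc = auc_mann_whitney(heldout_scores, heldout_labels)

    return FittedPredictionModel(
        tier=tier, metabolite_set=metabolite_set, coefficients=coefficients,
        intercept=intercept, penalty_weight=float(1.0 / est.C_[0]),
        train_fraction=train_fraction, folds=folds, seed=seed,
        train_index=train_idx, test_index=test_idx,
        heldout_scores=heldout_scores, heldout_labels=heldout_labels,
        heldout_auc=heldout_auc)


def compare_models(a: FittedPredictionModel, b: FittedPredictionModel) -> ModelComparison:
    """Paired DeLong comparison of two models on their shared hold-out."""
    if not np.array_equal(a.test_index, b.test_index):
        raise ValueError("models were evaluated on different held-out rows")
    if not np.array_equal(a.heldout_labels, b.heldout_labels):
        raise ValueError("held-out labels disagree")
    cmp = ModelComparison(model_a=a, model_b=b)
    cmp.auc_a, cmp.auc_b, cmp.delong_z, cmp.delong_p = delong_test(
        a.heldout_scores, b.heldout_scores, a.heldout_labels)
    return cmp


def _stratum_masks(table: CohortTable, rows: np.ndarray) -> dict[str, np.ndarray]:
    """Stratum membership masks over the given row subset."""
    sub = table.data.iloc[rows]
    masks: dict[str, np.ndarray] = {}
    for level in covariate_schema("ethnicity").levels:
        masks[f"ethnicity={level}"] = (sub["ethnicity"] == level).to_numpy()
    age = sub["age"].to_numpy(dtype=float)
    masks["age<55"] = age < 55.0
    masks["age>=55"] = age >= 55.0
    for level in covariate_schema("sex").levels:
        masks[f"sex={level}"] = (sub["sex"] == level).to_numpy()
    return masks


def stratified_auc(table: CohortTable, model_with: FittedPredictionModel,
                   model_without: FittedPredictionModel) -> pd.DataFrame:
    """Held-out AUC with vs without metabolites inside demographic strata.

    Strata are ethnicity levels, age dichotomized at 55 years, and sex. Both
    models must share the same hold-out; a stratum whose held-out subset
    lacks one of the classes is flagged and skipped rather than failing the
    whole table.
    """
    if not np.array_equal(model_with.test_index, model_without.test_index):
        raise ValueError("models were evaluated on different held-out rows")
    labels = model_with.heldout_labels
    rows = []
    for name, mask in _stratum_masks(table, model_with.test_index).items():
        record = {"stratum": name, "n": int(mask.sum()),
                  "n_cases": int(labels[mask].sum())}
        if mask.sum() == 0 or len(np.unique(labels[mask])) < 2:
            record.update({"auc_with": np.nan, "auc_without": np.nan,
                           "delong_p": np.nan, "skipped": True})
        else:
            auc_w, auc_wo, _z, p = delong_test(
                model_with.heldout_scores[mask], model_without.heldout_scores[mask],
                labels[mask])
            record.update({"auc_with": auc_w, "auc_without": auc_wo,
                           "delong_p": p, "skipped": False})
        rows.append(record)
    return pd.DataFrame(rows)
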