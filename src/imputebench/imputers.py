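"""Eight imputation methods for the masked hemorrhage-volume variable.

Traditional single imputation: mode fill and k-nearest-neighbour median
fill.  Traditional multiple imputation: chained-equations predictive mean
matching (20 chains of 50 iterations, averaged).  Machine-learning
imputation: logistic regression, random forest, a single-hidden-layer
back-propagation neural network, an RBF-kernel support vector machine, and
a stacked-generalisation ensemble that feeds out-of-fold class
probabilities of the four learners into a second-stage RBF-SVM.

All model-based methods treat the complete cases of the incomplete dataset
as the training set — the target variable is the label and the seven other
clinical variables *plus the discharge outcome* are the features — and
predict the masked cells.  Hyperparameters are tuned by grid search on mean
AUC over stratified cross-validation folds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from typing import Any

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .amputation import IncompleteCohort
from .cohort import OUTCOME, TARGET, encode_features, table2_profile

__all__ = [
    "METHODS",
    "ImputerConfig",
    "TunedModel",
    "CompletedCohort",
    "impute",
    "impute_mode",
    "impute_knn",
    "impute_mice_pmm",
    "tune_classifier",
    "impute_classifier",
    "impute_stacking",
]

MODE = "MODE"
KNN = "KNN"
MICE_PMM = "MICE_PMM"
LR = "LR"
RF = "RF"
NN = "NN"
SVM = "SVM"
EL = "EL"

#: all eight methods, canonical report order
METHODS = (LR, RF, NN, SVM, EL, MODE, KNN, MICE_PMM)

_CLASSIFIER_METHODS = (LR, RF, NN, SVM)


@dataclasses.dataclass(frozen=True)
class ImputerConfig:
    """Fixed parameters and hyperparameter grids for the eight methods."""

    k_neighbors: int = 10
    mice_m: int = 20
    mice_iterations: int = 50
    pmm_donors: int = 5
    rf_trees: int = 500
    rf_mtry_grid: tuple[int, ...] = tuple(range(1, 9))
    nn_size_grid: tuple[int, ...] = tuple(range(1, 25))
    nn_decay_grid: tuple[float, ...] = (0.0, 0.1, 0.01, 5e-4)
    svm_c_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    cv_folds: int = 10
    nn_max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for grid in (self.rf_mtry_grid, self.nn_size_grid,
                     self.nn_decay_grid, self.svm_c_grid):
            if len(grid) == 0:
                raise ValueError("hyperparameter grids must be non-empty")
        for value in (self.k_neighbors, self.mice_m, self.mice_iterations,
                      self.pmm_donors, self.rf_trees, self.cv_folds):
            if value <= 0:
                raise ValueError("fixed parameters must be positive")

    @classmethod
    def fast(cls, seed: int = 0) -> "ImputerConfig":
        """Reduced-grid profile for desk-scale end-to-end runs."""
        return cls(
            mice_m=5,
            mice_iterations=5,
            rf_trees=150,
            rf_mtry_grid=(2, 4, 8),
            nn_size_grid=(4, 16),
            nn_decay_grid=(0.0, 0.01),
            svm_c_grid=(0.25, 2.0, 32.0),
            cv_folds=5,
            nn_max_iter=150,
            seed=seed,
        )


@dataclasses.dataclass
class TunedModel:
    """Grid-search result: selected hyperparameters and the CV AUC table."""

    method: str
    params: dict[str, Any]
    cv_results: list[tuple[dict[str, Any], float]]
    seed: int

    @property
    def best_auc(self) -> float | None:
        if not self.cv_results:
            return None
        return max(auc for _, auc in self.cv_results)


@dataclasses.dataclass
class CompletedCohort:
    """A cohort with every target cell filled, plus imputation provenance."""

    records: pd.DataFrame
    imputed_mask: np.ndarray
    provenance: dict


# ---------------------------------------------------------------------------
# encoding helpers

def _feature_frame(records: pd.DataFrame) -> pd.DataFrame:
    # features for imputing the target: 7 covariates + the outcome
    return records[[c for c in records.columns if c != TARGET]]


def _encode_predictors(records: pd.DataFrame, method: str,
                       train_rows: np.ndarray) -> np.ndarray:
    scheme = "tree" if method == RF else "onehot"
    fm = encode_features(_feature_frame(records), scheme=scheme)
    X = fm.matrix
    if scheme == "onehot":
        # unit-variance scaling fit on the training (complete-case) rows
        std = X[train_rows].std(axis=0, ddof=0)
        std[std == 0] = 1.0
        X = X / std
    return X


def _target_codes(records: pd.DataFrame) -> np.ndarray:
    cats = table2_profile().variable(TARGET).categories
    return pd.Categorical(records[TARGET], categories=list(cats)).codes.astype(float)


def _decode_target(codes: np.ndarray) -> np.ndarray:
    cats = table2_profile().variable(TARGET).categories
    return np.asarray(cats, dtype=object)[np.asarray(codes, dtype=int)]


def _fill(incomplete: IncompleteCohort, values: np.ndarray,
          provenance: dict) -> CompletedCohort:
    records = incomplete.records.copy()
    records.loc[records.index[incomplete.missing_index], TARGET] = values
    if records[TARGET].isna().any():
        raise AssertionError("imputation left missing cells")
    return CompletedCohort(
        records=records,
        imputed_mask=incomplete.mask.copy(),
        provenance={"scenario": incomplete.scenario, **provenance},
    )


def _derive_seed(*parts: object) -> int:
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# traditional imputers

def impute_mode(incomplete: IncompleteCohort) -> CompletedCohort:
    """Fill every masked cell with the modal observed target category.

    Ties break toward the first-listed category ("<30 ml").
    """
    observed = incomplete.records[TARGET].dropna()
    if observed.empty:
        raise ValueError("cannot mode-impute an all-missing target column")
    cats = table2_profile().variable(TARGET).categories
    counts = observed.value_counts()
    best = max(cats, key=lambda c: (counts.get(c, 0), -cats.index(c)))
    values = np.full(len(incomplete.missing_index), best, dtype=object)
    return _fill(incomplete, values, {"method": MODE, "fill_value": best})


def impute_knn(incomplete: IncompleteCohort,
               config: ImputerConfig | None = None) -> CompletedCohort:
    """k-nearest-neighbour imputation (k=10, Euclidean, donor median).

    Distances are computed on the scaled one-hot encoding of the non-target
    variables (outcome included) between each masked record and every
    complete record.  The masked cell receives the median of the k nearest
    donors' 0/1 target codes; an exact 0.5 median falls back to the overall
    observed mode.  Distance ties break by record index.
    """
    config = config or ImputerConfig()
    obs = incomplete.complete_index
    mis = incomplete.missing_index
    if len(obs) < config.k_neighbors:
        raise ValueError(
            f"need at least k={config.k_neighbors} complete records, "
            f"have {len(obs)}"
        )
    if len(mis) == 0:
        return _fill(incomplete, np.empty(0, dtype=object), {"method": KNN})
    X = _encode_predictors(incomplete.records, KNN, obs)
    y_obs = _target_codes(incomplete.records)[obs]
    dist = cdist(X[mis], X[obs])
    overall_mode = 1.0 if (y_obs == 1).sum() > (y_obs == 0).sum() else 0.0
    codes = np.empty(len(mis))
    for i in range(len(mis)):
        order = np.argsort(dist[i], kind="stable")[: config.k_neighbors]
        med = np.median(y_obs[order])
        codes[i] = overall_mode if med == 0.5 else float(med > 0.5)
    return _fill(incomplete, _decode_target(codes),
                 {"method": KNN, "k": config.k_neighbors})


def impute_mice_pmm(incomplete: IncompleteCohort,
                    config: ImputerConfig | None = None) -> CompletedCohort:
    """Chained-equations predictive mean matching, aggregated over chains.

    Each of ``mice_m`` independent chains runs ``mice_iterations``
    iterations; an iteration draws regression coefficients from the
    approximate posterior of a least-squares fit of the 0/1 target code on
    the encoded predictors over complete cases, computes predictive means
    for all records, matches each masked record to its ``pmm_donors``
    nearest observed predictive means and copies one random donor's
    observed value.  The final cell value is the chain average of the last
    iteration's draws, decoded as ">=30 ml" iff the average is >= 0.5.
    """
    config = config or ImputerConfig()
    obs = incomplete.complete_index
    mis = incomplete.missing_index
    if len(mis) == 0:
        return _fill(incomplete, np.empty(0, dtype=object), {"method": MICE_PMM})
    y_obs = _target_codes(incomplete.records)[obs]
    if np.unique(y_obs).size == 1:
        # degenerate donor pool: every chain can only return the one value
        codes = np.full(len(mis), y_obs[0])
        return _fill(incomplete, _decode_target(codes),
                     {"method": MICE_PMM, "degenerate": True})

    X = _encode_predictors(incomplete.records, MICE_PMM, obs)
    X = np.column_stack([np.ones(len(X)), X])
    X_obs, X_mis = X[obs], X[mis]
    n_obs, p = X_obs.shape
    xtx = X_obs.T @ X_obs + 1e-6 * np.eye(p)  # ridge-stabilised normal eqns
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ (X_obs.T @ y_obs)
    rss = float(np.sum((y_obs - X_obs @ beta_hat) ** 2))
    dof = max(n_obs - p, 1)
    chol = np.linalg.cholesky(xtx_inv + 1e-12 * np.eye(p))
    donors = min(config.pmm_donors, n_obs)

    seed = _derive_seed(config.seed, incomplete.scenario.seed, MICE_PMM)
    draws = np.zeros((config.mice_m, len(mis)))
    for chain, child in enumerate(np.random.SeedSequence(seed).spawn(config.mice_m)):
        rng = np.random.default_rng(child)
        imputed = None
        for _ in range(config.mice_iterations):
            sigma2 = max(rss, 1e-12) / rng.chisquare(dof)
            beta = beta_hat + np.sqrt(sigma2) * (chol @ rng.standard_normal(p))
            mean_obs = X_obs @ beta
            mean_mis = X_mis @ beta
            gaps = np.abs(mean_mis[:, None] - mean_obs[None, :])
            pool = np.argsort(gaps, axis=1, kind="stable")[:, :donors]
            pick = rng.integers(0, donors, size=len(mis))
            imputed = y_obs[pool[np.arange(len(mis)), pick]]
        draws[chain] = imputed
    codes = (draws.mean(axis=0) >= 0.5).astype(float)  # ties -> ">=30 ml"
    return _fill(incomplete, _decode_target(codes),
                 {"method": MICE_PMM, "m": config.mice_m,
                  "iterations": config.mice_iterations})


# ---------------------------------------------------------------------------
# machine-learning imputers

def _median_heuristic_gamma(X: np.ndarray) -> float:
    # RBF bandwidth from the median pairwise distance of the training rows
    rows = X if len(X) <= 1500 else X[:: len(X) // 1500 + 1]
    sigma = float(np.median(pdist(rows)))
    if not np.isfinite(sigma) or sigma <= 0:
        return 1.0
    return 1.0 / (2.0 * sigma**2)


def _make_estimator(method: str, params: dict[str, Any], config: ImputerConfig,
                    seed: int, X_train: np.ndarray, probability: bool = False):
    if method == LR:
        return LogisticRegression(penalty=None, solver="lbfgs", max_iter=500)
    if method == RF:
        return RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_features=params["mtry"],
            random_state=seed,
        )
    if method == NN:
        return MLPClassifier(
            hidden_layer_sizes=(params["size"],),
            alpha=params["decay"],
            solver="lbfgs",
            max_iter=config.nn_max_iter,
            random_state=seed,
        )
    if method == SVM:
        return SVC(
            C=params["C"],
            kernel="rbf",
            gamma=_median_heuristic_gamma(X_train),
            probability=probability,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier method {method!r}")


def _fit(method: str, params: dict[str, Any], config: ImputerConfig, seed: int,
         X: np.ndarray, y: np.ndarray, probability: bool = False):
    est = _make_estimator(method, params, config, seed, X, probability)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(X, y)
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
    if method == LR and not converged:
        # quasi-separation: refit with a ridge penalty
        warnings.warn("logistic imputer did not converge; ridge fallback",
                      RuntimeWarning, stacklevel=2)
        est = LogisticRegression(penalty="l2", C=1e3, solver="lbfgs",
                                 max_iter=1000)
        est.fit(X, y)
    return est


def _scores(est, X: np.ndarray) -> np.ndarray:
    # ranking scores for AUC: decision values for non-probability SVMs,
    # class-1 probabilities otherwise
    if isinstance(est, SVC) and not est.probability:
        return est.decision_function(X)
    return est.predict_proba(X)[:, 1]


def _grid(method: str, config: ImputerConfig) -> list[dict[str, Any]]:
    # enumerated in simplicity order so the first grid-search maximum is the
    # simplest model (smaller size/mtry/C, larger decay)
    if method == LR:
        return []
    if method == RF:
        return [{"mtry": m} for m in sorted(config.rf_mtry_grid)]
    if method == NN:
        return [
            {"size": s, "decay": d}
            for s in sorted(config.nn_size_grid)
            for d in sorted(config.nn_decay_grid, reverse=True)
        ]
    if method == SVM:
        return [{"C": c} for c in sorted(config.svm_c_grid)]
    raise ValueError(f"unknown classifier method {method!r}")


def _check_folds(y: np.ndarray, folds: int) -> None:
    counts = np.bincount(y.astype(int))
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} complete cases; cannot form "
            f"{folds} stratified folds with both classes — reduce cv_folds"
        )


def tune_classifier(incomplete: IncompleteCohort, method: str,
                    config: ImputerConfig | None = None) -> TunedModel:
    """Grid-search hyperparameters by mean AUC over stratified CV folds.

    The complete cases are the CV population: the target variable is the
    label and all other variables (outcome included) are features.  Ties
    break toward the simpler model.  LR has no tunable hyperparameters and
    is returned as-is.
    """
    config = config or ImputerConfig()
    if method not in _CLASSIFIER_METHODS:
        raise ValueError(f"{method!r} is not a tunable classifier")
    seed = _derive_seed(config.seed, incomplete.scenario.seed, method)
    grid = _grid(method, config)
    if not grid:
        return TunedModel(method, {}, [], seed)

    obs = incomplete.complete_index
    X = _encode_predictors(incomplete.records, method, obs)[obs]
    y = _target_codes(incomplete.records)[obs].astype(int)
    _check_folds(y, config.cv_folds)
    splitter = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                               random_state=seed)
    folds = list(splitter.split(X, y))

    cv_results: list[tuple[dict[str, Any], float]] = []
    best_params, best_auc = None, -np.inf
    for params in grid:
        aucs = []
        for train, test in folds:
            est = _fit(method, params, config, seed, X[train], y[train])
            aucs.append(roc_auc_score(y[test], _scores(est, X[test])))
        mean_auc = float(np.mean(aucs))
        cv_results.append((params, mean_auc))
        if mean_auc > best_auc:
            best_params, best_auc = params, mean_auc
    return TunedModel(method, best_params, cv_results, seed)


def impute_classifier(incomplete: IncompleteCohort, tuned: TunedModel,
                      config: ImputerConfig | None = None) -> CompletedCohort:
    """Fit the tuned classifier on complete cases and predict masked cells."""
    config = config or ImputerConfig()
    obs = incomplete.complete_index
    mis = incomplete.missing_index
    if len(mis) == 0:
        return _fill(incomplete, np.empty(0, dtype=object),
                     {"method": tuned.method, "params": tuned.params})
    X = _encode_predictors(incomplete.records, tuned.method, obs)
    y = _target_codes(incomplete.records)[obs].astype(int)
    est = _fit(tuned.method, tuned.params, config, tuned.seed, X[obs], y)
    codes = est.predict(X[mis])
    return _fill(incomplete, _decode_target(codes),
                 {"method": tuned.method, "params": tuned.params,
                  "cv_results": tuned.cv_results})


def impute_stacking(incomplete: IncompleteCohort,
                    config: ImputerConfig | None = None) -> CompletedCohort:
    """Stacked-generalisation ensemble imputation.

    The four first-stage learners (LR, RF, NN, RBF-SVM) are tuned as usual,
    then produce out-of-fold class-1 probabilities over the complete cases
    through a shared stratified split; a second-stage RBF-SVM (cost tuned
    on the same grid) is trained on that n_complete x 4 matrix.  Masked
    records are scored by the first-stage models refit on all complete
    cases, and the meta-model emits the imputed class.
    """
    config = config or ImputerConfig()
    obs = incomplete.complete_index
    mis = incomplete.missing_index
    stage1 = {m: tune_classifier(incomplete, m, config)
              for m in _CLASSIFIER_METHODS}
    if len(mis) == 0:
        return _fill(incomplete, np.empty(0, dtype=object), {"method": EL})

    y = _target_codes(incomplete.records)[obs].astype(int)
    _check_folds(y, config.cv_folds)
    seed = _derive_seed(config.seed, incomplete.scenario.seed, EL)
    splitter = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                               random_state=seed)

    encodings = {
        m: _encode_predictors(incomplete.records, m, obs)
        for m in _CLASSIFIER_METHODS
    }
    # out-of-fold class-1 probabilities, one meta-feature per learner
    Z_obs = np.zeros((len(obs), len(_CLASSIFIER_METHODS)))
    folds = list(splitter.split(encodings[LR][obs], y))
    for j, method in enumerate(_CLASSIFIER_METHODS):
        X = encodings[method][obs]
        tm = stage1[method]
        for train, test in folds:
            est = _fit(method, tm.params, config, tm.seed, X[train], y[train],
                       probability=True)
            Z_obs[test, j] = est.predict_proba(X[test])[:, 1]

    # second-stage RBF-SVM, cost tuned by CV AUC on the meta-features
    meta_results: list[tuple[dict[str, Any], float]] = []
    best_c, best_auc = None, -np.inf
    for c in sorted(config.svm_c_grid):
        aucs = []
        for train, test in folds:
            est = SVC(C=c, kernel="rbf",
                      gamma=_median_heuristic_gamma(Z_obs[train]),
                      random_state=seed)
            est.fit(Z_obs[train], y[train])
            aucs.append(roc_auc_score(y[test], est.decision_function(Z_obs[test])))
        mean_auc = float(np.mean(aucs))
        meta_results.append(({"C": c}, mean_auc))
        if mean_auc > best_auc:
            best_c, best_auc = c, mean_auc
    meta = SVC(C=best_c, kernel="rbf",
               gamma=_median_heuristic_gamma(Z_obs), random_state=seed)
    meta.fit(Z_obs, y)

    Z_mis = np.zeros((len(mis), len(_CLASSIFIER_METHODS)))
    for j, method in enumerate(_CLASSIFIER_METHODS):
        X_all = encodings[method]
        tm = stage1[method]
        est = _fit(method, tm.params, config, tm.seed, X_all[obs], y,
                   probability=True)
        Z_mis[:, j] = est.predict_proba(X_all[mis])[:, 1]
    codes = meta.predict(Z_mis)
    return _fill(incomplete, _decode_target(codes),
                 {"method": EL,
                  "stage1_params": {m: stage1[m].params for m in stage1},
                  "meta_C": best_c, "meta_cv_results": meta_results})


# ---------------------------------------------------------------------------
# dispatcher

def impute(incomplete: IncompleteCohort, method: str,
           config: ImputerConfig | None = None) -> CompletedCohort:
    """Run one of the eight imputation methods on an incomplete cohort."""
    config = config or ImputerConfig()
    if method == MODE:
        return impute_mode(incomplete)
    if method == KNN:
        return impute_knn(incomplete, config)
    if method == MICE_PMM:
        return impute_mice_pmm(incomplete, config)
    if method in _CLASSIFIER_METHODS:
        tuned = tune_classifier(incomplete, method, config)
        return impute_classifier(incomplete, tuned, config)
    if method == EL:
        return impute_stacking(incomplete, config)
    raise ValueError(f"unknown imputation method {method!r}")
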