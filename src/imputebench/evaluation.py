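"""Decision-impact evaluation of completed cohorts.

An imputation method is judged not by how well it restores the masked
values themselves, but by how the downstream clinical decision model
behaves on the completed dataset: a binary logistic regression of
discharge failure (coded 1) on the eight clinical variables is fit on the
completed cohort and scored by sensitivity, AUC and Cohen's kappa, with
the same model fit on the original complete cohort as the reference.

Metric definitions (failure = positive class):

* sensitivity = TP / (TP + FN)
* kappa = (p_o - p_e) / (1 - p_e) with p_o = (TP + TN) / n and
  p_e = [(TP + FN)(TP + FP) + (TN + FP)(TN + FN)] / n^2
* AUC = probability that a random positive outranks a random negative,
  ties counted 1/2 (rank formulation).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .cohort import OUTCOME, encode_features, table2_profile
from .imputers import CompletedCohort

__all__ = [
    "OutcomeModel",
    "ConfusionCounts",
    "MetricSet",
    "ScenarioResult",
    "fit_outcome_model",
    "compute_metrics",
    "youden_threshold",
    "evaluate_scenario",
    "average_over_proportions",
    "average_metrics",
]


@dataclasses.dataclass
class OutcomeModel:
    """Fitted discharge-failure logit: coefficients and per-record risks."""

    coefficients: np.ndarray
    column_names: list[str]
    probabilities: np.ndarray
    converged: bool
    ridge_fallback: bool = False


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclasses.dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    auc: float
    kappa: float
    p_o: float
    p_e: float
    confusion: ConfusionCounts | None = None


@dataclasses.dataclass
class ScenarioResult:
    """Metrics for one scenario x method cell plus the reference triple."""

    mechanism: str
    proportion: float
    method: str
    metrics: MetricSet
    reference: MetricSet


def _design(records: pd.DataFrame) -> tuple[np.ndarray, list[str], np.ndarray]:
    # one-hot design with reference levels (first-listed categories) dropped
    profile = table2_profile()
    fm = encode_features(
        records, scheme="onehot",
        include=[v.name for v in profile.variables],
    )
    keep, names = [], []
    seen: dict[str, bool] = {}
    for j, (src, label) in enumerate(fm.columns):
        if label == "code":
            keep.append(j)
            names.append(src)
        else:
            if not seen.get(src):       # drop the first (reference) level
                seen[src] = True
                continue
            keep.append(j)
            names.append(f"{src}[{label}]")
    X = fm.matrix[:, keep]
    # constant columns carry no information and make the Hessian singular
    varying = X.std(axis=0) > 0
    X = X[:, varying]
    names = [n for n, v in zip(names, varying) if v]
    y = records[OUTCOME].to_numpy(dtype=float)
    return X, names, y


def fit_outcome_model(records: pd.DataFrame, tol: float = 1e-8,
                      maxiter: int = 100) -> OutcomeModel:
    """Maximum-likelihood logit of discharge failure on the 8 variables.

    On separation or non-convergence the fit falls back to a lightly
    ridge-penalised logistic regression, with a warning.
    """
    X, names, y = _design(records)
    if np.unique(y).size < 2:
        raise ValueError("outcome must contain both classes")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(method="newton", tol=tol,
                                      maxiter=maxiter, disp=0)
        converged = bool(fit.mle_retvals.get("converged", False))
        finite = np.all(np.isfinite(fit.params)) and float(
            np.abs(fit.params).max()
        ) < 1e3
    except (np.linalg.LinAlgError, ValueError):
        converged = finite = False
        fit = None
    if fit is not None and converged and finite:
        return OutcomeModel(
            coefficients=np.asarray(fit.params),
            column_names=["const", *names],
            probabilities=np.asarray(fit.predict(Xc)),
            converged=True,
        )
    warnings.warn("outcome logit did not converge; ridge fallback",
                  RuntimeWarning, stacklevel=2)
    ridge = LogisticRegression(penalty="l2", C=1e3, solver="lbfgs",
                               max_iter=2000)
    ridge.fit(X, y)
    coef = np.concatenate([ridge.intercept_, ridge.coef_.ravel()])
    return OutcomeModel(
        coefficients=coef,
        column_names=["const", *names],
        probabilities=ridge.predict_proba(X)[:, 1],
        converged=False,
        ridge_fallback=True,
    )


def _rank_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney form: ties in score counted half via midranks
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(probabilities)
    return float(
        (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def compute_metrics(probabilities: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> MetricSet:
    """Sensitivity, AUC and Cohen's kappa at a classification threshold.

    A record is classified as failure when its fitted probability is >=
    the threshold.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")
    if probabilities.min() < 0 or probabilities.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (probabilities >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    n = tp + fn + fp + tn
    sensitivity = tp / (tp + fn)
    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = 0.0 if p_e == 1 else (p_o - p_e) / (1 - p_e)
    return MetricSet(
        sensitivity=sensitivity,
        auc=_rank_auc(probabilities, labels),
        kappa=kappa,
        p_o=p_o,
        p_e=p_e,
        confusion=ConfusionCounts(tp, fn, fp, tn, threshold),
    )


def youden_threshold(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximising sensitivity + specificity - 1 (Youden's J)."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    candidates = np.unique(probabilities)
    best_t, best_j = 0.5, -np.inf
    for t in candidates:
        pred = probabilities >= t
        sens = np.sum(pred & (labels == 1)) / np.sum(labels == 1)
        spec = np.sum(~pred & (labels == 0)) / np.sum(labels == 0)
        j = sens + spec - 1
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def evaluate_scenario(completed: CompletedCohort,
                      reference: MetricSet,
                      threshold: float = 0.5,
                      threshold_mode: str = "fixed") -> ScenarioResult:
    """Fit the outcome model on a completed cohort and score it.

    Apparent (resubstitution) performance: the model is evaluated on the
    records it was fit on, mirroring the single reference fit on the
    original complete dataset.  ``threshold_mode="youden"`` replaces the
    fixed cutoff with the Youden-optimal one.
    """
    model = fit_outcome_model(completed.records)
    labels = completed.records[OUTCOME].to_numpy(dtype=int)
    if threshold_mode == "youden":
        threshold = youden_threshold(model.probabilities, labels)
    elif threshold_mode != "fixed":
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    metrics = compute_metrics(model.probabilities, labels, threshold)
    scenario = completed.provenance["scenario"]
    return ScenarioResult(
        mechanism=scenario.mechanism,
        proportion=scenario.proportion,
        method=completed.provenance.get("method", "?"),
        metrics=metrics,
        reference=reference,
    )


def average_metrics(metric_sets: list[MetricSet]) -> MetricSet:
    """Unweighted arithmetic mean of sensitivity, AUC and kappa."""
    if not metric_sets:
        raise ValueError("cannot average an empty list")
    return MetricSet(
        sensitivity=float(np.mean([m.sensitivity for m in metric_sets])),
        auc=float(np.mean([m.auc for m in metric_sets])),
        kappa=float(np.mean([m.kappa for m in metric_sets])),
        p_o=float(np.mean([m.p_o for m in metric_sets])),
        p_e=float(np.mean([m.p_e for m in metric_sets])),
    )


def average_over_proportions(results: list[ScenarioResult]) -> MetricSet:
    """Average one method's metrics across the proportion grid.

    All results must share mechanism and method (the "Average" row of the
    per-mechanism report tables).
    """
    if not results:
        raise ValueError("cannot average an empty list")
    mechanisms = {r.mechanism for r in results}
    methods = {r.method for r in results}
    if len(mechanisms) > 1 or len(methods) > 1:
        raise ValueError("results must share mechanism and method")
    return average_metrics([r.metrics for r in results])
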