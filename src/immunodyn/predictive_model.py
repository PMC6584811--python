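"""L1-penalized logistic modelling of feature rates with repeated holdout.

The estimator maximizes the penalized log-likelihood

    l(beta) = sum_i [y_i beta' x_i - log(1 + exp(beta' x_i))] - lam * ||beta||_1

(with an additional unpenalized intercept) by monotone coordinate descent,
selects lam by inner cross-validation over a log-spaced path, and evaluates
generalization by repeatedly training on a random subset of patients and
predicting the held-out rest; each patient's final blinded prediction is
the mean of their out-of-sample predicted probabilities.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._solver import _pls_logistic, _pls_path
from .dynamics import DynamicsMatrix
from .errors import ValidationError
from .univariate_stats import rank_sum_test, roc_auc

logger = logging.getLogger(__name__)

GROUP_CODES = {"control": 0, "case": 1}


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                     intercept: float, lam: float) -> float:
    """Penalized log-likelihood (the maximized objective)."""
    z = X @ beta + intercept
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    return ll - lam * float(np.abs(beta).sum())


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X and y shapes do not align")
    if not np.isfinite(X).all():
        raise ValidationError("non-finite values in X (impute first)")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) != 2:
        raise ValidationError("y must contain both classes coded 0/1")
    return X, y


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes every coefficient (intercept free)."""
    X, y = _check_Xy(X, y)
    return float(np.abs(X.T @ (y - y.mean())).max())


def lambda_path(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100,
                min_ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced path from lambda_max to min_ratio*lambda_max."""
    lmax = lambda_max(X, y)
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, min_ratio * lmax, n_lambdas)


@dataclass
class PenalizedLogisticFit:
    """Solution of one penalized-logistic fit at a fixed penalty."""

    beta: np.ndarray
    intercept: float
    lam: float
    objective: float            # penalized log-likelihood at the solution
    converged: bool
    n_passes: int
    objective_trace: np.ndarray | None = None

    @property
    def support(self) -> np.ndarray:
        return self.beta != 0.0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(X, dtype=float) @ self.beta + self.intercept)


def fit_penalized_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                           tol: float = 1e-10, max_outer: int = 500,
                           inner_tol: float = 1e-9, max_inner: int = 1000,
                           keep_trace: bool = False) -> PenalizedLogisticFit:
    """Fit at one penalty value by IRLS with inner coordinate descent.

    ``X`` is expected standardized by the caller; coefficients are reported
    on the scale of the columns as given. The outer objective sequence is
    non-increasing (step-halving safeguard); ``tol`` bounds the objective
    decrease at termination.
    """
    X, y = _check_Xy(X, y)
    if lam < 0:
        raise ValidationError("lam must be >= 0")
    beta = np.zeros(X.shape[1])
    ybar = y.mean()
    b_arr = np.array([np.log(ybar / (1.0 - ybar))])
    trace = np.empty(max_outer if keep_trace else 0)
    n_passes, converged = _pls_logistic(X, y, float(lam), beta, b_arr,
                                        max_outer, tol, inner_tol, max_inner,
                                        trace)
    if not converged:
        logger.warning("solver hit the iteration cap (%d) at lam=%.3g "
                       "(expected for separable data at tiny penalties)",
                       max_outer, lam)
    obj = penalized_loglik(X, y, beta, float(b_arr[0]), lam)
    return PenalizedLogisticFit(
        beta=beta, intercept=float(b_arr[0]), lam=float(lam), objective=obj,
        converged=bool(converged), n_passes=int(n_passes),
        objective_trace=-trace[:n_passes] if keep_trace else None)


def fit_lambda_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                    tol: float = 1e-9, inner_tol: float = 1e-8,
                    max_outer: int = 100, max_inner: int = 500
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started coefficients/intercepts along a descending path."""
    X, y = _check_Xy(X, y)
    betas, intercepts, flags = _pls_path(
        X, y, np.asarray(lambdas, dtype=float), max_outer, tol, inner_tol,
        max_inner)
    if not flags.all():
        logger.debug("path fits hitting the iteration cap: %d",
                     int((~flags).sum()))
    return betas, intercepts


def binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, -2*mean[y log p + (1-y) log(1-p)]."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def select_lambda(X: np.ndarray, y: np.ndarray, n_folds: int = 5,
                  seed: int = 0, n_lambdas: int = 100,
                  min_ratio: float = 0.01, rule: str = "1se") -> float:
    """Cross-validated penalty over a log-spaced path (stratified K-fold).

    ``rule='min'`` returns the penalty minimizing mean held-out binomial
    deviance; the default ``'1se'`` returns the largest (sparsest) penalty
    whose mean deviance is within one standard error of that minimum —
    the conservative choice needed for a calibrated null (plain argmin
    systematically over-selects noise features on small cohorts).
    """
    X, y = _check_Xy(X, y)
    lambdas = lambda_path(X, y, n_lambdas, min_ratio)
    n_minor = int(min(y.sum(), (1 - y).sum()))
    folds = max(2, min(n_folds, n_minor))
    if folds != n_folds:
        logger.info("reducing inner CV folds to %d (minority class size)",
                    folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_dev = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:  # cannot happen with stratification
            continue
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        betas, intercepts = fit_lambda_path(Xtr, y[tr], lambdas)
        P = _sigmoid(Xte @ betas.T + intercepts)
        P = np.clip(P, 1e-12, 1 - 1e-12)
        yk = y[te][:, None]
        fold_dev.append(-2.0 * np.mean(
            yk * np.log(P) + (1 - yk) * np.log(1 - P), axis=0))
    fold_dev = np.vstack(fold_dev)
    mean_dev = fold_dev.mean(axis=0)
    k_min = int(np.argmin(mean_dev))  # first = largest lam on ties
    if rule == "min":
        return float(lambdas[k_min])
    if rule != "1se":
        raise ValidationError(f"unknown selection rule {rule!r}")
    se = fold_dev[:, k_min].std(ddof=1) / np.sqrt(fold_dev.shape[0]) \
        if fold_dev.shape[0] > 1 else 0.0
    if not np.isfinite(se):
        se = 0.0
    within = np.flatnonzero(mean_dev <= mean_dev[k_min] + se)
    return float(lambdas[int(within[0])])  # largest qualifying penalty


@dataclass
class HoldoutIteration:
    test_patients: list[str]
    lam: float
    coefs: np.ndarray
    intercept: float


@dataclass
class ModelResult:
    """Repeated-holdout ensemble of penalized logistic fits."""

    feature_names: list[str]
    patients: list[str]
    labels: np.ndarray                       # 0/1 per patient
    iterations: list[HoldoutIteration]
    final_predictions: pd.Series             # mean out-of-sample probability
    predictions_per_patient: dict[str, list[float]]
    auc: float
    p_value: float
    n_iterations: int                        # requested
    n_iterations_total: int                  # incl. coverage top-ups
    seed: int
    rates: pd.DataFrame | None = None        # unstandardized design matrix

    @property
    def coef_matrix(self) -> np.ndarray:
        return np.vstack([it.coefs for it in self.iterations])

    @property
    def support_matrix(self) -> np.ndarray:
        return self.coef_matrix != 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "patients": self.patients,
            "labels": self.labels.astype(int).tolist(),
            "auc": self.auc,
            "p_value": self.p_value,
            "n_iterations": self.n_iterations,
            "n_iterations_total": self.n_iterations_total,
            "seed": self.seed,
            "final_predictions": self.final_predictions.round(10).to_dict(),
            "predictions_per_patient": {
                k: [round(v, 10) for v in vs]
                for k, vs in self.predictions_per_patient.items()},
            "iterations": [{
                "test_patients": it.test_patients,
                "lambda": it.lam,
                "intercept": it.intercept,
                "coefs": [round(c, 12) for c in it.coefs.tolist()],
            } for it in self.iterations],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelResult":
        d = json.loads(Path(path).read_text())
        iterations = [HoldoutIteration(it["test_patients"], it["lambda"],
                                       np.asarray(it["coefs"]), it["intercept"])
                      for it in d["iterations"]]
        return cls(feature_names=d["feature_names"], patients=d["patients"],
                   labels=np.asarray(d["labels"], dtype=float),
                   iterations=iterations,
                   final_predictions=pd.Series(d["final_predictions"]).reindex(
                       d["patients"]),
                   predictions_per_patient=d["predictions_per_patient"],
                   auc=d["auc"], p_value=d["p_value"],
                   n_iterations=d["n_iterations"],
                   n_iterations_total=d["n_iterations_total"], seed=d["seed"])


def evaluate_predictions(predictions: Sequence[float],
                         labels: Sequence[float]) -> tuple[float, float]:
    """AUC (Mann-Whitney U / n1 n0, ties 0.5) and a two-sided rank-sum
    p-value comparing predictions between the groups."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes required to evaluate predictions")
    if np.ptp(predictions) == 0:
        warnings.warn("constant predictions; AUC=0.5, p=1", stacklevel=2)
        return 0.5, 1.0
    auc = roc_auc(predictions, labels)
    p = rank_sum_test(predictions[labels == 1], predictions[labels == 0])
    return auc, p


def _labels_from_sheet(sheet: pd.DataFrame) -> np.ndarray:
    groups = sheet["group"].astype(str)
    unknown = set(groups) - set(GROUP_CODES)
    if unknown:
        raise ValidationError(
            f"group labels must be in {set(GROUP_CODES)}, got {unknown}")
    return groups.map(GROUP_CODES).to_numpy(dtype=float)


def _impute_train_test(Xtr: np.ndarray, ytr: np.ndarray,
                       Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group mean imputation on train; blinded (overall train mean)
    imputation on test."""
    Xtr = Xtr.copy()
    Xte = Xte.copy()
    overall = np.nanmean(Xtr, axis=0)
    overall = np.where(np.isfinite(overall), overall, 0.0)
    for cls in (0.0, 1.0):
        rows = ytr == cls
        gm = np.nanmean(Xtr[rows], axis=0)
        gm = np.where(np.isfinite(gm), gm, overall)
        sub = Xtr[rows]
        nan = np.isnan(sub)
        sub[nan] = np.broadcast_to(gm, sub.shape)[nan]
        Xtr[rows] = sub
    nan = np.isnan(Xte)
    Xte[nan] = np.broadcast_to(overall, Xte.shape)[nan]
    return Xtr, Xte


def repeated_holdout(D: DynamicsMatrix, sheet: pd.DataFrame | None = None,
                     n_test: int = 3, n_iterations: int = 100, seed: int = 0,
                     n_folds: int = 5, n_lambdas: int = 100,
                     min_ratio: float = 0.01,
                     calibrate_intercept: bool = True) -> ModelResult:
    """Repeated random-subsampling validation of the penalized model.

    Each iteration holds out ``n_test`` patients, standardizes and imputes
    on the training rest, selects the penalty by inner CV, fits, and
    predicts the held-out probabilities. Iterations are appended past
    ``n_iterations`` until every patient was held out at least once.

    ``calibrate_intercept`` shifts each iteration's intercept to a
    balanced prior before predicting (a per-iteration monotone transform).
    Without it, unstratified test draws leak the held-out labels through
    the training prevalence: a held-out case lowers the train prevalence
    and hence its own near-null predicted probability, driving ensemble
    AUC far below 0.5 on label-permuted data.
    """
    sheet = D.sheet if sheet is None else sheet
    patients = [str(p) for p in D.values.index]
    sheet = sheet.copy()
    sheet["patient"] = sheet["patient"].astype(str)
    sheet = sheet.set_index("patient").loc[patients].reset_index()
    y = _labels_from_sheet(sheet)
    X_full = D.values.to_numpy(dtype=float)
    n = len(patients)
    if n < n_test + 4:
        raise ValidationError(f"cohort of {n} too small for n_test={n_test}")
    if len(np.unique(y)) < 2:
        raise ValidationError("cohort must contain both groups")

    rng = np.random.default_rng(seed)
    iterations: list[HoldoutIteration] = []
    preds: dict[str, list[float]] = {p: [] for p in patients}
    n_redraws = 0

    def run_iteration(test_idx: np.ndarray) -> None:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xtr, Xte = _impute_train_test(X_full[train_idx], y[train_idx],
                                      X_full[test_idx])
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
        cv_seed = int(rng.integers(2 ** 31 - 1))
        lam = select_lambda(Xtr, y[train_idx], n_folds=n_folds, seed=cv_seed,
                            n_lambdas=n_lambdas, min_ratio=min_ratio)
        fit = fit_penalized_logistic(Xtr, y[train_idx], lam, tol=1e-9)
        intercept = fit.intercept
        if calibrate_intercept:
            pi = y[train_idx].mean()
            intercept -= np.log(pi / (1.0 - pi))
        p_te = _sigmoid(Xte @ fit.beta + intercept)
        for k, idx in enumerate(test_idx):
            preds[patients[idx]].append(float(p_te[k]))
        iterations.append(HoldoutIteration(
            [patients[i] for i in test_idx], lam, fit.beta, fit.intercept))

    def draw_test() -> np.ndarray:
        nonlocal n_redraws
        while True:
            test_idx = rng.choice(n, size=n_test, replace=False)
            train_y = np.delete(y, test_idx)
            if len(np.unique(train_y)) == 2:
                return np.sort(test_idx)
            n_redraws += 1

    for _ in range(n_iterations):
        run_iteration(draw_test())

    # coverage top-up: every patient must receive >= 1 blinded prediction
    uncovered = [i for i, p in enumerate(patients) if not preds[p]]
    while uncovered:
        take = uncovered[:n_test]
        if len(take) < n_test:
            others = np.setdiff1d(np.arange(n), take)
            take = list(take) + list(rng.choice(
                others, size=n_test - len(take), replace=False))
        test_idx = np.sort(np.asarray(take))
        if len(np.unique(np.delete(y, test_idx))) < 2:
            test_idx = draw_test()
        logger.info("coverage top-up iteration for patients %s",
                    [patients[i] for i in test_idx])
        run_iteration(test_idx)
        uncovered = [i for i, p in enumerate(patients) if not preds[p]]
    if n_redraws:
        logger.info("redrew %d single-class training splits", n_redraws)

    final = pd.Series({p: float(np.mean(v)) for p, v in preds.items()},
                      name="prediction").reindex(patients)
    auc, p_value = evaluate_predictions(final.to_numpy(), y)
    return ModelResult(
        feature_names=list(D.values.columns), patients=patients, labels=y,
        iterations=iterations, final_predictions=final,
        predictions_per_patient=preds, auc=auc, p_value=p_value,
        n_iterations=n_iterations, n_iterations_total=len(iterations),
        seed=seed, rates=D.values)
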