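"""Logistic-regression reranking of n-best LF candidate lists.

A candidate's correctness probability is modeled as sigma(z) with

    z = beta0 + beta1*rank + beta2*charmatch + beta3*log(1 + freq)

Three nested formulas are used: rank only; rank + charmatch; rank +
charmatch + log(1+freq).  Negative beta1 means candidates near the top of
the n-best list are more likely correct; positive beta2 and beta3 mean
spelling-convention agreement and cross-document co-definition frequency
both raise the probability.  Reranking sorts each n-best group by z.

Twelve preset coefficient vectors are shipped (three formulas x four
benchmark gold sets).  Fitting is unpenalized maximum likelihood via
Newton-Raphson, with an optional L2 ridge for separable data.  The
reranker is an sklearn-style estimator and composes with sklearn
pipelines/model selection; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

FEATURE_NAMES = ("rank", "charmatch", "log1p_freq")

#: Preset coefficient grid (beta0, beta1, beta2, beta3), model ids 1-12.
#: Models 1-4 use rank only; 5-8 add charmatch; 9-12 add log(1+freq).
PRESETS: dict[int, tuple[float, float, float, float]] = {
    1: (1.6, -3.3, 0.0, 0.0),
    2: (0.7, -1.6, 0.0, 0.0),
    3: (1.9, -3.9, 0.0, 0.0),
    4: (1.4, -3.3, 0.0, 0.0),
    5: (-1.2, -3.2, 3.5, 0.0),
    6: (-2.5, -1.5, 3.8, 0.0),
    7: (-1.0, -4.0, 3.9, 0.0),
    8: (-1.9, -3.2, 4.1, 0.0),
    9: (-2.7, -2.9, 3.7, 0.3),
    10: (-5.2, -1.5, 5.2, 0.5),
    11: (-3.2, -3.8, 4.7, 0.4),
    12: (-3.1, -2.9, 4.3, 0.3),
}

_ACTIVE_BY_PRESET = {
    **{k: ("rank",) for k in (1, 2, 3, 4)},
    **{k: ("rank", "charmatch") for k in (5, 6, 7, 8)},
    **{k: ("rank", "charmatch", "log1p_freq") for k in (9, 10, 11, 12)},
}


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass
class FitReport:
    """Convergence diagnostics for one maximum-likelihood fit."""

    coefficients: dict[str, float]
    log_likelihood: float
    n_iter: int
    converged: bool
    standard_errors: dict[str, float]


class SeparationError(RuntimeError):
    """Perfect separation: coefficients diverge; refit with ridge > 0."""


class LogisticReranker(BaseEstimator):
    """Sklearn-style logistic model over (rank, charmatch, log1p_freq).

    Parameters
    ----------
    active : sequence of str
        Feature subset from {"rank", "charmatch", "log1p_freq"};
        coefficients of inactive features are pinned to exactly 0.
    ridge : float
        L2 penalty on the non-intercept coefficients (0 = plain MLE).
    tol : float
        Convergence threshold on the log-likelihood change.
    max_iter : int
        Newton-Raphson iteration cap.

    Fitted attributes: ``beta_`` (beta0..beta3), ``report_``,
    ``provenance_`` ("fitted" or "preset-k").
    """

    def __init__(
        self,
        active: Sequence[str] = FEATURE_NAMES,
        ridge: float = 0.0,
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.active = active
        self.ridge = ridge
        self.tol = tol
        self.max_iter = max_iter

    # -- construction from the preset grid ---------------------------------
    @classmethod
    def from_preset(cls, model_id: int) -> "LogisticReranker":
        if model_id not in PRESETS:
            raise ValueError(f"model_id must be in 1..12, got {model_id}")
        est = cls(active=_ACTIVE_BY_PRESET[model_id])
        est.beta_ = np.array(PRESETS[model_id], dtype=float)
        est.report_ = None
        est.provenance_ = f"preset-{model_id}"
        return est

    # -- data marshalling ---------------------------------------------------
    def _check_active(self) -> tuple[str, ...]:
        active = tuple(self.active)
        unknown = set(active) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")
        if not active:
            raise ValueError("active feature subset must be non-empty")
        return active

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        """Accept a DataFrame with named columns or an (n, 3) array."""
        if isinstance(X, pd.DataFrame):
            return X.reindex(columns=list(FEATURE_NAMES), fill_value=0.0).to_numpy(float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != 3:
            raise ValueError("X must have columns (rank, charmatch, log1p_freq)")
        return X

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y) -> "LogisticReranker":
        active = self._check_active()
        Xm = self._as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if Xm.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if Xm.shape[0] == 0:
            raise ValueError("empty training data")
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ValueError("both gold classes (0 and 1) must be present")

        mask = np.array([name in active for name in FEATURE_NAMES])
        A = np.column_stack([np.ones(Xm.shape[0]), Xm[:, mask]])
        p_dim = A.shape[1]
        beta = np.zeros(p_dim)
        penalty = np.zeros(p_dim)
        penalty[1:] = self.ridge

        def loglik(b: np.ndarray) -> float:
            z = A @ b
            # log sigma(z)*y + log sigma(-z)*(1-y), numerically stable
            return float(np.sum(y * z - np.logaddexp(0.0, z)) - 0.5 * np.sum(penalty * b * b))

        ll_old = loglik(beta)
        converged = False
        n_iter = 0
        hessian = None
        for n_iter in range(1, self.max_iter + 1):
            p = sigmoid(A @ beta)
            w = p * (1.0 - p)
            grad = A.T @ (y - p) - penalty * beta
            hessian = (A * w[:, None]).T @ A + np.diag(penalty)
            try:
                step = np.linalg.solve(hessian, grad)
            except np.linalg.LinAlgError as exc:
                raise SeparationError(
                    "singular Hessian (perfect separation?); refit with ridge > 0"
                ) from exc
            beta = beta + step
            # on separable data Newton walks the coefficients off to infinity
            # while the log-likelihood creeps toward 0
            if self.ridge == 0.0 and np.max(np.abs(beta)) > 30.0:
                raise SeparationError(
                    "coefficients diverging (perfect separation); refit with ridge > 0"
                )
            ll_new = loglik(beta)
            if abs(ll_new - ll_old) < self.tol:
                converged = True
                ll_old = ll_new
                break
            ll_old = ll_new

        full = np.zeros(4)
        full[0] = beta[0]
        full[1:][mask] = beta[1:]
        self.beta_ = full
        se = np.sqrt(np.diag(np.linalg.inv(hessian)))
        names = ("intercept",) + active
        self.report_ = FitReport(
            coefficients=dict(zip(names, beta.tolist())),
            log_likelihood=ll_old,
            n_iter=n_iter,
            converged=converged,
            standard_errors=dict(zip(names, se.tolist())),
        )
        self.provenance_ = "fitted"
        return self

    # -- scoring ------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        Xm = self._as_matrix(X)
        b = self.beta_
        return b[0] + Xm @ b[1:]

    def predict_proba(self, X) -> np.ndarray:
        p1 = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


# -- module-level operations over FeatureVectors / Candidates ---------------

def _fv_row(fv) -> list[float]:
    return [float(fv.rank), float(fv.charmatch), float(fv.log1p_freq)]


def preset(model_id: int) -> LogisticReranker:
    """The preset coefficient vector ``model_id`` (1..12) as a ready model."""
    return LogisticReranker.from_preset(model_id)


def score(model: LogisticReranker, fv) -> float:
    """sigma(z) for one feature vector: the modeled Pr(correct)."""
    return float(sigmoid(model.decision_function(np.array([_fv_row(fv)])))[0])


def fit(
    data: Iterable[tuple[object, int]],
    active: Sequence[str] = FEATURE_NAMES,
    ridge: float = 0.0,
) -> tuple[LogisticReranker, FitReport]:
    """Maximum-likelihood fit over (FeatureVector, gold) pairs."""
    rows, y = [], []
    for fv, gold in data:
        rows.append(_fv_row(fv))
        y.append(int(gold))
    if not rows:
        raise ValueError("empty training data")
    est = LogisticReranker(active=active, ridge=ridge).fit(np.array(rows), np.array(y))
    return est, est.report_


def rerank(candidates: Sequence[tuple[object, object]], model: LogisticReranker):
    """Sort one n-best group by descending z; ties keep the original rank order.

    ``candidates`` is a sequence of (Candidate, FeatureVector) sharing one
    (doc_id, sf).  Returns [(candidate, feature_vector, sigma(z)), ...].
    """
    keys = {(c.doc_id, c.sf) for c, _ in candidates}
    if len(keys) > 1:
        raise ValueError(f"mixed (doc_id, sf) groups in one rerank call: {sorted(keys)}")
    scored = [(c, fv, score(model, fv)) for c, fv in candidates]
    scored.sort(key=lambda t: (-t[2], t[0].rank))
    return scored


def median_confidence(model: LogisticReranker, data: Iterable[tuple[object, int]]) -> float:
    """Median sigma(z) over the correct (gold=1) candidates."""
    scores = [score(model, fv) for fv, gold in data if gold == 1]
    if not scores:
        raise ValueError("no correct candidates in data")
    return float(np.median(scores))
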