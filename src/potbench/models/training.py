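"""Model training: per-target ST models, the multi-target DNN, and grid-search CV.

Single-target (ST) families are random forest regression (RFR), support
vector regression (SVR) with the Tanimoto kernel, and a one-output DNN.  The
multi-target DNN (MT-DNN) is a single network with one output neuron per
target trained on the sparse label matrix under the masked MSE loss.  Random
forest and SVR fitting is delegated to scikit-learn; the Tanimoto kernel is
supplied as a precomputed kernel matrix.

Hyper-parameters are selected by two-fold cross-validation over a grid,
minimizing validation MSE, with ties broken by grid enumeration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from ..curation import PotencyMatrix
from ..fingerprints import tanimoto_kernel
from .grids import MT_DNN_REFERENCE
from .nn import MaskedMLPRegressor, masked_mse_loss

__all__ = [
    "TanimotoSVR",
    "TrainedModel",
    "GridSearchResult",
    "grid_search_cv",
    "train_st_model",
    "train_mt_dnn",
    "predict",
]

FAMILIES = ("rfr", "svr", "dnn", "mt_dnn")


class TanimotoSVR:
    """Epsilon-tube SVR on the Tanimoto kernel of binary fingerprints.

    The dual optimization is delegated to scikit-learn's SVR with a
    precomputed kernel; only the cost C is treated as a hyper-parameter
    (epsilon stays at the solver default 0.1).
    """

    def __init__(self, C: float = 1.0, epsilon: float = 0.1):
        self.C = C
        self.epsilon = epsilon
        self._svr: SVR | None = None
        self._X_train: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TanimotoSVR":
        self._X_train = np.asarray(X, dtype=np.float64)
        self._svr = SVR(kernel="precomputed", C=self.C, epsilon=self.epsilon)
        self._svr.fit(tanimoto_kernel(self._X_train), np.asarray(y, dtype=float))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svr.predict(tanimoto_kernel(np.asarray(X, float), self._X_train))


def _make_estimator(family: str, params: dict, seed: int, n_outputs: int = 1, **overrides):
    params = {**params, **overrides}
    if family == "rfr":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if family == "svr":
        return TanimotoSVR(**params)
    if family in ("dnn", "mt_dnn"):
        return MaskedMLPRegressor(n_outputs=n_outputs, seed=seed, **params)
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class GridSearchResult:
    best_params: dict
    best_index: int
    cv_mse: list[float]
    degenerate: bool = False


def grid_search_cv(
    family: str,
    grid: Sequence[dict],
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 2,
    seed: int = 0,
    **overrides,
) -> GridSearchResult:
    """Grid search by k-fold cross-validation, minimizing validation MSE.

    Returns the grid point with the smallest mean validation MSE across
    folds; ties are broken by grid enumeration order.  Deterministic for a
    fixed seed.  A degenerate training set (all-identical labels) returns the
    first grid point with a warning, since no grid point can be
    distinguished.  ``overrides`` are applied on top of every candidate
    (e.g. a reduced epoch budget for DNN candidates).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=float)
    if len(grid) == 0:
        raise ValueError("empty grid")
    if X.shape[0] < 2 * folds:
        raise ValueError(f"need at least {2 * folds} compounds for {folds}-fold CV")
    if np.all(y == y.flat[0]):
        warnings.warn("degenerate training set: all labels identical; "
                      "returning the first grid point")
        return GridSearchResult(dict(grid[0]), 0, [0.0] * len(grid), degenerate=True)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    K_full = tanimoto_kernel(X) if family == "svr" else None

    cv_mse = []
    for params in grid:
        fold_mse = []
        for tr, va in splits:
            if family == "svr":
                est = SVR(kernel="precomputed", C=params["C"],
                          epsilon=params.get("epsilon", 0.1))
                est.fit(K_full[np.ix_(tr, tr)], y[tr])
                pred = est.predict(K_full[np.ix_(va, tr)])
            else:
                est = _make_estimator(family, params, seed, **overrides)
                est.fit(X[tr], y[tr])
                pred = np.asarray(est.predict(X[va]))
                if pred.ndim == 2:
                    pred = pred[:, 0]
            fold_mse.append(float(np.mean((pred - y[va]) ** 2)))
        cv_mse.append(float(np.mean(fold_mse)))
    best_index = int(np.argmin(cv_mse))  # argmin keeps the first minimum: ties
    return GridSearchResult(dict(grid[best_index]), best_index, cv_mse)


@dataclass
class TrainedModel:
    """A fitted model plus the metadata needed to audit and reuse it."""

    family: str
    model: object
    params: dict
    seed: int
    target_id: str | None = None          # ST models
    targets: list[str] | None = None      # MT models (output-column order)
    metadata: dict = field(default_factory=dict)


def train_st_model(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    target_id: str | None = None,
    params: dict | None = None,
    grid: Sequence[dict] | None = None,
    folds: int = 2,
    seed: int = 0,
    min_train: int = 10,
    **overrides,
) -> TrainedModel:
    """Fit one single-target model (family in {rfr, svr, dnn}).

    Either explicit ``params`` or a ``grid`` (searched by
    :func:`grid_search_cv`) must be given.  Training sets smaller than
    ``min_train`` compounds are refused.
    """
    if family not in ("rfr", "svr", "dnn"):
        raise ValueError(f"not a single-target family: {family!r}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < min_train:
        raise ValueError(
            f"refusing to train on {X.shape[0]} compounds (< min_train={min_train})"
        )
    meta: dict = {"n_train": int(X.shape[0])}
    if params is None:
        if grid is None:
            raise ValueError("provide params or a grid")
        result = grid_search_cv(family, grid, X, y, folds=folds, seed=seed, **overrides)
        params = result.best_params
        meta["cv_best_index"] = result.best_index
    est = _make_estimator(family, params, seed, n_outputs=1, **overrides)
    est.fit(X, y)
    if isinstance(est, MaskedMLPRegressor):
        meta["epochs_run"] = est.n_epochs_
    return TrainedModel(family, est, dict(params), seed, target_id=target_id, metadata=meta)


def train_mt_dnn(
    X: np.ndarray,
    matrix: PotencyMatrix,
    mask: frozenset[tuple[str, str]],
    compound_ids: Sequence[str],
    params: dict | None = None,
    seed: int = 0,
    **overrides,
) -> TrainedModel:
    """Fit one multi-target DNN across all targets of ``matrix``.

    ``X`` rows correspond to ``compound_ids``.  The label matrix is
    densified with one output column per target; only (compound, target)
    pairs in ``mask`` (annotations assigned to training by the split)
    contribute to the masked MSE loss.  The default architecture is the
    reference MT configuration (2000/1000 hidden neurons, no batch norm,
    batch 128, dropout 0.1, lr 1e-4).
    """
    if not mask:
        raise ValueError("empty training mask")
    params = dict(MT_DNN_REFERENCE if params is None else params)
    targets = list(matrix.targets)
    t_index = {t: j for j, t in enumerate(targets)}
    c_index = {c: i for i, c in enumerate(compound_ids)}
    n, k = len(compound_ids), len(targets)
    Y = np.zeros((n, k))
    M = np.zeros((n, k), dtype=bool)
    for (c, t) in mask:
        if c not in c_index:
            raise ValueError(f"masked compound {c!r} has no fingerprint row")
        Y[c_index[c], t_index[t]] = matrix.entries[(c, t)]
        M[c_index[c], t_index[t]] = True
    est = _make_estimator("mt_dnn", params, seed, n_outputs=k, **overrides)
    est.fit(np.asarray(X, np.float64), Y, M)
    meta = {"n_train_labels": int(M.sum()), "epochs_run": est.n_epochs_}
    return TrainedModel("mt_dnn", est, params, seed, targets=targets, metadata=meta)


def predict(
    trained: TrainedModel,
    X: np.ndarray,
    compound_ids: Sequence[str],
    matrix: PotencyMatrix,
    targets: Sequence[str] | None = None,
    test_sets: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Prediction set: one record per (compound, target) with an observed pKi.

    Predictions without an observed label are excluded (evaluation happens
    only on available annotations); raw dense predictions remain available
    via ``trained.model.predict``.  For an ST model, requesting any target
    other than the one it was trained for is an error.  ``test_sets``
    optionally restricts each target's compounds (e.g. to a split's test
    side).
    """
    X = np.asarray(X, dtype=np.float64)
    if trained.family == "mt_dnn":
        cols = trained.targets
        if targets is None:
            targets = cols
        unknown = set(targets) - set(cols)
        if unknown:
            raise ValueError(f"model has no output for targets {sorted(unknown)}")
        dense = trained.model.predict(X)
        pred_col = {t: dense[:, cols.index(t)] for t in targets}
    else:
        if trained.target_id is None:
            raise ValueError("ST model lacks a target_id")
        if targets is None:
            targets = [trained.target_id]
        for t in targets:
            if t != trained.target_id:
                raise ValueError(
                    f"ST model trained for {trained.target_id!r} cannot predict {t!r}"
                )
        yhat = np.asarray(trained.model.predict(X)).reshape(len(compound_ids), -1)[:, 0]
        pred_col = {t: yhat for t in targets}
    rows = []
    for t in targets:
        allowed = None if test_sets is None else test_sets.get(t, set())
        for i, c in enumerate(compound_ids):
            if (c, t) not in matrix.entries:
                continue
            if allowed is not None and c not in allowed:
                continue
            rows.append((c, t, matrix.entries[(c, t)], float(pred_col[t][i])))
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "y", "y_hat"])
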