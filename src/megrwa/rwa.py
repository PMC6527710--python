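"""Relative Weights Analysis (RWA): variance apportionment under collinearity.

Given an outcome vector y (a vectorized neural RDM) and p correlated
predictors X (vectorized model RDMs), RWA replaces X by its best-fitting
orthogonal approximation Z, regresses y on Z, regresses each original
predictor on Z, and combines the two to obtain a non-negative relative
weight per predictor:

    eps_j = sum_k lambda_jk^2 * beta_k^2

where beta_k^2 is the variance in y accounted for by the k-th orthogonal
variable and lambda_jk^2 the variance in predictor j accounted for by it.
With standardized predictors and outcome the weights partition the total
explained variance: sum_j eps_j = R^2 of the ordinary regression of y on X.

Two orthogonalizations are available:

* ``"johnson"`` (default) — the minimally distorting orthogonal
  approximation from the singular value decomposition, Z = P Q^T for
  X = P Delta Q^T.  The closer Z is to X, the more interpretable the
  weights, which motivates this default.
* ``"pca"`` — unit-variance principal component scores of X.

Both produce orthonormal Z spanning the column space of X and satisfy the
partition identity; the individual weights may differ between methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .containers import EpsilonMap, ModelRDM, NeuralRDMSeries

__all__ = [
    "RWAResult",
    "RelativeWeightsRegression",
    "orthogonalize",
    "relative_weights",
    "searchlight_rwa",
]


def _standardize_columns(X: np.ndarray, what: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError(f"constant column in {what}; cannot standardize")
    return (X - X.mean(axis=0)) / sd


def orthogonalize(X: np.ndarray, method: str = "johnson") -> np.ndarray:
    """Orthogonal approximation Z of X with Z^T Z = I.

    ``"johnson"``: Z = P Q^T from the SVD X = P Delta Q^T — the orthonormal
    matrix closest to X in least squares.  ``"pca"``: unit-norm principal
    component scores, Z = X V Lambda^{-1/2} from the eigendecomposition of
    X^T X.  Raises on rank-deficient X, naming the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than predictors")
    P, delta, Qt = np.linalg.svd(X, full_matrices=False)
    tol = delta[0] * max(n, p) * np.finfo(float).eps
    if (delta < tol).any():
        deficient = np.nonzero(np.abs(Qt[delta < tol]).max(axis=0) > 0.1)[0]
        raise ValueError(
            f"predictor matrix is rank deficient; collinear columns: {deficient.tolist()}"
        )
    if method == "johnson":
        return P @ Qt
    if method == "pca":
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        return (X @ evecs) / np.sqrt(evals)[None, :]
    raise ValueError(f"unknown orthogonalization method {method!r}")


@dataclass
class RWAResult:
    """Relative weights of one regression.

    ``epsilon[j]`` is model j's share of explained variance; ``beta_sq[k]``
    the variance of y on orthogonal component k; ``lambda_sq[j, k]`` the
    variance of model j on component k; ``r_squared`` the OLS R^2 of y on X.
    """

    epsilon: np.ndarray
    beta_sq: np.ndarray
    lambda_sq: np.ndarray
    r_squared: float


class RelativeWeightsRegression(BaseEstimator):
    """Relative Weights Analysis as a scikit-learn style estimator.

    Parameters
    ----------
    orthogonalization : {"johnson", "pca"}
        How to build the orthogonal counterpart of X (see module docs).
    rank_transform : bool
        Rank-transform y and the columns of X before standardizing.
    standardize : bool
        z-score X columns and y before fitting (required for the
        partition identity; disable only for pre-standardized inputs).

    Attributes (after ``fit``)
    --------------------------
    epsilon_ : (p,) relative weight per predictor, non-negative.
    beta_sq_ : (p,) squared standardized coefficients of y on Z.
    lambda_sq_ : (p, p) squared loadings of each predictor on Z.
    r_squared_ : total explained variance; equals ``epsilon_.sum()``.
    """

    def __init__(
        self,
        orthogonalization: str = "johnson",
        rank_transform: bool = False,
        standardize: bool = True,
    ):
        self.orthogonalization = orthogonalization
        self.rank_transform = rank_transform
        self.standardize = standardize

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RelativeWeightsRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("X must be 2-D with rows aligned to y")
        if self.rank_transform:
            X = rankdata(X, axis=0)
            y = rankdata(y)
        if self.standardize:
            X = _standardize_columns(X, "X")
            sd = y.std()
            if sd == 0:
                warnings.warn("constant outcome; all relative weights set to 0", stacklevel=2)
                p = X.shape[1]
                self.epsilon_ = np.zeros(p)
                self.beta_sq_ = np.zeros(p)
                self.lambda_sq_ = np.zeros((p, p))
                self.r_squared_ = 0.0
                self.n_features_in_ = p
                return self
            y = (y - y.mean()) / sd
        n, p = X.shape
        Z = orthogonalize(X, self.orthogonalization)
        # Z has unit-norm columns; X, y are standardized. In the n-metric,
        # lambda_jk = corr(x_j, z_k) and beta_k = corr(y, z_k).
        lam = (X.T @ Z) / np.sqrt(n)
        beta = (Z.T @ y) / np.sqrt(n)
        self.lambda_sq_ = lam**2
        self.beta_sq_ = beta**2
        self.epsilon_ = self.lambda_sq_ @ self.beta_sq_
        self.r_squared_ = float(self.beta_sq_.sum())
        self.n_features_in_ = p
        return self

    def result_(self) -> RWAResult:
        return RWAResult(self.epsilon_, self.beta_sq_, self.lambda_sq_, self.r_squared_)


def relative_weights(
    y: np.ndarray,
    X: np.ndarray,
    orthogonalization: str = "johnson",
    rank_transform: bool = False,
    standardize: bool = True,
) -> RWAResult:
    """Functional wrapper around :class:`RelativeWeightsRegression`."""
    est = RelativeWeightsRegression(orthogonalization, rank_transform, standardize)
    return est.fit(X, y).result_()


def _epsilon_batch(Y: np.ndarray, X: np.ndarray, orthogonalization: str) -> np.ndarray:
    """Relative weights for many outcomes sharing one predictor matrix.

    ``Y``: (n_pairs, n_outcomes) already standardized columns (zero
    columns allowed: they yield zero weights).  ``X``: (n_pairs, p)
    standardized.  Returns (n_outcomes, p).
    """
    n = X.shape[0]
    Z = orthogonalize(X, orthogonalization)
    lam_sq = ((X.T @ Z) / np.sqrt(n)) ** 2  # (p, p) [j, k]
    B = (Z.T @ Y) / np.sqrt(n)  # (p, n_outcomes)
    return (lam_sq @ B**2).T


def searchlight_rwa(
    neural: NeuralRDMSeries,
    models: list[ModelRDM],
    orthogonalization: str = "johnson",
    rank_transform: bool = False,
) -> EpsilonMap:
    """Relative weights for every spatiotemporal searchlight of one subject.

    The model matrix is built once (vectorized upper triangles,
    standardized); each searchlight's neural RDM vector is standardized
    and apportioned.  Model and neural stimulus orders must agree.
    """
    stim = np.asarray(neural.stimulus_ids)
    for m in models:
        if m.stimulus_ids is not None and not np.array_equal(np.asarray(m.stimulus_ids), stim):
            raise ValueError(f"stimulus order mismatch between neural data and model {m.name!r}")
    X = np.column_stack([m.vector for m in models])
    if rank_transform:
        X = rankdata(X, axis=0)
    X = _standardize_columns(X, "model RDMs")
    s, t, n_pairs = neural.rdms.shape
    Y = neural.rdms.reshape(s * t, n_pairs).T.astype(float)
    if rank_transform:
        Y = rankdata(Y, axis=0)
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} searchlight(s) with constant RDM; weights set to 0",
            stacklevel=2,
        )
    Y = (Y - mean) / np.where(constant, 1.0, sd)
    Y[:, constant] = 0.0
    eps = _epsilon_batch(Y, X, orthogonalization)
    return EpsilonMap(
        epsilon=eps.reshape(s, t, len(models)),
        model_names=[m.name for m in models],
        sensor_ids=neural.sensor_ids,
        times=neural.times,
    )
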