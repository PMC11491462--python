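"""Two-stage abundance normalization and hidden-factor residualization.

RFU abundance distributions differ strongly between individuals (sequencing
depth, repertoire size), so association scans operate on a doubly
normalized scale: (1) each individual's abundance distribution is quantile
normalized to the average empirical distribution across individuals, then
(2) each RFU column is rank-transformed to the standard normal
distribution.  Known covariates and hidden confounding factors (an
expression-residual-style adjustment, implemented as principal components
of the covariate residual) are then projected out before scanning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .quantify import AbundanceMatrix


def quantile_normalize_individuals(a: AbundanceMatrix) -> AbundanceMatrix:
    """Quantile normalize each individual to the mean empirical distribution.

    The target distribution is the mean of the per-individual order
    statistics; each individual's values are replaced by the target values
    at their within-individual ranks, with ties receiving the mean of the
    target values they span.  After the operation every individual's sorted
    abundance vector equals the target vector (up to tie averaging).
    """
    X = a.data.to_numpy(dtype=float)
    n_ind, n_rfu = X.shape
    if n_ind == 1:
        warnings.warn("single individual: quantile normalization is the identity")
        return AbundanceMatrix(a.data.copy(), stage="quantile")
    target = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i in range(n_ind):
        order = np.argsort(X[i], kind="stable")
        sorted_vals = X[i][order]
        assigned = (
            pd.Series(target)
            .groupby(pd.Series(sorted_vals), sort=False)
            .transform("mean")
            .to_numpy()
        )
        out[i, order] = assigned
    return AbundanceMatrix(
        pd.DataFrame(out, index=a.data.index, columns=a.data.columns),
        stage="quantile",
    )


def inverse_normal_transform(column: np.ndarray) -> np.ndarray:
    """Rank-based transform of a vector to standard normal quantiles.

    Uses the Blom offset: ``Phi^-1((r - 3/8) / (n + 1/4))`` with average
    ranks for ties, which keeps extreme ranks finite.  Constant input is an
    error (ranks are degenerate).
    """
    x = np.asarray(column, dtype=float)
    if x.size < 2:
        raise ValueError("inverse-normal transform needs at least 2 values")
    if np.all(x == x[0]):
        raise ValueError("constant column: inverse-normal transform undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (x.size + 0.25))


def inverse_normal_columns(a: AbundanceMatrix) -> AbundanceMatrix:
    """Apply the inverse-normal transform to every RFU column.

    Columns that are constant across individuals (rank-degenerate, e.g. an
    RFU with one tied abundance everywhere) cannot be transformed and are
    dropped with a warning.
    """
    out = {}
    dropped = []
    for c in a.data.columns:
        col = a.data[c].to_numpy()
        if np.all(col == col[0]):
            dropped.append(c)
        else:
            out[c] = inverse_normal_transform(col)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant RFU column(s): {dropped[:5]}...")
    kept = [c for c in a.data.columns if c not in set(dropped)]
    return AbundanceMatrix(
        pd.DataFrame(out, index=a.data.index)[kept],
        stage="inverse_normal",
    )


class FactorResidualizer(BaseEstimator, TransformerMixin):
    """Project out known covariates and hidden factors from trait columns.

    ``fit`` regresses every trait column on the covariates (plus intercept)
    by OLS, extracts the top ``n_factors`` principal components of the
    residual matrix as hidden-confounder proxies, and freezes an
    orthonormal basis of the joint nuisance space.  ``transform`` removes
    the projection onto that frozen space, so repeated application is
    idempotent and output columns are orthogonal to both covariates and
    retained factors.

    Parameters
    ----------
    n_factors : int, default 2
        Number of hidden factors; the discovery-style configuration uses 2
        and the validation-style configuration 8.
    """

    def __init__(self, n_factors: int = 2):
        self.n_factors = n_factors

    @staticmethod
    def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
        cols = [np.ones((n, 1))]
        if covariates is not None and covariates.shape[1] > 0:
            if covariates.isna().any().any():
                raise ValueError("covariates contain missing values")
            cols.append(covariates.to_numpy(dtype=float))
        D = np.hstack(cols)
        # rank-revealing QR: drop collinear covariate columns
        q, r, piv = linalg.qr(D, mode="economic", pivoting=True)
        tol = max(D.shape) * np.finfo(float).eps * abs(r[0, 0]) if r.size else 0.0
        rank = int((np.abs(np.diag(r)) > tol).sum())
        if rank < D.shape[1]:
            dropped = sorted(piv[rank:])
            warnings.warn(f"dropping {len(dropped)} collinear covariate column(s): {dropped}")
            D = D[:, sorted(piv[:rank])]
        return D

    def fit(self, X, covariates: pd.DataFrame | None = None):
        M = X.data.to_numpy(dtype=float) if isinstance(X, AbundanceMatrix) else np.asarray(X, float)
        n = M.shape[0]
        D = self._design(covariates, n)
        Qc, _ = np.linalg.qr(D)
        resid = M - Qc @ (Qc.T @ M)
        k = int(self.n_factors)
        if k > 0 and resid.shape[1] > 0:
            U, s, _ = np.linalg.svd(resid, full_matrices=False)
            k = min(k, (s > 1e-12 * (s[0] if s.size else 1.0)).sum())
            nuisance = np.hstack([D, U[:, :k]])
        else:
            nuisance = D
        self.basis_, _ = np.linalg.qr(nuisance)
        self.n_factors_used_ = int(k)
        return self

    def transform(self, X) -> AbundanceMatrix | np.ndarray:
        if isinstance(X, AbundanceMatrix):
            M = X.data.to_numpy(dtype=float)
        else:
            M = np.asarray(X, float)
        Q = self.basis_
        R = M - Q @ (Q.T @ M)
        if isinstance(X, AbundanceMatrix):
            return AbundanceMatrix(
                pd.DataFrame(R, index=X.data.index, columns=X.data.columns),
                stage="residual",
            )
        return R


def residualize_factors(
    a: AbundanceMatrix,
    covariates: pd.DataFrame | None = None,
    n_hidden_factors: int = 2,
) -> AbundanceMatrix:
    """Fit-and-apply covariate + hidden-factor residualization (residual stage)."""
    if a.stage != "inverse_normal":
        warnings.warn(f"residualizing a {a.stage!r}-stage matrix; expected inverse_normal")
    return FactorResidualizer(n_factors=n_hidden_factors).fit(a, covariates).transform(a)


def normalize_pipeline(
    a: AbundanceMatrix,
    covariates: pd.DataFrame | None = None,
    n_hidden_factors: int = 2,
) -> AbundanceMatrix:
    """raw -> quantile -> inverse-normal -> residual in one call."""
    q = quantile_normalize_individuals(a)
    z = inverse_normal_columns(q)
    return residualize_factors(z, covariates, n_hidden_factors)
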