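"""Linear discriminant analysis with a pooled within-group covariance.

Implemented from first principles: group means and an unbiased pooled
covariance (divisor n - G) are estimated, the generalised
between/within eigenproblem is solved by sphering, and the resulting
scalings are normalised so that the projected training data has unit
within-group variance.  Posteriors are shared-covariance Gaussians,
evaluated in the sphered discriminant space (exact, because the group
means span that space) with a log-sum-exp guard.

Sign convention: discriminant signs are arbitrary across statistical
software, so each scaling column is oriented to make its
largest-magnitude loading positive; results are comparable up to sign
with any other implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

RIDGE_EPS = 1e-8


class SingularCovarianceWarning(UserWarning):
    """Pooled covariance was singular; a ridge was added."""


@dataclass
class LdaModel:
    """A fitted discriminant model.

    Attributes
    ----------
    group_labels
        Ordered group identifiers (length ``G``).
    priors
        Prior probabilities per group, summing to 1.
    means
        ``G x p`` matrix of group means.
    pooled_cov
        ``p x p`` pooled within-group covariance (divisor ``n - G``).
    scalings
        ``p x m`` matrix with ``m = min(G - 1, p)``; projecting
        centred data through it yields unit within-group variance.
    xbar
        Prior-weighted grand mean used as the projection origin.
    training_sizes
        Sample count per group.
    feature_names
        Column names the model expects, in order.
    """

    group_labels: list
    priors: np.ndarray
    means: np.ndarray
    pooled_cov: np.ndarray
    scalings: np.ndarray
    xbar: np.ndarray
    training_sizes: np.ndarray
    feature_names: list
    ridge: float = 0.0
    eigenvalues: np.ndarray = field(default=None)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_functions(self) -> int:
        return self.scalings.shape[1]

    def group_centroids(self) -> pd.DataFrame:
        """Group means projected into discriminant space (LD columns)."""
        z = (self.means - self.xbar) @ self.scalings
        cols = [f"LD{j + 1}" for j in range(self.n_functions)]
        return pd.DataFrame(z, index=self.group_labels, columns=cols)


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            if missing:
                raise ValueError(
                    f"input is missing model columns {missing}; "
                    f"expected {list(feature_names)}"
                )
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float), list(X.columns), list(X.index)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be two-dimensional")
    names = feature_names if feature_names is not None else list(range(arr.shape[1]))
    if len(names) != arr.shape[1]:
        raise ValueError(
            f"X has {arr.shape[1]} columns but the model expects {len(names)}"
        )
    return arr, list(names), list(range(arr.shape[0]))


def fit_lda(X, groups, priors="proportional") -> LdaModel:
    """Fit the discriminant model.

    Parameters
    ----------
    X
        Training data, ``n x p`` (DataFrame or array).
    groups
        Group label per row; every group needs at least two members.
    priors
        ``"proportional"`` (to group size, the default),
        ``"uniform"``, or an explicit mapping/sequence of
        probabilities in group order.

    Returns
    -------
    LdaModel
        With ``m = min(G - 1, p)`` discriminant functions.
    """
    arr, names, _ = _as_matrix(X)
    groups = np.asarray(pd.Series(list(groups)))
    if arr.shape[0] != len(groups):
        raise ValueError("groups length must match number of rows")
    labels, inverse = np.unique(groups, return_inverse=True)
    labels = list(labels)
    G, p, n = len(labels), arr.shape[1], arr.shape[0]
    if G < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(inverse, minlength=G)
    if (sizes < 2).any():
        small = [labels[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with fewer than 2 members: {small}")

    if isinstance(priors, str):
        if priors == "proportional":
            pri = sizes / n
        elif priors == "uniform":
            pri = np.full(G, 1.0 / G)
        else:
            raise ValueError(f"unknown priors option {priors!r}")
    else:
        if isinstance(priors, dict):
            pri = np.array([priors[lab] for lab in labels], dtype=float)
        else:
            pri = np.asarray(priors, dtype=float)
        if pri.shape != (G,) or (pri < 0).any():
            raise ValueError("explicit priors must be G non-negative numbers")
        pri = pri / pri.sum()

    means = np.vstack([arr[inverse == g].mean(axis=0) for g in range(G)])
    centred = arr - means[inverse]
    W = centred.T @ centred / (n - G)

    # ridge fallback for singular pooled covariance
    ridge = 0.0
    evals = np.linalg.eigvalsh(W)
    scale = max(evals.max(), 0.0)
    if evals.min() <= 1e-12 * max(scale, 1e-300):
        zero_cols = [
            names[j] for j in range(p) if W[j, j] <= 1e-30
        ]
        if zero_cols:
            logger.warning("all-zero (constant) columns: %s", zero_cols)
        ridge = RIDGE_EPS * max(np.trace(W) / p, 1e-30)
        warnings.warn(
            f"pooled within-group covariance is singular; adding ridge {ridge:g}",
            SingularCovarianceWarning,
            stacklevel=2,
        )
        W = W + ridge * np.eye(p)

    # sphere, then eigen-decompose the between-group scatter
    evalw, evecw = np.linalg.eigh(W)
    W_isqrt = evecw @ np.diag(1.0 / np.sqrt(evalw)) @ evecw.T
    xbar = pri @ means
    diff = (means - xbar) * np.sqrt(pri)[:, None]
    B = diff.T @ diff
    Bs = W_isqrt @ B @ W_isqrt
    evalb, evecb = np.linalg.eigh(Bs)
    order = np.argsort(evalb)[::-1]
    m = min(G - 1, p)
    V = evecb[:, order[:m]]
    scalings = W_isqrt @ V

    # orient each discriminant so its largest-magnitude loading is positive
    for j in range(m):
        k = np.argmax(np.abs(scalings[:, j]))
        if scalings[k, j] < 0:
            scalings[:, j] = -scalings[:, j]

    return LdaModel(
        group_labels=labels,
        priors=pri,
        means=means,
        pooled_cov=W,
        scalings=scalings,
        xbar=xbar,
        training_sizes=sizes,
        feature_names=names,
        ridge=ridge,
        eigenvalues=evalb[order[:m]],
    )


def project(model: LdaModel, X) -> pd.DataFrame:
    """Unstandardised discriminant scores ``(X - xbar) @ scalings``."""
    arr, _, index = _as_matrix(X, model.feature_names)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in input")
    z = (arr - model.xbar) @ model.scalings
    cols = [f"LD{j + 1}" for j in range(model.n_functions)]
    return pd.DataFrame(z, index=index, columns=cols)


def posterior(model: LdaModel, X) -> pd.DataFrame:
    """Posterior group probabilities under the shared-covariance Gaussian.

    Computed in the sphered discriminant space:
    ``p_k(x) ∝ prior_k * exp(-0.5 * ||z(x) - z_k||^2)``, normalised
    per row with a log-sum-exp guard.  Rows sum to one.
    """
    z = project(model, X).to_numpy()
    zmeans = (model.means - model.xbar) @ model.scalings
    d2 = ((z[:, None, :] - zmeans[None, :, :]) ** 2).sum(axis=2)
    with np.errstate(divide="ignore"):
        logpri = np.log(model.priors)
    loglik = logpri[None, :] - 0.5 * d2
    post = np.exp(loglik - logsumexp(loglik, axis=1, keepdims=True))
    index = X.index if isinstance(X, pd.DataFrame) else range(z.shape[0])
    return pd.DataFrame(post, index=index, columns=model.group_labels)


def predict_class(model: LdaModel, X) -> pd.Series:
    """Most probable group per sample; ties go to the lowest group index."""
    post = posterior(model, X)
    idx = np.argmax(post.to_numpy(), axis=1)  # argmax takes the first maximum
    return pd.Series(
        [model.group_labels[i] for i in idx], index=post.index, name="class"
    )
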