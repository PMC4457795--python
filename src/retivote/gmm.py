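"""One-dimensional Gaussian mixture pixel clustering.

The fused enhancement image is summarized by its in-FOV intensity
sample, modeled as a K-component Gaussian mixture

    p(x) = sum_i w_i N(x; mu_i, sigma_i^2),

initialized by K-means and fitted by EM. Each pixel is then assigned to
the component with the largest posterior responsibility (optionally the
largest unweighted component density), partitioning the image into K
intensity layers; the layer corresponding to vessels is selected by
ranking the component means.

``IntensityGMM`` follows the scikit-learn estimator protocol (``fit`` /
``predict``, fitted attributes with trailing underscores) so it composes
with sklearn tooling; the module functions below it are thin wrappers
used by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = [
    "IntensityGMM",
    "GMMFit",
    "kmeans_init",
    "em_fit",
    "assign_clusters",
    "select_vessel_cluster",
]


@dataclass
class GMMFit:
    """Fitted mixture: weights, means, variances, and the EM trace."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik_trace: np.ndarray
    weights_trace: np.ndarray  # (n_iter, K), weights after each M-step
    n_iter: int
    n_samples: int

    @property
    def n_components(self) -> int:
        return self.means.size


def _log_gauss(values: np.ndarray, means: np.ndarray, variances: np.ndarray):
    """(n, K) log N(x; mu_i, sigma_i^2)."""
    d = values[:, None] - means[None, :]
    return -0.5 * (np.log(2.0 * np.pi * variances)[None, :] + d**2 / variances[None, :])


def kmeans_init(
    values: np.ndarray, n_components: int, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K-means (k-means++ seeding, Lloyd to convergence) -> GMM init.

    Returns per-cluster (means, variances, weights); weights are the
    relative cluster sizes.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < n_components:
        raise ValueError(
            f"need at least {n_components} distinct values for K-means init"
        )
    km = KMeans(n_clusters=n_components, n_init=10, random_state=seed)
    labels = km.fit_predict(values[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    means = np.empty(n_components)
    variances = np.empty(n_components)
    weights = np.empty(n_components)
    for rank, idx in enumerate(order):
        member = values[labels == idx]
        means[rank] = member.mean()
        variances[rank] = max(member.var(), 1e-6)
        weights[rank] = member.size / values.size
    return means, variances, weights


def em_fit(
    values: np.ndarray,
    init: tuple[np.ndarray, np.ndarray, np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 500,
    var_floor: float = 1e-6,
) -> GMMFit:
    """Expectation-maximization for the 1D Gaussian mixture.

    Responsibilities are the posterior component probabilities; the
    M-step updates weights as mean responsibility, means as the
    responsibility-weighted sample mean, and variances as the
    responsibility-weighted squared deviation from the *updated* mean.
    Iteration stops when the relative log-likelihood change drops below
    ``tol`` or at ``max_iter``. Components collapsing below ``var_floor``
    are re-floored with a warning.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    means, variances, weights = (np.array(a, dtype=np.float64) for a in init)
    n = values.size
    trace = []
    wtrace = []
    prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        log_joint = np.log(weights)[None, :] + _log_gauss(values, means, variances)
        log_norm = logsumexp(log_joint, axis=1)
        resp = np.exp(log_joint - log_norm[:, None])
        loglik = float(log_norm.sum())
        trace.append(loglik)
        # M-step
        mass = resp.sum(axis=0)
        weights = mass / n
        means = (resp * values[:, None]).sum(axis=0) / mass
        variances = (resp * (values[:, None] - means[None, :]) ** 2).sum(axis=0) / mass
        if np.any(variances < var_floor):
            warnings.warn("GMM component variance collapsed; applying floor")
            variances = np.maximum(variances, var_floor)
        wtrace.append(weights.copy())
        if np.isfinite(prev) and abs(loglik - prev) <= tol * abs(prev):
            break
        prev = loglik
    return GMMFit(
        weights=weights,
        means=means,
        variances=variances,
        loglik_trace=np.array(trace),
        weights_trace=np.array(wtrace),
        n_iter=n_iter,
        n_samples=n,
    )


def assign_clusters(
    fit: GMMFit, values: np.ndarray, weighted: bool = True
) -> np.ndarray:
    """Per-sample component labels (0-based).

    ``weighted`` assigns by maximum posterior (argmax of w_i p_i);
    ``weighted=False`` compares the unweighted component densities.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    log_dens = _log_gauss(values, fit.means, fit.variances)
    if weighted:
        log_dens = log_dens + np.log(fit.weights)[None, :]
    return np.argmax(log_dens, axis=1)


def select_vessel_cluster(
    fit: GMMFit,
    labels: np.ndarray,
    rule: str = "brightest_major",
    min_weight: float = 0.02,
):
    """Pick the vessel layer by ranking component means.

    Rules: ``brightest_major`` (largest mean among components holding at
    least ``min_weight`` of the mixture mass — vessels are the brightest
    *tissue class* of the fused image, while a sub-percent top component
    is an extreme-value tail, not a layer), ``highest`` / ``second_highest``
    (strict mean rank), or ``index:i`` (literal component index).
    """
    if fit.n_components < 2:
        raise ValueError("vessel-layer selection needs at least 2 components")
    order = np.argsort(fit.means)[::-1]  # descending mean
    if rule == "brightest_major":
        major = [i for i in order if fit.weights[i] >= min_weight]
        comp = major[0] if major else order[0]
    elif rule == "highest":
        comp = order[0]
    elif rule == "second_highest":
        comp = order[1]
    elif rule.startswith("index:"):
        comp = int(rule.split(":", 1)[1])
        if not 0 <= comp < fit.n_components:
            raise ValueError(f"component index {comp} out of range")
    else:
        raise ValueError(f"unknown vessel-cluster rule {rule!r}")
    return labels == comp, int(comp)


class IntensityGMM(BaseEstimator):
    """K-means-initialized EM Gaussian mixture over pixel intensities.

    Parameters
    ----------
    n_components : number of Gaussian layers (4 separates background,
        faint structure, vessels, and disc/strong edges in practice).
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap.
    var_floor : lower bound applied to component variances.
    random_state : seed for the K-means initialization.
    weighted_assign : assign by posterior (True) or by unweighted
        component density.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, variances_ : mixture parameters, sorted by the
        K-means init so means are in increasing order at initialization.
    loglik_trace_ : per-iteration log-likelihood (non-decreasing).
    n_iter_ : EM iterations run.
    """

    def __init__(
        self,
        n_components: int = 4,
        tol: float = 1e-6,
        max_iter: int = 500,
        var_floor: float = 1e-6,
        random_state: int | None = 0,
        weighted_assign: bool = True,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.random_state = random_state
        self.weighted_assign = weighted_assign

    def _as_sample(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("expected a 1D intensity sample or an (n, 1) column")
        if not np.all(np.isfinite(X)):
            raise ValueError("intensity sample contains non-finite values")
        return X

    def fit(self, X, y=None) -> "IntensityGMM":
        values = self._as_sample(X)
        init = kmeans_init(values, self.n_components, seed=self.random_state)
        fitres = em_fit(
            values, init, tol=self.tol, max_iter=self.max_iter,
            var_floor=self.var_floor,
        )
        self.weights_ = fitres.weights
        self.means_ = fitres.means
        self.variances_ = fitres.variances
        self.loglik_trace_ = fitres.loglik_trace
        self.n_iter_ = fitres.n_iter
        self.fit_result_ = fitres
        return self

    def predict(self, X) -> np.ndarray:
        values = self._as_sample(X)
        return assign_clusters(self.fit_result_, values, weighted=self.weighted_assign)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)
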