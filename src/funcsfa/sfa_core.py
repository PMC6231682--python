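"""Penalized sparse-factor analysis fitted by EM with coordinate descent.

Model: a sample vector x (n features, t data types stacked) is explained
by k latent factors z,

    x = B^T z + e,    z ~ N(0, I_k),    e ~ N(0, Psi),

with Psi diagonal and equal for features of the same data type, so Psi
is one scalar per data type.  The coefficients B (k x n) are made sparse
by an elastic-net penalty with per-data-type levels.

The fitting loop:

1. initialize B from PCA loadings;
2. E-step: posterior mean E[Z|X] and second moment E[Z^T Z|X], then
   rescale both so every factor has unit sample variance — this stops
   the penalty from shrinking coefficients while the factors blow up to
   compensate, and it is what licenses the simple coordinate update;
3. one sequential coordinate-descent sweep over all coefficients with
   soft-thresholding;
4. per-data-type residual variance update (floored at 1e-8);
5. repeat from 2 until the mean absolute change of the reconstruction
   error over the last 10 iterations drops below ``tol`` (default 1e-6),
   or 5000 iterations.

The algorithm is deterministic given the data; a ``seed`` argument is
accepted for interface uniformity with the stochastic parts of the
package but is not consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .data_io import MultiOmicsDataset
from .errors import (SingularPosteriorError, ValidationError,
                     ZeroVarianceFactorError)
from .penalties import PenaltyConfig

PSI_FLOOR = 1e-8

__all__ = [
    "FactorModel",
    "PosteriorFactors",
    "FitTrace",
    "FitResult",
    "CDState",
    "init_pca",
    "e_step",
    "soft_threshold",
    "update_coefficient",
    "coordinate_descent_pass",
    "update_residual_variance",
    "reconstruction_error",
    "loglik",
    "marginal_loglik",
    "penalized_loglik",
    "fit_sfa",
    "save_model",
    "load_model",
]


@dataclass
class FactorModel:
    """Sparse coefficients B (k x n) and per-data-type residual variances."""

    coefficients: np.ndarray
    residual_variance: np.ndarray  # one positive scalar per data type
    penalties: PenaltyConfig

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.residual_variance = np.atleast_1d(
            np.asarray(self.residual_variance, dtype=float))
        if self.coefficients.ndim != 2 or self.coefficients.shape[0] < 1:
            raise ValidationError("coefficients must be a k x n matrix, k >= 1")
        if not np.isfinite(self.coefficients).all():
            raise ValidationError("non-finite coefficients")
        if (self.residual_variance <= 0).any():
            raise ValidationError("residual variances must be positive")

    @property
    def k(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_features(self) -> int:
        return self.coefficients.shape[1]

    def psi_per_feature(self, datatype_of_feature: np.ndarray) -> np.ndarray:
        return self.residual_variance[np.asarray(datatype_of_feature, int)]

    def copy(self) -> "FactorModel":
        return FactorModel(self.coefficients.copy(),
                           self.residual_variance.copy(), self.penalties)


@dataclass
class PosteriorFactors:
    """Rescaled posterior factor moments: E[Z|X] (N x k), E[Z^T Z|X] (k x k)."""

    mean: np.ndarray
    second_moment: np.ndarray
    scale_applied: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.mean.shape[0]

    @property
    def k(self) -> int:
        return self.mean.shape[1]


@dataclass
class FitTrace:
    reconstruction_error: list[float] = field(default_factory=list)
    penalized_objective: list[float] = field(default_factory=list)
    explained_variance: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


@dataclass
class FitResult:
    model: FactorModel
    posterior: PosteriorFactors
    trace: FitTrace


# ---------------------------------------------------------------------------
# individual algorithm steps


def init_pca(dataset: MultiOmicsDataset, k: int,
             penalties: PenaltyConfig | None = None) -> FactorModel:
    """Initialize B from the top-k principal-axis loadings.

    Rows of B are scaled so the implied factor scores (projections of X)
    have unit sample variance; per component, the sign making the
    largest-magnitude loading positive is chosen, for run-to-run
    determinism.  Residual variance per data type starts at the mean
    squared residual after removing the rank-k reconstruction.
    """
    X = dataset.stacked()
    N, n = X.shape
    if k < 1 or k > min(N, n):
        raise ValidationError(f"k={k} outside [1, min(N, n)={min(N, n)}]")
    if not np.any(X):
        raise ValidationError("all-zero data matrix")
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
    B = (s[:k, None] * Vt[:k]) / np.sqrt(N)
    for i in range(k):
        j = np.argmax(np.abs(B[i]))
        if B[i, j] < 0:
            B[i] = -B[i]
    recon = U[:, :k] * s[:k] @ Vt[:k]
    resid = X - recon
    psi = np.empty(dataset.n_types)
    for i, sl in enumerate(dataset.block_slices):
        psi[i] = max(float(np.mean(resid[:, sl] ** 2)), PSI_FLOOR)
    if penalties is None:
        penalties = PenaltyConfig.zero(dataset.n_types)
    return FactorModel(B, psi, penalties)


def e_step(dataset: MultiOmicsDataset, model: FactorModel,
           rescale: bool = True) -> PosteriorFactors:
    """Posterior factor moments under the current model.

    Raw moments from the Gaussian factor-model identities

        V = (I_k + B Psi^-1 B^T)^-1
        E[Z|X]     = X Psi^-1 B^T V
        E[Z^T Z|X] = N V + E[Z|X]^T E[Z|X]

    then each factor column of E[Z|X] is divided by its sample standard
    deviation d_j and E[Z^T Z|X] is conjugated by diag(1/d).
    """
    X = dataset.stacked()
    N = X.shape[0]
    B = model.coefficients
    psi = model.psi_per_feature(dataset.datatype_of_feature)
    if (psi <= 0).any():
        raise ValidationError("residual variances must be positive")
    Bw = B / psi  # B Psi^-1
    P = np.eye(model.k) + Bw @ B.T
    try:
        V = scipy.linalg.solve(P, np.eye(model.k), assume_a="pos")
    except scipy.linalg.LinAlgError as exc:
        raise SingularPosteriorError(str(exc)) from exc
    if not np.isfinite(V).all():
        raise SingularPosteriorError("non-finite posterior covariance")
    M = X @ Bw.T @ V
    S = N * V + M.T @ M
    if not rescale:
        return PosteriorFactors(M, S, np.ones(model.k))
    d = M.std(axis=0, ddof=0)
    if np.any(d < 1e-12):
        bad = int(np.argmin(d))
        raise ZeroVarianceFactorError(
            f"factor {bad} has zero sample variance; cannot rescale")
    return PosteriorFactors(M / d, S / np.outer(d, d), d)


def soft_threshold(b, l1):
    """sign(b) * max(|b| - l1, 0); works element-wise on arrays."""
    return np.sign(b) * np.maximum(np.abs(b) - l1, 0.0)


@dataclass
class CDState:
    """Everything one coordinate update needs to see."""

    X: np.ndarray                 # N x n
    coefficients: np.ndarray      # current B-hat, k x n (mutated in place)
    posterior: PosteriorFactors   # rescaled moments
    lambda1: np.ndarray           # per feature
    lambda2: np.ndarray           # per feature


def update_coefficient(i: int, j: int, state: CDState) -> float:
    """One elastic-net coordinate update for factor i, feature j:

        S( B[i,j] + (1/N)(E[Z|X][:,i]^T X[:,j] - B[:,j]^T E[Z^TZ|X][:,i]),
           lambda1_j ) / (1 + lambda2_j)
    """
    B = state.coefficients
    M, S = state.posterior.mean, state.posterior.second_moment
    N = M.shape[0]
    u = B[i, j] + (M[:, i] @ state.X[:, j] - B[:, j] @ S[:, i]) / N
    return float(soft_threshold(u, state.lambda1[j]) / (1.0 + state.lambda2[j]))


def coordinate_descent_pass(state: CDState) -> np.ndarray:
    """One sweep updating every coefficient once, factor-major then
    feature order, each update seeing the latest values of the others.

    Within one factor the updates for different features are mutually
    independent (updating B[i, j] touches only column j), so the sweep
    is vectorized across features; the result is identical to the
    scalar sequential loop.
    """
    B = state.coefficients
    M, S = state.posterior.mean, state.posterior.second_moment
    N = M.shape[0]
    for i in range(B.shape[0]):
        u = B[i] + (M[:, i] @ state.X - S[:, i] @ B) / N
        B[i] = soft_threshold(u, state.lambda1) / (1.0 + state.lambda2)
    return B


def update_residual_variance(dataset: MultiOmicsDataset, model: FactorModel,
                             posterior: PosteriorFactors) -> np.ndarray:
    """M-step residual variance per data type,

        Psi_i = (trace(X_i X_i^T) - trace(E[Z|X] B_i X_i^T)) / (n_i N),

    floored at 1e-8.
    """
    M = posterior.mean
    N = dataset.n_samples
    out = np.empty(dataset.n_types)
    for i, sl in enumerate(dataset.block_slices):
        Xi = dataset.blocks[i].values
        Bi = model.coefficients[:, sl]
        n_i = Xi.shape[1]
        val = (np.sum(Xi * Xi) - np.sum((M @ Bi) * Xi)) / (n_i * N)
        out[i] = max(val, PSI_FLOOR)
    return out


def reconstruction_error(dataset: MultiOmicsDataset, model: FactorModel,
                         posterior: PosteriorFactors) -> float:
    """(1 / (N n)) * ||X - E[Z|X] B||_F^2 — normalized so a tolerance on
    its change is scale-comparable across datasets."""
    X = dataset.stacked()
    R = X - posterior.mean @ model.coefficients
    return float(np.mean(R ** 2))


def loglik(dataset: MultiOmicsDataset, model: FactorModel,
           posterior: PosteriorFactors) -> float:
    """Unpenalized complete-data log-likelihood with Z = rescaled E[Z|X]:

        -1/2 tr((X - ZB) Psi^-1 (X - ZB)^T) - (N/2) log det(Psi)
        - 1/2 tr(Z^T Z)
    """
    X = dataset.stacked()
    N = X.shape[0]
    psi = model.psi_per_feature(dataset.datatype_of_feature)
    if (psi <= 0).any():
        raise ValidationError("residual variances must be positive")
    R = X - posterior.mean @ model.coefficients
    quad = float(np.sum(R ** 2 / psi))
    logdet = float(np.sum(np.log(psi)))
    zz = float(np.sum(posterior.mean ** 2))
    return -0.5 * quad - 0.5 * N * logdet - 0.5 * zz


def marginal_loglik(dataset: MultiOmicsDataset, model: FactorModel) -> float:
    """Observed-data log-likelihood with the factors integrated out:
    x ~ N(0, B^T B + Psi), evaluated over the N samples.

    Computed through the Woodbury identity so only k x k systems are
    solved.  This is the likelihood model selection scores: the
    complete-data plug-in (``loglik``) rewards whatever the posterior
    factors happen to absorb and ranks neighboring penalty levels
    erratically, while the marginal likelihood is the quantity BIC is
    defined for.
    """
    X = dataset.stacked()
    N, n = X.shape
    psi = model.psi_per_feature(dataset.datatype_of_feature)
    if (psi <= 0).any():
        raise ValidationError("residual variances must be positive")
    B = model.coefficients
    Bw = B / psi
    P = np.eye(model.k) + Bw @ B.T
    sign, ld = np.linalg.slogdet(P)
    if sign <= 0:
        raise SingularPosteriorError("non-PD marginal covariance")
    logdet = float(np.sum(np.log(psi)) + ld)
    # tr(Sigma^-1 S_emp), Sigma^-1 = Psi^-1 - Psi^-1 B^T P^-1 B Psi^-1
    t1 = float(np.sum(X ** 2 / psi)) / N
    Y = (X / psi) @ B.T
    t2 = float(np.sum(Y * scipy.linalg.solve(P, Y.T, assume_a="pos").T)) / N
    return -0.5 * N * (n * np.log(2 * np.pi) + logdet + (t1 - t2))


def penalized_loglik(dataset: MultiOmicsDataset, model: FactorModel,
                     posterior: PosteriorFactors) -> float:
    """``loglik`` minus the elastic-net penalty
    sum_j lambda1_j |b_j|_1 + lambda2_j |b_j|_2^2."""
    lam1, lam2 = model.penalties.per_feature(dataset.datatype_of_feature)
    B = model.coefficients
    pen = float(np.sum(lam1 * np.sum(np.abs(B), axis=0))
                + np.sum(lam2 * np.sum(B ** 2, axis=0)))
    return loglik(dataset, model, posterior) - pen


def fit_sfa(dataset: MultiOmicsDataset, k: int,
            penalties: PenaltyConfig | None = None,
            max_iter: int = 5000, tol: float = 1e-6,
            window: int = 10,
            init: FactorModel | None = None,
            seed: int | None = None) -> FitResult:
    """Fit the sparse-factor model by penalized EM.

    Stops when the mean absolute change of the reconstruction error over
    the last ``window`` iterations falls below ``tol``, or at
    ``max_iter``.  ``init`` allows warm starts; ``seed`` is accepted for
    interface uniformity (the algorithm itself is deterministic).
    """
    if penalties is None:
        penalties = PenaltyConfig.zero(dataset.n_types)
    if len(penalties.levels) != dataset.n_types:
        raise ValidationError("one penalty level per data type required")
    model = init.copy() if init is not None else init_pca(dataset, k, penalties)
    if init is not None:
        model.penalties = penalties
    if model.k != k:
        raise ValidationError("init model has wrong number of factors")
    X = dataset.stacked()
    total_ss = float(np.sum(X ** 2))
    lam1, lam2 = penalties.per_feature(dataset.datatype_of_feature)
    trace = FitTrace()
    errors: list[float] = []
    posterior = None
    for it in range(1, max_iter + 1):
        posterior = e_step(dataset, model)
        state = CDState(X, model.coefficients, posterior, lam1, lam2)
        coordinate_descent_pass(state)
        model = FactorModel(state.coefficients,
                            update_residual_variance(dataset, model, posterior),
                            penalties)
        err = reconstruction_error(dataset, model, posterior)
        errors.append(err)
        trace.reconstruction_error.append(err)
        trace.penalized_objective.append(
            penalized_loglik(dataset, model, posterior))
        trace.explained_variance.append(
            1.0 - err * X.size / total_ss if total_ss > 0 else 0.0)
        trace.n_iter = it
        if len(errors) > window:
            recent = np.abs(np.diff(errors[-(window + 1):]))
            if float(np.mean(recent)) < tol:
                trace.converged = True
                break
    # final E-step so the returned posterior matches the returned model
    posterior = e_step(dataset, model)
    return FitResult(model, posterior, trace)


# ---------------------------------------------------------------------------
# model archive: one .npz with a JSON metadata entry


def save_model(model: FactorModel, path, *, feature_ids=None,
               datatype_labels=None, block_sizes=None,
               extra_meta: dict | None = None) -> None:
    import json

    meta = {
        "alpha": model.penalties.alpha,
        "levels": list(model.penalties.levels),
        "datatype_labels": list(datatype_labels) if datatype_labels else None,
        "block_sizes": [int(b) for b in block_sizes] if block_sizes is not None else None,
        "feature_ids": list(feature_ids) if feature_ids else None,
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(path, "wb") as fh:  # keep the exact filename (no .npz suffix)
        np.savez(fh, coefficients=model.coefficients,
                 residual_variance=model.residual_variance,
                 metadata=np.frombuffer(json.dumps(meta).encode(),
                                        dtype=np.uint8))


def load_model(path) -> tuple[FactorModel, dict]:
    import json

    with np.load(path) as f:
        meta = json.loads(bytes(f["metadata"].tobytes()).decode())
        model = FactorModel(
            f["coefficients"], f["residual_variance"],
            PenaltyConfig(alpha=meta["alpha"], levels=tuple(meta["levels"])))
    return model, meta
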