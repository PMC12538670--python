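"""Exact Gaussian process regression with an ARD squared-exponential kernel.

This is the regression engine used to map tower-observed carbon fluxes onto
gridded predictors.  The model is a zero-mean GP over standardized inputs and
targets,

    k(x_i, x_j) = sigma_s^2 exp( -1/2 sum_b ((x_i(b) - x_j(b)) / l_b)^2 ),

with one lengthscale ``l_b`` per predictor (automatic relevance
determination: the larger the fitted lengthscale, the less informative the
predictor) and i.i.d. Gaussian observation noise of variance ``sigma_n^2``.
Hyperparameters are chosen by maximizing the log marginal likelihood

    log p(y | X, theta) = -1/2 y^T (K + sigma_n^2 I)^-1 y
                          - 1/2 log det(K + sigma_n^2 I) - n/2 log 2 pi

via a quasi-Newton optimizer in log-hyperparameter space with random
restarts; all linear algebra goes through a Cholesky factor of
``K + sigma_n^2 I`` (never an explicit inverse or determinant).

The reported per-point uncertainty is the *epistemic* (latent-function)
standard deviation

    sigma(x*) = sqrt(max(0, k(x*, x*) - v^T v)),   v = L \\ k*,

without observation noise unless explicitly requested; this is the
uncertainty surface rendered in flux sigma maps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "Hyperparameters",
    "TrainingMatrix",
    "TrainedGPR",
    "Prediction",
    "FitConfig",
    "kernel_matrix",
    "log_marginal_likelihood",
    "fit",
    "predict",
    "standalone_predict",
]

# Jitter policy: start at JITTER_START * trace/n on the diagonal, escalate by
# x10 up to JITTER_MAX * trace/n before declaring the system unfactorizable.
JITTER_START = 1e-10
JITTER_MAX = 1e-4


@dataclass(frozen=True)
class Hyperparameters:
    """GP hyperparameters theta = {sigma_s^2, l_1..l_D, sigma_n^2}.

    All quantities are in standardized units: signal and noise variance in
    squared standardized-target units, lengthscales in standardized predictor
    units.
    """

    signal_var: float
    lengthscales: np.ndarray
    noise_var: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "lengthscales", np.asarray(self.lengthscales, dtype=float)
        )
        if not self.signal_var > 0:
            raise ValueError("signal_var must be > 0")
        if not np.all(self.lengthscales > 0):
            raise ValueError("every lengthscale must be > 0")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")

    @property
    def D(self) -> int:
        return self.lengthscales.size


@dataclass(frozen=True)
class TrainingMatrix:
    """Standardized design matrix X (n x D) and target y (n,) for one flux.

    ``X`` and ``y`` are stored standardized (zero mean, unit scale per
    column); the standardizers are retained so predictions can be returned in
    physical units (micromol CO2 m-2 s-1).
    """

    X: np.ndarray
    y: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    flux_variable: str = ""
    predictor_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be (n, D) and y (n,) with matching n")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("training data must be finite")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "x_mean", np.asarray(self.x_mean, dtype=float))
        object.__setattr__(self, "x_scale", np.asarray(self.x_scale, dtype=float))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def D(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_raw(
        cls,
        X_raw: np.ndarray,
        y_raw: np.ndarray,
        flux_variable: str = "",
        predictor_names: tuple[str, ...] = (),
    ) -> "TrainingMatrix":
        """Standardize raw-unit predictors/targets column-wise.

        Constant columns get unit scale (they carry no information but must
        not produce NaNs).
        """
        X_raw = np.asarray(X_raw, dtype=float)
        y_raw = np.asarray(y_raw, dtype=float)
        x_mean = X_raw.mean(axis=0)
        x_scale = X_raw.std(axis=0, ddof=0)
        x_scale = np.where(x_scale > 0, x_scale, 1.0)
        y_mean = float(y_raw.mean())
        y_scale = float(y_raw.std(ddof=0))
        if y_scale == 0.0:
            y_scale = 1.0
        return cls(
            X=(X_raw - x_mean) / x_scale,
            y=(y_raw - y_mean) / y_scale,
            x_mean=x_mean,
            x_scale=x_scale,
            y_mean=y_mean,
            y_scale=y_scale,
            flux_variable=flux_variable,
            predictor_names=tuple(predictor_names),
        )

    def standardize(self, X_raw: np.ndarray) -> np.ndarray:
        X_raw = np.asarray(X_raw, dtype=float)
        return (X_raw - self.x_mean) / self.x_scale


@dataclass(frozen=True)
class Prediction:
    """Predictive mean and epistemic standard deviation, physical units."""

    mean: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class TrainedGPR:
    """A fitted GP: hyperparameters plus cached solve products.

    ``alpha`` solves (K + sigma_n^2 I) alpha = y and ``chol_L`` is the lower
    Cholesky factor of the (jittered) K + sigma_n^2 I, so prediction needs
    only kernel evaluations, one matvec and one triangular solve.
    """

    hyperparameters: Hyperparameters
    training: TrainingMatrix
    alpha: np.ndarray
    chol_L: np.ndarray
    jitter: float
    log_marginal_likelihood: float


@dataclass(frozen=True)
class FitConfig:
    """Options for marginal-likelihood maximization.

    restarts: number of optimizer starts; the first is a deterministic
        unit-scale initialization, the rest are drawn log-uniform within
        ``restart_bounds`` (standardized units).
    bounds: box constraints on (signal_var, lengthscales) in log space.
    noise_bounds: box constraints on noise_var.
    maxiter: L-BFGS-B iteration cap per restart.
    seed: RNG seed for the random restarts.
    """

    restarts: int = 5
    bounds: tuple[float, float] = (1e-2, 1e2)
    noise_bounds: tuple[float, float] = (1e-8, 1e2)
    restart_bounds: tuple[float, float] = (1e-2, 1e2)
    maxiter: int = 200
    tol: float = 1e-9
    seed: int = 0


def kernel_matrix(A: np.ndarray, B: np.ndarray, hyp: Hyperparameters) -> np.ndarray:
    """ARD-RBF kernel matrix between row sets A (m x D) and B (p x D)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != hyp.D or B.shape[1] != hyp.D:
        raise ValueError(
            f"dimension mismatch: A has D={A.shape[1]}, B has D={B.shape[1]}, "
            f"hyperparameters have D={hyp.D}"
        )
    ell = hyp.lengthscales
    d2 = cdist(A / ell, B / ell, metric="sqeuclidean")
    return hyp.signal_var * np.exp(-0.5 * d2)


def _chol_with_jitter(Kn: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky of Kn with escalating relative diagonal jitter."""
    n = Kn.shape[0]
    tau = float(np.trace(Kn)) / n
    jitter = 0.0
    mult = JITTER_START
    while True:
        try:
            L = cholesky(Kn + jitter * np.eye(n), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            pass
        except Exception:
            pass
        if mult > JITTER_MAX:
            raise np.linalg.LinAlgError(
                f"Cholesky failed after jitter escalation to {jitter:.3e} "
                f"(matrix trace/n = {tau:.3e}); the system is too "
                "ill-conditioned"
            )
        jitter = mult * tau
        mult *= 10.0


def _pairwise_sq_diffs(X: np.ndarray) -> list[np.ndarray]:
    """Per-dimension matrices of squared coordinate differences (for grads)."""
    return [
        (X[:, b : b + 1] - X[:, b : b + 1].T) ** 2 for b in range(X.shape[1])
    ]


def log_marginal_likelihood(
    hyp: Hyperparameters,
    training: TrainingMatrix,
    *,
    sq_diffs: list[np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Log marginal likelihood and its gradient w.r.t. log-hyperparameters.

    Returns ``(lml, grad)`` where ``grad`` is ordered
    (log signal_var, log l_1 .. log l_D, log noise_var).  The value is
    computed through a Cholesky factor; the gradient uses the standard trace
    identity d lml / d theta = 1/2 tr((alpha alpha^T - K^-1) dK/d theta).
    """
    X, y = training.X, training.y
    n = X.shape[0]
    if X.shape[1] != hyp.D:
        raise ValueError(
            f"dimension mismatch: training D={X.shape[1]}, "
            f"hyperparameters D={hyp.D}"
        )
    K = kernel_matrix(X, X, hyp)
    Kn = K + hyp.noise_var * np.eye(n)
    L, jitter = _chol_with_jitter(Kn)
    alpha = cho_solve((L, True), y)
    lml = (
        -0.5 * float(y @ alpha)
        - float(np.sum(np.log(np.diag(L))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )

    Kinv = cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv

    if sq_diffs is None:
        sq_diffs = _pairwise_sq_diffs(X)
    grad = np.empty(hyp.D + 2)
    grad[0] = 0.5 * float(np.sum(A * K))  # dK/dlog sigma_s^2 = K
    AK = A * K
    for b in range(hyp.D):
        # dK/dlog l_b = K * d_b^2 / l_b^2
        grad[1 + b] = 0.5 * float(np.sum(AK * sq_diffs[b])) / hyp.lengthscales[b] ** 2
    grad[hyp.D + 1] = 0.5 * hyp.noise_var * float(np.trace(A))
    return lml, grad


def _pack(hyp: Hyperparameters) -> np.ndarray:
    return np.concatenate(
        ([np.log(hyp.signal_var)], np.log(hyp.lengthscales), [np.log(hyp.noise_var)])
    )


def _unpack(theta: np.ndarray, D: int) -> Hyperparameters:
    return Hyperparameters(
        signal_var=float(np.exp(theta[0])),
        lengthscales=np.exp(theta[1 : 1 + D]),
        noise_var=float(np.exp(theta[D + 1])),
    )


def fit(training: TrainingMatrix, config: FitConfig | None = None) -> TrainedGPR:
    """Maximize the log marginal likelihood; keep the best restart.

    Ties in the final objective are broken by lowest restart index (the
    first-found optimum wins).
    """
    config = config or FitConfig()
    D = training.D
    sq_diffs = _pairwise_sq_diffs(training.X)
    rng = np.random.default_rng(config.seed)

    lo, hi = config.restart_bounds
    starts = [
        Hyperparameters(signal_var=1.0, lengthscales=np.ones(D), noise_var=0.1)
    ]
    for _ in range(max(0, config.restarts - 1)):
        starts.append(
            Hyperparameters(
                signal_var=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                lengthscales=np.exp(rng.uniform(np.log(lo), np.log(hi), size=D)),
                noise_var=float(np.exp(rng.uniform(np.log(1e-4), np.log(1.0)))),
            )
        )

    blo, bhi = np.log(config.bounds[0]), np.log(config.bounds[1])
    nlo, nhi = np.log(config.noise_bounds[0]), np.log(config.noise_bounds[1])
    box = [(blo, bhi)] * (D + 1) + [(nlo, nhi)]

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        hyp = _unpack(theta, D)
        try:
            lml, grad = log_marginal_likelihood(hyp, training, sq_diffs=sq_diffs)
        except np.linalg.LinAlgError:
            return 1e25, np.zeros_like(theta)
        return -lml, -grad

    best: tuple[float, np.ndarray] | None = None
    failures: list[str] = []
    for i, start in enumerate(starts):
        res = minimize(
            objective,
            _pack(start),
            jac=True,
            method="L-BFGS-B",
            bounds=box,
            options={"maxiter": config.maxiter, "ftol": config.tol},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e24:
            failures.append(f"restart {i}: {res.message}")
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), np.asarray(res.x))
    if best is None:
        raise RuntimeError(
            "all optimizer restarts failed: " + "; ".join(failures)
        )

    hyp = _unpack(best[1], D)
    K = kernel_matrix(training.X, training.X, hyp)
    Kn = K + hyp.noise_var * np.eye(training.n)
    L, jitter = _chol_with_jitter(Kn)
    alpha = cho_solve((L, True), training.y)
    lml = (
        -0.5 * float(training.y @ alpha)
        - float(np.sum(np.log(np.diag(L))))
        - 0.5 * training.n * np.log(2.0 * np.pi)
    )
    return TrainedGPR(
        hyperparameters=hyp,
        training=training,
        alpha=alpha,
        chol_L=L,
        jitter=jitter,
        log_marginal_likelihood=lml,
    )


def _predict_standardized(
    Xs: np.ndarray,
    X_train: np.ndarray,
    hyp: Hyperparameters,
    alpha: np.ndarray,
    L: np.ndarray,
    include_noise: bool,
) -> tuple[np.ndarray, np.ndarray]:
    Ks = kernel_matrix(Xs, X_train, hyp)  # (q, n)
    # einsum (not BLAS gemv/gemm) keeps per-row summation order fixed, so
    # results are bitwise identical regardless of how queries are chunked
    mean = np.einsum("qn,n->q", Ks, alpha)
    B = Ks.T
    if B.shape[1] == 1:
        # the single-column solve dispatches a different BLAS routine with a
        # different accumulation order; pad to keep the multi-column path
        v = solve_triangular(L, np.concatenate([B, B], axis=1),
                             lower=True)[:, :1]
    else:
        v = solve_triangular(L, B, lower=True)  # (n, q)
    var = hyp.signal_var - np.einsum("ij,ij->j", v, v)
    if include_noise:
        var = var + hyp.noise_var
    var = np.maximum(var, 0.0)
    return mean, var


def predict(
    model: TrainedGPR,
    Xnew: np.ndarray,
    *,
    include_noise: bool = False,
    chunk_size: int | None = None,
) -> Prediction:
    """Predictive mean and epistemic sigma at raw-unit query points.

    ``include_noise=True`` adds the observation-noise variance before the
    square root (predictive-observation intervals rather than latent
    epistemic uncertainty).  ``chunk_size`` bounds memory for large query
    sets; results are identical regardless of chunking.
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    tr = model.training
    if Xnew.shape[1] != tr.D:
        raise ValueError(
            f"dimension mismatch: query D={Xnew.shape[1]}, model D={tr.D}"
        )
    Xs = tr.standardize(Xnew)
    q = Xs.shape[0]
    step = q if chunk_size is None else max(1, int(chunk_size))
    mean = np.empty(q)
    var = np.empty(q)
    for start in range(0, q, step):
        sl = slice(start, min(start + step, q))
        m, v = _predict_standardized(
            Xs[sl], tr.X, model.hyperparameters, model.alpha, model.chol_L,
            include_noise,
        )
        mean[sl] = m
        var[sl] = v
    return Prediction(
        mean=mean * tr.y_scale + tr.y_mean,
        sigma=np.sqrt(var) * tr.y_scale,
    )


def standalone_predict(
    record: dict,
    Xnew: np.ndarray,
    *,
    include_noise: bool = False,
) -> Prediction:
    """Predict from an exported model record using arithmetic only.

    Operates on the plain serialized arrays (no fitting code): rebuilds the
    kernel, refactorizes the jittered K + sigma_n^2 I, and applies the stored
    weight vector.  Intended as the portable-deployment contract — any
    runtime that can do these array operations reproduces the native
    predictions.
    """
    if record.get("format") != "fluxgpr-model":
        raise ValueError("record is not a fluxgpr model export")
    theta = record["theta"]
    ell = np.asarray(theta["lengthscales"], dtype=float)
    sv = float(theta["signal_var"])
    nv = float(theta["noise_var"])
    X_train = np.asarray(record["X_train"], dtype=float)
    alpha = np.asarray(record["alpha"], dtype=float)
    x_mean = np.asarray(record["x_mean"], dtype=float)
    x_scale = np.asarray(record["x_scale"], dtype=float)
    y_mean = float(record["y_mean"])
    y_scale = float(record["y_scale"])
    jitter = float(record.get("jitter", 0.0))

    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != X_train.shape[1]:
        raise ValueError(
            f"dimension mismatch: query D={Xnew.shape[1]}, "
            f"record D={X_train.shape[1]}"
        )
    Xs = (Xnew - x_mean) / x_scale

    n = X_train.shape[0]
    d2 = cdist(X_train / ell, X_train / ell, metric="sqeuclidean")
    Kn = sv * np.exp(-0.5 * d2) + (nv + jitter) * np.eye(n)
    L = cholesky(Kn, lower=True)

    d2s = cdist(Xs / ell, X_train / ell, metric="sqeuclidean")
    Ks = sv * np.exp(-0.5 * d2s)
    mean = np.einsum("qn,n->q", Ks, alpha)
    B = Ks.T
    if B.shape[1] == 1:
        B = np.concatenate([B, B], axis=1)
        v = solve_triangular(L, B, lower=True)[:, :1]
    else:
        v = solve_triangular(L, B, lower=True)
    var = sv - np.einsum("ij,ij->j", v, v)
    if include_noise:
        var = var + nv
    var = np.maximum(var, 0.0)
    return Prediction(mean=mean * y_scale + y_mean, sigma=np.sqrt(var) * y_scale)
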