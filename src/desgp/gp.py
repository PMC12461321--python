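"""Gaussian-process regression on sigma-profile mixture descriptors.

Labels are modelled as a joint Gaussian with a null mean function and a
stationary kernel of the Euclidean distance between feature vectors:

    RBF:  k(x, x') = s2 * exp(-d^2 / (2 l^2))
    RQ:   k(x, x') = s2 * (1 + d^2 / (2 a l^2))^(-a)
    M32:  k(x, x') = s2 * (1 + sqrt(3) d / l) * exp(-sqrt(3) d / l)

each supplemented with an index-diagonal White noise term sW2 * delta(i, j)
to absorb experimental scatter.  Given training data (X, Y) the predictive
distribution at x* is the usual Gaussian conditional,

    mu'    = K*^T (K + sW2 I)^-1 Y
    Sigma' = k** - K*^T (K + sW2 I)^-1 K*

computed through a cached Cholesky factorization.  Hyperparameters
(s2, l, a, sW2) are fitted by maximizing the log marginal likelihood with
L-BFGS-B in log-hyperparameter space, with multiple restarts.

Features and labels may be normalized by standardization,
z' = (z - <z>) / s_z, or log-standardization, z' = (log z - <log z>) / s_log_z,
with a 1e-3 buffer added inside the logarithm so zero-valued entries (common
in sigma-profile bins) stay finite.  Normalizer moments are always fitted on
training data only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import linalg, optimize
from scipy.spatial.distance import cdist

logger = logging.getLogger("desgp")

__all__ = [
    "KernelConfig",
    "Normalizer",
    "Prediction",
    "TrainedGP",
    "LOG_BUFFER",
    "KERNEL_FAMILIES",
    "NORMALIZATION_MODES",
    "kernel_eval",
    "fit_normalizer",
    "log_marginal_likelihood",
    "train_gp",
    "save_model",
    "load_model",
]

LOG_BUFFER = 1e-3
KERNEL_FAMILIES = ("RBF", "RQ", "M32")
NORMALIZATION_MODES = ("none", "standardize", "log_standardize")

# Jitter escalation policy: relative to the mean kernel diagonal.
JITTER_START = 1e-8
JITTER_MAX = 1e-2

_SQRT3 = np.sqrt(3.0)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelConfig:
    """A stationary kernel family with its hyperparameters.

    ``alpha`` is only meaningful for the rational quadratic family;
    ``white_variance`` is the variance of the additive White noise term.
    """

    family: str
    variance: float = 1.0
    length_scale: float = 1.0
    alpha: float | None = None
    white_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.variance <= 0 or self.length_scale <= 0:
            raise ValueError("variance and length_scale must be > 0")
        if self.family == "RQ":
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("RQ kernel requires alpha > 0")
        if self.white_variance < 0:
            raise ValueError("white_variance must be >= 0")

    @property
    def n_hyperparameters(self) -> int:
        return 4 if self.family == "RQ" else 3

    def theta(self) -> np.ndarray:
        """Hyperparameters as a log-space vector (optimizer coordinates)."""
        vals = [self.variance, self.length_scale]
        if self.family == "RQ":
            vals.append(self.alpha)
        vals.append(max(self.white_variance, 1e-300))
        return np.log(np.asarray(vals))

    def with_theta(self, theta: np.ndarray) -> "KernelConfig":
        vals = np.exp(np.asarray(theta, dtype=float))
        if self.family == "RQ":
            return replace(
                self, variance=vals[0], length_scale=vals[1],
                alpha=vals[2], white_variance=vals[3],
            )
        return replace(
            self, variance=vals[0], length_scale=vals[1], white_variance=vals[2],
        )


def kernel_eval(
    config: KernelConfig,
    X: np.ndarray,
    X2: np.ndarray | None = None,
    include_white: bool = False,
) -> np.ndarray:
    """Evaluate the kernel matrix between two point sets.

    The White term ``sW2 * I`` is index-diagonal, so it only applies when
    both arguments are the same set (``X2 is None``); requesting it for a
    cross-covariance is an error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    same = X2 is None
    X2m = X if same else np.atleast_2d(np.asarray(X2, dtype=float))
    if X.shape[1] != X2m.shape[1]:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} vs {X2m.shape[1]} features"
        )
    if include_white and not same:
        raise ValueError("White noise is index-diagonal; pass X2=None to include it")
    K = _kernel_core(config, _dists(X, X2m))
    if include_white and config.white_variance > 0:
        K = K + config.white_variance * np.eye(X.shape[0])
    return K


def _dists(X: np.ndarray, X2: np.ndarray) -> np.ndarray:
    return cdist(X, X2, metric="euclidean")


def _kernel_core(config: KernelConfig, D: np.ndarray) -> np.ndarray:
    s2, ell = config.variance, config.length_scale
    if config.family == "RBF":
        return s2 * np.exp(-(D * D) / (2.0 * ell * ell))
    if config.family == "RQ":
        a = config.alpha
        return s2 * (1.0 + (D * D) / (2.0 * a * ell * ell)) ** (-a)
    # M32
    r = _SQRT3 * D / ell
    return s2 * (1.0 + r) * np.exp(-r)


def _kernel_core_grads(config: KernelConfig, D: np.ndarray) -> list[np.ndarray]:
    """Gradients of the core kernel w.r.t. log-hyperparameters.

    Returns [dK/dlog s2, dK/dlog l] plus [dK/dlog alpha] for RQ.
    """
    s2, ell = config.variance, config.length_scale
    D2 = D * D
    if config.family == "RBF":
        K = s2 * np.exp(-D2 / (2.0 * ell * ell))
        return [K, K * D2 / (ell * ell)]
    if config.family == "RQ":
        a = config.alpha
        B = 1.0 + D2 / (2.0 * a * ell * ell)
        K = s2 * B ** (-a)
        dK_dlog_l = s2 * B ** (-a - 1.0) * D2 / (ell * ell)
        # dK/dalpha = K * (-log B + D2 / (2 a l^2 B)); chain to log alpha
        dK_dlog_a = a * K * (-np.log(B) + D2 / (2.0 * a * ell * ell * B))
        return [K, dK_dlog_l, dK_dlog_a]
    # M32
    r = _SQRT3 * D / ell
    E = np.exp(-r)
    K = s2 * (1.0 + r) * E
    dK_dlog_l = s2 * r * r * E
    return [K, dK_dlog_l]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Normalizer:
    """Per-dimension standardization or log-standardization.

    Moments use the sample standard deviation (divisor n-1); constant
    dimensions get sd = 1 so they map to zero instead of dividing by zero.
    In log mode a 1e-3 buffer is added inside the logarithm, permitting
    zero-valued data.
    """

    mode: str
    mean: np.ndarray
    sd: np.ndarray
    buffer: float = LOG_BUFFER

    def __post_init__(self) -> None:
        if self.mode not in NORMALIZATION_MODES:
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if np.any(self.sd <= 0):
            raise ValueError("normalizer sd entries must be > 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.mode == "none":
            return values.copy()
        if self.mode == "standardize":
            return (values - self.mean) / self.sd
        if np.any(values < 0):
            raise ValueError("log-standardization requires nonnegative values")
        return (np.log(values + self.buffer) - self.mean) / self.sd

    def invert(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.mode == "none":
            return values.copy()
        if self.mode == "standardize":
            return values * self.sd + self.mean
        return np.exp(values * self.sd + self.mean) - self.buffer


def fit_normalizer(values: np.ndarray, mode: str) -> Normalizer:
    """Fit per-dimension moments on ``values`` (1-D vector or 2-D matrix)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot fit a normalizer on empty data")
    if mode == "none":
        d = values.shape[-1] if values.ndim == 2 else ()
        return Normalizer(mode, np.zeros(d), np.ones(d))
    work = values
    if mode == "log_standardize":
        if np.any(values < 0):
            raise ValueError("log-standardization requires nonnegative values")
        work = np.log(values + LOG_BUFFER)
    axis = 0 if work.ndim == 2 else None
    mean = work.mean(axis=axis)
    n = work.shape[0]
    sd = work.std(axis=axis, ddof=1) if n > 1 else np.zeros_like(np.asarray(mean))
    sd = np.where(np.asarray(sd) > 0, sd, 1.0)
    return Normalizer(mode, np.asarray(mean), np.asarray(sd))


# ---------------------------------------------------------------------------
# Log marginal likelihood
# ---------------------------------------------------------------------------

def _full_kernel(config: KernelConfig, X: np.ndarray, jitter: float) -> np.ndarray:
    K = kernel_eval(config, X, include_white=True)
    return K + jitter * np.eye(X.shape[0])


def log_marginal_likelihood(
    config: KernelConfig,
    X: np.ndarray,
    Y: np.ndarray,
    jitter: float = 1e-10,
    grad: bool = False,
):
    """log N(Y | 0, K + sW2 I + jitter I) under the zero-mean GP prior.

    With ``grad=True`` also returns the gradient w.r.t. the kernel's
    log-hyperparameters (in the order of :meth:`KernelConfig.theta`).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).ravel()
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    K = _full_kernel(config, X, jitter)
    L = linalg.cholesky(K, lower=True)
    alpha = linalg.cho_solve((L, True), Y)
    lml = (
        -0.5 * float(Y @ alpha)
        - float(np.log(np.diag(L)).sum())
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    if not grad:
        return lml
    Kinv = linalg.cho_solve((L, True), np.eye(n))
    inner = np.outer(alpha, alpha) - Kinv
    D = _dists(X, X)
    grads = _kernel_core_grads(config, D)
    grads.append(config.white_variance * np.eye(n))  # d/dlog sW2
    g = np.array([0.5 * float(np.sum(inner * dK)) for dK in grads])
    return lml, g


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    """Posterior predictions mapped back to label units.

    For log-standardized labels ``mean`` is the predictive median
    (exp of the log-space mean) and ``lower``/``upper`` the 95%
    multiplicative band; ``variance`` is a delta-method approximation.
    ``mean_normalized``/``variance_normalized`` expose the posterior in
    the GP's normalized working space.
    """

    mean: np.ndarray
    variance: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    mean_normalized: np.ndarray
    variance_normalized: np.ndarray

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)


@dataclass
class TrainedGP:
    """A fitted GP: kernel, normalizers, and the cached factorization."""

    kernel: KernelConfig
    feature_normalizer: Normalizer
    label_normalizer: Normalizer
    X_train: np.ndarray          # normalized features, (n, d)
    Y_train: np.ndarray          # normalized labels, (n,)
    L: np.ndarray                # lower Cholesky of K + sW2 I + jitter I
    alpha_: np.ndarray           # (K + sW2 I + jitter I)^-1 Y
    jitter: float
    lml: float
    include_noise_in_predictive: bool = True

    @property
    def n_train(self) -> int:
        return self.X_train.shape[0]

    @property
    def n_features(self) -> int:
        return self.X_train.shape[1]

    def predict(self, X_raw: np.ndarray) -> Prediction:
        """Predictive mean and variance at new (raw, unnormalized) inputs."""
        X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
        if X_raw.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X_raw.shape[1]}"
            )
        Xn = self.feature_normalizer.apply(X_raw)
        Ks = kernel_eval(self.kernel, self.X_train, Xn)          # (n, m)
        # per-query contiguous dot products keep the reduction order
        # independent of batch size: batched and one-at-a-time predictions
        # agree bit-for-bit
        KsT = np.ascontiguousarray(Ks.T)                         # (m, n)
        mu = np.array([row @ self.alpha_ for row in KsT])
        vT = np.ascontiguousarray(
            linalg.solve_triangular(self.L, Ks, lower=True).T
        )
        k_ss = self.kernel.variance
        if self.include_noise_in_predictive:
            k_ss = k_ss + self.kernel.white_variance
        var = np.maximum(
            k_ss - np.array([row @ row for row in vT]), 0.0
        )
        return self._back_transform(mu, var)

    def _back_transform(self, mu: np.ndarray, var: np.ndarray) -> Prediction:
        norm = self.label_normalizer
        sd = np.sqrt(var)
        if norm.mode == "log_standardize":
            mu_log = mu * norm.sd + norm.mean
            sd_log = sd * norm.sd
            median = np.exp(mu_log) - norm.buffer
            lower = np.exp(mu_log - 1.96 * sd_log) - norm.buffer
            upper = np.exp(mu_log + 1.96 * sd_log) - norm.buffer
            var_out = (np.exp(mu_log) * sd_log) ** 2
            return Prediction(median, var_out, lower, upper, mu, var)
        mean = norm.invert(mu)
        scale = 1.0 if norm.mode == "none" else float(norm.sd)
        var_out = var * scale**2
        sd_out = np.sqrt(var_out)
        return Prediction(
            mean, var_out, mean - 1.96 * sd_out, mean + 1.96 * sd_out, mu, var
        )


def _factorize(config: KernelConfig, X: np.ndarray):
    """Cholesky of the full training covariance with jitter escalation."""
    K = kernel_eval(config, X, include_white=True)
    mean_diag = float(np.mean(np.diag(K)))
    rel = JITTER_START
    while rel <= JITTER_MAX:
        jitter = rel * mean_diag
        try:
            L = linalg.cholesky(K + jitter * np.eye(X.shape[0]), lower=True)
            return L, jitter
        except linalg.LinAlgError:
            logger.warning("Cholesky failed at jitter %.1e, escalating x10", jitter)
            rel *= 10.0
    raise linalg.LinAlgError(
        f"covariance not positive definite up to relative jitter {JITTER_MAX:.0e} "
        f"(n={X.shape[0]}, kernel={config})"
    )


def _initial_length_scale(Xn: np.ndarray, rng: np.random.Generator) -> float:
    """Median pairwise distance of (a subsample of) the normalized inputs."""
    n = Xn.shape[0]
    sub = Xn if n <= 200 else Xn[rng.choice(n, 200, replace=False)]
    d = _dists(sub, sub)
    med = float(np.median(d[np.triu_indices_from(d, k=1)])) if sub.shape[0] > 1 else 1.0
    return med if med > 0 else 1.0


def train_gp(
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    family: str = "M32",
    feature_mode: str = "log_standardize",
    label_mode: str = "log_standardize",
    n_restarts: int = 5,
    seed: int = 0,
    bounds: tuple[float, float] = (1e-6, 1e6),
    include_noise_in_predictive: bool = True,
) -> TrainedGP:
    """Fit normalizers and kernel hyperparameters on training data.

    Normalizer moments come exclusively from ``(X_raw, Y_raw)`` — callers
    must pass the training split only.  Hyperparameters are optimized by
    L-BFGS-B on log-hyperparameters bounded to ``bounds``, from a
    median-distance-heuristic start plus ``n_restarts`` log-uniform random
    restarts drawn from a generator seeded with ``seed``; the best final
    log marginal likelihood wins, so the result is deterministic given
    the seed and never worse than its own starting point.
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    Y_raw = np.asarray(Y_raw, dtype=float).ravel()
    if X_raw.shape[0] != Y_raw.shape[0]:
        raise ValueError("X and Y row counts differ")
    if X_raw.shape[0] < 2:
        raise ValueError("need at least 2 training rows")

    fnorm = fit_normalizer(X_raw, feature_mode)
    lnorm = fit_normalizer(Y_raw, label_mode)
    Xn = fnorm.apply(X_raw)
    Yn = lnorm.apply(Y_raw)

    rng = np.random.default_rng(seed)
    l0 = _initial_length_scale(Xn, rng)
    base = KernelConfig(
        family=family,
        variance=1.0,
        length_scale=l0,
        alpha=1.0 if family == "RQ" else None,
        white_variance=0.1,
    )
    n_hyp = base.n_hyperparameters
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    opt_bounds = [(lo, hi)] * n_hyp

    def objective(theta: np.ndarray):
        cfg = base.with_theta(theta)
        try:
            lml, g = log_marginal_likelihood(cfg, Xn, Yn, jitter=1e-10, grad=True)
        except linalg.LinAlgError:
            return 1e25, np.zeros_like(theta)
        if not np.isfinite(lml):
            return 1e25, np.zeros_like(theta)
        return -lml, -g

    starts = [base.theta()]
    for _ in range(n_restarts):
        draw = rng.uniform(np.log(1e-2), np.log(1e2), size=n_hyp)
        draw[1] += np.log(l0)  # centre length-scale draws on the heuristic
        starts.append(np.clip(draw, lo, hi))

    initial_lml = -objective(starts[0])[0]
    best_theta, best_val = None, np.inf
    for theta0 in starts:
        res = optimize.minimize(
            objective, theta0, jac=True, method="L-BFGS-B", bounds=opt_bounds
        )
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    if best_theta is None or not np.isfinite(best_val):
        raise RuntimeError("hyperparameter optimization failed from every start")
    if -best_val < initial_lml - 1e-9:
        # L-BFGS-B never accepts a worse point than its start, so the best
        # of all restarts cannot fall below the default start's LML.
        best_theta = starts[0]

    kernel = base.with_theta(best_theta)
    L, jitter = _factorize(kernel, Xn)
    alpha = linalg.cho_solve((L, True), Yn)
    n = Xn.shape[0]
    lml = (
        -0.5 * float(Yn @ alpha)
        - float(np.log(np.diag(L)).sum())
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    return TrainedGP(
        kernel=kernel,
        feature_normalizer=fnorm,
        label_normalizer=lnorm,
        X_train=Xn,
        Y_train=Yn,
        L=L,
        alpha_=alpha,
        jitter=jitter,
        lml=float(lml),
        include_noise_in_predictive=include_noise_in_predictive,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_FORMAT_VERSION = "desgp-model-1"


def save_model(model: TrainedGP, path) -> None:
    """Serialize a trained model to a single JSON archive.

    Floats survive the JSON round trip exactly, so a reloaded model's
    predictions are bit-identical to the saved session's.
    """
    payload = {
        "format": _FORMAT_VERSION,
        "kernel": {
            "family": model.kernel.family,
            "variance": model.kernel.variance,
            "length_scale": model.kernel.length_scale,
            "alpha": model.kernel.alpha,
            "white_variance": model.kernel.white_variance,
        },
        "feature_normalizer": _norm_to_dict(model.feature_normalizer),
        "label_normalizer": _norm_to_dict(model.label_normalizer),
        "X_train": model.X_train.tolist(),
        "Y_train": model.Y_train.tolist(),
        "L": model.L.tolist(),
        "alpha_": model.alpha_.tolist(),
        "jitter": model.jitter,
        "lml": model.lml,
        "include_noise_in_predictive": model.include_noise_in_predictive,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> TrainedGP:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format')!r}")
    k = payload["kernel"]
    return TrainedGP(
        kernel=KernelConfig(
            family=k["family"],
            variance=k["variance"],
            length_scale=k["length_scale"],
            alpha=k["alpha"],
            white_variance=k["white_variance"],
        ),
        feature_normalizer=_norm_from_dict(payload["feature_normalizer"]),
        label_normalizer=_norm_from_dict(payload["label_normalizer"]),
        X_train=np.array(payload["X_train"]),
        Y_train=np.array(payload["Y_train"]),
        L=np.array(payload["L"]),
        alpha_=np.array(payload["alpha_"]),
        jitter=payload["jitter"],
        lml=payload["lml"],
        include_noise_in_predictive=payload["include_noise_in_predictive"],
    )


def _norm_to_dict(norm: Normalizer) -> dict:
    return {
        "mode": norm.mode,
        "mean": np.asarray(norm.mean).tolist(),
        "sd": np.asarray(norm.sd).tolist(),
        "buffer": norm.buffer,
    }


def _norm_from_dict(d: dict) -> Normalizer:
    return Normalizer(d["mode"], np.array(d["mean"]), np.array(d["sd"]), d["buffer"])
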