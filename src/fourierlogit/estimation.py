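"""Maximum-likelihood fitting of the cosine-harmonic logit model.

Implements the Bernoulli log-likelihood with analytic score and Hessian and a
Newton–Raphson solver with step-halving, plus the plain binary-logistic
baseline fitted by the same engine on an intercept+linear design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .basis import (
    DesignMatrix,
    DimensionError,
    OscillationCombo,
    PredictorMatrix,
    ValidationError,
    build_design,
    inverse_logit,
    linear_predictor,
)

__all__ = [
    "CoefficientSet",
    "FitResult",
    "log_likelihood",
    "score_vector",
    "hessian_matrix",
    "newton_raphson_fit",
    "fit_fourier_logit",
    "fit_binary_logistic",
    "deviance_of",
    "aic_of",
    "SeparationError",
    "SingularSystemError",
    "SeparationWarning",
]

#: convergence tolerance on the max-norm coefficient change
DEFAULT_EPS = 1e-6
DEFAULT_MAX_ITER = 100
_MAX_HALVINGS = 30
_RIDGE = 1e-8
_SEPARATION_BETA = 1e3
_SEPARATION_PROB = 1e-10


class SeparationError(ValueError):
    """Response contains a single class: the MLE does not exist."""


class SingularSystemError(np.linalg.LinAlgError):
    """Observed information singular beyond the ridge fallback."""


class SeparationWarning(UserWarning):
    """Quasi-complete separation detected during fitting."""


@dataclass(frozen=True)
class CoefficientSet:
    """Structured view of the coefficient vector for a cosine-harmonic design.

    ``a0`` pairs with the constant-1/2 column, ``b[j]`` with the raw linear
    column of predictor ``j`` and ``a[j][k-1]`` with ``cos(k * x_j)``.
    """

    a0: float
    b: np.ndarray
    a: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float).ravel())
        object.__setattr__(
            self, "a", tuple(np.asarray(aj, dtype=float).ravel() for aj in self.a)
        )
        if len(self.a) != self.b.size:
            raise DimensionError(
                f"{self.b.size} linear coefficients but {len(self.a)} cosine blocks"
            )

    @property
    def combo(self) -> OscillationCombo:
        return OscillationCombo(tuple(aj.size for aj in self.a))

    def to_flat(self) -> np.ndarray:
        """Flatten to the design-column order: a0, then per j (b_j, a_1j..a_Kj)."""
        parts = [np.array([self.a0])]
        for bj, aj in zip(self.b, self.a):
            parts.append(np.array([bj]))
            parts.append(aj)
        return np.concatenate(parts)

    @classmethod
    def from_flat(cls, flat: np.ndarray, combo: OscillationCombo) -> "CoefficientSet":
        flat = np.asarray(flat, dtype=float).ravel()
        if flat.size != combo.n_params():
            raise DimensionError(
                f"flat vector has {flat.size} entries, combo implies {combo.n_params()}"
            )
        a0 = flat[0]
        b = np.empty(combo.p)
        a = []
        pos = 1
        for j, kj in enumerate(combo):
            b[j] = flat[pos]
            a.append(flat[pos + 1 : pos + 1 + kj].copy())
            pos += 1 + kj
        return cls(a0=a0, b=b, a=tuple(a))

    @classmethod
    def zeros(cls, combo: OscillationCombo) -> "CoefficientSet":
        return cls(a0=0.0, b=np.zeros(combo.p), a=tuple(np.zeros(k) for k in combo))


@dataclass
class FitResult:
    """Converged (or best-effort) maximum-likelihood estimate and diagnostics."""

    beta: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    grad_maxnorm: float
    neg_hessian: np.ndarray
    fitted_probs: np.ndarray
    trace: list[tuple[float, float]]
    design: DesignMatrix | None = None
    combo: OscillationCombo | None = None
    label: str = "fourier"
    warnings_: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.beta.size

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.m

    @property
    def beta_hat(self) -> CoefficientSet:
        if self.combo is None:
            raise ValueError("structured coefficients only defined for cosine fits")
        return CoefficientSet.from_flat(self.beta, self.combo)


def _as_matrix(Z: DesignMatrix | np.ndarray) -> np.ndarray:
    return Z.Z if isinstance(Z, DesignMatrix) else np.asarray(Z, dtype=float)


def _check_response(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).ravel()
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(f"response must be coded 0/1, found values {vals}")
    return y.astype(float)


def log_likelihood(
    beta: CoefficientSet | np.ndarray, Z: DesignMatrix | np.ndarray, y: np.ndarray
) -> float:
    """Bernoulli log-likelihood sum{ y_i eta_i - ln(1 + e^{eta_i}) }.

    Uses the linear-predictor form, which is algebraically identical to
    sum y ln(pi) + (1-y) ln(1-pi) but stable for large |eta|.
    """
    if isinstance(beta, CoefficientSet):
        beta = beta.to_flat()
    mat = _as_matrix(Z)
    y = _check_response(y)
    if y.size != mat.shape[0]:
        raise DimensionError(f"{y.size} responses for {mat.shape[0]} design rows")
    eta = linear_predictor(mat, beta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def score_vector(
    beta: CoefficientSet | np.ndarray, Z: DesignMatrix | np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Gradient of the log-likelihood: g = Z^T (y - pi)."""
    if isinstance(beta, CoefficientSet):
        beta = beta.to_flat()
    mat = _as_matrix(Z)
    y = _check_response(y)
    if y.size != mat.shape[0]:
        raise DimensionError(f"{y.size} responses for {mat.shape[0]} design rows")
    pi = inverse_logit(linear_predictor(mat, beta))
    return mat.T @ (y - pi)


def hessian_matrix(
    beta: CoefficientSet | np.ndarray, Z: DesignMatrix | np.ndarray
) -> np.ndarray:
    """Hessian of the log-likelihood: H = -Z^T diag(pi(1-pi)) Z.

    Symmetric negative semidefinite for every beta (canonical-link concavity);
    the 1/2 intercept column produces the 1/4 and 1/2 factors in the
    intercept rows automatically.
    """
    if isinstance(beta, CoefficientSet):
        beta = beta.to_flat()
    mat = _as_matrix(Z)
    pi = inverse_logit(linear_predictor(mat, beta))
    w = pi * (1.0 - pi)
    return -(mat.T * w) @ mat


def _solve_newton(neg_h: np.ndarray, g: np.ndarray, Z: DesignMatrix | np.ndarray):
    """Solve (−H) d = g, with a single ridge fallback before failing loudly."""
    try:
        return np.linalg.solve(neg_h, g), False
    except np.linalg.LinAlgError:
        pass
    ridged = neg_h + _RIDGE * np.eye(neg_h.shape[0])
    try:
        return np.linalg.solve(ridged, g), True
    except np.linalg.LinAlgError:
        evals, evecs = np.linalg.eigh(neg_h)
        null = evecs[:, np.argmin(np.abs(evals))]
        worst = np.argsort(-np.abs(null))[:3]
        labels = (
            [Z.column_labels()[i] for i in worst]
            if isinstance(Z, DesignMatrix)
            else [f"column {i}" for i in worst]
        )
        raise SingularSystemError(
            "observed information singular even after ridge; "
            f"near-collinear columns: {', '.join(labels)}"
        )


def newton_raphson_fit(
    Z: DesignMatrix | np.ndarray,
    y: np.ndarray,
    init: CoefficientSet | np.ndarray | None = None,
    eps: float = DEFAULT_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
    label: str = "fourier",
) -> FitResult:
    """Maximise the Bernoulli log-likelihood by damped Newton–Raphson.

    Starts from zeros unless ``init`` is given, takes the full Newton step
    when it improves the log-likelihood and halves it (up to 30 times)
    otherwise, and stops when the max-norm coefficient change drops below
    ``eps``.  Hitting ``max_iter`` or detecting separation yields
    ``converged=False`` with a warning rather than an exception.
    """
    mat = _as_matrix(Z)
    y = _check_response(y)
    n, m = mat.shape
    if y.size != n:
        raise DimensionError(f"{y.size} responses for {n} design rows")
    if len(np.unique(y)) < 2:
        raise SeparationError("response contains a single class; MLE does not exist")
    if n <= m:
        warnings.warn(
            f"n={n} observations for m={m} coefficients; fit may be unstable",
            UserWarning,
            stacklevel=2,
        )

    if init is None:
        beta = np.zeros(m)
    elif isinstance(init, CoefficientSet):
        beta = init.to_flat()
    else:
        beta = np.asarray(init, dtype=float).ravel()
        if beta.size != m:
            raise DimensionError(f"init has {beta.size} entries for m={m} columns")

    fit_warnings: list[str] = []
    ll = log_likelihood(beta, mat, y)
    trace: list[tuple[float, float]] = [(ll, float("inf"))]
    converged = False
    prev_grad_norm = float("inf")
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        g = score_vector(beta, mat, y)
        neg_h = -hessian_matrix(beta, mat)
        direction, ridged = _solve_newton(neg_h, g, Z)
        if ridged:
            fit_warnings.append("ridge 1e-8 applied to a singular information matrix")

        step = 1.0
        for _ in range(_MAX_HALVINGS):
            candidate = beta + step * direction
            ll_new = log_likelihood(candidate, mat, y)
            if ll_new >= ll:
                break
            step *= 0.5
        else:
            candidate, ll_new = beta, ll  # no improving step found

        change = float(np.max(np.abs(candidate - beta)))
        beta, ll = candidate, ll_new
        trace.append((ll, change))

        grad_norm = float(np.max(np.abs(score_vector(beta, mat, y))))
        probs = inverse_logit(linear_predictor(mat, beta))
        at_boundary = np.any(probs < _SEPARATION_PROB) or np.any(
            probs > 1.0 - _SEPARATION_PROB
        )
        if np.any(np.abs(beta) > _SEPARATION_BETA) or (
            at_boundary and grad_norm >= prev_grad_norm
        ):
            msg = "quasi-complete separation detected; coefficients diverging"
            fit_warnings.append(msg)
            warnings.warn(msg, SeparationWarning, stacklevel=2)
            break
        prev_grad_norm = grad_norm

        if change < eps:
            converged = True
            break
    else:
        fit_warnings.append(f"max_iter={max_iter} reached without convergence")

    if not converged and not fit_warnings:
        fit_warnings.append(f"max_iter={max_iter} reached without convergence")

    probs = inverse_logit(linear_predictor(mat, beta))
    return FitResult(
        beta=beta,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        grad_maxnorm=float(np.max(np.abs(score_vector(beta, mat, y)))),
        neg_hessian=-hessian_matrix(beta, mat),
        fitted_probs=probs,
        trace=trace,
        design=Z if isinstance(Z, DesignMatrix) else None,
        combo=Z.combo if isinstance(Z, DesignMatrix) else None,
        label=label,
        warnings_=fit_warnings,
    )


def fit_fourier_logit(
    X: PredictorMatrix | np.ndarray,
    y: np.ndarray,
    combo: OscillationCombo | tuple[int, ...],
    rescale: bool = False,
    eps: float = DEFAULT_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Build the cosine-harmonic design for ``combo`` and fit it."""
    Z = build_design(X, combo, rescale=rescale)
    return newton_raphson_fit(Z, y, eps=eps, max_iter=max_iter)


def fit_binary_logistic(
    X: PredictorMatrix | np.ndarray,
    y: np.ndarray,
    eps: float = DEFAULT_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Plain logistic baseline: constant-1 intercept plus linear terms.

    Uses the same Newton–Raphson engine; m = 1 + p and the intercept
    coefficient is the usual beta0 (not the half-scaled a0).
    """
    if not isinstance(X, PredictorMatrix):
        X = PredictorMatrix(np.asarray(X, dtype=float))
    Z = np.column_stack([np.ones(X.n), X.values])
    return newton_raphson_fit(Z, y, eps=eps, max_iter=max_iter, label="logistic")


def deviance_of(fit: FitResult) -> float:
    """-2 log-likelihood; the saturated model of ungrouped binary data has loglik 0."""
    return fit.deviance


def aic_of(fit: FitResult) -> float:
    """AIC = deviance + 2 m with m = 1 + p + sum(K_j) coefficients."""
    return fit.aic
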