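"""Cosine-harmonic design matrices for the binary Fourier-logit model.

The linear predictor for observation *i* is

    eta_i = (1/2) a0 + sum_j [ b_j x_ji + sum_{k=1}^{K_j} a_kj cos(k x_ji) ]

so the design matrix carries one constant 1/2 column, one raw linear column
per predictor, and ``K_j`` cosine columns per predictor.  The intercept is
scaled by 1/2 (rather than folded into the coefficient) so that the reported
``a0`` matches the half-intercept parameterisation of the model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "PredictorMatrix",
    "OscillationCombo",
    "DesignMatrix",
    "build_design",
    "linear_predictor",
    "inverse_logit",
    "DimensionError",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when input data violate a precondition (non-finite, bad coding...)."""


class DimensionError(ValueError):
    """Raised when two aligned objects disagree on shape."""


@dataclass(frozen=True)
class PredictorMatrix:
    """An n x p block of continuous predictors in native units."""

    values: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.ndim != 2:
            raise ValidationError(f"predictor block must be 2-D, got ndim={values.ndim}")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValidationError(f"predictor block must be non-empty, got shape {values.shape}")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite predictor value at row {i}, column {j}"
            )
        names = tuple(self.names) if self.names else tuple(
            f"x{j + 1}" for j in range(values.shape[1])
        )
        if len(names) != values.shape[1]:
            raise DimensionError(
                f"{len(names)} names for {values.shape[1]} predictor columns"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class OscillationCombo:
    """Number of cosine harmonics per predictor: the model-complexity knob."""

    ks: tuple[int, ...]

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.ks)
        if any(k < 0 for k in ks):
            raise ValidationError(f"harmonic counts must be >= 0, got {ks}")
        object.__setattr__(self, "ks", ks)

    def __len__(self) -> int:
        return len(self.ks)

    def __iter__(self):
        return iter(self.ks)

    @property
    def p(self) -> int:
        return len(self.ks)

    @property
    def total(self) -> int:
        return sum(self.ks)

    @property
    def level(self) -> int:
        """Largest per-predictor harmonic count."""
        return max(self.ks) if self.ks else 0

    def n_params(self) -> int:
        """Coefficient count of the paired design: intercept + linear + cosines."""
        return 1 + self.p + self.total

    @classmethod
    def of(cls, *ks: int) -> "OscillationCombo":
        return cls(tuple(ks))


@dataclass(frozen=True)
class DesignMatrix:
    """Expanded n x m basis with one descriptor per column.

    Descriptors are ``("intercept",)``, ``("linear", j)`` or ``("cos", j, k)``
    with 0-based predictor index j and harmonic order k >= 1.
    """

    Z: np.ndarray
    columns: tuple[tuple, ...]
    combo: OscillationCombo | None = None
    names: tuple[str, ...] = field(default=())

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]

    def column_labels(self) -> list[str]:
        """Human-readable labels aligned with coefficient order."""
        labels = []
        for col in self.columns:
            if col[0] == "intercept":
                labels.append("a0")
            elif col[0] == "linear":
                name = self.names[col[1]] if self.names else f"x{col[1] + 1}"
                labels.append(f"b[{name}]")
            else:
                name = self.names[col[1]] if self.names else f"x{col[1] + 1}"
                labels.append(f"a{col[2]}[{name}]")
        return labels


def _rescale_to_pi(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) * (np.pi / (hi - lo))


def build_design(
    X: PredictorMatrix | np.ndarray,
    combo: OscillationCombo | Sequence[int],
    rescale: bool = False,
) -> DesignMatrix:
    """Construct the half-intercept + linear + cosine design matrix.

    Parameters
    ----------
    X
        n x p predictor block (finite entries).
    combo
        Per-predictor cosine-harmonic counts ``(K_1, ..., K_p)``.
    rescale
        If True, affinely map each predictor to ``[0, pi]`` before taking
        cosines (the linear columns keep raw units).  Default False: cosines
        are applied to raw values.

    Returns
    -------
    DesignMatrix
        ``m = 1 + p + sum(K_j)`` columns ordered intercept, then per
        predictor its linear column followed by ``cos(1*x) .. cos(K_j*x)``.
    """
    if not isinstance(X, PredictorMatrix):
        X = PredictorMatrix(np.asarray(X, dtype=float))
    if not isinstance(combo, OscillationCombo):
        combo = OscillationCombo(tuple(combo))
    if combo.p != X.p:
        raise DimensionError(
            f"combo has {combo.p} entries but predictor block has {X.p} columns"
        )

    n = X.n
    cols: list[np.ndarray] = [np.full(n, 0.5)]
    descriptors: list[tuple] = [("intercept",)]
    for j, kj in enumerate(combo):
        xj = X.values[:, j]
        cols.append(xj)
        descriptors.append(("linear", j))
        xc = _rescale_to_pi(xj) if rescale else xj
        for k in range(1, kj + 1):
            cols.append(np.cos(k * xc))
            descriptors.append(("cos", j, k))
    Z = np.column_stack(cols)
    return DesignMatrix(Z=Z, columns=tuple(descriptors), combo=combo, names=X.names)


def linear_predictor(Z: DesignMatrix | np.ndarray, beta: np.ndarray) -> np.ndarray:
    """eta = Z beta, checking column alignment."""
    mat = Z.Z if isinstance(Z, DesignMatrix) else np.asarray(Z, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    if mat.shape[1] != beta.size:
        raise DimensionError(
            f"design has {mat.shape[1]} columns but coefficient vector has {beta.size}"
        )
    return mat @ beta


_PROB_LO = np.nextafter(0.0, 1.0)
_PROB_HI = np.nextafter(1.0, 0.0)


def inverse_logit(eta: np.ndarray) -> np.ndarray:
    """Overflow-safe exp(eta)/(1+exp(eta)); saturates smoothly for large |eta|.

    Output is clamped to the open interval (0, 1) at the nearest
    representable doubles so downstream logs never hit exact 0 or 1.
    """
    return np.clip(expit(np.asarray(eta, dtype=float)), _PROB_LO, _PROB_HI)
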