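"""AIC-driven search over cosine-harmonic counts.

Fits every combination of per-predictor harmonic counts on a grid and keeps
the minimum-AIC model, reporting cumulative per-level minima (the minimum over
all combinations whose largest count is at most K, for K = 1..k_max).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .basis import OscillationCombo, PredictorMatrix, ValidationError
from .estimation import FitResult, SingularSystemError, fit_fourier_logit

__all__ = [
    "SelectionRow",
    "SelectionTable",
    "enumerate_combos",
    "select_oscillation",
    "SelectionError",
]

logger = logging.getLogger(__name__)


class SelectionError(RuntimeError):
    """No combination produced a converged fit."""


@dataclass(frozen=True)
class SelectionRow:
    combo: OscillationCombo
    level: int
    aic: float
    converged: bool


@dataclass
class SelectionTable:
    """Full grid-search record plus the per-level and global minima."""

    rows: list[SelectionRow]
    level_minima: list[tuple[int, OscillationCombo, float]]
    best_combo: OscillationCombo
    best_aic: float
    best_fit: FitResult

    def to_records(self) -> list[dict]:
        return [
            {
                "combo": ",".join(str(k) for k in row.combo),
                "level": row.level,
                "aic": row.aic,
                "converged": row.converged,
            }
            for row in self.rows
        ]


def enumerate_combos(p: int, k_max: int, k_min: int = 1) -> list[OscillationCombo]:
    """All harmonic-count vectors in {k_min..k_max}^p, lexicographic order."""
    if p < 1:
        raise ValidationError(f"need p >= 1 predictors, got {p}")
    if k_min < 0 or k_max < k_min:
        raise ValidationError(f"need 0 <= k_min <= k_max, got k_min={k_min}, k_max={k_max}")
    return [
        OscillationCombo(ks)
        for ks in itertools.product(range(k_min, k_max + 1), repeat=p)
    ]


def _tie_key(combo: OscillationCombo, aic: float):
    # ties broken toward fewer total harmonics, then lexicographically
    return (aic, combo.total, combo.ks)


def select_oscillation(
    X: PredictorMatrix | np.ndarray,
    y: np.ndarray,
    k_max: int = 4,
    k_min: int = 1,
    rescale: bool = False,
    greedy: bool = False,
    eps: float = 1e-6,
    max_iter: int = 100,
) -> SelectionTable:
    """Exhaustive minimum-AIC search over harmonic-count combinations.

    Parameters
    ----------
    X, y
        Predictor block and 0/1 response.
    k_max
        Largest per-predictor harmonic count (default 4).
    k_min
        Smallest count in the search grid (default 1: every predictor keeps at
        least one harmonic; pass 0 to allow purely linear components).
    greedy
        Coordinate-ascent shortcut for large p: start from all-``k_min`` and
        repeatedly increment the single K_j that most improves AIC.  Explores
        a subset of the grid, so it may miss the exhaustive optimum.

    Returns
    -------
    SelectionTable
        Every evaluated combination, the cumulative minimum AIC per level
        K = k_min+... .. k_max, and the global best fit.
    """
    if not isinstance(X, PredictorMatrix):
        X = PredictorMatrix(np.asarray(X, dtype=float))
    if k_max < 1:
        raise ValidationError(f"k_max must be >= 1, got {k_max}")

    rows: list[SelectionRow] = []
    fits: dict[tuple[int, ...], FitResult] = {}

    def try_combo(combo: OscillationCombo) -> FitResult | None:
        if combo.ks in fits:
            return fits[combo.ks]
        if any(r.combo.ks == combo.ks for r in rows):
            return None  # previously failed
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_fourier_logit(
                    X, y, combo, rescale=rescale, eps=eps, max_iter=max_iter
                )
        except SingularSystemError as exc:
            logger.warning("combo %s skipped: %s", combo.ks, exc)
            rows.append(SelectionRow(combo, combo.level, float("nan"), False))
            return None
        if not fit.converged:
            logger.warning(
                "combo %s did not converge (AIC %.4f excluded)", combo.ks, fit.aic
            )
        rows.append(SelectionRow(combo, combo.level, fit.aic, fit.converged))
        if fit.converged:
            fits[combo.ks] = fit
            return fit
        return None

    if greedy:
        # coordinate ascent: from the all-k_min corner, repeatedly take the
        # single-K_j increment that lowers AIC the most (non-paper shortcut)
        current = OscillationCombo((k_min,) * X.p)
        current_fit = try_combo(current)
        current_aic = current_fit.aic if current_fit is not None else float("inf")
        improved = True
        while improved:
            improved = False
            best_neighbor, best_aic = None, current_aic
            for j in range(X.p):
                if current.ks[j] >= k_max:
                    continue
                ks = list(current.ks)
                ks[j] += 1
                neighbor = OscillationCombo(tuple(ks))
                fit = try_combo(neighbor)
                if fit is not None and fit.aic < best_aic:
                    best_neighbor, best_aic = neighbor, fit.aic
            if best_neighbor is not None:
                current, current_aic, improved = best_neighbor, best_aic, True
    else:
        for combo in enumerate_combos(X.p, k_max, k_min):
            try_combo(combo)

    if not fits:
        raise SelectionError("no oscillation combination produced a converged fit")

    converged_rows = [r for r in rows if r.converged]
    level_minima: list[tuple[int, OscillationCombo, float]] = []
    lo_level = max(k_min, 1)
    for level in range(lo_level, k_max + 1):
        eligible = [r for r in converged_rows if r.level <= level]
        if not eligible:
            continue
        best = min(eligible, key=lambda r: _tie_key(r.combo, r.aic))
        level_minima.append((level, best.combo, best.aic))

    best_row = min(converged_rows, key=lambda r: _tie_key(r.combo, r.aic))
    return SelectionTable(
        rows=rows,
        level_minima=level_minima,
        best_combo=best_row.combo,
        best_aic=best_row.aic,
        best_fit=fits[best_row.combo.ks],
    )
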