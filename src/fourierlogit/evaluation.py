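"""Model comparison and classification accuracy.

Deviance/AIC tabulation across fitted models, confusion-matrix metrics at a
fixed probability cutoff, rank-based (Mann–Whitney) AUC, Press's Q against its
chi-square threshold, and the grouped-proportion diagnostic used to eyeball
repeating patterns in the response rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, rankdata

from .basis import ValidationError
from .estimation import FitResult

__all__ = [
    "ClassificationReport",
    "confusion_metrics",
    "auc_mann_whitney",
    "press_q",
    "chi_square_critical",
    "compare_models",
    "grouped_proportions",
    "UndefinedAUCError",
]


class UndefinedAUCError(ValueError):
    """AUC requires both classes to be present."""


@dataclass
class ClassificationReport:
    """Confusion counts and derived accuracy metrics at a single cutoff.

    Sensitivity/specificity are reported under both orientations because which
    class counts as "positive" is a labelling convention: ``sensitivity`` /
    ``specificity`` treat class 1 as positive; the ``*_class0`` pair swaps the
    roles.  Undefined rates (empty class) are NaN.
    """

    n: int
    cutoff: float
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    sensitivity_class0: float
    specificity_class0: float
    auc: float | None = None
    press_q: float | None = None
    chi2_crit: float | None = None
    reject_h0: bool | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn

    @property
    def confusion(self) -> np.ndarray:
        """2x2 matrix, rows = true class (0, 1), columns = predicted class."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def _check_pair(y: np.ndarray, p_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y).ravel()
    p_hat = np.asarray(p_hat, dtype=float).ravel()
    if y.size != p_hat.size:
        raise ValidationError(f"{y.size} responses but {p_hat.size} scores")
    if not np.all(np.isin(np.unique(y), (0, 1))):
        raise ValidationError("response must be coded 0/1")
    return y.astype(int), p_hat


def confusion_metrics(
    y: np.ndarray, p_hat: np.ndarray, cutoff: float = 0.5
) -> ClassificationReport:
    """Classify at ``p_hat >= cutoff`` and compute accuracy and per-class rates."""
    if not 0.0 < cutoff < 1.0:
        raise ValidationError(f"cutoff must lie in (0, 1), got {cutoff}")
    y, p_hat = _check_pair(y, p_hat)
    pred = (p_hat >= cutoff).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    n = y.size
    n1, n0 = tp + fn, tn + fp

    notes = []
    sens = tp / n1 if n1 else float("nan")
    spec = tn / n0 if n0 else float("nan")
    if n1 == 0:
        notes.append("no class-1 observations: sensitivity undefined")
    if n0 == 0:
        notes.append("no class-0 observations: specificity undefined")

    return ClassificationReport(
        n=n,
        cutoff=cutoff,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        sensitivity_class0=spec,
        specificity_class0=sens,
        notes=notes,
    )


def auc_mann_whitney(y: np.ndarray, p_hat: np.ndarray) -> float:
    """P(score of random positive > score of random negative), ties count 1/2.

    Computed from midranks: AUC = (R1 - n1(n1+1)/2) / (n1 n0) where R1 is the
    rank sum of the positive class.
    """
    y, p_hat = _check_pair(y, p_hat)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("AUC undefined: response contains a single class")
    ranks = rankdata(p_hat)  # midranks for ties
    r1 = float(np.sum(ranks[y == 1]))
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def press_q(n: int, n_correct: int, k_groups: int = 2) -> float:
    """Press's Q = (n - n_correct * k)^2 / (n (k - 1)).

    Referenced against the chi-square distribution with 1 degree of freedom;
    Q above the critical value means classification beats chance.
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if not 0 <= n_correct <= n:
        raise ValidationError(f"need 0 <= n_correct <= n, got n_correct={n_correct}, n={n}")
    if k_groups < 2:
        raise ValidationError(f"k_groups must be >= 2, got {k_groups}")
    return (n - n_correct * k_groups) ** 2 / (n * (k_groups - 1))


def chi_square_critical(alpha: float = 0.05, df: int = 1) -> float:
    """(1 - alpha) quantile of the chi-square distribution with ``df`` dof."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    return float(chi2.ppf(1.0 - alpha, df))


def evaluate_fit(
    y: np.ndarray, p_hat: np.ndarray, cutoff: float = 0.5, alpha: float = 0.05
) -> ClassificationReport:
    """Full per-model report: confusion metrics, AUC, Press's Q, decision flag."""
    report = confusion_metrics(y, p_hat, cutoff=cutoff)
    try:
        report.auc = auc_mann_whitney(y, p_hat)
    except UndefinedAUCError:
        report.auc = float("nan")
        report.notes.append("single-class response: AUC undefined")
    report.press_q = press_q(report.n, report.n_correct, 2)
    report.chi2_crit = chi_square_critical(alpha, df=1)
    report.reject_h0 = report.press_q > report.chi2_crit
    return report


def compare_models(
    fits: list[FitResult], y: np.ndarray, cutoff: float = 0.5
) -> dict:
    """Tabulate deviance, AIC and classification metrics across fitted models.

    Flags the smallest-deviance and largest-AUC models; exact ties are listed
    together and marked.
    """
    if not fits:
        raise ValidationError("compare_models needs at least one fitted model")
    y = np.asarray(y).ravel()
    rows = []
    for idx, fit in enumerate(fits):
        if fit.fitted_probs.size != y.size:
            raise ValidationError(
                f"fit {idx} has {fit.fitted_probs.size} fitted values for {y.size} responses"
            )
        report = evaluate_fit(y, fit.fitted_probs, cutoff=cutoff)
        rows.append(
            {
                "model": fit.label if fit.label else f"model{idx}",
                "combo": ",".join(map(str, fit.combo.ks)) if fit.combo else "",
                "deviance": fit.deviance,
                "aic": fit.aic,
                "converged": fit.converged,
                "report": report,
            }
        )
    deviances = np.array([r["deviance"] for r in rows])
    aucs = np.array([r["report"].auc for r in rows])
    best_dev = float(np.min(deviances))
    best_auc = float(np.nanmax(aucs))
    for r in rows:
        r["best_deviance"] = bool(np.isclose(r["deviance"], best_dev))
        r["best_auc"] = bool(np.isclose(r["report"].auc, best_auc, equal_nan=False))
    ties = {
        "deviance": int(np.sum(np.isclose(deviances, best_dev))) > 1,
        "auc": int(np.sum(np.isclose(aucs, best_auc))) > 1,
    }
    return {"rows": rows, "ties": ties, "cutoff": cutoff}


def grouped_proportions(
    x: np.ndarray, y: np.ndarray, n_bins: int
) -> list[tuple[float, float, int]]:
    """Equal-width binning of x with per-bin empirical success proportion.

    Returns (bin midpoint, proportion of ones, count) per bin; empty bins get
    count 0 and NaN proportion.  Constant x collapses to a single bin with a
    warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValidationError(f"{x.size} x values but {y.size} responses")
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        if n_bins > 1:
            warnings.warn(
                "constant x: falling back to a single bin", UserWarning, stacklevel=2
            )
        return [(lo, float(np.mean(y)), int(x.size))]
    edges = np.linspace(lo, hi, n_bins + 1)
    # right-closed last bin so the maximum lands in the final bin
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        mask = idx == b
        mid = 0.5 * (edges[b] + edges[b + 1])
        count = int(np.sum(mask))
        prop = float(np.mean(y[mask])) if count else float("nan")
        out.append((mid, prop, count))
    return out
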