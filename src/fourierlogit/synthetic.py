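"""Seeded generators for binary data with linear-plus-cosine logit structure.

Stands in for real applications: predictors are drawn independently uniform
over configurable ranges, the true logit is built through the same design
machinery used for fitting, and responses are Bernoulli draws from the implied
probabilities.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import (
    OscillationCombo,
    PredictorMatrix,
    ValidationError,
    build_design,
    inverse_logit,
    linear_predictor,
)
from .estimation import CoefficientSet

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "make_fixture_suite"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    n: int
    true_combo: OscillationCombo
    true_beta: CoefficientSet
    x_ranges: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        p = self.true_combo.p
        if self.true_beta.combo.ks != self.true_combo.ks:
            raise ValidationError(
                f"true_beta shaped for combo {self.true_beta.combo.ks}, "
                f"spec says {self.true_combo.ks}"
            )
        ranges = self.x_ranges or tuple((0.0, 2.0 * np.pi) for _ in range(p))
        ranges = tuple((float(lo), float(hi)) for lo, hi in ranges)
        if len(ranges) != p:
            raise ValidationError(f"{len(ranges)} ranges for p={p} predictors")
        for j, (lo, hi) in enumerate(ranges):
            if not lo < hi:
                raise ValidationError(f"range for predictor {j} must have low < high, got ({lo}, {hi})")
        object.__setattr__(self, "x_ranges", ranges)

    @property
    def p(self) -> int:
        return self.true_combo.p


@dataclass(frozen=True)
class SyntheticDataset:
    X: PredictorMatrix
    y: np.ndarray
    true_probs: np.ndarray
    spec: SyntheticSpec

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X.values, columns=list(self.X.names))
        df["y"] = self.y
        return df


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw predictors uniform over their ranges, then y ~ Bernoulli(pi(x))."""
    rng = np.random.default_rng(spec.seed)
    lows = np.array([lo for lo, _ in spec.x_ranges])
    highs = np.array([hi for _, hi in spec.x_ranges])
    X = PredictorMatrix(rng.uniform(lows, highs, size=(spec.n, spec.p)))
    Z = build_design(X, spec.true_combo)
    eta = linear_predictor(Z, spec.true_beta.to_flat())
    probs = inverse_logit(eta)
    y = rng.binomial(1, probs)
    return SyntheticDataset(X=X, y=y, true_probs=probs, spec=spec)


def _fixture_specs() -> dict[str, SyntheticSpec]:
    """Four canonical regimes used across the test-suite and CLI demos."""
    return {
        "null": SyntheticSpec(
            n=400,
            true_combo=OscillationCombo((0, 0)),
            true_beta=CoefficientSet(0.0, np.zeros(2), (np.zeros(0), np.zeros(0))),
            seed=101,
        ),
        "linear_only": SyntheticSpec(
            n=400,
            true_combo=OscillationCombo((0, 0)),
            true_beta=CoefficientSet(1.0, np.array([0.8, -0.5]), (np.zeros(0), np.zeros(0))),
            seed=102,
        ),
        "cosine_dominant": SyntheticSpec(
            n=600,
            true_combo=OscillationCombo((2, 1)),
            true_beta=CoefficientSet(
                0.5,
                np.array([0.3, -0.2]),
                (np.array([2.0, -1.5]), np.array([1.8])),
            ),
            seed=103,
        ),
        "near_separated": SyntheticSpec(
            n=120,
            true_combo=OscillationCombo((0,)),
            true_beta=CoefficientSet(0.0, np.array([8.0]), (np.zeros(0),)),
            x_ranges=((-2.0, 2.0),),
            seed=104,
        ),
    }


def make_fixture_suite(out_dir: str | Path) -> dict:
    """Write the four canonical fixture CSVs plus a JSON manifest of truths.

    Returns the manifest; files are ``<name>.csv`` and ``manifest.json`` under
    ``out_dir``.  Re-running with the same seeds reproduces identical bytes.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write fixtures to {out_dir}: {exc}") from exc

    manifest: dict = {"fixtures": {}}
    for name, spec in _fixture_specs().items():
        ds = generate_dataset(spec)
        path = out_dir / f"{name}.csv"
        # default float repr is shortest-round-trip: re-reading is lossless
        ds.to_frame().to_csv(path, index=False)
        manifest["fixtures"][name] = {
            "path": path.name,
            "n": spec.n,
            "p": spec.p,
            "seed": spec.seed,
            "true_combo": list(spec.true_combo.ks),
            "true_beta": {
                "a0": spec.true_beta.a0,
                "b": spec.true_beta.b.tolist(),
                "a": [aj.tolist() for aj in spec.true_beta.a],
            },
            "x_ranges": [list(r) for r in spec.x_ranges],
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
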