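"""CSV reading/validation, run configuration, and report serialization."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import PredictorMatrix, ValidationError

__all__ = ["RunConfig", "read_dataset", "write_report", "report_to_json"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; mirrors the CLI flags one-to-one."""

    input: str
    response: str = "y"
    predictors: list[str] | None = None
    combo: list[int] | None = None
    k_max: int = 4
    cutoff: float = 0.5
    rescale: bool = False
    eps: float = 1e-6
    max_iter: int = 100
    seed: int = 0
    output: str | None = None
    greedy: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValidationError(f"eps must be positive, got {self.eps}")
        if self.k_max < 1:
            raise ValidationError(f"k_max must be >= 1, got {self.k_max}")
        if not 0.0 < self.cutoff < 1.0:
            raise ValidationError(f"cutoff must lie in (0, 1), got {self.cutoff}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)} - {"extras"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extras = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extras=extras)


def read_dataset(
    path: str | Path,
    response_name: str = "y",
    predictor_names: list[str] | None = None,
) -> tuple[PredictorMatrix, np.ndarray]:
    """Read a headed CSV into a predictor block and a strictly-0/1 response.

    Predictors default to every non-response column.  Missing cells and
    non-binary response codes are rejected with row-level detail — downstream
    fitting assumes complete numeric data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if response_name not in df.columns:
        raise ValidationError(
            f"response column '{response_name}' not in file (columns: {list(df.columns)})"
        )
    if predictor_names is None:
        predictor_names = [c for c in df.columns if c != response_name]
    else:
        unknown = [c for c in predictor_names if c not in df.columns]
        if unknown:
            raise ValidationError(f"unknown predictor column(s): {unknown}")
    if not predictor_names:
        raise ValidationError("no predictor columns found")

    use = df[predictor_names + [response_name]]
    na_rows = use.index[use.isna().any(axis=1)].tolist()
    if na_rows:
        raise ValidationError(f"missing values in rows (0-based): {na_rows}")

    y_raw = df[response_name].to_numpy()
    bad = ~np.isin(y_raw, (0, 1))
    if bad.any():
        rows = np.flatnonzero(bad).tolist()
        raise ValidationError(
            f"response column '{response_name}' must be coded 0/1; "
            f"offending rows (0-based): {rows}"
        )
    try:
        values = df[predictor_names].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric predictor values: {exc}") from exc

    return PredictorMatrix(values, tuple(predictor_names)), y_raw.astype(int)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, NaN -> null)."""
    return json.dumps(_jsonify(report), indent=2, sort_keys=True)


def write_report(report: dict, path: str | Path | None) -> str:
    text = report_to_json(report)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
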