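# fourierlogit

Nonparametric logistic regression with a Fourier-series (cosine-harmonic)
basis for binary responses. Each predictor contributes a linear trend plus
`K_j` cosine harmonics to the logit; the model is fitted by maximum
likelihood with analytic score and Hessian via damped Newton–Raphson, the
per-predictor harmonic counts are chosen by exhaustive minimum-AIC search,
and fitted models are compared to a plain binary-logistic baseline on
deviance, confusion metrics, Mann–Whitney AUC and Press's Q.

The linear predictor for observation *i* is

```
eta_i = (1/2) a0 + sum_j [ b_j x_ji + sum_{k=1..K_j} a_kj cos(k x_ji) ]
```

and `P(y_i = 1) = exp(eta_i) / (1 + exp(eta_i))`.

## Library quick start

```python
import numpy as np
from fourierlogit import (
    fit_fourier_logit, fit_binary_logistic, select_oscillation, compare_models,
)

X = np.random.default_rng(0).uniform(0, 2 * np.pi, size=(500, 2))
eta = 0.5 + 2.0 * np.cos(X[:, 0]) - 1.5 * np.cos(2 * X[:, 0]) + 1.8 * np.cos(X[:, 1])
y = np.random.default_rng(1).binomial(1, 1 / (1 + np.exp(-eta)))

table = select_oscillation(X, y, k_max=4)      # exhaustive AIC grid search
fit = table.best_fit                           # FitResult with deviance/AIC/trace
baseline = fit_binary_logistic(X, y)
report = compare_models([fit, baseline], y)    # deviance, AUC, Press's Q, ...
```

Synthetic data with a known linear-plus-cosine truth comes from
`fourierlogit.synthetic`:

```python
from fourierlogit import SyntheticSpec, OscillationCombo, CoefficientSet, generate_dataset

spec = SyntheticSpec(
    n=2000,
    true_combo=OscillationCombo((2, 1)),
    true_beta=CoefficientSet(0.5, np.array([0.3, -0.2]),
                             (np.array([2.0, -1.5]), np.array([1.8]))),
    seed=7,
)
ds = generate_dataset(spec)   # ds.X, ds.y, ds.true_probs
```

## Command line

```bash
# fit one model at a fixed harmonic combination
fourierlogit fit --input data.csv --response y --combo 3,2,1,1,1,1 --output fit.json

# minimum-AIC search over combinations with K_j in 1..4
fourierlogit select --input data.csv --response y --k-max 4

# full pipeline: selection, best model vs logistic baseline, classification report
fourierlogit evaluate --input data.csv --response y --k-max 4 --cutoff 0.5 --output report.json

# seeded synthetic data (YAML spec) or the canonical four-fixture suite
fourierlogit simulate --spec spec.yaml --out synthetic.csv
fourierlogit simulate --fixtures --out fixtures/
```

Input is headed CSV with a strictly 0/1 response column; predictors default
to every other column. Reports are deterministic JSON (no timestamps in the
payload); progress and warnings go to stderr. `--rescale` maps each
predictor affinely to `[0, pi]` before the cosines are taken (off by
default: cosines act on raw values).

## Layout

- `src/fourierlogit/basis.py` — design-matrix construction, inverse logit
- `src/fourierlogit/estimation.py` — log-likelihood, score, Hessian, Newton–Raphson, logistic baseline
- `src/fourierlogit/selection.py` — AIC grid search (plus a greedy shortcut)
- `src/fourierlogit/evaluation.py` — deviance/AIC comparison, confusion metrics, AUC, Press's Q, grouped proportions
- `src/fourierlogit/synthetic.py` — seeded generators and the fixture suite
- `src/fourierlogit/io.py`, `cli.py` — CSV validation, config, reports, CLI
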