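"""Hyper-parameter search: exhaustive grids and Bayesian optimisation.

Grid search serves the forest and SVM families; the neural families use a
Gaussian-process Bayesian optimiser (Matern-5/2 surrogate, expected
improvement acquisition) over mixed continuous / integer / categorical
spaces.  Both searchers maximise the objective and are deterministic for a
fixed seed.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


def grid_search(space: dict[str, list], objective, seed: int = 0):
    """Evaluate every combination of a finite space; return (best_params,
    results table).

    Ties are broken deterministically: parameter names are iterated in
    sorted order and each parameter's values in their given order, and the
    first combination attaining the maximum wins — so the result does not
    depend on dict insertion order.
    """
    if not space:
        raise ValueError("empty search space")
    for name, values in space.items():
        if not isinstance(values, (list, tuple)) or not values:
            raise ValueError(f"grid parameter {name!r} needs a non-empty value list")
    names = sorted(space)
    rows = []
    best_params, best_value = None, -math.inf
    for combo in itertools.product(*(space[n] for n in names)):
        params = dict(zip(names, combo))
        value = float(objective(params))
        rows.append({**params, "objective": value})
        if value > best_value:
            best_params, best_value = params, value
    table = pd.DataFrame(rows)
    table["rank"] = table["objective"].rank(ascending=False, method="min").astype(int)
    return best_params, table


class SearchSpace:
    """Mixed parameter space for the Bayesian optimiser.

    Each entry is ``("uniform", lo, hi)``, ``("loguniform", lo, hi)``,
    ``("int", lo, hi)`` or ``("choice", [values...])``.
    """

    def __init__(self, params: dict[str, tuple]):
        if not params:
            raise ValueError("empty search space")
        self.params = params
        for name, schema in params.items():
            kind = schema[0]
            if kind in ("uniform", "loguniform", "int"):
                lo, hi = schema[1], schema[2]
                if not lo < hi:
                    raise ValueError(f"{name!r}: range must satisfy lo < hi")
                if kind == "loguniform" and lo <= 0:
                    raise ValueError(f"{name!r}: loguniform needs lo > 0")
            elif kind == "choice":
                if not schema[1]:
                    raise ValueError(f"{name!r}: empty choice list")
            else:
                raise ValueError(f"{name!r}: unknown schema kind {kind!r}")

    @property
    def names(self) -> list[str]:
        return sorted(self.params)

    def sample_unit(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.random((n, len(self.names)))

    def decode(self, unit_row: np.ndarray) -> dict:
        out = {}
        for u, name in zip(unit_row, self.names):
            kind, *rest = self.params[name]
            if kind == "uniform":
                lo, hi = rest
                out[name] = lo + u * (hi - lo)
            elif kind == "loguniform":
                lo, hi = rest
                out[name] = float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
            elif kind == "int":
                lo, hi = rest
                out[name] = int(min(hi, lo + math.floor(u * (hi - lo + 1))))
            else:  # choice
                values = rest[0]
                out[name] = values[int(min(len(values) - 1, math.floor(u * len(values))))]
        return out


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def bayesian_optimize(
    space: SearchSpace | dict,
    objective,
    budget: int = 50,
    seed: int = 0,
    n_init: int | None = None,
    n_candidates: int = 256,
):
    """Maximise ``objective(params)`` within ``budget`` evaluations.

    The first ``n_init`` points (default: min(10, budget)) are random; each
    later point maximises expected improvement under a Gaussian-process
    surrogate over ``n_candidates`` random candidates.  Returns
    (best_params, history table).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if isinstance(space, dict):
        space = SearchSpace(space)
    rng = np.random.default_rng(seed)
    n_init = min(budget, 10 if n_init is None else n_init)

    X_unit: list[np.ndarray] = []
    values: list[float] = []
    rows: list[dict] = []

    def evaluate(u: np.ndarray) -> None:
        params = space.decode(u)
        value = float(objective(params))
        X_unit.append(u)
        values.append(value)
        rows.append({**params, "objective": value, "trial": len(values) - 1})

    for u in space.sample_unit(rng, n_init):
        evaluate(u)

    while len(values) < budget:
        X = np.vstack(X_unit)
        y = np.asarray(values)
        y_mean, y_std = y.mean(), y.std() or 1.0
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * Matern(length_scale=0.25, nu=2.5)
            + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1)),
            normalize_y=False,
            random_state=seed,
        )
        gp.fit(X, (y - y_mean) / y_std)
        candidates = space.sample_unit(rng, n_candidates)
        mu, sigma = gp.predict(candidates, return_std=True)
        ei = _expected_improvement(mu, sigma, (y.max() - y_mean) / y_std)
        evaluate(candidates[int(np.argmax(ei))])

    history = pd.DataFrame(rows)
    best_idx = int(np.argmax(values))
    best_params = space.decode(X_unit[best_idx])
    return best_params, history


DEFAULT_RF_GRID = {"n_trees": [100, 220, 340, 460, 580, 700]}
DEFAULT_SVM_GRID = {
    "C": [0.1, 1.0, 10.0],
    "gamma": [0.001, 0.01, 0.1, "scale"],
}
# ten tunables mirroring the neural search dimensionality: window length,
# embedding width, recurrent units, dense width, conv filters, kernel size,
# dropout, batch size, epochs, learning rate
DEFAULT_NEURAL_SPACE = {
    "L": ("choice", [27, 29, 31, 33, 35]),
    "embedding_dim": ("int", 2, 8),
    "lstm_units": ("choice", [16, 32, 64]),
    "dense_units": ("choice", [8, 16, 32]),
    "filters": ("int", 8, 32),
    "kernel_size": ("choice", [5, 7, 9, 11]),
    "dropout": ("uniform", 0.0, 0.6),
    "batch_size": ("choice", [128, 256, 512]),
    "max_epochs": ("int", 50, 500),
    "learning_rate": ("loguniform", 1e-4, 1e-2),
}


def cv_objective(build_spec, cv_groups, seed: int = 0, n_inner: int = 3):
    """Objective factory: mean AUC of an inner cross-validation.

    ``build_spec(params)`` must return a ModelSpec; the inner CV uses the
    first ``n_inner`` groups as folds to keep search affordable and leaves
    any outer test data untouched.
    """
    from .evaluation import kfold_cv

    groups = cv_groups[:n_inner] if n_inner else cv_groups

    def objective(params: dict) -> float:
        spec = build_spec(params)
        report = kfold_cv(spec, groups, seed=seed)
        return float(report.per_fold["AUC"].mean())

    return objective


def write_trial_log(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
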