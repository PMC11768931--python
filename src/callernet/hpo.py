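"""Bayesian hyperparameter optimization: GP surrogate + expected improvement.

The search space covers the three tuned hyperparameters — learning rate
(log-uniform), dropout probability (uniform) and convolution kernel size
(odd-integer choices). Continuous dimensions are normalized to [0, 1]
(log10 scale for the learning rate); kernel sizes map to an index scale. The
surrogate is a Gaussian process with a Matern-5/2 kernel and observation
jitter; the acquisition is expected improvement maximized over a seeded
candidate set (kernel sizes enumerated, continuous dims sampled).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .audio import ValidationError


@dataclass(frozen=True)
class SearchSpace:
    learning_rate: tuple[float, float] = (1e-4, 1e-2)
    dropout_p: tuple[float, float] = (0.0, 0.5)
    kernel_size: tuple[int, ...] = (3, 5, 7, 9)

    def validate(self) -> None:
        for lo, hi in (self.learning_rate, self.dropout_p):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValidationError("interval bounds must be finite with low < high")
        if self.learning_rate[0] <= 0:
            raise ValidationError("learning rate bounds must be positive")
        if not self.kernel_size or any(k < 3 or k % 2 == 0 for k in self.kernel_size):
            raise ValidationError("kernel sizes must be odd integers >= 3")

    # -- normalized coordinates ------------------------------------------
    def to_unit(self, params: dict) -> np.ndarray:
        l0, l1 = np.log10(self.learning_rate)
        d0, d1 = self.dropout_p
        k_idx = self.kernel_size.index(int(params["kernel_size"]))
        denom = max(len(self.kernel_size) - 1, 1)
        return np.array([
            (np.log10(params["learning_rate"]) - l0) / (l1 - l0),
            (params["dropout_p"] - d0) / (d1 - d0),
            k_idx / denom,
        ])

    def from_unit(self, z: np.ndarray) -> dict:
        l0, l1 = np.log10(self.learning_rate)
        d0, d1 = self.dropout_p
        k_idx = int(round(z[2] * max(len(self.kernel_size) - 1, 1)))
        return {
            "learning_rate": float(10.0 ** (l0 + z[0] * (l1 - l0))),
            "dropout_p": float(d0 + z[1] * (d1 - d0)),
            "kernel_size": int(self.kernel_size[min(k_idx, len(self.kernel_size) - 1)]),
        }

    def contains(self, params: dict) -> bool:
        return (self.learning_rate[0] <= params["learning_rate"] <= self.learning_rate[1]
                and self.dropout_p[0] <= params["dropout_p"] <= self.dropout_p[1]
                and int(params["kernel_size"]) in self.kernel_size)


@dataclass
class Trial:
    params: dict
    objective_value: float | None
    status: str = "completed"  # completed | failed

    def validate(self) -> None:
        if self.status == "completed" and not (
                self.objective_value is not None and np.isfinite(self.objective_value)):
            raise ValidationError("completed trials need a finite objective value")

    def to_json(self) -> str:
        return json.dumps({"params": self.params, "objective_value": self.objective_value,
                           "status": self.status})


def expected_improvement(mu, sigma, best_so_far) -> np.ndarray | float:
    """EI for maximization: (mu-best)*Phi(z) + sigma*phi(z), z=(mu-best)/sigma.

    At sigma == 0 this degenerates to max(mu - best, 0). Always >= 0.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValidationError("sigma must be non-negative")
    improve = mu - best_so_far
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, improve / np.where(sigma > 0, sigma, 1.0), 0.0)
        ei = np.where(sigma > 0,
                      improve * norm.cdf(z) + sigma * norm.pdf(z),
                      np.maximum(improve, 0.0))
    ei = np.maximum(ei, 0.0)
    return float(ei) if ei.ndim == 0 else ei


def _quasi_random_unit(n: int, seed: int) -> np.ndarray:
    sampler = qmc.Sobol(d=3, scramble=True, seed=seed)
    with warnings.catch_warnings():
        # Sobol balance only holds at powers of two; irrelevant for seeding
        warnings.simplefilter("ignore", UserWarning)
        return sampler.random(n)


def _fit_gp(X: np.ndarray, y: np.ndarray, seed: int) -> GaussianProcessRegressor:
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(X.shape[1], 0.3), length_scale_bounds=(1e-2, 1e1), nu=2.5)
    gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6, normalize_y=True,
                                  n_restarts_optimizer=1, random_state=seed)
    with warnings.catch_warnings():
        # near-duplicate points make the marginal-likelihood surface flat;
        # an early lbfgs stop is fine for an acquisition surrogate
        warnings.simplefilter("ignore")
        gp.fit(X, y)
    return gp


def suggest(history: list[Trial], space: SearchSpace, seed: int,
            n_init: int = 5, n_candidates: int = 256) -> dict:
    """Next point to evaluate; deterministic given (history, seed).

    Fewer than ``n_init`` completed trials: quasi-random draw. Otherwise fit
    the GP on completed trials and return the EI argmax over a seeded
    candidate set with every kernel-size choice enumerated.
    """
    space.validate()
    completed = [t for t in history if t.status == "completed"]
    if len(completed) < n_init:
        z = _quasi_random_unit(len(history) + 1, seed)[-1]
        return space.from_unit(z)

    X = np.array([space.to_unit(t.params) for t in completed])
    y = np.array([t.objective_value for t in completed], dtype=float)
    gp = _fit_gp(X, y, seed)

    rng = np.random.default_rng(seed)
    n_k = len(space.kernel_size)
    per_k = max(n_candidates // n_k, 1)
    cand = rng.random((per_k * n_k, 3))
    denom = max(n_k - 1, 1)
    cand[:, 2] = np.repeat(np.arange(n_k) / denom, per_k)
    mu, sigma = gp.predict(cand, return_std=True)
    ei = expected_improvement(mu, sigma, float(y.max()))
    return space.from_unit(cand[int(np.argmax(ei))])


def run_hpo(objective_fn: Callable[[dict], float], space: SearchSpace,
            n_init: int = 5, n_iter: int = 15, seed: int = 0) -> tuple[Trial, list[Trial]]:
    """Random initialization then EI-guided evaluations; returns (best, history).

    Failed evaluations (objective raised) are recorded as failed trials and do
    not abort the search; if every trial fails the search itself errors.
    """
    space.validate()
    if n_init < 2 or n_iter < 0:
        raise ValidationError("need n_init >= 2 and n_iter >= 0")
    history: list[Trial] = []
    init_points = _quasi_random_unit(n_init, seed)
    for i in range(n_init + n_iter):
        if i < n_init:
            params = space.from_unit(init_points[i])
        else:
            params = suggest(history, space, seed=seed + i, n_init=n_init)
        try:
            value = float(objective_fn(params))
            trial = Trial(params=params, objective_value=value, status="completed")
        except Exception:  # noqa: BLE001 - a failed trial is data, not fatal
            trial = Trial(params=params, objective_value=None, status="failed")
        history.append(trial)
    completed = [t for t in history if t.status == "completed"]
    if not completed:
        raise RuntimeError(f"all {len(history)} trials failed")
    best = max(completed, key=lambda t: t.objective_value)
    return best, history


def random_search(objective_fn: Callable[[dict], float], space: SearchSpace,
                  n_evals: int, seed: int = 0) -> tuple[Trial, list[Trial]]:
    """Pure random-search baseline with the same evaluation budget."""
    space.validate()
    rng = np.random.default_rng(seed)
    history = []
    for _ in range(n_evals):
        params = space.from_unit(rng.random(3))
        try:
            value = float(objective_fn(params))
            history.append(Trial(params, value, "completed"))
        except Exception:  # noqa: BLE001
            history.append(Trial(params, None, "failed"))
    completed = [t for t in history if t.status == "completed"]
    if not completed:
        raise RuntimeError("all random-search trials failed")
    return max(completed, key=lambda t: t.objective_value), history
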