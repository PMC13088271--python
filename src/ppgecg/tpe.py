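"""A compact, seeded tree-structured Parzen estimator (TPE) for
hyperparameter search over box-constrained spaces.

Observations are split at the gamma-quantile of the objective into a "good"
and a "bad" set; each set induces a one-dimensional Parzen (Gaussian-mixture)
density per parameter, with a flat prior component for exploration.
Candidates are drawn from the good density and ranked by the density ratio
l(x)/g(x); the factorized product over parameters selects the next trial.
Log-scaled and integer parameters are handled in their transformed space.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["ParamSpec", "TPEOptimizer", "minimize"]


@dataclass(frozen=True)
class ParamSpec:
    """One search dimension: kind in {uniform, loguniform, int, intlog}."""

    name: str
    kind: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "loguniform", "int", "intlog"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if not self.low < self.high:
            raise ValueError(f"{self.name}: need low < high")
        if self.kind in ("loguniform", "intlog") and self.low <= 0:
            raise ValueError(f"{self.name}: log-scaled bounds must be positive")

    # Internal (transformed) coordinates.
    def _bounds(self) -> tuple[float, float]:
        if self.kind in ("loguniform", "intlog"):
            return math.log(self.low), math.log(self.high)
        return self.low, self.high

    def to_internal(self, v: float) -> float:
        return math.log(v) if self.kind in ("loguniform", "intlog") else float(v)

    def to_external(self, z: float):
        lo, hi = self._bounds()
        z = min(max(z, lo), hi)
        v = math.exp(z) if self.kind in ("loguniform", "intlog") else z
        if self.kind in ("int", "intlog"):
            return int(round(min(max(v, self.low), self.high)))
        return float(v)

    def sample_prior(self, rng: np.random.Generator):
        lo, hi = self._bounds()
        return self.to_external(rng.uniform(lo, hi))


def _parzen_logpdf(z: np.ndarray, obs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Log-density of a Parzen mixture over ``obs`` plus a uniform prior."""
    span = hi - lo
    # Scott-style bandwidth with a floor so the mixture never collapses.
    if obs.size > 1:
        bw = max(float(np.std(obs)) * obs.size ** (-0.2), span / (4.0 * obs.size))
    else:
        bw = span / 2.0
    sigma = np.full(obs.size, bw)
    k = obs.size + 1  # +1 for the uniform prior component
    z = np.atleast_1d(z)[:, None]
    comp = (
        -0.5 * ((z - obs[None, :]) / sigma[None, :]) ** 2
        - np.log(sigma[None, :] * math.sqrt(2 * math.pi))
    )
    prior = np.full((z.shape[0], 1), -math.log(span))
    allc = np.concatenate([comp, prior], axis=1) - math.log(k)
    m = allc.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(allc - m).sum(axis=1, keepdims=True))).ravel()


class TPEOptimizer:
    """Sequential minimizer; ask/tell interface, fully deterministic by seed."""

    def __init__(
        self,
        space: Sequence[ParamSpec],
        seed: int = 0,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ) -> None:
        self.space = list(space)
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.params_history: list[dict] = []
        self.losses: list[float] = []

    def ask(self) -> dict:
        if len(self.losses) < self.n_startup:
            return {s.name: s.sample_prior(self.rng) for s in self.space}
        losses = np.asarray(self.losses)
        order = np.argsort(losses, kind="stable")
        n_good = max(2, int(math.ceil(self.gamma * losses.size)))
        good_idx, bad_idx = order[:n_good], order[n_good:]
        out: dict = {}
        for s in self.space:
            lo, hi = s._bounds()
            vals = np.array(
                [s.to_internal(h[s.name]) for h in self.params_history]
            )
            good, bad = vals[good_idx], vals[bad_idx]
            # Candidates from the good mixture (or prior as fallback).
            pick = self.rng.integers(0, good.size + 1, size=self.n_candidates)
            span = hi - lo
            width = max(span / (2.0 * good.size), 1e-12)
            cand = np.where(
                pick < good.size,
                good[np.minimum(pick, good.size - 1)]
                + self.rng.normal(0, width, self.n_candidates),
                self.rng.uniform(lo, hi, self.n_candidates),
            )
            cand = np.clip(cand, lo, hi)
            score = _parzen_logpdf(cand, good, lo, hi) - _parzen_logpdf(
                cand, bad, lo, hi
            )
            out[s.name] = s.to_external(float(cand[int(np.argmax(score))]))
        return out

    def tell(self, params: dict, loss: float) -> None:
        self.params_history.append(dict(params))
        self.losses.append(float(loss))

    @property
    def best(self) -> tuple[dict, float]:
        i = int(np.argmin(self.losses))
        return self.params_history[i], self.losses[i]


def minimize(
    objective: Callable[[dict], float],
    space: Sequence[ParamSpec],
    n_trials: int,
    seed: int = 0,
    **kwargs,
) -> tuple[dict, float, TPEOptimizer]:
    """Run ``n_trials`` sequential TPE evaluations of ``objective``."""
    opt = TPEOptimizer(space, seed=seed, **kwargs)
    for _ in range(n_trials):
        p = opt.ask()
        opt.tell(p, objective(p))
    best_params, best_loss = opt.best
    return best_params, best_loss, opt
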