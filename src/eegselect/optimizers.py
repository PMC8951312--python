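"""Binary flower pollination search with beta-hill-climbing refinement.

Three optimizers over binary channel masks share one machinery:

* **FPA** — population metaheuristic alternating global pollination
  (Levy-flight moves toward the global best, drawn with switch
  probability ``p``) and local pollination (moves along the difference of
  two random population members), with real-valued positions mapped to
  masks through a sigmoid transfer function.
* **beta-hc** — single-solution local search whose candidate is a
  single-bit flip (N-operator) followed by per-bit random resetting with
  probability ``beta`` (beta-operator), accepting non-worsening moves.
* **FPAbeta-hc** — the hybrid: every pollinated-and-binarized solution is
  refined by an inner beta-hc loop before it re-enters the population.

Fitness is any callable mapping a 0/1 mask to a percentage to maximize.
All randomness flows from one ``numpy`` generator seeded by the config,
so runs are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "OptimizerConfig",
    "RunHistory",
    "sigmoid",
    "binarize",
    "levy_step",
    "global_pollination",
    "local_pollination",
    "n_operator",
    "beta_operator",
    "bhc_refine",
    "fpa_bhc_optimize",
    "fpa_optimize",
    "bhc_optimize",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Search parameters.

    Defaults follow the reference setting: switch probability p = 0.8,
    population N = 64, T = 100 outer iterations, beta = 0.5.  ``D`` is the
    number of channels (solution dimension).  ``max_evals`` optionally
    caps the number of distinct fitness evaluations for matched-budget
    comparisons; ``None`` means no cap.
    """

    D: int = 16
    p: float = 0.8
    N: int = 64
    T: int = 100
    beta: float = 0.5
    bhc_inner_iters: int = 20
    levy_lambda: float = 1.5
    levy_scale: float = 0.01
    seed: int = 0
    max_evals: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("switch probability p must lie in [0, 1]")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must lie in [0, 1]")
        if self.N < 2 or self.D < 1 or self.T < 1:
            raise ValueError("need N >= 2, D >= 1, T >= 1")
        if not 1 < self.levy_lambda <= 2:
            raise ValueError("levy_lambda must lie in (1, 2]")


@dataclass
class RunHistory:
    """Trace of one optimizer run."""

    best_fitness_per_iter: np.ndarray
    best_mask: np.ndarray
    best_fitness: float
    evaluations: int
    selection_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


class _BudgetExhausted(Exception):
    pass


class _CountedFitness:
    """Memoizing wrapper that counts cache misses against a budget."""

    def __init__(self, fn, max_evals: int | None):
        self._fn = fn
        self._cache: dict[bytes, float] = {}
        self.max_evals = max_evals
        self.evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=np.int8).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if self.max_evals is not None and self.evaluations >= self.max_evals:
            raise _BudgetExhausted
        val = float(self._fn(mask))
        self.evaluations += 1
        self._cache[key] = val
        return val


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Logistic transfer function 1 / (1 + exp(-x))."""
    return expit(np.asarray(x, dtype=float))


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if mask.sum() == 0:
        mask[rng.integers(mask.size)] = 1
    return mask


def binarize(real_vec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map a real vector to a mask: bit i is 1 with probability sigmoid(x_i).

    An all-zero outcome is repaired by switching one uniformly random bit
    on, since an empty channel subset cannot be evaluated.
    """
    x = np.asarray(real_vec, dtype=float)
    mask = (sigmoid(x) > rng.uniform(size=x.size)).astype(np.int8)
    return _repair(mask, rng)


def levy_step(
    D: int, lam: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Heavy-tailed step vector via the Mantegna construction.

    Each component is ``scale * u / |v|**(1/lam)`` with
    ``u ~ N(0, sigma_u^2)``, ``v ~ N(0, 1)`` and ``sigma_u`` chosen so the
    steps follow a symmetric Levy-stable law with exponent ``lam``.
    """
    sigma_u = (
        math.gamma(1 + lam)
        * math.sin(math.pi * lam / 2)
        / (math.gamma((1 + lam) / 2) * lam * 2 ** ((lam - 1) / 2))
    ) ** (1 / lam)
    u = rng.normal(0.0, sigma_u, size=D)
    v = rng.normal(0.0, 1.0, size=D)
    return scale * u / np.abs(v) ** (1 / lam)


def global_pollination(
    sol: np.ndarray,
    gbest: np.ndarray,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Levy-flight move toward the global best: sol + L * (gbest - sol)."""
    L = levy_step(len(sol), cfg.levy_lambda, cfg.levy_scale, rng)
    return sol + L * (np.asarray(gbest) - np.asarray(sol))


def local_pollination(
    sol: np.ndarray,
    sol_j: np.ndarray,
    sol_k: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move along the difference of two population members: sol + eps*(j - k)."""
    eps = rng.uniform()
    return np.asarray(sol) + eps * (np.asarray(sol_j) - np.asarray(sol_k))


def n_operator(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Neighborhood operator: flip exactly one uniformly chosen bit."""
    out = np.asarray(mask, dtype=np.int8).copy()
    i = rng.integers(out.size)
    out[i] = 1 - out[i]
    return out


def beta_operator(
    mask: np.ndarray, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-bit random resetting: with probability beta replace a bit with
    a uniform random bit, otherwise keep it."""
    out = np.asarray(mask, dtype=np.int8).copy()
    reset = rng.uniform(size=out.size) < beta
    out[reset] = rng.integers(0, 2, size=int(reset.sum()), dtype=np.int8)
    return out


def bhc_refine(
    mask: np.ndarray,
    fitness_fn,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Inner beta-hill-climbing loop from ``mask``.

    For ``cfg.bhc_inner_iters`` iterations the candidate
    ``beta_operator(n_operator(current))`` replaces the current solution
    whenever its fitness is not worse (ties accepted, enabling neutral
    drift).  The returned fitness is therefore never below the input's.
    """
    cur = np.asarray(mask, dtype=np.int8).copy()
    f_cur = fitness_fn(cur)
    for _ in range(cfg.bhc_inner_iters):
        cand = beta_operator(n_operator(cur, rng), cfg.beta, rng)
        cand = _repair(cand, rng)
        f_cand = fitness_fn(cand)
        if f_cand >= f_cur:
            cur, f_cur = cand, f_cand
    return cur, f_cur


def _init_population(
    fit: _CountedFitness, cfg: OptimizerConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    real = rng.uniform(-1.0, 1.0, size=(cfg.N, cfg.D))
    masks = np.stack([binarize(real[i], rng) for i in range(cfg.N)])
    fits = np.array([fit(masks[i]) for i in range(cfg.N)])
    return real, masks, fits


def _finalize(
    best_per_iter: list[float],
    best_mask: np.ndarray,
    best_fit: float,
    fit: _CountedFitness,
    masks: np.ndarray,
) -> RunHistory:
    return RunHistory(
        best_fitness_per_iter=np.asarray(best_per_iter, dtype=float),
        best_mask=best_mask.copy(),
        best_fitness=float(best_fit),
        evaluations=fit.evaluations,
        selection_counts=np.asarray(masks, dtype=int).sum(axis=0),
    )


def _fpa_core(fitness_fn, cfg: OptimizerConfig, refine: bool) -> RunHistory:
    rng = np.random.default_rng(cfg.seed)
    fit = _CountedFitness(fitness_fn, cfg.max_evals)
    best_per_iter: list[float] = []
    try:
        real, masks, fits = _init_population(fit, cfg, rng)
    except _BudgetExhausted:
        raise ValueError("max_evals too small to initialize the population")
    b = int(np.argmax(fits))
    best_mask, best_fit = masks[b].copy(), float(fits[b])
    gbest_real = real[b].copy()

    try:
        for _ in range(cfg.T):
            for i in range(cfg.N):
                if rng.uniform() <= cfg.p:
                    new_real = global_pollination(real[i], gbest_real, cfg, rng)
                else:
                    j, k = rng.integers(cfg.N), rng.integers(cfg.N)
                    new_real = local_pollination(real[i], real[j], real[k], rng)
                new_mask = binarize(new_real, rng)
                if refine:
                    # the refined solution replaces the pollen outright
                    new_mask, new_fit = bhc_refine(new_mask, fit, cfg, rng)
                    real[i], masks[i], fits[i] = new_real, new_mask, new_fit
                else:
                    # plain FPA keeps a move only if it is not worse
                    new_fit = fit(new_mask)
                    if new_fit >= fits[i]:
                        real[i], masks[i], fits[i] = new_real, new_mask, new_fit
                if new_fit > best_fit:
                    best_mask, best_fit = new_mask.copy(), float(new_fit)
                    gbest_real = new_real.copy()
            best_per_iter.append(best_fit)
    except _BudgetExhausted:
        pass
    return _finalize(best_per_iter, best_mask, best_fit, fit, masks)


def fpa_bhc_optimize(fitness_fn, cfg: OptimizerConfig) -> RunHistory:
    """Hybrid search: FPA pollination with beta-hc refinement of every
    binarized solution before it replaces its pollen."""
    return _fpa_core(fitness_fn, cfg, refine=True)


def fpa_optimize(fitness_fn, cfg: OptimizerConfig) -> RunHistory:
    """Standard binary FPA (no local-search refinement)."""
    return _fpa_core(fitness_fn, cfg, refine=False)


def bhc_optimize(fitness_fn, cfg: OptimizerConfig) -> RunHistory:
    """Standalone beta-hill climbing from one random mask.

    Runs ``T`` outer iterations of ``N`` accept/reject steps each — an
    evaluation budget equivalent to one FPA run — and records the best
    fitness after each outer iteration.
    """
    rng = np.random.default_rng(cfg.seed)
    fit = _CountedFitness(fitness_fn, cfg.max_evals)
    cur = _repair(rng.integers(0, 2, size=cfg.D, dtype=np.int8), rng)
    try:
        f_cur = fit(cur)
    except _BudgetExhausted:
        raise ValueError("max_evals too small for the initial evaluation")
    best_mask, best_fit = cur.copy(), f_cur
    best_per_iter: list[float] = []
    try:
        for _ in range(cfg.T):
            for _ in range(cfg.N):
                cand = beta_operator(n_operator(cur, rng), cfg.beta, rng)
                cand = _repair(cand, rng)
                f_cand = fit(cand)
                if f_cand >= f_cur:
                    cur, f_cur = cand, f_cand
                if f_cur > best_fit:
                    best_mask, best_fit = cur.copy(), float(f_cur)
            best_per_iter.append(best_fit)
    except _BudgetExhausted:
        pass
    return _finalize(best_per_iter, best_mask, best_fit, fit, cur[None, :])
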