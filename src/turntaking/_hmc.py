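"""Adaptive Hamiltonian Monte Carlo for smooth log-densities.

A compact HMC sampler with dual-averaging step-size adaptation and
diagonal mass-matrix estimation during warmup, used by
:mod:`turntaking.models` for the hierarchical regression posteriors
(which are smooth and have analytic gradients).

Warmup is split in three phases: an initial step-size adaptation on the
unit metric, a variance-collection window whose sample variances become
the diagonal inverse mass, and a final step-size re-adaptation on the
new metric.  Trajectory lengths target ``path_length`` in parameter
space and are jittered uniformly to avoid resonance.  A proposal whose
energy error exceeds ``divergence_threshold`` is counted as a divergent
transition and rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCResult:
    draws: np.ndarray          # (n_chains, n_kept, dim)
    n_divergences: int
    accept_rate: float
    step_sizes: np.ndarray     # per chain


def _leapfrog(
    logp_grad: LogpGrad,
    x: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
):
    p = p + 0.5 * eps * grad
    for _ in range(n_steps - 1):
        x = x + eps * inv_mass * p
        lp, grad = logp_grad(x)
        p = p + eps * grad
    x = x + eps * inv_mass * p
    lp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _find_initial_step(
    logp_grad: LogpGrad,
    x: np.ndarray,
    rng: np.random.Generator,
    inv_mass: np.ndarray,
) -> float:
    eps = 0.1
    lp0, grad0 = logp_grad(x)
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p0**2)
    _, p1, lp1, _ = _leapfrog(logp_grad, x, p0, grad0, eps, 1, inv_mass)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2)
    ratio = h1 - h0
    direction = 1 if ratio > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, lp1, _ = _leapfrog(logp_grad, x, p0, grad0, eps, 1, inv_mass)
        if not np.isfinite(lp1):
            ratio = -np.inf
        else:
            h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2)
            ratio = h1 - h0
        if direction == 1 and ratio < np.log(0.5):
            break
        if direction == -1 and ratio > np.log(0.5):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target
    acceptance probability."""

    def __init__(self, eps0: float, target: float = 0.8):
        self.mu = np.log(10 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0
        self.gamma, self.t0, self.kappa = 0.05, 10, 0.75

    def update(self, accept_prob: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_chains: int = 4,
    n_iter: int = 4000,
    n_warmup: int = 1000,
    seed: int | None = None,
    target_accept: float = 0.8,
    path_length: float = 1.0,
    max_leapfrog: int = 64,
    divergence_threshold: float = 1000.0,
    init_jitter: float = 0.5,
) -> HMCResult:
    """Run ``n_chains`` HMC chains and keep ``n_iter - n_warmup`` draws
    per chain."""
    if n_warmup >= n_iter:
        raise ValueError("n_warmup must be < n_iter")
    dim = x0.size
    rng = np.random.default_rng(seed)
    n_kept = n_iter - n_warmup
    draws = np.empty((n_chains, n_kept, dim))
    total_div = 0
    accepts: list[float] = []
    step_sizes = np.empty(n_chains)

    w1 = max(1, n_warmup // 4)          # step adaptation, unit-ish metric
    w2 = max(1, n_warmup // 2)          # variance collection
    # remaining warmup: re-adaptation on the estimated metric

    for c in range(n_chains):
        crng = np.random.default_rng(rng.integers(2**31 - 1))
        x = x0 + init_jitter * crng.standard_normal(dim)
        inv_mass = np.ones(dim)
        lp, grad = logp_grad(x)
        eps = _find_initial_step(logp_grad, x, crng, inv_mass)
        da = _DualAveraging(eps, target_accept)
        var_buf: list[np.ndarray] = []

        for it in range(n_iter):
            p = crng.standard_normal(dim) / np.sqrt(inv_mass)
            h0 = lp - 0.5 * np.sum(inv_mass * p**2)
            n_steps = max(1, min(max_leapfrog, int(np.ceil(path_length / eps))))
            n_steps = crng.integers(max(1, n_steps // 2), n_steps + 1)
            x_new, p_new, lp_new, grad_new = _leapfrog(
                logp_grad, x, p, grad, eps, int(n_steps), inv_mass
            )
            if np.isfinite(lp_new):
                h1 = lp_new - 0.5 * np.sum(inv_mass * p_new**2)
                delta = h1 - h0
            else:
                delta = -np.inf
            divergent = (not np.isfinite(delta)) or (-delta > divergence_threshold)
            accept_prob = 0.0 if divergent else min(1.0, np.exp(min(0.0, delta)))
            if (not divergent) and crng.random() < accept_prob:
                x, lp, grad = x_new, lp_new, grad_new

            if it < n_warmup:
                eps = da.update(accept_prob)
                if w1 <= it < w1 + w2:
                    var_buf.append(x.copy())
                if it == w1 + w2 - 1 and len(var_buf) >= 10:
                    v = np.var(np.asarray(var_buf), axis=0)
                    inv_mass = np.clip(v, 1e-6, None)
                    eps = _find_initial_step(logp_grad, x, crng, inv_mass)
                    da = _DualAveraging(eps, target_accept)
                if it == n_warmup - 1:
                    eps = da.adapted
            else:
                if divergent:
                    total_div += 1
                accepts.append(accept_prob)
                draws[c, it - n_warmup] = x
        step_sizes[c] = eps

    return HMCResult(
        draws=draws,
        n_divergences=total_div,
        accept_rate=float(np.mean(accepts)) if accepts else 0.0,
        step_sizes=step_sizes,
    )
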