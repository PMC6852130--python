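"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained implementation of multinomial NUTS (dynamic Hamiltonian Monte
Carlo with a no-U-turn termination criterion), with the usual warmup schedule:
an initial step-size-only buffer, doubling windows that re-estimate a diagonal
mass matrix from warmup draws, and a terminal step-size buffer.  Draws after
warmup use the frozen step size and metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["sample_nuts", "NutsResult"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the energy error


@dataclass
class NutsResult:
    draws: np.ndarray          # (n_draws, dim) post-warmup positions
    logp: np.ndarray           # (n_draws,)
    diverging: np.ndarray      # (n_draws,) bool
    treedepth: np.ndarray      # (n_draws,) int
    accept_stat: np.ndarray    # (n_draws,)
    step_size: float = 0.0
    inv_mass: np.ndarray | None = None
    n_divergent_warmup: int = 0


class _Hamiltonian:
    def __init__(self, logp_grad: Callable, inv_mass: np.ndarray):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass

    def sample_momentum(self, rng: np.random.Generator, dim: int) -> np.ndarray:
        return rng.standard_normal(dim) / np.sqrt(self.inv_mass)

    def energy(self, logp: float, p: np.ndarray) -> float:
        return -logp + 0.5 * float(p**2 @ self.inv_mass)

    def leapfrog(self, q, p, grad, eps):
        p = p + 0.5 * eps * grad
        q = q + eps * self.inv_mass * p
        logp, grad = self.logp_grad(q)
        p = p + 0.5 * eps * grad
        return q, p, grad, logp


@dataclass(slots=True)
class _Tree:
    q_minus: np.ndarray
    p_minus: np.ndarray
    grad_minus: np.ndarray
    q_plus: np.ndarray
    p_plus: np.ndarray
    grad_plus: np.ndarray
    q_prop: np.ndarray
    grad_prop: np.ndarray
    logp_prop: float
    log_weight: float
    sum_accept: float
    n_states: int
    diverging: bool
    turning: bool


def _logaddexp(a: float, b: float) -> float:
    if a == -math.inf:
        return b
    if b == -math.inf:
        return a
    m = a if a > b else b
    return m + math.log(math.exp(a - m) + math.exp(b - m))


def _uturn(ham, q_minus, q_plus, p_minus, p_plus) -> bool:
    dq = q_plus - q_minus
    return (dq @ (ham.inv_mass * p_minus) < 0) or (dq @ (ham.inv_mass * p_plus) < 0)


def _build_tree(ham, rng, q, p, grad, logp, direction, depth, eps, H0) -> _Tree:
    if depth == 0:
        q1, p1, grad1, logp1 = ham.leapfrog(q, p, grad, direction * eps)
        H1 = ham.energy(logp1, p1)
        delta = H0 - H1  # log weight of the new state
        finite = math.isfinite(delta)
        diverging = not finite or (-delta) > _MAX_DELTA_H
        accept = min(1.0, math.exp(min(delta, 0.0))) if finite else 0.0
        lw = delta if finite else -math.inf
        return _Tree(q1, p1, grad1, q1, p1, grad1, q1, grad1, logp1, lw,
                     accept, 1, diverging, False)

    half = _build_tree(ham, rng, q, p, grad, logp, direction, depth - 1, eps, H0)
    if half.diverging or half.turning:
        return half
    if direction == 1:
        other = _build_tree(ham, rng, half.q_plus, half.p_plus, half.grad_plus,
                            0.0, direction, depth - 1, eps, H0)
        half.q_plus, half.p_plus, half.grad_plus = (
            other.q_plus, other.p_plus, other.grad_plus)
    else:
        other = _build_tree(ham, rng, half.q_minus, half.p_minus, half.grad_minus,
                            0.0, direction, depth - 1, eps, H0)
        half.q_minus, half.p_minus, half.grad_minus = (
            other.q_minus, other.p_minus, other.grad_minus)

    total_lw = _logaddexp(half.log_weight, other.log_weight)
    if other.log_weight > -math.inf and (
        -rng.exponential() < other.log_weight - total_lw
    ):
        half.q_prop, half.grad_prop, half.logp_prop = (
            other.q_prop, other.grad_prop, other.logp_prop)
    half.log_weight = total_lw
    half.sum_accept += other.sum_accept
    half.n_states += other.n_states
    half.diverging = other.diverging
    half.turning = other.turning or _uturn(
        ham, half.q_minus, half.q_plus, half.p_minus, half.p_plus
    )
    return half


def _nuts_step(ham, rng, q, logp, grad, eps, max_treedepth):
    dim = len(q)
    p0 = ham.sample_momentum(rng, dim)
    H0 = ham.energy(logp, p0)
    tree = _Tree(q, p0, grad, q, p0, grad, q, grad, logp, 0.0, 0.0, 0, False,
                 False)
    sum_accept, n_states = 0.0, 0
    diverging = False
    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(ham, rng, tree.q_plus, tree.p_plus, tree.grad_plus,
                              0.0, 1, depth, eps, H0)
            tree.q_plus, tree.p_plus, tree.grad_plus = (
                sub.q_plus, sub.p_plus, sub.grad_plus)
        else:
            sub = _build_tree(ham, rng, tree.q_minus, tree.p_minus, tree.grad_minus,
                              0.0, -1, depth, eps, H0)
            tree.q_minus, tree.p_minus, tree.grad_minus = (
                sub.q_minus, sub.p_minus, sub.grad_minus)
        sum_accept += sub.sum_accept
        n_states += sub.n_states
        if sub.diverging:
            diverging = True
            break
        if sub.turning:
            break
        # progressive multinomial sampling between old tree and new subtree
        if math.isfinite(sub.log_weight) and (
            -rng.exponential() < sub.log_weight - tree.log_weight
        ):
            tree.q_prop, tree.grad_prop, tree.logp_prop = (
                sub.q_prop, sub.grad_prop, sub.logp_prop)
        tree.log_weight = _logaddexp(tree.log_weight, sub.log_weight)
        if _uturn(ham, tree.q_minus, tree.q_plus, tree.p_minus, tree.p_plus):
            break
        depth += 1
    accept_stat = sum_accept / max(n_states, 1)
    return tree.q_prop, tree.logp_prop, tree.grad_prop, accept_stat, diverging, depth


def _find_initial_step(ham, rng, q, logp, grad) -> float:
    eps = 1.0
    p0 = ham.sample_momentum(rng, len(q))
    H0 = ham.energy(logp, p0)
    _, p1, _, logp1 = ham.leapfrog(q, p0, grad, eps)
    H1 = ham.energy(logp1, p1)
    delta = H0 - H1
    direction = 1 if (np.isfinite(delta) and delta > np.log(0.5)) else -1
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, _, logp1 = ham.leapfrog(q, p0, grad, eps)
        H1 = ham.energy(logp1, p1)
        delta = H0 - H1
        if not np.isfinite(delta):
            delta = -np.inf
        if direction == 1 and delta <= np.log(0.5):
            break
        if direction == -1 and delta >= np.log(0.5):
            break
    return eps


@dataclass
class _DualAveraging:
    mu: float
    target: float = 0.8
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    _count: int = 0
    _h_bar: float = 0.0
    _log_eps_bar: float = 0.0

    @classmethod
    def start(cls, eps0: float, target: float) -> "_DualAveraging":
        return cls(mu=float(np.log(10.0 * eps0)), target=target)

    def update(self, accept_stat: float) -> float:
        self._count += 1
        w = 1.0 / (self._count + self.t0)
        self._h_bar = (1 - w) * self._h_bar + w * (self.target - accept_stat)
        log_eps = self.mu - np.sqrt(self._count) / self.gamma * self._h_bar
        w2 = self._count ** (-self.kappa)
        self._log_eps_bar = w2 * log_eps + (1 - w2) * self._log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self._log_eps_bar))


def _warmup_windows(warmup: int) -> list[tuple[int, int, str]]:
    """Stan-style schedule: (start, end, kind) with kind in {ss, metric}."""
    if warmup < 20:
        return [(0, warmup, "ss")]
    init_buf, term_buf, base = 75, 50, 25
    if warmup < init_buf + term_buf + base:
        scale = warmup / (init_buf + term_buf + base)
        init_buf = max(int(init_buf * scale), 1)
        term_buf = max(int(term_buf * scale), 1)
        base = max(warmup - init_buf - term_buf, 1)
    windows = [(0, init_buf, "ss")]
    start, size = init_buf, base
    last_metric_end = warmup - term_buf
    while start < last_metric_end:
        end = min(start + size, last_metric_end)
        if last_metric_end - end < size:  # absorb the remainder
            end = last_metric_end
        windows.append((start, end, "metric"))
        start, size = end, size * 2
    windows.append((last_metric_end, warmup, "ss"))
    return windows


def sample_nuts(
    logp_grad: Callable,
    q0: np.ndarray,
    *,
    warmup: int,
    iterations: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws and sampler statistics."""
    dim = len(q0)
    inv_mass = np.ones(dim)
    ham = _Hamiltonian(logp_grad, inv_mass)
    q = np.asarray(q0, dtype=float).copy()
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(ham, rng, q, logp, grad)
    da = _DualAveraging.start(eps, target_accept)
    n_div_warmup = 0
    window_draws: list[np.ndarray] = []

    for start, end, kind in _warmup_windows(warmup):
        for _ in range(start, end):
            q, logp, grad, a_stat, div, _ = _nuts_step(
                ham, rng, q, logp, grad, eps, max_treedepth)
            eps = da.update(a_stat)
            n_div_warmup += int(div)
            if kind == "metric":
                window_draws.append(q.copy())
        if kind == "metric" and len(window_draws) >= 10:
            draws = np.asarray(window_draws)
            m = draws.shape[0]
            var = draws.var(axis=0, ddof=1)
            inv_mass = (m / (m + 5.0)) * var + 1e-3 * (5.0 / (m + 5.0))
            ham.inv_mass = inv_mass
            window_draws = []
            eps = _find_initial_step(ham, rng, q, logp, grad)
            da = _DualAveraging.start(eps, target_accept)
    eps = da.adapted if warmup > 0 else eps

    draws = np.empty((iterations, dim))
    logps = np.empty(iterations)
    divs = np.zeros(iterations, dtype=bool)
    depths = np.zeros(iterations, dtype=int)
    accepts = np.zeros(iterations)
    for i in range(iterations):
        q, logp, grad, a_stat, div, depth = _nuts_step(
            ham, rng, q, logp, grad, eps, max_treedepth)
        draws[i] = q
        logps[i] = logp
        divs[i] = div
        depths[i] = depth
        accepts[i] = a_stat
    return NutsResult(draws, logps, divs, depths, accepts, eps, inv_mass,
                      n_div_warmup)
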