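"""Self-contained No-U-Turn sampler (NUTS) with dual-averaging step size.

Implements the classic recursive NUTS of Hoffman & Gelman (2014, Alg. 6)
with a diagonal mass matrix and Stan-style divergence detection
(energy error > 1000). Sufficient for the low-dimensional, unimodal
posteriors fit in this package; gradients are supplied analytically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DELTA_MAX = 1000.0  # divergence threshold on the energy error


@dataclass
class NUTSChain:
    draws: np.ndarray          # (n_draws, dim), post-warmup
    divergences: int
    mean_accept: float
    step_size: float
    max_depth_hits: int


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(p * inv_mass, p))


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    x = x + eps * inv_mass * p
    logp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _find_reasonable_epsilon(logp_grad, x0, logp0, grad0, inv_mass, rng) -> float:
    eps = 1.0
    p0 = rng.normal(size=x0.size) / np.sqrt(inv_mass)
    h0 = logp0 - _kinetic(p0, inv_mass)
    x, p, logp, _ = _leapfrog(logp_grad, x0, p0, grad0, eps, inv_mass)
    h = logp - _kinetic(p, inv_mass)
    if not np.isfinite(h):
        h = -np.inf
    direction = 1.0 if (h - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        x, p, logp, _ = _leapfrog(logp_grad, x0, p0, grad0, eps, inv_mass)
        h = logp - _kinetic(p, inv_mass)
        if not np.isfinite(h):
            h = -np.inf
        if direction * (h - h0) <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    __slots__ = (
        "x_minus", "p_minus", "grad_minus",
        "x_plus", "p_plus", "grad_plus",
        "x_prop", "n_valid", "stop", "alpha", "n_alpha", "diverged",
    )


def _build_tree(logp_grad, x, p, grad, log_u, direction, depth, eps, h0, inv_mass, rng):
    t = _Tree()
    if depth == 0:
        x1, p1, logp1, grad1 = _leapfrog(logp_grad, x, p, grad, direction * eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        t.n_valid = int(log_u <= h1)
        t.diverged = (log_u - _DELTA_MAX) >= h1
        t.stop = t.diverged
        t.x_minus = t.x_plus = t.x_prop = x1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = grad1
        t.alpha = min(1.0, float(np.exp(h1 - h0))) if np.isfinite(h1) else 0.0
        t.n_alpha = 1
        return t

    t = _build_tree(logp_grad, x, p, grad, log_u, direction, depth - 1, eps, h0, inv_mass, rng)
    if not t.stop:
        if direction == -1:
            t2 = _build_tree(
                logp_grad, t.x_minus, t.p_minus, t.grad_minus,
                log_u, direction, depth - 1, eps, h0, inv_mass, rng,
            )
            t.x_minus, t.p_minus, t.grad_minus = t2.x_minus, t2.p_minus, t2.grad_minus
        else:
            t2 = _build_tree(
                logp_grad, t.x_plus, t.p_plus, t.grad_plus,
                log_u, direction, depth - 1, eps, h0, inv_mass, rng,
            )
            t.x_plus, t.p_plus, t.grad_plus = t2.x_plus, t2.p_plus, t2.grad_plus
        total = t.n_valid + t2.n_valid
        if total > 0 and rng.uniform() < t2.n_valid / total:
            t.x_prop = t2.x_prop
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        t.n_valid = total
        dx = t.x_plus - t.x_minus
        no_uturn = (
            np.dot(dx, inv_mass * t.p_minus) >= 0
            and np.dot(dx, inv_mass * t.p_plus) >= 0
        )
        t.diverged = t.diverged or t2.diverged
        t.stop = t2.stop or not no_uturn
    return t


def sample_nuts(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    adapt_delta: float = 0.9,
    max_treedepth: int = 10,
    inv_mass: np.ndarray | None = None,
) -> NUTSChain:
    """Run one NUTS chain; returns post-warmup draws on the unconstrained scale."""
    x = np.asarray(x0, float).copy()
    dim = x.size
    if inv_mass is None:
        inv_mass = np.ones(dim)
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_epsilon(logp_grad, x, logp, grad, inv_mass, rng)
    # dual averaging (Hoffman & Gelman eq. 3.2) constants
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    draws = np.empty((n_draws, dim))
    divergences = 0
    max_depth_hits = 0
    accept_sum = 0.0

    for it in range(n_warmup + n_draws):
        p0 = rng.normal(size=dim) / np.sqrt(inv_mass)
        h0 = logp - _kinetic(p0, inv_mass)
        log_u = h0 + np.log(rng.uniform())

        x_minus = x_plus = x
        p_minus = p_plus = p0
        grad_minus = grad_plus = grad
        x_new = x
        n_valid = 1
        stop = False
        alpha, n_alpha = 0.0, 1
        diverged = False
        depth = 0
        while not stop and depth < max_treedepth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == -1:
                t = _build_tree(
                    logp_grad, x_minus, p_minus, grad_minus,
                    log_u, direction, depth, eps, h0, inv_mass, rng,
                )
                x_minus, p_minus, grad_minus = t.x_minus, t.p_minus, t.grad_minus
            else:
                t = _build_tree(
                    logp_grad, x_plus, p_plus, grad_plus,
                    log_u, direction, depth, eps, h0, inv_mass, rng,
                )
                x_plus, p_plus, grad_plus = t.x_plus, t.p_plus, t.grad_plus
            if not t.stop and t.n_valid > 0:
                if rng.uniform() < min(1.0, t.n_valid / n_valid):
                    x_new = t.x_prop
            n_valid += t.n_valid
            alpha, n_alpha = t.alpha, t.n_alpha
            diverged = diverged or t.diverged
            dx = x_plus - x_minus
            stop = t.stop or not (
                np.dot(dx, inv_mass * p_minus) >= 0
                and np.dot(dx, inv_mass * p_plus) >= 0
            )
            depth += 1

        if depth >= max_treedepth:
            max_depth_hits += 1
        x = x_new
        logp, grad = logp_grad(x)
        accept_prob = alpha / max(n_alpha, 1)

        if it < n_warmup:
            frac = 1.0 / (it + 1 + t0)
            h_bar = (1 - frac) * h_bar + frac * (adapt_delta - accept_prob)
            log_eps = mu - np.sqrt(it + 1) / gamma * h_bar
            eta = (it + 1) ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
        else:
            if it == n_warmup:
                eps = float(np.exp(log_eps_bar))
            draws[it - n_warmup] = x
            divergences += int(diverged)
            accept_sum += accept_prob

    return NUTSChain(
        draws=draws,
        divergences=divergences,
        mean_accept=accept_sum / max(n_draws, 1),
        step_size=eps,
        max_depth_hits=max_depth_hits,
    )
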