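"""No-U-Turn sampler with dual-averaging step-size and diagonal mass
adaptation.

Generic over any callable returning (log density, gradient).  The
implementation follows the original recursive doubling scheme with a slice
variable, a diagonal Euclidean metric adapted from warmup draws, and
divergence detection on large energy errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_nuts", "NutsStats"]

_MAX_DELTA = 1000.0  # energy error above which a trajectory is divergent


@dataclass
class NutsStats:
    step_size: float
    inv_mass: np.ndarray
    divergences: int
    mean_accept: float
    mean_treedepth: float


class _Tree:
    __slots__ = ("minus_q", "minus_p", "plus_q", "plus_p", "prop_q",
                 "prop_logp", "n", "keep_going", "sum_alpha", "n_alpha",
                 "diverged", "_grad_minus", "_grad_plus")


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _find_reasonable_step(logp_grad, q, rng, inv_mass):
    eps = 1.0
    logp, grad = logp_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    joint0 = logp - 0.5 * np.sum(inv_mass * p * p)
    q1, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
    joint1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    a = 1.0 if joint1 - joint0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** a
        q1, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        joint1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if a * (joint1 - joint0) <= a * np.log(0.5):
            break
    return eps


def sample_nuts(logp_grad, x0, n_warmup, n_samples, seed=0,
                max_treedepth=8, target_accept=0.8, init_step=None):
    """Run one NUTS chain.  Returns (draws (n_samples, dim), logps, stats)."""
    rng = np.random.default_rng(seed)
    q = np.array(x0, float)
    dim = q.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")

    eps = init_step or _find_reasonable_step(logp_grad, q, rng, inv_mass)
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    # warmup schedule: step-size only, then mass-estimation window, then
    # step-size re-adaptation with the new metric
    w_a = max(1, int(0.15 * n_warmup))
    w_b = max(w_a + 1, int(0.85 * n_warmup))
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    divergences = 0
    acc_sum, acc_n, depth_sum = 0.0, 0, 0

    def joint(lp, p):
        return lp - 0.5 * np.sum(inv_mass * p * p)

    def build_tree(q, p, grad, logu, direction, depth, joint0):
        nonlocal divergences
        if depth == 0:
            q1, p1, lp1, g1 = _leapfrog(logp_grad, q, p, grad,
                                        direction * eps, inv_mass)
            j1 = joint(lp1, p1) if np.isfinite(lp1) else -np.inf
            t = _Tree()
            t.minus_q, t.minus_p = q1, p1
            t.plus_q, t.plus_p = q1, p1
            t.prop_q, t.prop_logp = q1, lp1
            t.n = 1 if logu <= j1 else 0
            t.diverged = (j1 - logu) < -_MAX_DELTA or not np.isfinite(j1)
            t.keep_going = not t.diverged
            t.sum_alpha = min(1.0, np.exp(min(0.0, j1 - joint0)))
            t.n_alpha = 1
            t._grad_minus = g1
            t._grad_plus = g1
            return t
        t = build_tree(q, p, grad, logu, direction, depth - 1, joint0)
        if t.keep_going:
            if direction == -1:
                t2 = build_tree(t.minus_q, t.minus_p, t._grad_minus, logu,
                                direction, depth - 1, joint0)
                t.minus_q, t.minus_p = t2.minus_q, t2.minus_p
                t._grad_minus = t2._grad_minus
            else:
                t2 = build_tree(t.plus_q, t.plus_p, t._grad_plus, logu,
                                direction, depth - 1, joint0)
                t.plus_q, t.plus_p = t2.plus_q, t2.plus_p
                t._grad_plus = t2._grad_plus
            if t2.n > 0 and rng.uniform() < t2.n / max(t.n + t2.n, 1):
                t.prop_q, t.prop_logp = t2.prop_q, t2.prop_logp
            t.n += t2.n
            dq = t.plus_q - t.minus_q
            no_uturn = (np.dot(dq, inv_mass * t.minus_p) >= 0
                        and np.dot(dq, inv_mass * t.plus_p) >= 0)
            t.keep_going = t2.keep_going and no_uturn
            t.diverged = t.diverged or t2.diverged
            t.sum_alpha += t2.sum_alpha
            t.n_alpha += t2.n_alpha
        return t

    total = n_warmup + n_samples
    for it in range(total):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = joint(logp, p0)
        logu = joint0 - rng.exponential()
        minus_q, minus_p, grad_minus = q, p0, grad
        plus_q, plus_p, grad_plus = q, p0, grad
        prop_q, prop_logp = q, logp
        n, depth, keep_going = 1, 0, True
        diverged = False
        sum_alpha, n_alpha = 0.0, 0
        while keep_going and depth < max_treedepth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == -1:
                t = build_tree(minus_q, minus_p, grad_minus, logu,
                               direction, depth, joint0)
                minus_q, minus_p, grad_minus = t.minus_q, t.minus_p, t._grad_minus
            else:
                t = build_tree(plus_q, plus_p, grad_plus, logu,
                               direction, depth, joint0)
                plus_q, plus_p, grad_plus = t.plus_q, t.plus_p, t._grad_plus
            if t.keep_going and t.n > 0 and rng.uniform() < min(1.0, t.n / n):
                prop_q, prop_logp = t.prop_q, t.prop_logp
            n += t.n
            sum_alpha += t.sum_alpha
            n_alpha += t.n_alpha
            diverged = diverged or t.diverged
            dq = plus_q - minus_q
            keep_going = (t.keep_going
                          and np.dot(dq, inv_mass * minus_p) >= 0
                          and np.dot(dq, inv_mass * plus_p) >= 0)
            depth += 1
        if diverged and it >= n_warmup:
            divergences += 1
        q, logp = prop_q, prop_logp
        _, grad = logp_grad(q)
        alpha_stat = sum_alpha / max(n_alpha, 1)

        if it < n_warmup:
            # dual averaging
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha_stat)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w_a <= it < w_b:
                welford_n += 1
                delta = q - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (q - welford_mean)
            if it == w_b - 1 and welford_n > 4:
                var = welford_m2 / (welford_n - 1)
                inv_mass = (welford_n / (welford_n + 5.0)) * var \
                    + 1e-3 * (5.0 / (welford_n + 5.0))
                inv_mass = np.maximum(inv_mass, 1e-8)
                eps = _find_reasonable_step(logp_grad, q, rng, inv_mass)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = q
            logps[it - n_warmup] = logp
            acc_sum += alpha_stat
            acc_n += 1
            depth_sum += depth

    stats = NutsStats(step_size=eps, inv_mass=inv_mass,
                      divergences=divergences,
                      mean_accept=acc_sum / max(acc_n, 1),
                      mean_treedepth=depth_sum / max(acc_n, 1))
    return draws, logps, stats
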