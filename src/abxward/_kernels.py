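"""Fixed-step RK4 inner loops.

The right-hand side is re-stated here in scalar form so the hot loops can be
JIT-compiled with numba when it is available; without numba the same code
runs as plain Python (correct but slow).  :func:`abxward.population.rhs_multi`
is the vectorized reference implementation; the unit tests pin the two
against each other.

Doses are piecewise constant, so within any integration segment the strain
growth rates are fixed and enter the loops as a precomputed ``(m, 4)`` array
(arms x strains).  State layout: ``[X, S^1, R1^1, R2^1, R3^1, S^2, ...]``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(func):
            return func

        return deco


@njit(cache=False)
def _deriv(y, dy, growth, weights, beta, sigma, gamma, cost):
    """In-place derivative of the multi-arm state; component sum is zero."""
    m = growth.shape[0]
    x = y[0]
    tot0 = 0.0
    tot1 = 0.0
    tot2 = 0.0
    tot3 = 0.0
    for a in range(m):
        base = 1 + 4 * a
        tot0 += y[base]
        tot1 += y[base + 1]
        tot2 += y[base + 2]
        tot3 += y[base + 3]
    inf0 = beta * x * tot0
    br = beta * (1.0 - cost)
    inf1 = br * x * tot1
    inf2 = br * x * tot2
    inf3 = br * x * tot3
    dx = -(inf0 + inf1 + inf2 + inf3)
    # S takes over resistant carriers at sigma*beta*c (cost-driven takeover)
    sb = sigma * beta * cost * tot0
    for a in range(m):
        base = 1 + 4 * a
        w = weights[a]
        c0 = (growth[a, 0] - gamma) * y[base]
        c1 = (growth[a, 1] - gamma) * y[base + 1]
        c2 = (growth[a, 2] - gamma) * y[base + 2]
        c3 = (growth[a, 3] - gamma) * y[base + 3]
        sup1 = sb * y[base + 1]
        sup2 = sb * y[base + 2]
        sup3 = sb * y[base + 3]
        dy[base] = w * inf0 + sup1 + sup2 + sup3 + c0
        dy[base + 1] = w * inf1 - sup1 + c1
        dy[base + 2] = w * inf2 - sup2 + c2
        dy[base + 3] = w * inf3 - sup3 + c3
        dx -= c0 + c1 + c2 + c3
    dy[0] = dx


@njit(cache=False)
def _rk4_step(y, growth, weights, beta, sigma, gamma, cost, dt, k1, k2, k3, k4, yt):
    """One classic RK4 step in place; returns the sup-norm of the update."""
    n = y.size
    _deriv(y, k1, growth, weights, beta, sigma, gamma, cost)
    for i in range(n):
        yt[i] = y[i] + 0.5 * dt * k1[i]
    _deriv(yt, k2, growth, weights, beta, sigma, gamma, cost)
    for i in range(n):
        yt[i] = y[i] + 0.5 * dt * k2[i]
    _deriv(yt, k3, growth, weights, beta, sigma, gamma, cost)
    for i in range(n):
        yt[i] = y[i] + dt * k3[i]
    _deriv(yt, k4, growth, weights, beta, sigma, gamma, cost)
    delta = 0.0
    for i in range(n):
        d = dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        y[i] += d
        if abs(d) > delta:
            delta = abs(d)
    return delta


@njit(cache=False)
def rk4_static(y, growth, weights, beta, sigma, gamma, cost, dt, max_steps, tol):
    """Integrate with constant doses until the per-step change drops below
    ``tol`` (sup-norm) or ``max_steps`` is exhausted.

    Returns ``(steps_taken, converged)``; ``y`` is updated in place.
    """
    n = y.size
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    for step in range(max_steps):
        delta = _rk4_step(y, growth, weights, beta, sigma, gamma, cost, dt, k1, k2, k3, k4, yt)
        if delta < tol:
            return step + 1, True
    return max_steps, False


@njit(cache=False)
def rk4_run(y, growth, weights, beta, sigma, gamma, cost, dt, n_steps):
    """Integrate ``n_steps`` with constant doses (no convergence check)."""
    n = y.size
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    for _ in range(n_steps):
        _rk4_step(y, growth, weights, beta, sigma, gamma, cost, dt, k1, k2, k3, k4, yt)


@njit(cache=False)
def rk4_record(y, growth, weights, beta, sigma, gamma, cost, dt, n_steps, out):
    """Integrate ``n_steps`` with constant doses, writing the state after
    every step into ``out`` (shape ``(n_steps, y.size)``)."""
    n = y.size
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    for s in range(n_steps):
        _rk4_step(y, growth, weights, beta, sigma, gamma, cost, dt, k1, k2, k3, k4, yt)
        for i in range(n):
            out[s, i] = y[i]


@njit(cache=False)
def rk4_block(
    y,
    growth_first,
    growth_second,
    weights,
    beta,
    sigma,
    gamma,
    cost,
    dt,
    steps_per_period,
    env_min,
    env_max,
    sums,
):
    """Integrate one full forcing block (two drug periods: first then second
    dose configuration), accumulating per-component envelope bounds, the
    per-component running sum and the running sum of the population recovery
    flux z.

    ``env_min``/``env_max``/``sums`` must be preset by the caller
    (``env_min=+inf``, ``env_max=-inf``, ``sums=0``; ``sums`` has one extra
    trailing slot that receives the z sum).  Returns nothing; all outputs are
    in place.
    """
    n = y.size
    m = weights.size
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    for half in range(2):
        growth = growth_first if half == 0 else growth_second
        for _ in range(steps_per_period):
            _rk4_step(y, growth, weights, beta, sigma, gamma, cost, dt, k1, k2, k3, k4, yt)
            z = 0.0
            for i in range(n):
                v = y[i]
                if v < env_min[i]:
                    env_min[i] = v
                if v > env_max[i]:
                    env_max[i] = v
                sums[i] += v
            for a in range(m):
                base = 1 + 4 * a
                for j in range(4):
                    z -= (growth[a, j] - gamma) * y[base + j]
            sums[n] += z
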