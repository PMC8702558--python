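"""Numba-compiled inner loops for the slow-fast network.

Every kernel mutates its array arguments in place and draws no randomness of
its own: initial states, switch perturbations and dynamics noise are all
produced by the caller from numpy Generators, so the seeding policy lives in
one place (:mod:`tsnet.model`).  Kernels integrate the coupled rate equations

    tau_x dx_i/dt = tanh(beta_x I_i) - x_i
    tau_y dy_i/dt = tanh(beta_y x_i) - y_i
    I_i = sum_{j != i} JX_ij x_j + tanh(sum_j JXY_ij tanh(y_j)) + eta_i

with explicit Euler steps, and (optionally) the local plasticity rule

    tau_syn dJX_ij/dt = (1/N) (xi_i - x_i) (x_j - u_i JX_ij)

synchronously after each state step.  The JX diagonal is pinned at zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["present_pattern", "run_piecewise", "relax_fast_batch"]


@njit(cache=True)
def present_pattern(
    JX,
    JXY,
    eta,
    xi,
    x,
    y,
    dt,
    tau_x,
    tau_y,
    tau_syn,
    beta_x,
    beta_y,
    thr_x,
    thr_xy,
    max_steps,
    timed,
    plastic,
):
    """Present one (target, input) pair with plasticity.

    If ``timed`` is True the presentation runs for exactly ``max_steps``
    Euler steps; otherwise it stops as soon as the two learning criteria
    (overlap with the target above ``thr_x`` and x-y overlap above
    ``thr_xy``) are met, or at ``max_steps``.

    Returns ``(steps_taken, m_x, m_xy, converged)``.
    """
    N = x.shape[0]
    mx = 0.0
    mxy = 0.0
    converged = False
    steps = 0
    while steps < max_steps:
        r = np.dot(JXY, np.tanh(y))
        u = np.dot(JX, x)
        I = u + np.tanh(r) + eta
        fx = np.tanh(beta_x * I)
        fy = np.tanh(beta_y * x)
        if plastic:
            for i in range(N):
                d = (xi[i] - x[i]) * dt / (tau_syn * N)
                ui = u[i]
                for j in range(N):
                    JX[i, j] += d * (x[j] - ui * JX[i, j])
                JX[i, i] = 0.0
        for i in range(N):
            x[i] += dt / tau_x * (fx[i] - x[i])
            y[i] += dt / tau_y * (fy[i] - y[i])
        steps += 1
        mx = np.dot(x, xi) / N
        mxy = np.dot(x, y) / N
        if (not timed) and mx > thr_x and mxy > thr_xy:
            converged = True
            break
    if timed:
        converged = True
    return steps, mx, mxy, converged


@njit(cache=True)
def run_piecewise(
    JX,
    JXY,
    seg_end_steps,
    etas,
    x,
    y,
    dt,
    tau_x,
    tau_y,
    beta_x,
    beta_y,
    n_steps,
    sample_every,
    noise,
    X,
    Y,
):
    """Integrate the frozen-connectivity dynamics under a piecewise input.

    ``seg_end_steps[k]`` is the exclusive step index at which input row
    ``etas[k]`` stops applying.  ``noise`` holds pre-scaled additive
    increments for x (shape ``(n_steps, N)``) or is empty for the
    deterministic path.  Samples are written to ``X``/``Y`` every
    ``sample_every`` steps; row 0 must be prefilled with the initial state.
    """
    N = x.shape[0]
    has_noise = noise.shape[0] > 0
    seg = 0
    k = 1
    for t in range(n_steps):
        while t >= seg_end_steps[seg]:
            seg += 1
        eta = etas[seg]
        r = np.dot(JXY, np.tanh(y))
        u = np.dot(JX, x)
        I = u + np.tanh(r) + eta
        fx = np.tanh(beta_x * I)
        fy = np.tanh(beta_y * x)
        if has_noise:
            for i in range(N):
                x[i] += dt / tau_x * (fx[i] - x[i]) + noise[t, i]
                y[i] += dt / tau_y * (fy[i] - y[i])
        else:
            for i in range(N):
                x[i] += dt / tau_x * (fx[i] - x[i])
                y[i] += dt / tau_y * (fy[i] - y[i])
        if (t + 1) % sample_every == 0 and k < X.shape[0]:
            for i in range(N):
                X[k, i] = x[i]
                Y[k, i] = y[i]
            k += 1
    return k


@njit(cache=True)
def relax_fast_batch(
    JXT,
    drive,
    X,
    dt,
    tau_x,
    beta_x,
    n_transient,
    n_extra,
    hold_steps,
    tol,
):
    """Relax a batch of initial conditions of the quenched-y fast subsystem.

    With y frozen the slow feedback tanh(r) is a constant vector, folded
    with the input into ``drive``.  Each row of ``X`` is integrated for
    ``n_transient`` steps, then up to ``n_extra`` more until the residual
    ``max_i |dx_i/dt|`` stays below ``tol`` for ``hold_steps`` consecutive
    steps.  Returns a boolean array marking rows that converged (rows that
    keep oscillating are flagged False).
    """
    B = X.shape[0]
    held = np.zeros(B, dtype=np.int64)
    done = np.zeros(B, dtype=np.bool_)
    for _ in range(n_transient):
        F = np.tanh(beta_x * (np.dot(X, JXT) + drive))
        X += dt / tau_x * (F - X)
    for _ in range(n_extra):
        F = np.tanh(beta_x * (np.dot(X, JXT) + drive))
        all_done = True
        for b in range(B):
            if done[b]:
                continue
            dmax = 0.0
            for i in range(X.shape[1]):
                dx = (F[b, i] - X[b, i]) / tau_x
                X[b, i] += dt * dx
                a = abs(dx)
                if a > dmax:
                    dmax = a
            if dmax < tol:
                held[b] += 1
                if held[b] >= hold_steps:
                    done[b] = True
            else:
                held[b] = 0
            if not done[b]:
                all_done = False
        if all_done:
            break
    return done
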