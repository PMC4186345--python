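"""Numba-accelerated trial integration core.

The inner Euler loop of a trial is a few dozen small array operations per
step; JIT-compiling the whole loop removes the per-step dispatch overhead
and makes multi-thousand-trial learning campaigns desk-scale.  The pure
NumPy reference loop lives in :mod:`maskfield.learning` (used for recorded
trajectories and as the cross-check in the test suite); both paths implement
the identical update and produce identical results to machine precision.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def trial_core(
    xs,            # (T_pres+1, m) cached working-memory activities
    W,             # (m, n) adaptive weights, updated in place
    support,       # (m, n) 0/1 chunk membership
    sizes,         # (n,) float chunk sizes |J|
    masking_T,     # (n, n) transposed normalized masking coefficients
    admissible,    # (n,) bool: uncommitted or committed to presented seq
    # Masking Field parameters
    A, B, D, E, F, L, H, f0, g0, tau, threshold,
    ffi_weighted,  # bool
    # gate parameters
    eps, lam, mu,
    # learning / protocol
    eta, post_time, dt, max_steps,
    learn, learn_during_search, wta_on_selection, supervised,
):
    m, n = W.shape
    t_pres = xs.shape[0] - 1
    c = np.zeros(n)
    Z = np.ones(m)
    R = np.ones(n)
    processed = np.zeros(n, dtype=np.bool_)
    winner = -1
    selection_time = -1.0
    reset_chunks = np.empty(max_steps, dtype=np.int64)
    reset_times = np.empty(max_steps)
    n_resets = 0
    f02 = f0 * f0
    g02 = g0 * g0
    end_step = max_steps
    supp_counts = np.zeros(m)
    for i in range(m):
        for j in range(n):
            supp_counts[i] += support[i, j]

    for step in range(max_steps):
        x = xs[step] if step <= t_pres else xs[t_pres]
        u = x * Z
        # f and g signals
        fc = np.empty(n)
        gc = np.empty(n)
        for j in range(n):
            cj2 = c[j] * c[j]
            fc[j] = cj2 / (cj2 + f02)
            gc[j] = cj2 / (cj2 + g02)
        bottom_up = W.T @ u
        if ffi_weighted:
            uw = np.zeros(m)
            for i in range(m):
                if supp_counts[i] > 0:
                    wsum = 0.0
                    for j in range(n):
                        wsum += W[i, j] * support[i, j]
                    uw[i] = u[i] * wsum / supp_counts[i]
            total_u = uw.sum()
            ffi = total_u - support.T @ uw
        else:
            total_u = u.sum()
            ffi = total_u - support.T @ u
        rec = masking_T @ gc
        sum_x = x.sum()
        new_c = np.empty(n)
        for j in range(n):
            exc = R[j] * (B * bottom_up[j] + D * sizes[j] * fc[j])
            inh = L * ffi[j] + H * rec[j]
            dc = (-A * c[j] + (1.0 - c[j]) * exc
                  - E * (c[j] + F) * inh) / tau
            new_c[j] = c[j] + dt * dc
        if learn and eta > 0.0 and (learn_during_search or winner >= 0):
            if winner >= 0 and not learn_during_search:
                gate_w = eta * fc[winner]
                for i in range(m):
                    if support[i, winner] > 0.0:
                        W[i, winner] += dt * gate_w * (
                            x[i] - W[i, winner] * sum_x
                        )
            else:
                for j in range(n):
                    gate_j = eta * fc[j]
                    if gate_j > 0.0:
                        for i in range(m):
                            if support[i, j] > 0.0:
                                W[i, j] += dt * gate_j * (
                                    x[i] - W[i, j] * sum_x
                                )
        for i in range(m):
            Z[i] += dt * (eps * (1.0 - Z[i])
                          - Z[i] * (lam * x[i] + mu * x[i] * x[i]))
        c = new_c
        for j in range(n):
            if not np.isfinite(c[j]):
                return winner, selection_time, reset_chunks[:n_resets], \
                    reset_times[:n_resets], step, -2
        t_next = (step + 1) * dt

        if winner < 0:
            any_crossed = False
            for j in range(n):
                if c[j] >= threshold and R[j] > 0.0 and not processed[j]:
                    any_crossed = True
                    break
            if any_crossed:
                # collect and process crossings in descending activity order
                ids = np.empty(n, dtype=np.int64)
                k = 0
                for j in range(n):
                    if c[j] >= threshold and R[j] > 0.0 and not processed[j]:
                        ids[k] = j
                        k += 1
                for a in range(k):
                    processed[ids[a]] = True
                # selection sort by -c (k is tiny)
                for a in range(k):
                    best = a
                    for b in range(a + 1, k):
                        if c[ids[b]] > c[ids[best]]:
                            best = b
                    tmp = ids[a]
                    ids[a] = ids[best]
                    ids[best] = tmp
                if supervised:
                    for a in range(k):
                        j = ids[a]
                        if not admissible[j]:
                            R[j] = 0.0
                            reset_chunks[n_resets] = j
                            reset_times[n_resets] = t_next
                            n_resets += 1
                        else:
                            winner = j
                            selection_time = t_next
                            break
                else:
                    winner = ids[0]
                    selection_time = t_next
                if winner >= 0 and wta_on_selection:
                    for j in range(n):
                        R[j] = 0.0
                    R[winner] = 1.0
        elif t_next >= selection_time + post_time:
            end_step = step + 1
            break

    return winner, selection_time, reset_chunks[:n_resets], \
        reset_times[:n_resets], end_step, 0
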