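"""Numba kernels for the rate-model integrator.

Fixed-step Euler for the rate and adaptation variables; the
Ornstein-Uhlenbeck noise channel is advanced by its exact discrete update
``n <- n*exp(-dt/tau_n) + sigma*sqrt(1 - exp(-2dt/tau_n))*xi`` so the noise
statistics carry no discretisation bias.  The unit Gaussian draws ``xi`` are
generated vectorised by the caller (one array per channel, plus stationary
initial noise states), which keeps the kernels free of per-step RNG calls;
both kernels consume the same arrays, so for a given seed the online
reversal labelling reproduces exactly the labelling of the recorded
trajectory.
"""

import numpy as np
from numba import njit

__all__ = ["integrate_trajectory", "integrate_reversals", "label_samples"]


@njit(cache=True)
def integrate_trajectory(beta, phi_a, i0, sigma_n, tau_a, tau_r, tau_n, k, alpha,
                         n_steps, dt, r1, r2, a1, a2, n1, n2, xi1, xi2,
                         mod_amp, mod_period, stride):
    """Integrate and record every ``stride``-th sample (including t=0).

    Returns (r1s, r2s, a1s, a2s, n1s, n2s, bad_step); bad_step is -1 on
    success, else the first step index with a non-finite state.
    """
    n_rec = n_steps // stride + 1
    r1s = np.empty(n_rec)
    r2s = np.empty(n_rec)
    a1s = np.empty(n_rec)
    a2s = np.empty(n_rec)
    n1s = np.empty(n_rec)
    n2s = np.empty(n_rec)

    noisy = xi1.shape[0] > 0
    decay = np.exp(-dt / tau_n)
    nsd = sigma_n * np.sqrt(1.0 - decay * decay)

    r1s[0], r2s[0], a1s[0], a2s[0], n1s[0], n2s[0] = r1, r2, a1, a2, n1, n2

    cr = dt / tau_r
    ca = dt / tau_a
    modulated = mod_period > 0.0
    two_pi = 2.0 * np.pi
    bad_step = -1

    for step in range(n_steps):
        if modulated:
            c = mod_amp * np.cos(two_pi * (step * dt) / mod_period)
            i1 = i0 + c
            i2 = i0 - c
        else:
            i1 = i0
            i2 = i0
        x1 = alpha * r1 - beta * r2 - phi_a * a1 + i1 + n1
        x2 = alpha * r2 - beta * r1 - phi_a * a2 + i2 + n2
        f1 = 1.0 / (1.0 + np.exp(-x1 / k))
        f2 = 1.0 / (1.0 + np.exp(-x2 / k))
        nr1 = r1 + cr * (f1 - r1)
        nr2 = r2 + cr * (f2 - r2)
        na1 = a1 + ca * (r1 - a1)
        na2 = a2 + ca * (r2 - a2)
        r1, r2, a1, a2 = nr1, nr2, na1, na2
        if noisy:
            n1 = n1 * decay + nsd * xi1[step]
            n2 = n2 * decay + nsd * xi2[step]
        if not np.isfinite(r1 + r2 + a1 + a2):
            bad_step = step
            break
        if (step + 1) % stride == 0:
            idx = (step + 1) // stride
            r1s[idx], r2s[idx], a1s[idx] = r1, r2, a1
            a2s[idx], n1s[idx], n2s[idx] = a2, n1, n2

    return r1s, r2s, a1s, a2s, n1s, n2s, bad_step


@njit(cache=True)
def integrate_reversals(beta, phi_a, i0, sigma_n, tau_a, tau_r, tau_n, k, alpha,
                        n_steps, dt, r1, r2, a1, a2, n1, n2, xi1, xi2,
                        mod_amp, mod_period, threshold_ratio):
    """Integrate and label dominance online with the hysteretic ratio rule.

    A reversal to percept x occurs at the first step where
    ``r_x >= (1 + threshold_ratio) * r_y`` (and ``r_x > r_y``) while x is not
    already dominant.  Returns (states, onset_times, bad_step) where states
    are 1/2 percept codes and onsets are seconds.
    """
    noisy = xi1.shape[0] > 0
    decay = np.exp(-dt / tau_n)
    nsd = sigma_n * np.sqrt(1.0 - decay * decay)

    cr = dt / tau_r
    ca = dt / tau_a
    modulated = mod_period > 0.0
    two_pi = 2.0 * np.pi
    thr = 1.0 + threshold_ratio
    bad_step = -1

    cap = n_steps + 1
    states = np.empty(cap, dtype=np.int8)
    onsets = np.empty(cap, dtype=np.float64)
    count = 0
    dom = 0

    # initial state may already satisfy the dominance condition at t = 0
    if r1 >= thr * r2 and r1 > r2:
        states[0] = 1
        onsets[0] = 0.0
        count = 1
        dom = 1
    elif r2 >= thr * r1 and r2 > r1:
        states[0] = 2
        onsets[0] = 0.0
        count = 1
        dom = 2

    for step in range(n_steps):
        if modulated:
            c = mod_amp * np.cos(two_pi * (step * dt) / mod_period)
            i1 = i0 + c
            i2 = i0 - c
        else:
            i1 = i0
            i2 = i0
        x1 = alpha * r1 - beta * r2 - phi_a * a1 + i1 + n1
        x2 = alpha * r2 - beta * r1 - phi_a * a2 + i2 + n2
        f1 = 1.0 / (1.0 + np.exp(-x1 / k))
        f2 = 1.0 / (1.0 + np.exp(-x2 / k))
        nr1 = r1 + cr * (f1 - r1)
        nr2 = r2 + cr * (f2 - r2)
        na1 = a1 + ca * (r1 - a1)
        na2 = a2 + ca * (r2 - a2)
        r1, r2, a1, a2 = nr1, nr2, na1, na2
        if noisy:
            n1 = n1 * decay + nsd * xi1[step]
            n2 = n2 * decay + nsd * xi2[step]
        if not np.isfinite(r1 + r2 + a1 + a2):
            bad_step = step
            break
        if dom != 1 and r1 >= thr * r2 and r1 > r2:
            states[count] = 1
            onsets[count] = (step + 1) * dt
            count += 1
            dom = 1
        elif dom != 2 and r2 >= thr * r1 and r2 > r1:
            states[count] = 2
            onsets[count] = (step + 1) * dt
            count += 1
            dom = 2

    return states[:count].copy(), onsets[:count].copy(), bad_step


@njit(cache=True)
def label_samples(r1s, r2s, dt_sample, threshold_ratio):
    """Hysteretic dominance labelling of a recorded trajectory.

    Returns (states, onset_times) with the same rule as
    :func:`integrate_reversals`, applied to the sample grid.
    """
    thr = 1.0 + threshold_ratio
    n = r1s.shape[0]
    states = np.empty(n, dtype=np.int8)
    onsets = np.empty(n, dtype=np.float64)
    count = 0
    dom = 0
    for i in range(n):
        r1 = r1s[i]
        r2 = r2s[i]
        if dom != 1 and r1 >= thr * r2 and r1 > r2:
            states[count] = 1
            onsets[count] = i * dt_sample
            count += 1
            dom = 1
        elif dom != 2 and r2 >= thr * r1 and r2 > r1:
            states[count] = 2
            onsets[count] = i * dt_sample
            count += 1
            dom = 2
    return states[:count].copy(), onsets[:count].copy()
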