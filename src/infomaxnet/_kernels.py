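"""Compiled inner loops for simulation and learning.

The kernels are deliberately free of any random-number generation: uniforms
are drawn by the caller from a numpy Generator in (step, neuron) order and
passed in as blocks, so trajectories are bit-reproducible for a fixed seed and
independent of chunking.  A pure-python reference implementation of the same
step schedule lives in :mod:`infomaxnet.learning` and cross-checks these
kernels in the test suite.

Step schedule inside ``train_chunk`` (time t, with x = x^t and s_prev the
input that generated it):

1. compute s^t from x^t;
2. compute the global signals from x^t, s^{t-1} (predictability term) and the
   slow averages, which at this point contain quantities up to t-1 only;
3. apply the parameter update using eligibility traces containing pairs up to
   (psi^{t-1}, x^{t-1});
4. sample x^{t+1} from s^t;
5. compute psi^t and fold (psi^t, x^t) into the eligibility traces;
6. fold the step-t quantities into the slow averages.
"""

import math

import numpy as np
from numba import njit

__all__ = ["simulate_chunk", "train_chunk", "lif_run"]


@njit(cache=True, fastmath=False)
def _sigmoid(s):
    if s >= 0.0:
        return 1.0 / (1.0 + math.exp(-s))
    es = math.exp(s)
    return es / (1.0 + es)


@njit(cache=True)
def simulate_chunk(W, h, x, u, stim, p_max, out_spikes, out_s, record_s):
    """Advance the frozen-parameter dynamics by ``u.shape[0]`` steps in place.

    ``x`` (length n_total, uint8) is the current firing vector and is left at
    the final state.  Row ``t`` of ``out_spikes`` receives the firing vector
    sampled at that step; with ``record_s`` the generating membrane inputs go
    to ``out_s``.
    """
    b, n_rec = u.shape
    n_tot = W.shape[1]
    n_ext = n_tot - n_rec
    s = np.empty(n_rec)
    for step in range(b):
        for i in range(n_rec):
            s[i] = -h[i]
        for j in range(n_tot):
            if x[j] == 1:
                for i in range(n_rec):
                    s[i] += W[i, j]
        for i in range(n_rec):
            p = p_max * _sigmoid(s[i])
            x[i] = 1 if u[step, i] < p else 0
        for j in range(n_ext):
            x[n_rec + j] = stim[step, j]
        for i in range(n_tot):
            out_spikes[step, i] = x[i]
        if record_s:
            for i in range(n_rec):
                out_s[step, i] = s[i]


@njit(cache=True)
def train_chunk(
    W, h, x, s_prev,
    elig_pair, elig_post, avg_m, avg_p, avg_lr,
    u, stim,
    p_max, p0, s0, eps, kappa, eta, zeta, tau, T, delta,
    row_mask, col_mask, scope_mask,
    aprime, apply_updates,
    grad_W, grad_h, accumulate, warmup,
    t_start,
    out_spikes, out_s, record_spikes, record_s,
    acc,
):
    """Run the full learning schedule for ``u.shape[0]`` steps in place.

    State carried across chunks: parameters ``W, h``; current firing vector
    ``x`` (= x^t, length n_total); ``s_prev`` (input that generated x^t);
    eligibility traces ``elig_pair`` ((n_rec, n_total)) and ``elig_post``;
    slow averages ``avg_m`` (1-element), ``avg_p``, ``avg_lr``.

    With ``apply_updates`` false the parameters stay frozen; with
    ``accumulate`` true the per-step update (for the frozen parameters) is
    summed into ``grad_W, grad_h`` for steps with global index >= ``warmup``.
    ``acc`` collects running sums: [g1, g2, g3, g4, combined, m, n_steps,
    n_accumulated].
    """
    b, n_rec = u.shape
    n_tot = W.shape[1]
    n_ext = n_tot - n_rec
    inv_tau = 1.0 / tau
    keep_tau = 1.0 - inv_tau
    inv_T = 1.0 / T
    keep_T = 1.0 - inv_T
    c1base = eps * tau / T
    c2 = eps * zeta / T

    s_now = np.empty(n_rec)
    sig_now = np.empty(n_rec)
    lr = np.zeros(n_rec)
    x_new = np.empty(n_rec, dtype=np.uint8)

    for step in range(b):
        t = t_start + step
        # (1) membrane inputs from x^t
        for i in range(n_rec):
            s_now[i] = -h[i]
        for j in range(n_tot):
            if x[j] == 1:
                for i in range(n_rec):
                    s_now[i] += W[i, j]
        # (2) per-neuron log-likelihood ratios from s^{t-1}
        if t == 0:
            for i in range(n_rec):
                lr[i] = 0.0
        else:
            for i in range(n_rec):
                p = p_max * _sigmoid(s_prev[i])
                if x[i] == 1:
                    pobs = p
                    Z = avg_p[i]
                else:
                    pobs = 1.0 - p
                    Z = 1.0 - avg_p[i]
                if Z <= delta:
                    Z = delta
                if pobs < 1e-300:
                    pobs = 1e-300
                lr[i] = math.log(pobs / Z)
        # global signals over the scope
        m = 0.0
        g1 = 0.0
        g3 = 0.0
        g4 = 0.0
        sum_lr = 0.0
        sum_avg_lr = 0.0
        for i in range(n_rec):
            if scope_mask[i]:
                if x[i] == 1:
                    m += 1.0
                    g3 += avg_p[i] - p0
                if aprime:
                    sum_lr += lr[i]
                    sum_avg_lr += avg_lr[i]
                else:
                    den = avg_lr[i]
                    if den <= delta:
                        den = delta
                    g1 += lr[i] / den
                d = s_now[i] - s0
                g4 += d * d
        if aprime:
            den = sum_avg_lr
            if den <= delta:
                den = delta
            g1 = sum_lr / den
        g2 = kappa * (0.5 * m * (m - 1.0) - (avg_m[0] - p0) * m)
        g3 = eta * g3
        g4 = 0.5 * zeta * g4
        combined = g1 - g2 - g3 - g4
        acc[0] += g1
        acc[1] += g2
        acc[2] += g3
        acc[3] += g4
        acc[4] += combined
        acc[5] += m
        acc[6] += 1.0
        # (3) parameter update from traces up to (psi^{t-1}, x^{t-1})
        c1 = c1base * combined
        if apply_updates:
            for i in range(n_rec):
                if row_mask[i]:
                    ds = s_now[i] - s0
                    h[i] += -c1 * elig_post[i] + c2 * ds
                    for j in range(n_tot):
                        if col_mask[j] and j != i:
                            dw = c1 * elig_pair[i, j]
                            if x[j] == 1:
                                dw -= c2 * ds
                            W[i, j] += dw
        if accumulate and t >= warmup:
            acc[7] += 1.0
            for i in range(n_rec):
                if row_mask[i]:
                    ds = s_now[i] - s0
                    grad_h[i] += -c1 * elig_post[i] + c2 * ds
                    for j in range(n_tot):
                        if col_mask[j] and j != i:
                            dw = c1 * elig_pair[i, j]
                            if x[j] == 1:
                                dw -= c2 * ds
                            grad_W[i, j] += dw
        # (4) sample x^{t+1}
        for i in range(n_rec):
            sig_now[i] = _sigmoid(s_now[i])
            x_new[i] = 1 if u[step, i] < p_max * sig_now[i] else 0
        # (5) psi^t and eligibility traces with (psi^t, x^t)
        for i in range(n_rec):
            for j in range(n_tot):
                elig_pair[i, j] *= keep_tau
            elig_post[i] *= keep_tau
        for i in range(n_rec):
            sig = sig_now[i]
            if x_new[i] == 1:
                psi = 1.0 - sig
            else:
                denom = 1.0 - p_max * sig
                if denom < 1e-12:
                    denom = 1e-12
                psi = -p_max * sig * (1.0 - sig) / denom
            elig_post[i] += inv_tau * psi
            contrib = inv_tau * psi
            for j in range(n_tot):
                if x[j] == 1:
                    elig_pair[i, j] += contrib
        # (6) slow averages with step-t quantities
        avg_m[0] = keep_T * avg_m[0] + inv_T * m
        for i in range(n_rec):
            avg_p[i] = keep_T * avg_p[i] + inv_T * (p_max * sig_now[i])
            avg_lr[i] = keep_T * avg_lr[i] + inv_T * lr[i]
        # shift state
        for i in range(n_rec):
            s_prev[i] = s_now[i]
            x[i] = x_new[i]
        for j in range(n_ext):
            x[n_rec + j] = stim[step, j]
        if record_spikes:
            for i in range(n_rec):
                out_spikes[step, i] = x[i]
            for j in range(n_ext):
                out_spikes[step, n_rec + j] = x[n_rec + j]
        if record_s:
            for i in range(n_rec):
                out_s[step, i] = s_now[i]


@njit(cache=True)
def lif_run(current, tau_m, theta, v_rest, noise_coef, t_ref, dt, n_steps, noise):
    """Integrate one leaky integrate-and-fire neuron; returns the spike count.

    Euler-Maruyama with step dt; after a threshold crossing the voltage is
    clamped at rest for the refractory period.
    """
    v = v_rest
    sqrt_dt = math.sqrt(dt)
    ref_steps = int(round(t_ref / dt))
    ref_left = 0
    n_spikes = 0
    has_noise = noise.shape[0] > 0
    for k in range(n_steps):
        if ref_left > 0:
            ref_left -= 1
            continue
        dv = (-v + v_rest + current) * dt / tau_m
        if has_noise:
            dv += noise_coef * sqrt_dt * noise[k] / tau_m
        v += dv
        if v > theta:
            v = v_rest
            ref_left = ref_steps
            n_spikes += 1
    return n_spikes
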