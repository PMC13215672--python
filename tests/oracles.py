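"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's sequential Monte Carlo machinery:
posteriors are computed by exhaustive enumeration of discrete sequences
with the Gaussian baseline integrated out by Kalman prediction-error
decomposition, and densities are checked by quadrature.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln, logsumexp


def kernel_by_recursion(gamma1, gamma2, a, t_max):
    """Single-spike response by direct iteration of the AR(2) recursion."""
    c = np.zeros(t_max)
    c[0] = a
    if t_max > 1:
        c[1] = gamma1 * c[0]
    for t in range(2, t_max):
        c[t] = gamma1 * c[t - 1] + gamma2 * c[t - 2]
    return c


def calcium_by_recursion(s, gamma1, gamma2, a, c0):
    c = np.zeros(len(s))
    c[0] = c0 + a * s[0]
    if len(s) > 1:
        c[1] = gamma1 * c[0] + a * s[1]
    for t in range(2, len(s)):
        c[t] = gamma1 * c[t - 1] + gamma2 * c[t - 2] + a * s[t]
    return c


def _kalman_loglik(y, sigma2, vb):
    """log N(y_1:T) for y_t = b_t + noise, b a random walk with
    b_1 ~ N(0,1); vectorized over rows of y (shape (M, T))."""
    m_, t_ = y.shape
    mu = np.zeros(m_)
    p = np.ones(m_)
    ll = np.zeros(m_)
    for t in range(t_):
        pv = p + (vb if t > 0 else 0.0)
        s = pv + sigma2
        resid = y[:, t] - mu
        ll += -0.5 * np.log(2 * np.pi * s) - resid**2 / (2 * s)
        gain = pv / s
        mu = mu + gain * resid
        p = pv * (1 - gain)
    return ll


def posterior_by_enumeration(f, dt, theta, gamma1, gamma2, a, s_max):
    """Exact single-site posterior marginals of (s_t, q_t) for a short
    trace, enumerating all spike sequences and marginalizing the regimes
    by the forward-backward algorithm and the baseline by Kalman.

    Returns (s_marginals (T, s_max+1), q1_marginals (T,)).
    """
    t_steps = len(f)
    seqs = np.array(
        list(itertools.product(range(s_max + 1), repeat=t_steps)), dtype=np.int64
    )
    m_ = len(seqs)

    # baseline/noise part: Gaussian loglik of residuals after calcium
    c_all = np.zeros((m_, t_steps))
    c_all[:, 0] = theta.c0 + a * seqs[:, 0]
    if t_steps > 1:
        c_all[:, 1] = gamma1 * c_all[:, 0] + a * seqs[:, 1]
    for t in range(2, t_steps):
        c_all[:, t] = (
            gamma1 * c_all[:, t - 1] + gamma2 * c_all[:, t - 2] + a * seqs[:, t]
        )
    ll_gauss = _kalman_loglik(f[None, :] - c_all, theta.sigma2, theta.sigma2_b * dt)

    # regime part: forward algorithm over the 2-state chain
    w = theta.transition_matrix(dt)
    rates = theta.rates() * dt
    with np.errstate(divide="ignore"):
        log_w = np.log(w)
    log_pois = (
        seqs[:, :, None] * np.log(rates)[None, None, :]
        - rates[None, None, :]
        - gammaln(seqs + 1.0)[:, :, None]
    )  # (M, T, 2)
    log_alpha = np.log(0.5) + log_pois[:, 0, :]  # (M, 2)
    alphas = [log_alpha]
    for t in range(1, t_steps):
        log_alpha = (
            logsumexp(log_alpha[:, :, None] + log_w[None, :, :], axis=1)
            + log_pois[:, t, :]
        )
        alphas.append(log_alpha)
    ll_chain = logsumexp(log_alpha, axis=1)

    log_weight = ll_gauss + ll_chain
    log_weight -= logsumexp(log_weight)
    weight = np.exp(log_weight)

    s_marg = np.zeros((t_steps, s_max + 1))
    for t in range(t_steps):
        for k in range(s_max + 1):
            s_marg[t, k] = weight[seqs[:, t] == k].sum()

    # backward pass for q marginals
    log_beta = np.zeros((m_, 2))
    q1 = np.zeros(t_steps)
    for t in range(t_steps - 1, -1, -1):
        log_post = alphas[t] + log_beta
        log_post -= logsumexp(log_post, axis=1, keepdims=True)
        q1[t] = np.dot(weight, np.exp(log_post[:, 1]))
        if t > 0:
            log_beta = logsumexp(
                log_w[None, :, :] + (log_pois[:, t, :] + log_beta)[:, None, :],
                axis=2,
            )
    return s_marg, q1
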