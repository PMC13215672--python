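"""Numba-compiled inner loop of the conditional SMC sweep.

This mirrors the pure-numpy sweep in :mod:`pgbar.pgas` exactly (same
proposal, same ancestor rule, same weight formula); only the arithmetic is
fused into explicit loops.  The numpy implementation remains the reference
against which this one is validated.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _searchsorted_right(cdf, u):
    lo, hi = 0, cdf.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if cdf[mid] <= u:
            lo = mid + 1
        else:
            hi = mid
    if lo >= cdf.shape[0]:
        lo = cdf.shape[0] - 1
    return lo


@njit(cache=True)
def sweep_core(
    f,
    q_ref,
    s_ref,
    b_ref,
    log_w_mat,
    log_pois,
    g1,
    g2,
    a,
    c0,
    s2,
    vb,
    rates_dt,
    n,
    s_max,
    seed,
    corrupt,
    ancestor_sampling,
    as_lookahead,
):
    """Run one conditional SMC sweep; returns (status, t_fail, q, s, c, b).

    status 0 = ok, 1 = degenerate weights, 2 = proposal underflow.

    Ancestor scores include the future observation-likelihood ratio of the
    glued trajectory: switching ancestry changes the reference's calcium,
    whose discrepancy propagates homogeneously through the AR(2) recursion
    and is summed against the reference residuals until it decays below
    tolerance (or ``as_lookahead`` steps).
    """
    np.random.seed(seed)
    big_t = f.shape[0]
    n_s = s_max + 1
    vz = s2 + vb
    inv2vz = 0.5 / vz
    log_norm_z = -0.5 * np.log(2.0 * np.pi * vz)
    log_norm_obs = -0.5 * np.log(2.0 * np.pi * s2)
    var_prop = 1.0 / (1.0 / s2 + 1.0 / vb)
    sd_prop = np.sqrt(var_prop)
    delta_tol = 1e-3 * np.sqrt(s2)

    # reference calcium along its own history, and its residuals
    c_ref = np.empty(big_t)
    c_ref[0] = c0 + a * s_ref[0]
    if big_t > 1:
        c_ref[1] = g1 * c_ref[0] + a * s_ref[1]
    for t in range(2, big_t):
        c_ref[t] = g1 * c_ref[t - 1] + g2 * c_ref[t - 2] + a * s_ref[t]
    resid_ref = np.empty(big_t)
    for t in range(big_t):
        resid_ref[t] = f[t] - c_ref[t] - b_ref[t]

    hist_q = np.empty((big_t, n), dtype=np.int8)
    hist_s = np.empty((big_t, n), dtype=np.int64)
    hist_c = np.empty((big_t, n))
    hist_b = np.empty((big_t, n))
    hist_anc = np.zeros((big_t, n), dtype=np.int64)

    q = np.empty(n, dtype=np.int64)
    s = np.empty(n, dtype=np.int64)
    b = np.empty(n)
    c1 = np.empty(n)
    c2 = np.zeros(n)
    log_w = np.empty(n)

    for i in range(n - 1):
        q[i] = np.random.randint(0, 2)
        s[i] = np.random.poisson(rates_dt[q[i]])
        b[i] = np.random.normal(0.0, 1.0)
    q[n - 1] = q_ref[0]
    s[n - 1] = s_ref[0]
    b[n - 1] = b_ref[0]
    for i in range(n):
        c1[i] = c0 + a * s[i]
        r = f[0] - c1[i] - b[i]
        log_w[i] = log_norm_obs - r * r / (2.0 * s2)
        if corrupt:
            log_w[i] += 0.2 * s[i]
    hist_q[0] = q.astype(np.int8)
    hist_s[0] = s
    hist_c[0] = c1
    hist_b[0] = b

    cdf = np.empty(n)
    score_cdf = np.empty(n)
    score_buf = np.empty(n)
    log_tab = np.empty(2 * n_s)
    p_tab = np.empty(2 * n_s)
    anc = np.empty(n, dtype=np.int64)
    q_new = np.empty(n, dtype=np.int64)
    s_new = np.empty(n, dtype=np.int64)
    c1_new = np.empty(n)
    c2_new = np.empty(n)
    b_new = np.empty(n)
    log_w_new = np.empty(n)

    for t in range(1, big_t):
        m = log_w[0]
        for i in range(1, n):
            if log_w[i] > m:
                m = log_w[i]
        if not np.isfinite(m):
            return 1, t, hist_s[0], hist_s[0], hist_c[0], hist_b[0]
        acc = 0.0
        for i in range(n):
            acc += np.exp(log_w[i] - m)
            cdf[i] = acc
        for i in range(n - 1):
            anc[i] = _searchsorted_right(cdf, np.random.random() * acc)

        # ancestor sampling for the reference particle (stochastic factors)
        if not ancestor_sampling:
            anc[n - 1] = n - 1
        if ancestor_sampling:
            sc_max = -np.inf
            for i in range(n):
                sc = (
                    log_w[i]
                    - m
                    + log_w_mat[q[i], q_ref[t]]
                    - (b_ref[t] - b[i]) ** 2 / (2.0 * vb)
                )
                # glued-calcium observation correction over the future
                d1 = (g1 * c1[i] + g2 * c2[i] + a * s_ref[t]) - c_ref[t]
                d2 = c1[i] - c_ref[t - 1]
                if abs(d1) + abs(d2) > delta_tol:
                    u_end = min(big_t, t + as_lookahead)
                    corr = 0.0
                    for u in range(t, u_end):
                        corr += d1 * (2.0 * resid_ref[u] - d1)
                        d_new = g1 * d1 + g2 * d2
                        d2 = d1
                        d1 = d_new
                        if abs(d1) + abs(d2) < delta_tol:
                            break
                    sc += corr / (2.0 * s2)
                score_buf[i] = sc
                if sc > sc_max:
                    sc_max = sc
            sacc = 0.0
            for i in range(n):
                sacc += np.exp(score_buf[i] - sc_max)
                score_cdf[i] = sacc
            if np.isfinite(sc_max) and sacc > 0.0:
                anc[n - 1] = _searchsorted_right(
                    score_cdf, np.random.random() * sacc
                )
            else:
                anc[n - 1] = _searchsorted_right(cdf, np.random.random() * acc)

        for i in range(n):
            j = anc[i]
            c_pred = g1 * c1[j] + g2 * c2[j]
            resid0 = f[t] - b[j] - c_pred
            tm = -np.inf
            for qi in range(2):
                base = log_w_mat[q[j], qi]
                for si in range(n_s):
                    r = resid0 - a * si
                    v = base + log_pois[qi, si] + log_norm_z - r * r * inv2vz
                    log_tab[qi * n_s + si] = v
                    if v > tm:
                        tm = v
            if not np.isfinite(tm):
                return 2, t, hist_s[0], hist_s[0], hist_c[0], hist_b[0]
            tot = 0.0
            for k in range(2 * n_s):
                d = log_tab[k] - tm
                # terms below exp(-40) are lost to double rounding anyway
                p = np.exp(d) if d > -40.0 else 0.0
                p_tab[k] = p
                tot += p
            log_z = tm + np.log(tot)
            log_w_new[i] = log_z

            if i < n - 1:
                u = np.random.random() * tot
                run = 0.0
                idx = 2 * n_s - 1
                for k in range(2 * n_s):
                    run += p_tab[k]
                    if run > u:
                        idx = k
                        break
                q_new[i] = idx // n_s
                s_new[i] = idx % n_s
                c1_new[i] = c_pred + a * s_new[i]
                mu = (b[j] * s2 + (f[t] - c1_new[i]) * vb) / vz
                b_new[i] = mu + sd_prop * np.random.normal(0.0, 1.0)
            else:
                q_new[i] = q_ref[t]
                s_new[i] = s_ref[t]
                c1_new[i] = c_pred + a * s_new[i]
                b_new[i] = b_ref[t]
            c2_new[i] = c1[j]
            if corrupt:
                log_w_new[i] += 0.2 * s_new[i]

        for i in range(n):
            q[i] = q_new[i]
            s[i] = s_new[i]
            c1[i] = c1_new[i]
            c2[i] = c2_new[i]
            b[i] = b_new[i]
            log_w[i] = log_w_new[i]
        hist_q[t] = q.astype(np.int8)
        hist_s[t] = s
        hist_c[t] = c1
        hist_b[t] = b
        hist_anc[t] = anc

    m = log_w[0]
    for i in range(1, n):
        if log_w[i] > m:
            m = log_w[i]
    if not np.isfinite(m):
        return 1, big_t - 1, hist_s[0], hist_s[0], hist_c[0], hist_b[0]
    acc = 0.0
    for i in range(n):
        acc += np.exp(log_w[i] - m)
        cdf[i] = acc
    k = _searchsorted_right(cdf, np.random.random() * acc)

    out_q = np.empty(big_t, dtype=np.int64)
    out_s = np.empty(big_t, dtype=np.int64)
    out_c = np.empty(big_t)
    out_b = np.empty(big_t)
    i = k
    for t in range(big_t - 1, -1, -1):
        out_q[t] = hist_q[t, i]
        out_s[t] = hist_s[t, i]
        out_c[t] = hist_c[t, i]
        out_b[t] = hist_b[t, i]
        i = hist_anc[t, i]
    return 0, -1, out_q, out_s, out_c, out_b
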