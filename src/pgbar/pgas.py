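"""Conditional sequential Monte Carlo with ancestor sampling.

One sweep regenerates a full latent trajectory given a reference trajectory
and fixed parameters, using the analytically available optimal proposal:
the regime/spike-count pair is drawn from a closed-form probability table
(baseline integrated out), calcium propagates deterministically, and the
baseline is drawn from its Gaussian full conditional.  Importance weights
equal the proposal-table normalizer.

Calcium is a deterministic function of the spike history, so it is treated
as a derived component: ancestor probabilities score only the stochastic
factors (regime switch, Poisson count, baseline increment) and the
reference particle's calcium is re-propagated through whichever ancestry it
is attached to.  A literal delta-function treatment would make ancestor
reassignment impossible for a continuous deterministic component.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ._kernels import HAVE_NUMBA as _HAVE_NUMBA
from .model import (
    ContractViolation,
    DomainError,
    FluorescenceTrace,
    KernelCoefficients,
    LatentState,
    ModelParameters,
    calcium_from_spikes,
    kinetics_to_ar,
)

__all__ = [
    "DEFAULT_S_MAX",
    "LatentTrajectory",
    "ParticleSystem",
    "ProposalTable",
    "NumericalError",
    "build_proposal_table",
    "sample_baseline",
    "propagate_calcium",
    "ancestor_weights",
    "pgas_sweep",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: Spike-count cutoff per time step used when enumerating the optimal
#: proposal's support {0, ..., DEFAULT_S_MAX}.
DEFAULT_S_MAX = 20


class NumericalError(RuntimeError):
    """Raised when weights or proposal tables degenerate numerically."""

    def __init__(self, message: str, t: int | None = None):
        super().__init__(message if t is None else f"{message} (time index {t})")
        self.t = t


@dataclass
class LatentTrajectory:
    """Arrays ``q``, ``s``, ``c``, ``b`` of equal length T; ``c[t]`` is the
    calcium level at step t (the pair view is ``[c[t], c[t-1]]``)."""

    q: np.ndarray
    s: np.ndarray
    c: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=np.int8)
        self.s = np.asarray(self.s, dtype=np.int64)
        self.c = np.asarray(self.c, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        lengths = {len(self.q), len(self.s), len(self.c), len(self.b)}
        if len(lengths) != 1:
            raise ContractViolation("trajectory components differ in length")

    def __len__(self) -> int:
        return len(self.q)

    def state_at(self, t: int) -> LatentState:
        c_prev = self.c[t - 1] if t > 0 else 0.0
        return LatentState(
            q=int(self.q[t]),
            s=int(self.s[t]),
            c_vec=np.array([self.c[t], c_prev]),
            b=float(self.b[t]),
        )

    def recompute_calcium(self, coeffs: KernelCoefficients, c0: float) -> None:
        self.c = calcium_from_spikes(self.s, coeffs, c0=c0)


@dataclass
class ParticleSystem:
    """N weighted particles at the current time step, plus per-step history
    and ancestry buffers (shape ``(T, N)``)."""

    n: int
    s_max: int
    q: np.ndarray
    s: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    b: np.ndarray
    log_w: np.ndarray
    hist_q: np.ndarray = field(repr=False, default=None)
    hist_s: np.ndarray = field(repr=False, default=None)
    hist_c: np.ndarray = field(repr=False, default=None)
    hist_b: np.ndarray = field(repr=False, default=None)
    hist_anc: np.ndarray = field(repr=False, default=None)
    hist_log_w: np.ndarray = field(repr=False, default=None)

    def states(self) -> list[LatentState]:
        return [
            LatentState(
                q=int(self.q[i]),
                s=int(self.s[i]),
                c_vec=np.array([self.c1[i], self.c2[i]]),
                b=float(self.b[i]),
            )
            for i in range(self.n)
        ]


@dataclass(frozen=True)
class ProposalTable:
    """Normalized joint proposal over (regime, spike count) and its
    pre-normalization sum ``z`` (the importance weight)."""

    probs: np.ndarray  # (2, s_max+1)
    z: float
    log_z: float


def _log_transition_matrix(theta: ModelParameters, dt: float) -> np.ndarray:
    w = theta.transition_matrix(dt)
    with np.errstate(divide="ignore"):
        return np.log(w)


def _log_poisson_grid(theta: ModelParameters, dt: float, s_max: int) -> np.ndarray:
    """(2, s_max+1) table of Poisson log-pmfs under each regime's rate."""
    s = np.arange(s_max + 1, dtype=float)
    rates = theta.rates() * dt
    out = np.empty((2, s_max + 1))
    for qi, rate in enumerate(rates):
        if rate == 0.0:
            out[qi] = np.where(s == 0, 0.0, -np.inf)
        else:
            out[qi] = s * math.log(rate) - rate - gammaln(s + 1.0)
    return out


def build_proposal_table(
    x_prev: LatentState,
    f: float,
    theta: ModelParameters,
    coeffs: KernelCoefficients,
    dt: float,
    s_max: int = DEFAULT_S_MAX,
    t: int | None = None,
) -> ProposalTable:
    """Closed-form optimal proposal over (q', s') given the previous state
    and the current observation, with the baseline integrated out.

    Entry (q', s') is proportional to

        W[q_prev, q'] * Poisson(s'; r_q' dt) * I(b_prev, f - c(s'), sb2*dt, s2)

    where ``c(s')`` is the deterministically propagated calcium and ``I`` is
    the Gaussian convolution integral.  Computed in log space.
    """
    log_w_mat = _log_transition_matrix(theta, dt)
    log_pois = _log_poisson_grid(theta, dt, s_max)
    s_grid = np.arange(s_max + 1, dtype=float)
    c_pred = coeffs.gamma1 * x_prev.c_vec[0] + coeffs.gamma2 * x_prev.c_vec[1]
    v = theta.sigma2 + theta.sigma2_b * dt
    resid = (f - x_prev.b - c_pred) - coeffs.a * s_grid
    log_i = -0.5 * (_LOG_2PI + math.log(v)) - resid**2 / (2.0 * v)
    log_table = log_w_mat[x_prev.q][:, None] + log_pois + log_i[None, :]
    m = np.max(log_table)
    if not np.isfinite(m):
        raise NumericalError("proposal table underflowed to zero", t=t)
    z_rel = np.exp(log_table - m)
    total = z_rel.sum()
    log_z = m + math.log(total)
    return ProposalTable(probs=z_rel / total, z=math.exp(log_z), log_z=log_z)


def sample_baseline(
    b_prev: float,
    c_t: float,
    f: float,
    theta: ModelParameters,
    dt: float,
    rng: np.random.Generator,
) -> float:
    """Draw the baseline from its Gaussian full conditional: a precision-
    weighted compromise between the random-walk prediction and the
    observation residual."""
    vb = theta.sigma2_b * dt
    s2 = theta.sigma2
    if s2 <= 0 or vb <= 0:
        raise DomainError("sigma2 and sigma2_b*dt must be positive")
    mu = (b_prev * s2 + (f - c_t) * vb) / (s2 + vb)
    var = 1.0 / (1.0 / s2 + 1.0 / vb)
    return mu + math.sqrt(var) * rng.standard_normal()


def propagate_calcium(
    c_vec_prev: np.ndarray, s: int, coeffs: KernelCoefficients
) -> np.ndarray:
    """Deterministic one-step calcium update ``C_t = M C_{t-1} + a [s, 0]``."""
    c_prev = np.asarray(c_vec_prev, dtype=float)
    return np.array(
        [
            coeffs.gamma1 * c_prev[0] + coeffs.gamma2 * c_prev[1] + coeffs.a * s,
            c_prev[0],
        ]
    )


def ancestor_weights(
    particles: ParticleSystem,
    x_ref_t: LatentState,
    theta: ModelParameters,
    dt: float,
) -> np.ndarray:
    """Probability vector over particles for the reference's ancestor.

    Scores combine the previous importance weights with the stochastic
    transition factors towards the reference state (regime switch, Poisson
    count, baseline increment); the deterministic calcium component is
    excluded by design.
    """
    log_w_mat = _log_transition_matrix(theta, dt)
    rate = theta.rates()[x_ref_t.q] * dt
    if rate == 0.0:
        log_pois = 0.0 if x_ref_t.s == 0 else -np.inf
    else:
        log_pois = x_ref_t.s * math.log(rate) - rate - float(gammaln(x_ref_t.s + 1))
    vb = theta.sigma2_b * dt
    score = (
        particles.log_w
        + log_w_mat[particles.q, x_ref_t.q]
        + log_pois
        - 0.5 * (_LOG_2PI + math.log(vb))
        - (x_ref_t.b - particles.b) ** 2 / (2.0 * vb)
    )
    m = np.max(score)
    if not np.isfinite(m):
        warnings.warn(
            "all ancestor scores vanished; falling back to plain resampling",
            RuntimeWarning,
        )
        score = particles.log_w - np.max(particles.log_w)
        p = np.exp(score)
        return p / p.sum()
    p = np.exp(score - m)
    return p / p.sum()


def _as_lookahead(coeffs: KernelCoefficients) -> int:
    # eight decay constants: the propagated calcium discrepancy shrinks by
    # e^-8 over this window
    return int(math.ceil(-8.0 / coeffs.g_plus)) + 2


def _sweep_numba(
    trace: FluorescenceTrace,
    x_ref: LatentTrajectory,
    theta: ModelParameters,
    coeffs: KernelCoefficients,
    n_particles: int,
    rng: np.random.Generator,
    s_max: int,
    corrupt_weights: bool,
    ancestor_sampling: bool,
) -> LatentTrajectory:
    from ._kernels import sweep_core

    dt = trace.dt
    seed = int(rng.integers(0, 2**31 - 1))
    status, t_fail, q, s, c, b = sweep_core(
        trace.values,
        x_ref.q.astype(np.int64),
        x_ref.s.astype(np.int64),
        x_ref.b,
        _log_transition_matrix(theta, dt),
        _log_poisson_grid(theta, dt, s_max),
        coeffs.gamma1,
        coeffs.gamma2,
        coeffs.a,
        theta.c0,
        theta.sigma2,
        theta.sigma2_b * dt,
        theta.rates() * dt,
        n_particles,
        s_max,
        seed,
        corrupt_weights,
        ancestor_sampling,
        _as_lookahead(coeffs),
    )
    if status == 1:
        raise NumericalError("particle weights degenerated", t=t_fail)
    if status == 2:
        raise NumericalError("proposal table underflowed to zero", t=t_fail)
    return LatentTrajectory(q=q, s=s, c=c, b=b)


def _categorical_rows(
    log_p: np.ndarray, log_norm: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Vectorized categorical draw per row of a log-probability matrix."""
    p = np.exp(log_p - log_norm[:, None])
    cp = np.cumsum(p, axis=1)
    idx = np.sum(cp < u[:, None] * cp[:, -1:], axis=1)
    return np.minimum(idx, log_p.shape[1] - 1)


def pgas_sweep(
    trace: FluorescenceTrace,
    x_ref: LatentTrajectory,
    theta: ModelParameters,
    n_particles: int,
    rng: np.random.Generator,
    s_max: int = DEFAULT_S_MAX,
    coeffs: KernelCoefficients | None = None,
    corrupt_weights: bool = False,
    return_particles: bool = False,
    backend: str = "auto",
    ancestor_sampling: bool = True,
):
    """One conditional SMC sweep with ancestor sampling.

    Parameters
    ----------
    trace : FluorescenceTrace
        Observed fluorescence, length T.
    x_ref : LatentTrajectory
        Reference trajectory (its ``q``, ``s``, ``b`` are conditioned on;
        calcium is re-propagated internally).
    theta : ModelParameters
        Current parameter values.
    n_particles : int
        Number of particles N (>= 2).
    rng : numpy Generator
        Randomness source.
    s_max : int
        Per-step spike-count cutoff of the proposal support.
    coeffs : KernelCoefficients, optional
        Precomputed AR coefficients (derived from ``theta`` otherwise).
    corrupt_weights : bool
        Testing hook: deliberately biases the weight formula so that
        sampler-validation diagnostics must detect the error.  Never use
        for inference.
    return_particles : bool
        Also return the full :class:`ParticleSystem` with history buffers
        (forces the numpy backend).
    backend : {"auto", "numpy", "numba"}
        "auto" uses the compiled kernel when available.  Both backends
        implement the identical algorithm; the numpy one is the reference.

    Returns
    -------
    LatentTrajectory, or ``(LatentTrajectory, ParticleSystem)``.
    """
    f = trace.values
    big_t = len(f)
    dt = trace.dt
    if len(x_ref) != big_t:
        raise ContractViolation(
            f"reference length {len(x_ref)} != trace length {big_t}"
        )
    if n_particles < 2:
        raise DomainError("n_particles must be >= 2")
    theta.validate(dt)
    if theta.sigma2_b <= 0:
        raise DomainError("pgas_sweep requires sigma2_b > 0")
    if coeffs is None:
        coeffs = kinetics_to_ar(theta.tau_r, theta.tau_d, theta.a_max, dt)

    if backend not in ("auto", "numpy", "numba"):
        raise DomainError(f"unknown backend {backend!r}")
    if backend == "auto":
        backend = "numba" if (_HAVE_NUMBA and not return_particles) else "numpy"
    if backend == "numba":
        if not _HAVE_NUMBA:
            raise DomainError("numba backend requested but numba is missing")
        if return_particles:
            raise DomainError("return_particles requires the numpy backend")
        return _sweep_numba(
            trace, x_ref, theta, coeffs, n_particles, rng, s_max,
            corrupt_weights, ancestor_sampling,
        )

    n = n_particles
    s_grid = np.arange(s_max + 1, dtype=float)
    n_cat = 2 * (s_max + 1)
    log_w_mat = _log_transition_matrix(theta, dt)
    log_pois = _log_poisson_grid(theta, dt, s_max)
    g1, g2, a = coeffs.gamma1, coeffs.gamma2, coeffs.a
    s2 = theta.sigma2
    vb = theta.sigma2_b * dt
    vz = s2 + vb
    log_norm_z = -0.5 * (_LOG_2PI + math.log(vz))
    var_prop = 1.0 / (1.0 / s2 + 1.0 / vb)
    sd_prop = math.sqrt(var_prop)
    rates_dt = theta.rates() * dt
    delta_tol = 1e-3 * math.sqrt(s2)
    as_lookahead = _as_lookahead(coeffs)

    q_ref, s_ref, b_ref = x_ref.q, x_ref.s, x_ref.b
    c_ref = calcium_from_spikes(s_ref, coeffs, c0=theta.c0)
    resid_ref = f - c_ref - b_ref

    hist_q = np.empty((big_t, n), dtype=np.int8)
    hist_s = np.empty((big_t, n), dtype=np.int64)
    hist_c = np.empty((big_t, n))
    hist_b = np.empty((big_t, n))
    hist_anc = np.zeros((big_t, n), dtype=np.int64)
    hist_log_w = np.empty((big_t, n))

    # --- initialization: N-1 prior draws, slot N-1 pinned to the reference
    q = rng.integers(0, 2, size=n).astype(np.int8)
    s = rng.poisson(rates_dt[q]).astype(np.int64)
    b = rng.standard_normal(n)
    q[n - 1] = q_ref[0]
    s[n - 1] = s_ref[0]
    b[n - 1] = b_ref[0]
    c1 = theta.c0 + a * s
    c2 = np.zeros(n)
    # proposal equals the initial density, so weights reduce to the
    # observation density
    log_w = -0.5 * (_LOG_2PI + math.log(s2)) - (f[0] - c1 - b) ** 2 / (2.0 * s2)
    if corrupt_weights:
        log_w = log_w + 0.2 * s
    hist_q[0], hist_s[0], hist_c[0], hist_b[0] = q, s, c1, b
    hist_log_w[0] = log_w

    for t in range(1, big_t):
        m = np.max(log_w)
        if not np.isfinite(m):
            raise NumericalError("particle weights degenerated", t=t)
        w_rel = np.exp(log_w - m)
        cdf = np.cumsum(w_rel)
        # multinomial resampling of N-1 ancestors
        anc = np.empty(n, dtype=np.int64)
        u = rng.random(n - 1) * cdf[-1]
        anc[: n - 1] = np.minimum(np.searchsorted(cdf, u), n - 1)
        # ancestor sampling for the reference particle: stochastic factors
        # towards the reference state, plus the future observation-
        # likelihood correction for the glued calcium
        score = (
            (log_w - m)
            + log_w_mat[q, q_ref[t]]
            - (b_ref[t] - b) ** 2 / (2.0 * vb)
        )
        if ancestor_sampling:
            d1 = (g1 * c1 + g2 * c2 + a * s_ref[t]) - c_ref[t]
            d2 = c1 - c_ref[t - 1]
            corr = np.zeros(n)
            active = np.abs(d1) + np.abs(d2) > delta_tol
            u_end = min(big_t, t + as_lookahead)
            u = t
            while active.any() and u < u_end:
                corr[active] += d1[active] * (2.0 * resid_ref[u] - d1[active])
                d1, d2 = g1 * d1 + g2 * d2, d1
                active &= np.abs(d1) + np.abs(d2) > delta_tol
                u += 1
            score = score + corr / (2.0 * s2)
            sm = np.max(score)
            if np.isfinite(sm):
                ps = np.exp(score - sm)
            else:
                warnings.warn(
                    "all ancestor scores vanished; falling back to plain "
                    "resampling",
                    RuntimeWarning,
                )
                ps = w_rel
            cps = np.cumsum(ps)
            anc[n - 1] = min(
                np.searchsorted(cps, rng.random() * cps[-1]), n - 1
            )
        else:
            anc[n - 1] = n - 1

        qa = q[anc]
        ba = b[anc]
        c1a = c1[anc]
        c_pred = g1 * c1a + g2 * c2[anc]

        resid0 = f[t] - ba - c_pred
        log_like = (
            -((resid0[:, None] - a * s_grid[None, :]) ** 2) / (2.0 * vz)
            + log_norm_z
        )
        log_table = (
            log_w_mat[qa][:, :, None]
            + log_pois[None, :, :]
            + log_like[:, None, :]
        ).reshape(n, n_cat)
        tm = np.max(log_table, axis=1)
        if not np.all(np.isfinite(tm)):
            raise NumericalError("proposal table underflowed to zero", t=t)
        log_z = tm + np.log(np.exp(log_table - tm[:, None]).sum(axis=1))

        idx = _categorical_rows(log_table, log_z, rng.random(n))
        q = (idx // (s_max + 1)).astype(np.int8)
        s = (idx % (s_max + 1)).astype(np.int64)
        q[n - 1] = q_ref[t]
        s[n - 1] = s_ref[t]
        # calcium re-propagated along the (possibly reassigned) ancestry
        c_new = c_pred + a * s
        mu = (ba * s2 + (f[t] - c_new) * vb) / vz
        b = mu + sd_prop * rng.standard_normal(n)
        b[n - 1] = b_ref[t]

        c2 = c1a
        c1 = c_new
        log_w = log_z
        if corrupt_weights:
            log_w = log_w + 0.2 * s

        hist_q[t], hist_s[t], hist_c[t], hist_b[t] = q, s, c1, b
        hist_anc[t] = anc
        hist_log_w[t] = log_w

    # final trajectory draw proportional to the terminal weights
    m = np.max(log_w)
    if not np.isfinite(m):
        raise NumericalError("terminal weights degenerated", t=big_t - 1)
    w_rel = np.exp(log_w - m)
    cdf = np.cumsum(w_rel)
    k = min(np.searchsorted(cdf, rng.random() * cdf[-1]), n - 1)

    out_q = np.empty(big_t, dtype=np.int8)
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
    traj = LatentTrajectory(q=out_q, s=out_s, c=out_c, b=out_b)

    if return_particles:
        system = ParticleSystem(
            n=n,
            s_max=s_max,
            q=q,
            s=s,
            c1=c1,
            c2=c2,
            b=b,
            log_w=log_w,
            hist_q=hist_q,
            hist_s=hist_s,
            hist_c=hist_c,
            hist_b=hist_b,
            hist_anc=hist_anc,
            hist_log_w=hist_log_w,
        )
        return traj, system
    return traj
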