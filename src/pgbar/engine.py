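"""Gibbs orchestration: alternating PGAS trajectory draws with parameter
updates, plus initialization and sampler-correctness diagnostics."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    DomainError,
    FluorescenceTrace,
    ModelParameters,
    calcium_from_spikes,
    kinetics_to_ar,
)
from .pgas import DEFAULT_S_MAX, LatentTrajectory, NumericalError, pgas_sweep
from .priors import PriorSpec
from .simulate import simulate_trace
from .updates import (
    MHState,
    compute_stats,
    update_baseline_variance,
    update_firing_rates,
    update_kernel_params_mh,
    update_noise_variance,
    update_transition_rates,
)

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "initialize",
    "run_sampler",
    "geweke_check",
]

_THETA_COLS = (
    "r0", "r1", "w01", "w10", "a_max", "tau_r", "tau_d", "c0",
    "sigma2", "sigma2_b",
)


@dataclass(frozen=True)
class SamplerConfig:
    """Iteration bookkeeping and sampler switches.

    ``burn_in`` defaults to 20% of ``n_iterations``.  ``bursting=False``
    ties the two firing rates into a single global Poisson rate and freezes
    the switching rates.  ``update_sigma2_b=False`` holds the baseline
    variance at its initial value instead of Gibbs-updating it.
    """

    n_iterations: int = 1000
    burn_in: int | None = None
    thinning: int = 1
    n_particles: int = 100
    s_max: int = DEFAULT_S_MAX
    seed: int = 0
    bursting: bool = True
    ancestor_sampling: bool = True
    update_sigma2_b: bool = True
    update_c0: bool = True
    update_kinetics: bool = True
    literal_rate_exposure: bool = False
    deterministic_start: bool = True
    adapt_window: int = 50
    mh_scale_fraction: float = 0.1
    mh_steps: int = 3

    def __post_init__(self):
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", self.n_iterations // 5)
        if not (0 <= self.burn_in < self.n_iterations):
            raise DomainError("need 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise DomainError("thinning must be >= 1")
        if self.n_particles < 2:
            raise DomainError("n_particles must be >= 2")

    @property
    def n_retained(self) -> int:
        return -((self.n_iterations - self.burn_in) // -self.thinning)


@dataclass
class PosteriorSamples:
    """Retained draws of theta and of the latent trajectory.

    Per-draw calcium is reconstructable from the spike counts and that
    draw's kinetic parameters via :meth:`calcium`.
    """

    theta: pd.DataFrame
    spikes: np.ndarray    # (K, T) int
    q: np.ndarray         # (K, T) int
    baseline: np.ndarray  # (K, T) float
    dt: float
    config: SamplerConfig
    diagnostics: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.theta)

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    def calcium(self, k: int) -> np.ndarray:
        row = self.theta.iloc[k]
        coeffs = kinetics_to_ar(row.tau_r, row.tau_d, row.a_max, self.dt)
        return calcium_from_spikes(self.spikes[k], coeffs, c0=row.c0)


def _bootstrap_filter(
    trace: FluorescenceTrace,
    theta: ModelParameters,
    n_particles: int,
    rng: np.random.Generator,
    s_max: int,
) -> LatentTrajectory:
    """Plain bootstrap particle filter; returns a single trajectory drawn
    from the terminal weights.  Used only for initialization."""
    f = trace.values
    big_t = len(f)
    dt = trace.dt
    n = n_particles
    coeffs = kinetics_to_ar(theta.tau_r, theta.tau_d, theta.a_max, dt)
    g1, g2, a = coeffs.gamma1, coeffs.gamma2, coeffs.a
    w = theta.transition_matrix(dt)
    rates_dt = theta.rates() * dt
    sd_b = math.sqrt(theta.sigma2_b * dt)
    s2 = theta.sigma2

    hist_q = np.empty((big_t, n), dtype=np.int8)
    hist_s = np.empty((big_t, n), dtype=np.int64)
    hist_c = np.empty((big_t, n))
    hist_b = np.empty((big_t, n))
    hist_anc = np.zeros((big_t, n), dtype=np.int64)

    q = rng.integers(0, 2, size=n).astype(np.int8)
    s = np.minimum(rng.poisson(rates_dt[q]), s_max).astype(np.int64)
    b = rng.standard_normal(n)
    c1 = theta.c0 + a * s
    c2 = np.zeros(n)
    log_w = -((f[0] - c1 - b) ** 2) / (2.0 * s2)
    hist_q[0], hist_s[0], hist_c[0], hist_b[0] = q, s, c1, b

    for t in range(1, big_t):
        m = np.max(log_w)
        if not np.isfinite(m):
            raise NumericalError("bootstrap filter degenerated", t=t)
        w_rel = np.exp(log_w - m)
        cdf = np.cumsum(w_rel)
        anc = np.minimum(
            np.searchsorted(cdf, rng.random(n) * cdf[-1]), n - 1
        )
        qa = q[anc]
        q = (rng.random(n) < w[qa, 1]).astype(np.int8)
        s = np.minimum(rng.poisson(rates_dt[q]), s_max).astype(np.int64)
        b = b[anc] + sd_b * rng.standard_normal(n)
        c_new = g1 * c1[anc] + g2 * c2[anc] + a * s
        c2 = c1[anc]
        c1 = c_new
        log_w = -((f[t] - c1 - b) ** 2) / (2.0 * s2)
        hist_q[t], hist_s[t], hist_c[t], hist_b[t] = q, s, c1, b
        hist_anc[t] = anc

    m = np.max(log_w)
    w_rel = np.exp(log_w - m)
    cdf = np.cumsum(w_rel)
    k = min(np.searchsorted(cdf, rng.random() * cdf[-1]), n - 1)
    out = {
        name: np.empty(big_t, dtype=arr.dtype)
        for name, arr in (
            ("q", hist_q), ("s", hist_s), ("c", hist_c), ("b", hist_b),
        )
    }
    i = k
    for t in range(big_t - 1, -1, -1):
        out["q"][t] = hist_q[t, i]
        out["s"][t] = hist_s[t, i]
        out["c"][t] = hist_c[t, i]
        out["b"][t] = hist_b[t, i]
        i = hist_anc[t, i]
    return LatentTrajectory(**out)


def initialize(
    trace: FluorescenceTrace,
    priors: PriorSpec,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> tuple[ModelParameters, LatentTrajectory]:
    """Starting point for the Gibbs chain: theta from the priors (means in
    deterministic-start mode) and a reference trajectory from a bootstrap
    particle filter pass, retried with inflated noise on degeneracy."""
    if config.deterministic_start:
        theta = priors.mean_theta()
    else:
        theta = priors.draw_theta(rng)
    theta.validate(trace.dt)
    inflate = 1.0
    for attempt in range(4):
        try:
            traj = _bootstrap_filter(
                trace,
                theta.replace(sigma2=theta.sigma2 * inflate),
                config.n_particles,
                rng,
                config.s_max,
            )
            return theta, traj
        except NumericalError:
            inflate *= 10.0
    raise NumericalError(
        "bootstrap initialization failed even with inflated noise"
    )


def _tied_rate_update(stats, priors, dt, rng) -> float:
    shape = priors.r0.alpha + stats.spike_sums.sum()
    rate = priors.r0.beta + dt * stats.t_steps
    return float(rng.gamma(shape, 1.0 / rate))


def run_sampler(
    trace: FluorescenceTrace,
    priors: PriorSpec,
    config: SamplerConfig,
    log_path: str | None = None,
) -> PosteriorSamples:
    """Run the full Gibbs chain (PGAS sweep + parameter block) and return
    the retained posterior draws.

    Fully reproducible: identical (trace, priors, config) give identical
    output.  A JSON-lines progress log is written if ``log_path`` is set.
    """
    rng = np.random.default_rng(config.seed)
    theta, ref = initialize(trace, priors, config, rng)
    mh = MHState.from_priors(priors, config.mh_scale_fraction)
    dt = trace.dt
    big_t = len(trace)

    keep = config.n_retained
    theta_out = np.empty((keep, len(_THETA_COLS)))
    spikes_out = np.empty((keep, big_t), dtype=np.int16)
    q_out = np.empty((keep, big_t), dtype=np.int8)
    b_out = np.empty((keep, big_t))
    diagnostics: list[dict] = []
    log_file = open(log_path, "w") if log_path else None

    mh_params = []
    if config.update_kinetics:
        mh_params += ["a_max", "tau_r", "tau_d"]
    if config.update_c0:
        mh_params.append("c0")

    try:
        kept = 0
        for it in range(config.n_iterations):
            coeffs = kinetics_to_ar(theta.tau_r, theta.tau_d, theta.a_max, dt)
            try:
                ref = pgas_sweep(
                    trace,
                    ref,
                    theta,
                    config.n_particles,
                    rng,
                    s_max=config.s_max,
                    coeffs=coeffs,
                    ancestor_sampling=config.ancestor_sampling,
                )
            except NumericalError as exc:
                raise NumericalError(
                    f"PGAS sweep failed at iteration {it}: {exc}"
                ) from exc
            stats = compute_stats(ref, trace)

            if config.bursting:
                r0, r1 = update_firing_rates(
                    stats, priors, dt, rng,
                    literal_exposure=config.literal_rate_exposure,
                )
                w01, w10 = update_transition_rates(stats, priors, dt, rng)
            else:
                r0 = r1 = _tied_rate_update(stats, priors, dt, rng)
                w01, w10 = theta.w01, theta.w10
            sigma2 = update_noise_variance(stats, priors, rng)
            if config.update_sigma2_b:
                sigma2_b = update_baseline_variance(stats, priors, dt, rng)
            else:
                sigma2_b = theta.sigma2_b
            theta = theta.replace(
                r0=r0, r1=r1, w01=w01, w10=w10, sigma2=sigma2, sigma2_b=sigma2_b
            )
            if mh_params:
                theta = update_kernel_params_mh(
                    theta, ref, trace, priors, mh, rng,
                    params=tuple(mh_params), n_steps=config.mh_steps,
                )
                ref.recompute_calcium(
                    kinetics_to_ar(theta.tau_r, theta.tau_d, theta.a_max, dt),
                    theta.c0,
                )

            in_burn = it < config.burn_in
            if in_burn and mh_params and (it + 1) % config.adapt_window == 0:
                mh.adapt()
            if not in_burn and (it - config.burn_in) % config.thinning == 0:
                theta_out[kept] = [getattr(theta, c) for c in _THETA_COLS]
                spikes_out[kept] = ref.s
                q_out[kept] = ref.q
                b_out[kept] = ref.b
                kept += 1
            if log_file and (it % 50 == 0 or it == config.n_iterations - 1):
                rec = {
                    "iteration": it,
                    "burn_in": in_burn,
                    "acceptance": mh.acceptance_rates(),
                    "total_spikes": int(ref.s.sum()),
                    "theta": {c: getattr(theta, c) for c in _THETA_COLS},
                }
                log_file.write(json.dumps(rec) + "\n")
    finally:
        if log_file:
            log_file.close()

    diagnostics.append({"mh_acceptance": mh.acceptance_rates()})
    return PosteriorSamples(
        theta=pd.DataFrame(theta_out[:kept], columns=list(_THETA_COLS)),
        spikes=spikes_out[:kept],
        q=q_out[:kept],
        baseline=b_out[:kept],
        dt=dt,
        config=config,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Getting-it-right diagnostics


def _ess(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    total = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        total += pair
        t += 2
    ess = n / (1.0 + 2.0 * total)
    return float(min(max(ess, 1.0), n))


def _geweke_stats(theta: ModelParameters, traj_s, traj_q, traj_b) -> dict:
    return {
        "r0": theta.r0,
        "r1": theta.r1,
        "sigma2": theta.sigma2,
        "sigma2_b": theta.sigma2_b,
        "a_max": theta.a_max,
        "tau_d": theta.tau_d,
        "total_spikes": float(np.sum(traj_s)),
        "mean_baseline": float(np.mean(traj_b)),
        "frac_bursting": float(np.mean(traj_q)),
    }


def geweke_check(
    priors: PriorSpec,
    config: SamplerConfig,
    t_steps: int,
    dt: float,
    n_rounds: int,
    seed: int = 0,
    corrupt_weights: bool = False,
) -> pd.DataFrame:
    """Joint-distribution ('getting it right') test of the Gibbs kernel.

    Compares moments of parameters and latent summaries between (a)
    prior-predictive forward simulation and (b) a successive-conditional
    chain that alternates one Gibbs transition with re-simulation of the
    data.  For a correct sampler both target the same joint distribution.

    Returns a DataFrame indexed by statistic with columns
    ``mean_marginal``, ``mean_successive``, ``z``.
    """
    if n_rounds == 0:
        return pd.DataFrame(columns=["mean_marginal", "mean_successive", "z"])
    rng = np.random.default_rng(seed)

    marg = []
    for _ in range(n_rounds):
        theta = priors.draw_theta(rng)
        sim = simulate_trace(theta, t_steps, dt, seed=rng)
        marg.append(_geweke_stats(theta, sim.spikes, sim.states, sim.baseline))
    marg = pd.DataFrame(marg)

    theta = priors.draw_theta(rng)
    sim = simulate_trace(theta, t_steps, dt, seed=rng)
    trace = sim.trace
    ref = LatentTrajectory(q=sim.states, s=sim.spikes, c=sim.calcium, b=sim.baseline)
    mh = MHState.from_priors(priors, config.mh_scale_fraction)
    succ = []
    for _ in range(n_rounds):
        coeffs = kinetics_to_ar(theta.tau_r, theta.tau_d, theta.a_max, dt)
        ref = pgas_sweep(
            trace, ref, theta, config.n_particles, rng,
            s_max=config.s_max, coeffs=coeffs,
            corrupt_weights=corrupt_weights,
            ancestor_sampling=config.ancestor_sampling,
        )
        stats = compute_stats(ref, trace)
        r0, r1 = update_firing_rates(stats, priors, dt, rng)
        w01, w10 = update_transition_rates(stats, priors, dt, rng)
        sigma2 = update_noise_variance(stats, priors, rng)
        sigma2_b = update_baseline_variance(stats, priors, dt, rng)
        theta = theta.replace(
            r0=r0, r1=r1, w01=w01, w10=w10, sigma2=sigma2, sigma2_b=sigma2_b
        )
        theta = update_kernel_params_mh(
            theta, ref, trace, priors, mh, rng, n_steps=config.mh_steps
        )
        coeffs = kinetics_to_ar(theta.tau_r, theta.tau_d, theta.a_max, dt)
        ref.recompute_calcium(coeffs, theta.c0)
        # data refresh keeps the joint chain on the full generative model
        noise = rng.normal(0.0, math.sqrt(theta.sigma2), t_steps)
        trace = FluorescenceTrace(ref.c + ref.b + noise, dt)
        succ.append(_geweke_stats(theta, ref.s, ref.q, ref.b))
    succ = pd.DataFrame(succ)

    rows = {}
    for col in marg.columns:
        m1, m2 = marg[col].mean(), succ[col].mean()
        v1 = marg[col].var(ddof=1) / len(marg)
        v2 = succ[col].var(ddof=1) / _ess(succ[col].to_numpy())
        z = (m1 - m2) / math.sqrt(v1 + v2) if (v1 + v2) > 0 else 0.0
        rows[col] = {"mean_marginal": m1, "mean_successive": m2, "z": z}
    return pd.DataFrame.from_dict(rows, orient="index")
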