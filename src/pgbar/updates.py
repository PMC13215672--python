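"""Full-conditional and Metropolis-Hastings updates of the time-independent
parameters given a latent trajectory.

Firing rates, switching rates and the two variances have conjugate
gamma/inverse-gamma full conditionals; the kernel parameters (peak
amplitude, rise and decay times) and the initial calcium level are updated
by single-site random-walk Metropolis-Hastings on the full-trace Gaussian
observation likelihood with calcium recomputed from the fixed spikes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import (
    DomainError,
    FluorescenceTrace,
    ModelParameters,
    calcium_from_spikes,
    kinetics_to_ar,
)
from .pgas import LatentTrajectory
from .priors import PriorSpec

__all__ = [
    "SufficientStats",
    "compute_stats",
    "update_firing_rates",
    "update_transition_rates",
    "update_noise_variance",
    "update_baseline_variance",
    "update_kernel_params_mh",
    "MHState",
]

_MH_PARAMS = ("a_max", "tau_r", "tau_d", "c0")


@dataclass(frozen=True)
class SufficientStats:
    """Trajectory summaries feeding the conjugate updates."""

    spike_sums: np.ndarray       # (2,) total spikes while in each regime
    occupancy: np.ndarray        # (2,) number of steps spent in each regime
    trans_counts: np.ndarray     # (2,2) regime transition counts
    rss: float                   # sum (F_t - c_t - b_t)^2
    baseline_incr_ss: float      # sum (b_t - b_{t-1})^2
    t_steps: int

    def __post_init__(self):
        if self.trans_counts.sum() != self.t_steps - 1:
            raise DomainError("transition counts must sum to T - 1")


def compute_stats(
    trajectory: LatentTrajectory, trace: FluorescenceTrace
) -> SufficientStats:
    q = trajectory.q
    s = trajectory.s
    spike_sums = np.array([s[q == 0].sum(), s[q == 1].sum()], dtype=float)
    occupancy = np.array([(q == 0).sum(), (q == 1).sum()], dtype=float)
    trans = np.zeros((2, 2))
    np.add.at(trans, (q[:-1], q[1:]), 1.0)
    resid = trace.values - trajectory.c - trajectory.b
    incr = np.diff(trajectory.b)
    return SufficientStats(
        spike_sums=spike_sums,
        occupancy=occupancy,
        trans_counts=trans,
        rss=float(resid @ resid),
        baseline_incr_ss=float(incr @ incr),
        t_steps=len(trajectory),
    )


def update_firing_rates(
    stats: SufficientStats,
    priors: PriorSpec,
    dt: float,
    rng: np.random.Generator,
    literal_exposure: bool = False,
) -> tuple[float, float]:
    """Gamma full-conditional draws for (r0, r1).

    The rate update adds the exposure of the regime, ``dt * T_q`` with
    ``T_q`` the regime occupancy.  ``literal_exposure=True`` switches to
    using the total duration ``dt * T`` for both regimes instead.
    """
    out = []
    for qi, prior in ((0, priors.r0), (1, priors.r1)):
        shape = prior.alpha + stats.spike_sums[qi]
        exposure = stats.t_steps if literal_exposure else stats.occupancy[qi]
        rate = prior.beta + dt * exposure
        out.append(float(rng.gamma(shape, 1.0 / rate)))
    return out[0], out[1]


def update_transition_rates(
    stats: SufficientStats,
    priors: PriorSpec,
    dt: float,
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Gamma full-conditional draws for (w01, w10) under the slow-switching
    approximation; draws implying a step probability >= 1 are redrawn."""
    out = []
    for (qf, qt), prior in (((0, 1), priors.w01), ((1, 0), priors.w10)):
        shape = prior.alpha + stats.trans_counts[qf, qt]
        rate = prior.beta + dt * stats.trans_counts[qf, qf]
        draw = float(rng.gamma(shape, 1.0 / rate))
        tries = 0
        while draw * dt >= 1.0:
            tries += 1
            if tries > max_redraws:
                draw = 0.99 / dt
                warnings.warn(
                    f"switching-rate draw capped at {draw:.3g}/s after "
                    f"{max_redraws} redraws",
                    RuntimeWarning,
                )
                break
            warnings.warn(
                "redrawing switching rate with w*dt >= 1", RuntimeWarning
            )
            draw = float(rng.gamma(shape, 1.0 / rate))
        out.append(draw)
    return out[0], out[1]


def update_noise_variance(
    stats: SufficientStats, priors: PriorSpec, rng: np.random.Generator
) -> float:
    """Inverse-gamma full-conditional draw for the observation-noise
    variance."""
    shape = priors.sigma2.alpha + stats.t_steps / 2.0
    scale = priors.sigma2.beta + stats.rss / 2.0
    return float(scale / rng.gamma(shape, 1.0))


def update_baseline_variance(
    stats: SufficientStats,
    priors: PriorSpec,
    dt: float,
    rng: np.random.Generator,
) -> float:
    """Inverse-gamma full-conditional draw for the baseline random-walk
    variance rate implied by the Gaussian increment model."""
    shape = priors.sigma2_b.alpha + (stats.t_steps - 1) / 2.0
    scale = priors.sigma2_b.beta + stats.baseline_incr_ss / (2.0 * dt)
    return float(scale / rng.gamma(shape, 1.0))


def _trace_loglik(
    theta: ModelParameters,
    spikes: np.ndarray,
    baseline: np.ndarray,
    trace: FluorescenceTrace,
) -> float:
    coeffs = kinetics_to_ar(theta.tau_r, theta.tau_d, theta.a_max, trace.dt)
    c = calcium_from_spikes(spikes, coeffs, c0=theta.c0)
    resid = trace.values - c - baseline
    n = len(trace)
    return -0.5 * n * math.log(2.0 * math.pi * theta.sigma2) - float(
        resid @ resid
    ) / (2.0 * theta.sigma2)


@dataclass
class MHState:
    """Random-walk proposal scales and acceptance bookkeeping for the
    kernel-parameter block."""

    scales: dict
    accepted: dict
    proposed: dict

    @classmethod
    def from_priors(cls, priors: PriorSpec, fraction: float = 0.1) -> "MHState":
        scales = {
            name: fraction * getattr(priors, name).std() for name in _MH_PARAMS
        }
        return cls(
            scales=scales,
            accepted={name: 0 for name in _MH_PARAMS},
            proposed={name: 0 for name in _MH_PARAMS},
        )

    def acceptance_rates(self) -> dict:
        return {
            name: (self.accepted[name] / self.proposed[name])
            if self.proposed[name]
            else math.nan
            for name in _MH_PARAMS
        }

    def adapt(self, target: float = 0.3, step: float = 0.1) -> None:
        """Robbins-Monro style scale adaptation (burn-in only)."""
        for name in _MH_PARAMS:
            rate = self.acceptance_rates()[name]
            if not math.isnan(rate):
                self.scales[name] *= math.exp(step * (rate - target))
            self.accepted[name] = 0
            self.proposed[name] = 0


def update_kernel_params_mh(
    theta: ModelParameters,
    trajectory: LatentTrajectory,
    trace: FluorescenceTrace,
    priors: PriorSpec,
    mh: MHState,
    rng: np.random.Generator,
    params: tuple[str, ...] = _MH_PARAMS,
    n_steps: int = 1,
) -> ModelParameters:
    """Random-walk MH sweeps over the kernel parameters (and c0), holding
    the spike sequence and baseline fixed; ``n_steps`` repetitions improve
    mixing along the amplitude/spike-count ridge at O(T) cost each.

    Proposals outside the prior support or violating ``tau_r < tau_d`` are
    rejected without a likelihood evaluation.
    """
    current_ll = _trace_loglik(theta, trajectory.s, trajectory.b, trace)
    for name in params * n_steps:
        mh.proposed[name] += 1
        value = getattr(theta, name)
        scale = mh.scales[name]
        proposal = value + scale * rng.standard_normal()
        if not getattr(priors, name).in_support(proposal):
            continue
        cand = theta.replace(**{name: proposal})
        if not (0 < cand.tau_r < cand.tau_d) or cand.a_max <= 0:
            continue
        log_ratio = (
            getattr(priors, name).logpdf(proposal)
            - getattr(priors, name).logpdf(value)
        )
        cand_ll = _trace_loglik(cand, trajectory.s, trajectory.b, trace)
        log_ratio += cand_ll - current_ll
        if log_ratio >= 0 or rng.random() < math.exp(log_ratio):
            theta = cand
            current_ll = cand_ll
            mh.accepted[name] += 1
    return theta
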