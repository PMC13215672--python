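"""Forward simulation of the generative model.

Produces fluorescence traces with complete ground truth (spike counts,
regime sequence, calcium, baseline and the raw noise stream), either free
running or clamped to a prescribed stimulus train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    DomainError,
    FluorescenceTrace,
    KernelCoefficients,
    ModelParameters,
    calcium_from_spikes,
    kinetics_to_ar,
)

__all__ = [
    "SimulationResult",
    "simulate_trace",
    "simulate_stimulus_trace",
    "snr",
    "standardized_noise",
    "two_spike_theta",
]


@dataclass
class SimulationResult:
    """A simulated trace plus every latent ground-truth component.

    ``trace.values == calcium + baseline + noise`` exactly.
    """

    trace: FluorescenceTrace
    spikes: np.ndarray
    states: np.ndarray
    calcium: np.ndarray
    baseline: np.ndarray
    noise: np.ndarray
    theta: ModelParameters
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def spike_times(self) -> np.ndarray:
        """Spike times in seconds, one entry per spike (counts expanded)."""
        idx = np.repeat(np.arange(len(self.spikes)), self.spikes)
        return idx * self.trace.dt


def _sample_latents(
    theta: ModelParameters,
    coeffs: KernelCoefficients,
    t_steps: int,
    dt: float,
    rng: np.random.Generator,
    spikes: np.ndarray | None,
    pin_baseline: bool,
):
    w = theta.transition_matrix(dt)
    rates = theta.rates() * dt

    q = np.empty(t_steps, dtype=np.int8)
    q[0] = rng.integers(0, 2)
    u = rng.random(t_steps - 1)
    for t in range(1, t_steps):
        q[t] = 1 if u[t - 1] < w[q[t - 1], 1] else 0

    if spikes is None:
        s = rng.poisson(rates[q])
    else:
        s = np.asarray(spikes, dtype=np.int64)

    b = np.empty(t_steps)
    b[0] = 0.0 if pin_baseline else rng.normal(0.0, 1.0)
    b[1:] = b[0] + np.cumsum(
        rng.normal(0.0, np.sqrt(theta.sigma2_b * dt), t_steps - 1)
    )
    c = calcium_from_spikes(s, coeffs, c0=theta.c0)
    return q, s, c, b


def simulate_trace(
    theta: ModelParameters,
    t_steps: int,
    dt: float,
    seed: int | np.random.Generator | None = None,
    pin_baseline: bool = False,
) -> SimulationResult:
    """Forward-sample regimes, spikes, calcium, baseline and noise.

    Parameters
    ----------
    theta : ModelParameters
        Generating parameters (validated against ``dt``).
    t_steps : int
        Trace length.
    dt : float
        Sampling period (s).
    seed : int, Generator or None
        Randomness source; fixed seeds give bit-identical results.
    pin_baseline : bool
        Start the baseline at exactly zero instead of ``Normal(0, 1)``.
    """
    if t_steps < 2:
        raise DomainError("t_steps must be >= 2")
    theta.validate(dt)
    rng = np.random.default_rng(seed)
    seed_record = seed if isinstance(seed, int) else None
    coeffs = kinetics_to_ar(theta.tau_r, theta.tau_d, theta.a_max, dt)
    q, s, c, b = _sample_latents(theta, coeffs, t_steps, dt, rng, None, pin_baseline)
    noise = rng.normal(0.0, np.sqrt(theta.sigma2), t_steps)
    trace = FluorescenceTrace(c + b + noise, dt)
    return SimulationResult(trace, s, q, c, b, noise, theta, seed_record)


def simulate_stimulus_trace(
    spike_times: np.ndarray,
    theta: ModelParameters,
    t_steps: int,
    dt: float,
    seed: int | np.random.Generator | None = None,
    pin_baseline: bool = True,
) -> SimulationResult:
    """Simulate with the spike train clamped to given times (seconds).

    Each listed time is snapped to the nearest sampling step (ties go to
    the later step); duplicates on the same step accumulate into one count.
    """
    if t_steps < 2:
        raise DomainError("t_steps must be >= 2")
    theta.validate(dt)
    times = np.atleast_1d(np.asarray(spike_times, dtype=float))
    steps = np.floor(times / dt + 0.5).astype(np.int64)
    if np.any(steps < 0) or np.any(steps >= t_steps):
        raise DomainError("spike times must fall within the trace duration")
    s = np.bincount(steps, minlength=t_steps).astype(np.int64)

    rng = np.random.default_rng(seed)
    seed_record = seed if isinstance(seed, int) else None
    coeffs = kinetics_to_ar(theta.tau_r, theta.tau_d, theta.a_max, dt)
    q, s, c, b = _sample_latents(theta, coeffs, t_steps, dt, rng, s, pin_baseline)
    noise = rng.normal(0.0, np.sqrt(theta.sigma2), t_steps)
    trace = FluorescenceTrace(c + b + noise, dt)
    return SimulationResult(
        trace, s, q, c, b, noise, theta, seed_record,
        meta={"stimulus_times": times.tolist()},
    )


def snr(theta: ModelParameters) -> float:
    """Signal-to-noise ratio: peak unitary response over noise sd."""
    if theta.sigma2 <= 0:
        raise DomainError("sigma2 must be positive")
    return theta.a_max / np.sqrt(theta.sigma2)


def standardized_noise(trace: FluorescenceTrace) -> float:
    """Trace standard deviation divided by the square root of the sampling
    frequency; a sampling-rate-independent noise index."""
    return float(np.std(trace.values) / np.sqrt(1.0 / trace.dt))


def two_spike_theta(
    isi: float = 0.010,
    snr_level: float = 3.4,
    a_max: float = 1.0,
    tau_r: float = 0.0037,
    tau_d: float = 0.040,
    sigma2_b: float = 0.01,
    burst_rate: float = 100.0,
) -> ModelParameters:
    """Reference parameter set for the short-interval stimulus experiments
    (3 kHz simulations with GCaMP8f-like kinetics)."""
    del isi  # spike placement is handled by the caller
    return ModelParameters(
        r0=0.1,
        r1=burst_rate,
        w01=1.0,
        w10=100.0,
        a_max=a_max,
        tau_r=tau_r,
        tau_d=tau_d,
        c0=0.0,
        sigma2=(a_max / snr_level) ** 2,
        sigma2_b=sigma2_b,
    )
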