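"""Core model definitions: parameters, latent states, densities, and the
AR(2) response-kernel reparameterization.

The generative model describes a normalized fluorescence trace as

    F_t = c_t + b_t + eta_t

where ``c_t`` follows deterministic AR(2) dynamics driven by Poisson spike
counts, ``b_t`` is a Gaussian random-walk baseline and ``eta_t`` is white
Gaussian noise.  Spiking alternates between a quiescent regime (rate ``r0``)
and a bursting regime (rate ``r1``) according to a two-state Markov chain
with switching rates ``w01`` and ``w10``.

All rates (``r0``, ``r1``, ``w01``, ``w10``, ``sigma2_b``) are per second;
AR coefficients and log-roots are per sampling step; kinetic times
(``tau_r``, ``tau_d``) are in seconds at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParameters",
    "KernelCoefficients",
    "LatentState",
    "FluorescenceTrace",
    "kinetics_to_ar",
    "ar_to_kinetics",
    "kernel_response",
    "transition_logdensity",
    "observation_logdensity",
    "initial_logdensity",
    "gaussian_convolution",
    "calcium_from_spikes",
]

_LOG_2PI = math.log(2.0 * math.pi)

# Near-repeated AR roots are outside the physiological regime; refuse rather
# than switch to the repeated-root limit.
_ROOT_DISC_EPS = 1e-12


class DomainError(ValueError):
    """Raised when inputs violate a mathematical domain constraint."""


class ContractViolation(RuntimeError):
    """Raised when a caller-enforced structural constraint does not hold."""


@dataclass(frozen=True)
class ModelParameters:
    """Time-independent parameter vector theta.

    Attributes
    ----------
    r0, r1 : float
        Baseline and burst firing rates (Hz).
    w01, w10 : float
        Burst onset / offset switching rates (Hz).
    a_max : float
        Peak fluorescence response to a single spike (dF/F units).
    tau_r, tau_d : float
        Rise (time-to-peak) and decay time constants of the unitary
        response (seconds), with ``0 < tau_r < tau_d``.
    c0 : float
        Initial calcium level (dF/F units).
    sigma2 : float
        Observation-noise variance.
    sigma2_b : float
        Baseline random-walk variance rate (variance per second).
    """

    r0: float
    r1: float
    w01: float
    w10: float
    a_max: float
    tau_r: float
    tau_d: float
    c0: float
    sigma2: float
    sigma2_b: float

    def validate(self, dt: float | None = None) -> None:
        if self.r0 < 0 or self.r1 < 0:
            raise DomainError("firing rates must be non-negative")
        if self.w01 < 0 or self.w10 < 0:
            raise DomainError("switching rates must be non-negative")
        if dt is not None and (self.w01 * dt >= 1 or self.w10 * dt >= 1):
            raise DomainError(
                f"switching probabilities w*dt must be < 1 "
                f"(w01*dt={self.w01 * dt:.3g}, w10*dt={self.w10 * dt:.3g})"
            )
        if self.a_max <= 0:
            raise DomainError("a_max must be positive")
        if not (0 < self.tau_r < self.tau_d):
            raise DomainError(
                f"need 0 < tau_r < tau_d, got tau_r={self.tau_r}, tau_d={self.tau_d}"
            )
        if self.sigma2 <= 0:
            raise DomainError("sigma2 must be positive")
        if self.sigma2_b < 0:
            raise DomainError("sigma2_b must be non-negative")

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def transition_matrix(self, dt: float) -> np.ndarray:
        """2x2 regime transition matrix for sampling period ``dt``."""
        p01 = self.w01 * dt
        p10 = self.w10 * dt
        return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])

    def rates(self) -> np.ndarray:
        return np.array([self.r0, self.r1])


@dataclass(frozen=True)
class KernelCoefficients:
    """Discrete AR(2) representation of the unitary calcium response.

    ``gamma1``/``gamma2`` are the AR coefficients, ``a`` the per-spike
    calcium increment, ``g_plus``/``g_minus`` the logs of the dominant and
    subdominant AR roots (per step, both negative) and ``g_a`` the factor
    converting ``a`` to the peak amplitude (``a_max = a * g_a``).
    """

    gamma1: float
    gamma2: float
    a: float
    g_plus: float
    g_minus: float
    g_a: float

    @property
    def roots(self) -> tuple[float, float]:
        return math.exp(self.g_plus), math.exp(self.g_minus)


@dataclass
class LatentState:
    """Per-step hidden state: regime ``q``, spike count ``s``, calcium pair
    ``c_vec = [c_t, c_{t-1}]`` and baseline ``b``."""

    q: int
    s: int
    c_vec: np.ndarray
    b: float

    def __post_init__(self):
        self.c_vec = np.asarray(self.c_vec, dtype=float)
        if self.q not in (0, 1):
            raise DomainError("q must be 0 or 1")
        if self.s < 0 or self.s != int(self.s):
            raise DomainError("s must be a non-negative integer")
        if not np.all(np.isfinite(self.c_vec)) or self.c_vec.shape != (2,):
            raise DomainError("c_vec must be a finite pair")


@dataclass(frozen=True)
class FluorescenceTrace:
    """A uniformly sampled dF/F trace with sampling period ``dt`` (s)."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise DomainError("trace must be 1-D with at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("trace contains non-finite values")
        if self.dt <= 0:
            raise DomainError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt


def _f_ratio(x: float) -> float:
    """f(x) = log(x)/(x-1), the rise/decay time ratio as a function of the
    ratio of kernel log-roots x = g_minus/g_plus > 1."""
    return math.log(x) / (x - 1.0)


def _peak_factor(g_plus: float, g_minus: float) -> float:
    """Ratio of the continuous-time kernel peak to its value one step after
    the spike; converts the per-spike increment to the peak amplitude."""
    t_star = math.log(g_plus / g_minus) / (g_minus - g_plus)
    return (math.exp(g_plus * t_star) - math.exp(g_minus * t_star)) / (
        math.exp(g_plus) - math.exp(g_minus)
    )


def kinetics_to_ar(
    tau_r: float, tau_d: float, a_max: float, dt: float
) -> KernelCoefficients:
    """Invert the kinetic parameterization (rise/decay/peak) into AR(2)
    coefficients for sampling period ``dt``.

    Solves ``log(x)/(x-1) = tau_r/tau_d`` for ``x = g_minus/g_plus > 1`` by
    bracketed root-finding, then builds the per-step log-roots and AR
    coefficients.

    Raises
    ------
    DomainError
        If ``tau_r >= tau_d`` or the implied discrete kernel is degenerate.
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    if not (0 < tau_r < tau_d):
        raise DomainError(
            f"need 0 < tau_r < tau_d, got tau_r={tau_r}, tau_d={tau_d}"
        )
    if a_max <= 0:
        raise DomainError("a_max must be positive")
    ratio = tau_r / tau_d
    lo, hi = 1.0 + 1e-12, 1e6
    if not (_f_ratio(hi) < ratio < _f_ratio(lo)):
        raise DomainError(f"tau_r/tau_d = {ratio:.3g} outside invertible range")
    try:
        x = brentq(lambda v: _f_ratio(v) - ratio, lo, hi, xtol=1e-10, rtol=1e-15)
    except RuntimeError as exc:  # pragma: no cover - brentq is robust here
        raise RuntimeError(
            f"root finding failed for tau_r/tau_d={ratio:.6g}: {exc}"
        ) from exc
    g_plus = -dt / tau_d  # per-step log of the dominant root
    g_minus = g_plus * x
    gamma1 = math.exp(g_plus) + math.exp(g_minus)
    gamma2 = -math.exp(g_plus + g_minus)
    g_a = _peak_factor(g_plus, g_minus)
    return KernelCoefficients(
        gamma1=gamma1,
        gamma2=gamma2,
        a=a_max / g_a,
        g_plus=g_plus,
        g_minus=g_minus,
        g_a=g_a,
    )


def ar_to_kinetics(
    coeffs: KernelCoefficients, dt: float
) -> tuple[float, float, float]:
    """Map AR(2) coefficients back to ``(a_max, tau_r, tau_d)`` in seconds.

    Raises
    ------
    DomainError
        If the AR polynomial has complex, repeated, negative or unstable
        roots (including the degenerate first-order case ``gamma2 == 0``).
    """
    disc = coeffs.gamma1**2 + 4.0 * coeffs.gamma2
    if disc < _ROOT_DISC_EPS:
        raise DomainError(
            f"AR roots complex or near-repeated (discriminant {disc:.3g})"
        )
    sq = math.sqrt(disc)
    root_plus = (coeffs.gamma1 + sq) / 2.0
    root_minus = (coeffs.gamma1 - sq) / 2.0
    if root_minus <= 0:
        raise DomainError(
            f"subdominant root {root_minus:.3g} not in (0,1); "
            "first-order/degenerate kernel"
        )
    if not (0 < root_minus < root_plus < 1):
        raise DomainError(
            f"AR roots ({root_minus:.4g}, {root_plus:.4g}) must lie in (0,1)"
        )
    g_plus = math.log(root_plus)
    g_minus = math.log(root_minus)
    tau_r = math.log(g_plus / g_minus) / (g_minus - g_plus) * dt
    tau_d = -dt / g_plus
    a_max = coeffs.a * _peak_factor(g_plus, g_minus)
    return a_max, tau_r, tau_d


def kernel_response(coeffs: KernelCoefficients, t_max: int) -> np.ndarray:
    """Calcium response ``c_1..c_{t_max}`` to a single spike (``c0 = 0``).

    Closed form ``c_t = a (r+^t - r-^t)/(r+ - r-)``; identical to iterating
    the AR(2) recursion.
    """
    if t_max < 1:
        raise DomainError("t_max must be >= 1")
    t = np.arange(1, t_max + 1, dtype=float)
    rp, rm = coeffs.roots
    return coeffs.a * (rp**t - rm**t) / (rp - rm)


def calcium_from_spikes(
    spikes: np.ndarray, coeffs: KernelCoefficients, c0: float = 0.0
) -> np.ndarray:
    """Deterministic calcium trajectory implied by a spike-count sequence.

    ``c_1 = c0 + a*s_1`` and ``c_t = gamma1*c_{t-1} + gamma2*c_{t-2} + a*s_t``
    with ``c_0 := 0`` before the trace.
    """
    from scipy.signal import lfilter

    s = np.asarray(spikes, dtype=float)
    den = [1.0, -coeffs.gamma1, -coeffs.gamma2]
    c = lfilter([coeffs.a], den, s)
    if c0 != 0.0:
        impulse = np.zeros_like(s)
        impulse[0] = 1.0
        c = c + c0 * lfilter([1.0], den, impulse)
    return c


def _check_calcium_consistency(
    c_vec: np.ndarray, expected_c: float, prev_c: float
) -> None:
    tol = 1e-8 * (1.0 + abs(expected_c))
    if abs(c_vec[0] - expected_c) > tol or abs(c_vec[1] - prev_c) > tol:
        raise ContractViolation(
            f"calcium pair {c_vec} inconsistent with deterministic propagation "
            f"(expected [{expected_c:.6g}, {prev_c:.6g}])"
        )


def _poisson_logpmf(s: float, mean: float) -> float:
    if mean == 0.0:
        return 0.0 if s == 0 else -math.inf
    return s * math.log(mean) - mean - math.lgamma(s + 1.0)


def transition_logdensity(
    x_prev: LatentState,
    x: LatentState,
    theta: ModelParameters,
    coeffs: KernelCoefficients,
    dt: float,
) -> float:
    """Log-density of the stochastic components of one latent transition.

    Covers regime switching, the Poisson spike count and the baseline
    random-walk increment.  Deterministic calcium propagation is a
    structural precondition, not a density factor: the caller must supply a
    consistent calcium pair or a :class:`ContractViolation` is raised.
    """
    expected_c = (
        coeffs.gamma1 * x_prev.c_vec[0]
        + coeffs.gamma2 * x_prev.c_vec[1]
        + coeffs.a * x.s
    )
    _check_calcium_consistency(x.c_vec, expected_c, x_prev.c_vec[0])
    w = theta.transition_matrix(dt)[x_prev.q, x.q]
    logw = math.log(w) if w > 0 else -math.inf
    rate = (theta.r1 if x.q == 1 else theta.r0) * dt
    logpois = _poisson_logpmf(x.s, rate)
    var_b = theta.sigma2_b * dt
    if var_b <= 0:
        raise DomainError("sigma2_b*dt must be positive for a density value")
    logb = -0.5 * (_LOG_2PI + math.log(var_b)) - (x.b - x_prev.b) ** 2 / (2 * var_b)
    return logw + logpois + logb


def observation_logdensity(
    f: float, x: LatentState, theta: ModelParameters
) -> float:
    """Gaussian log-density of an observed fluorescence value."""
    resid = f - x.c_vec[0] - x.b
    return -0.5 * (_LOG_2PI + math.log(theta.sigma2)) - resid**2 / (
        2 * theta.sigma2
    )


def initial_logdensity(
    x1: LatentState,
    theta: ModelParameters,
    coeffs: KernelCoefficients,
    dt: float,
) -> float:
    """Log-density of the initial latent state.

    The two firing regimes carry equal prior mass, the spike count is
    Poisson under the regime's rate, and the baseline starts at
    ``Normal(0, 1)``; calcium is constrained to ``[c0 + a*s1, 0]``.
    """
    _check_calcium_consistency(x1.c_vec, theta.c0 + coeffs.a * x1.s, 0.0)
    rate = (theta.r1 if x1.q == 1 else theta.r0) * dt
    return (
        math.log(0.5)
        + _poisson_logpmf(x1.s, rate)
        - 0.5 * (_LOG_2PI)
        - x1.b**2 / 2.0
    )


def gaussian_convolution(y1: float, y2: float, v1: float, v2: float) -> float:
    """The integral of a product of two Gaussian densities over their shared
    argument: ``exp(-(y1-y2)^2 / (2(v1+v2))) / sqrt(2 pi (v1+v2))``."""
    if v1 <= 0 or v2 <= 0:
        raise DomainError("variances must be positive")
    v = v1 + v2
    return math.exp(-((y1 - y2) ** 2) / (2.0 * v)) / math.sqrt(2.0 * math.pi * v)
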