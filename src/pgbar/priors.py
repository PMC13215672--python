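"""Prior families and the per-parameter prior specification.

Families are fixed by the model: truncated normals for the kernel
parameters (``a_max``, ``c0``, ``tau_r``, ``tau_d``), gammas for the firing
and switching rates, inverse gammas for the two variances.  Hyperparameter
values are configuration, not model structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy import special, stats

from .model import DomainError, ModelParameters

__all__ = [
    "TruncatedNormalPrior",
    "GammaPrior",
    "InverseGammaPrior",
    "PriorSpec",
]


def _phi(z: float) -> float:
    return math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


def _z_phi(z: float) -> float:
    """z * phi(z) with the correct zero limit at infinite bounds."""
    return 0.0 if math.isinf(z) else z * _phi(z)


@dataclass(frozen=True)
class TruncatedNormalPrior:
    """Normal(loc, scale^2) truncated to [low, high].

    Moments and densities use the closed-form expressions directly (the
    generic scipy frozen-distribution machinery is far too slow for
    per-iteration MH use); draws are inverse-CDF for reproducibility.
    """

    loc: float
    scale: float
    low: float = 0.0
    high: float = math.inf

    def __post_init__(self):
        if self.scale <= 0:
            raise DomainError("truncated-normal scale must be positive")
        if not self.low < self.high:
            raise DomainError("truncated-normal bounds must satisfy low < high")

    def _std_bounds(self) -> tuple[float, float]:
        return (
            (self.low - self.loc) / self.scale,
            (self.high - self.loc) / self.scale,
        )

    def _mass(self) -> float:
        a, b = self._std_bounds()
        return float(special.ndtr(b) - special.ndtr(a))

    def mean(self) -> float:
        a, b = self._std_bounds()
        return self.loc + self.scale * (_phi(a) - _phi(b)) / self._mass()

    def std(self) -> float:
        a, b = self._std_bounds()
        z = self._mass()
        d = (_phi(a) - _phi(b)) / z
        var = self.scale**2 * (1.0 + (_z_phi(a) - _z_phi(b)) / z - d * d)
        return math.sqrt(max(var, 0.0))

    def draw(self, rng: np.random.Generator) -> float:
        a, b = self._std_bounds()
        lo = float(special.ndtr(a))
        u = lo + rng.uniform() * (float(special.ndtr(b)) - lo)
        return self.loc + self.scale * float(special.ndtri(u))

    def logpdf(self, x: float) -> float:
        if not (self.low <= x <= self.high):
            return -math.inf
        z = (x - self.loc) / self.scale
        return (
            -0.5 * z * z
            - math.log(self.scale)
            - 0.5 * math.log(2.0 * math.pi)
            - math.log(self._mass())
        )

    def in_support(self, x: float) -> bool:
        return self.low <= x <= self.high


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(alpha, beta) with shape ``alpha`` and *rate* ``beta``."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise DomainError("gamma hyperparameters must be positive")

    def mean(self) -> float:
        return self.alpha / self.beta

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.alpha, 1.0 / self.beta))

    def logpdf(self, x: float) -> float:
        return float(stats.gamma.logpdf(x, self.alpha, scale=1.0 / self.beta))


@dataclass(frozen=True)
class InverseGammaPrior:
    """Inverse gamma with shape ``alpha`` and scale ``beta``
    (mean ``beta/(alpha-1)`` for ``alpha > 1``)."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise DomainError("inverse-gamma hyperparameters must be positive")

    def mean(self) -> float:
        if self.alpha <= 1:
            raise DomainError("inverse-gamma mean undefined for alpha <= 1")
        return self.beta / (self.alpha - 1.0)

    def draw(self, rng: np.random.Generator) -> float:
        return float(self.beta / rng.gamma(self.alpha, 1.0))

    def logpdf(self, x: float) -> float:
        return float(stats.invgamma.logpdf(x, self.alpha, scale=self.beta))


_FAMILIES = {
    "r0": GammaPrior,
    "r1": GammaPrior,
    "w01": GammaPrior,
    "w10": GammaPrior,
    "a_max": TruncatedNormalPrior,
    "tau_r": TruncatedNormalPrior,
    "tau_d": TruncatedNormalPrior,
    "c0": TruncatedNormalPrior,
    "sigma2": InverseGammaPrior,
    "sigma2_b": InverseGammaPrior,
}


@dataclass(frozen=True)
class PriorSpec:
    """One prior per element of the parameter vector theta."""

    r0: GammaPrior
    r1: GammaPrior
    w01: GammaPrior
    w10: GammaPrior
    a_max: TruncatedNormalPrior
    tau_r: TruncatedNormalPrior
    tau_d: TruncatedNormalPrior
    c0: TruncatedNormalPrior
    sigma2: InverseGammaPrior
    sigma2_b: InverseGammaPrior

    def __post_init__(self):
        for f in fields(self):
            value = getattr(self, f.name)
            expected = _FAMILIES[f.name]
            if not isinstance(value, expected):
                raise DomainError(
                    f"prior for {f.name} must be {expected.__name__}, "
                    f"got {type(value).__name__}"
                )
        if self.tau_r.mean() >= self.tau_d.mean():
            raise DomainError(
                "tau_r prior mean must be below tau_d prior mean "
                f"({self.tau_r.mean():.4g} >= {self.tau_d.mean():.4g})"
            )

    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self))

    def mean_theta(self) -> ModelParameters:
        """Deterministic starting point: per-parameter prior means."""
        return ModelParameters(**{n: getattr(self, n).mean() for n in self.names()})

    def draw_theta(
        self, rng: np.random.Generator, max_tries: int = 100
    ) -> ModelParameters:
        """Joint prior draw, redrawing the kinetic pair until tau_r < tau_d."""
        values = {n: getattr(self, n).draw(rng) for n in self.names()}
        tries = 0
        while values["tau_r"] >= values["tau_d"]:
            values["tau_r"] = self.tau_r.draw(rng)
            values["tau_d"] = self.tau_d.draw(rng)
            tries += 1
            if tries >= max_tries:
                raise DomainError(
                    "could not draw tau_r < tau_d from the priors; "
                    "check the kinetic hyperparameters"
                )
        return ModelParameters(**values)

    def logpdf(self, theta: ModelParameters) -> float:
        return sum(
            getattr(self, n).logpdf(getattr(theta, n)) for n in self.names()
        )
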