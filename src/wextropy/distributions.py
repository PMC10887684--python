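"""Catalogue of lifetime distributions used for theory and simulation.

Each :class:`DistributionSpec` carries the density ``f``, its first two
derivatives (analytic, needed by the bias expansion of the log-kernel
density estimator), an inverse-transform sampler, the quantile function,
and — where available — closed forms for the extropy
``J(X) = -1/2 \\int f^2`` and the weighted extropy
``Jw(X) = -1/2 \\int x f^2``.

Families
--------
``exponential(rate)``
    ``f(x) = rate * exp(-rate x)``.  Weighted extropy ``-1/8`` for every
    rate, a convenient scale-free reference value.
``lognormal(mu, sigma)``
    Weighted extropy ``-1/(4 sigma sqrt(pi))``, free of ``mu``.
``uniform01``
    Uniform on ``(0, 1)``; weighted extropy ``-1/4``.
``power2x``
    Density ``2x`` on ``(0, 1)``; the square of such a variable is
    standard uniform.  Weighted extropy ``-1/2``.
``rayleigh1``
    Rayleigh with scale 1, ``f(x) = x exp(-x^2/2)``; the square is
    exponential with mean 2.  Weighted extropy ``-1/4``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .exceptions import DomainError

__all__ = [
    "DistributionSpec",
    "exponential",
    "lognormal",
    "uniform01",
    "power2x",
    "rayleigh1",
    "get_distribution",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_SQRT_PI = math.sqrt(math.pi)


@dataclass(frozen=True)
class DistributionSpec:
    """A lifetime distribution with the functionals the estimators need."""

    family: str
    params: dict = field(default_factory=dict)
    pdf: Callable[[np.ndarray], np.ndarray] = None
    pdf_d1: Callable[[np.ndarray], np.ndarray] = None
    pdf_d2: Callable[[np.ndarray], np.ndarray] = None
    sampler: Callable[[int, np.random.Generator], np.ndarray] = None
    quantile: Callable[[float], float] = None
    support: tuple = (0.0, math.inf)
    closed_form_we: Optional[float] = None
    closed_form_extropy: Optional[float] = None

    @property
    def name(self) -> str:
        if self.params:
            inner = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
            return f"{self.family}({inner})"
        return self.family

    def in_support(self, x) -> np.ndarray:
        lo, hi = self.support
        x = np.asarray(x, dtype=float)
        return (x > lo) & (x < hi)


def _open_uniform(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform draws on the open interval (0, 1)."""
    u = rng.random(n)
    while True:
        bad = u <= 0.0
        if not np.any(bad):
            return u
        u[bad] = rng.random(int(bad.sum()))


def exponential(rate: float = 1.0) -> DistributionSpec:
    if not rate > 0:
        raise DomainError("exponential rate must be positive")
    lam = float(rate)

    def pdf(x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, lam * np.exp(-lam * np.clip(x, 0, None)), 0.0)

    return DistributionSpec(
        family="exponential",
        params={"rate": lam},
        pdf=pdf,
        pdf_d1=lambda x: -lam * pdf(x),
        pdf_d2=lambda x: lam * lam * pdf(x),
        sampler=lambda n, rng: -np.log(_open_uniform(rng, n)) / lam,
        quantile=lambda p: -math.log1p(-p) / lam,
        support=(0.0, math.inf),
        closed_form_we=-0.125,
        closed_form_extropy=-lam / 4.0,
    )


def lognormal(mu: float = 0.0, sigma: float = 1.0) -> DistributionSpec:
    if not sigma > 0:
        raise DomainError("lognormal sigma must be positive")
    mu, sigma = float(mu), float(sigma)
    s2 = sigma * sigma

    def pdf(x):
        x = np.asarray(x, dtype=float)
        xp = np.where(x > 0, x, 1.0)
        u = np.log(xp) - mu
        val = np.exp(-u * u / (2.0 * s2)) / (xp * sigma * _SQRT_2PI)
        return np.where(x > 0, val, 0.0)

    def pdf_d1(x):
        x = np.asarray(x, dtype=float)
        xp = np.where(x > 0, x, 1.0)
        u = np.log(xp) - mu
        return np.where(x > 0, -pdf(xp) * (1.0 + u / s2) / xp, 0.0)

    def pdf_d2(x):
        x = np.asarray(x, dtype=float)
        xp = np.where(x > 0, x, 1.0)
        u = np.log(xp) - mu
        a = 1.0 + u / s2
        return np.where(x > 0, pdf(xp) / (xp * xp) * (a * a + a - 1.0 / s2), 0.0)

    from scipy.special import ndtri

    return DistributionSpec(
        family="lognormal",
        params={"mu": mu, "sigma": sigma},
        pdf=pdf,
        pdf_d1=pdf_d1,
        pdf_d2=pdf_d2,
        sampler=lambda n, rng: np.exp(mu + sigma * rng.standard_normal(n)),
        quantile=lambda p: math.exp(mu + sigma * float(ndtri(p))),
        support=(0.0, math.inf),
        closed_form_we=-1.0 / (4.0 * sigma * _SQRT_PI),
        closed_form_extropy=-math.exp(s2 / 4.0 - mu) / (4.0 * sigma * _SQRT_PI),
    )


def uniform01() -> DistributionSpec:
    def pdf(x):
        x = np.asarray(x, dtype=float)
        return np.where((x > 0) & (x < 1), 1.0, 0.0)

    zero = lambda x: np.zeros_like(np.asarray(x, dtype=float))
    return DistributionSpec(
        family="uniform01",
        pdf=pdf,
        pdf_d1=zero,
        pdf_d2=zero,
        sampler=lambda n, rng: _open_uniform(rng, n),
        quantile=lambda p: float(p),
        support=(0.0, 1.0),
        closed_form_we=-0.25,
        closed_form_extropy=-0.5,
    )


def power2x() -> DistributionSpec:
    """Density ``2x`` on (0, 1); inverse-transform sampler ``X = sqrt(U)``."""

    def pdf(x):
        x = np.asarray(x, dtype=float)
        return np.where((x > 0) & (x < 1), 2.0 * x, 0.0)

    def pdf_d1(x):
        x = np.asarray(x, dtype=float)
        return np.where((x > 0) & (x < 1), 2.0, 0.0)

    return DistributionSpec(
        family="power2x",
        pdf=pdf,
        pdf_d1=pdf_d1,
        pdf_d2=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        sampler=lambda n, rng: np.sqrt(_open_uniform(rng, n)),
        quantile=lambda p: math.sqrt(p),
        support=(0.0, 1.0),
        closed_form_we=-0.5,
        closed_form_extropy=-2.0 / 3.0,
    )


def rayleigh1() -> DistributionSpec:
    """Rayleigh with scale 1; inverse-transform sampler ``X = sqrt(-2 log U)``."""

    def pdf(x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, x * np.exp(-0.5 * x * x), 0.0)

    def pdf_d1(x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, (1.0 - x * x) * np.exp(-0.5 * x * x), 0.0)

    def pdf_d2(x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, (x * x * x - 3.0 * x) * np.exp(-0.5 * x * x), 0.0)

    return DistributionSpec(
        family="rayleigh1",
        pdf=pdf,
        pdf_d1=pdf_d1,
        pdf_d2=pdf_d2,
        sampler=lambda n, rng: np.sqrt(-2.0 * np.log(_open_uniform(rng, n))),
        quantile=lambda p: math.sqrt(-2.0 * math.log1p(-p)),
        support=(0.0, math.inf),
        closed_form_we=-0.25,
        closed_form_extropy=-_SQRT_PI / 8.0,
    )


_FACTORIES = {
    "exponential": exponential,
    "lognormal": lognormal,
    "uniform01": uniform01,
    "power2x": power2x,
    "rayleigh1": rayleigh1,
}


def get_distribution(family: str, **params) -> DistributionSpec:
    """Look up a catalogue family by name, e.g. ``get_distribution("exponential", rate=2)``."""
    try:
        factory = _FACTORIES[family]
    except KeyError:
        raise DomainError(
            f"unknown distribution family {family!r}; known: {sorted(_FACTORIES)}"
        ) from None
    return factory(**params)
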