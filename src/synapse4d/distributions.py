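"""Small parametric distribution objects used by the condition presets.

Presets need right-skewed, non-negative distributions whose medians can be
pinned to published summary statistics.  Log-normals are parameterised by
their *median* (not mu) because medians are what the calibration sources
print; a two-component log-normal mixture covers bimodal latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["LogNormal", "LogNormalMixture", "Uniform", "Beta", "Constant"]


@dataclass(frozen=True)
class LogNormal:
    """Log-normal given by median and log-space sigma, optionally truncated.

    ``low``/``high`` truncate by inverse-CDF sampling, so draws are exact
    (no rejection loop) and the seeded stream stays reproducible.
    """

    median: float
    sigma: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.median <= 0 or self.sigma <= 0:
            raise ValueError("median and sigma must be positive")

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    def mean(self) -> float:
        # untruncated mean; truncation bounds used here are always far tails
        return float(self.median * np.exp(self.sigma**2 / 2))

    def cdf(self, x):
        return sps.lognorm.cdf(x, s=self.sigma, scale=self.median)

    def sample(self, rng: np.random.Generator, size=None):
        lo = 0.0 if self.low is None else self.cdf(self.low)
        hi = 1.0 if self.high is None else self.cdf(self.high)
        u = rng.uniform(lo, hi, size=size)
        return sps.lognorm.ppf(u, s=self.sigma, scale=self.median)


@dataclass(frozen=True)
class LogNormalMixture:
    """Two-component log-normal mixture (fast/slow responder latencies)."""

    weight: float  # weight of the first component
    a: LogNormal = field(default_factory=lambda: LogNormal(1.0, 1.0))
    b: LogNormal = field(default_factory=lambda: LogNormal(1.0, 1.0))

    def __post_init__(self):
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")

    def mean(self) -> float:
        return self.weight * self.a.mean() + (1 - self.weight) * self.b.mean()

    def cdf(self, x):
        return self.weight * self.a.cdf(x) + (1 - self.weight) * self.b.cdf(x)

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            comp = self.a if rng.random() < self.weight else self.b
            return comp.sample(rng)
        pick = rng.random(size) < self.weight
        out = np.empty(size, dtype=float)
        out[pick] = self.a.sample(rng, int(pick.sum()))
        out[~pick] = self.b.sample(rng, int((~pick).sum()))
        return out


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def mean(self) -> float:
        return 0.5 * (self.low + self.high)

    def cdf(self, x):
        return np.clip((np.asarray(x) - self.low) / (self.high - self.low), 0, 1)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.low, self.high, size=size)


@dataclass(frozen=True)
class Beta:
    """Beta distribution on [0, 1]; used for true depleted-area fractions."""

    a: float
    b: float

    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def cdf(self, x):
        return sps.beta.cdf(x, self.a, self.b)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.a, self.b, size=size)


@dataclass(frozen=True)
class Constant:
    value: float

    def mean(self) -> float:
        return self.value

    def cdf(self, x):
        return (np.asarray(x) >= self.value).astype(float)

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value, dtype=float)
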