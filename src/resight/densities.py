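"""Continuous densities on [0, 1] for sighting quality.

Quality is a subjective score of how convincing a sighting is (1 = certain).
Expert judgements arrive as triangle densities (lower/best/upper), published
records as uniform ranges, and model fits as Beta laws.  Linear opinion
pooling combines triangles into weighted mixtures.  Every density exposes
quadrature nodes so likelihoods can marginalise over quality exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "QualityDensity",
    "PointQuality",
    "UniformQuality",
    "TriangleDensity",
    "BetaQuality",
    "MixtureQuality",
]

_MODE_GRID = np.linspace(0.0, 1.0, 1001)  # 1e-3 resolution for mode search


class QualityDensity:
    """A probability density for one sighting's quality, supported on [0, 1]."""

    support: tuple[float, float] = (0.0, 1.0)

    def pdf(self, q):  # pragma: no cover - abstract
        raise NotImplementedError

    def rvs(self, rng: np.random.Generator, size=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def mean(self) -> float:
        x, w = self.nodes_weights(64)
        return float(np.sum(w * x))

    def mode(self) -> float:
        """Peak of the density, by grid search at 1e-3 resolution.

        Ties break toward the lower value (``argmax`` returns the first).
        """
        return float(_MODE_GRID[np.argmax(self.pdf(_MODE_GRID))])

    def nodes_weights(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Quadrature nodes/weights such that ``E[f(Q)] ~= sum(w * f(x))``.

        Gauss–Legendre within each smooth segment of the density.
        """
        nodes, weights = [], []
        breaks = np.unique(np.clip(self._breakpoints(), *self.support))
        gl_x, gl_w = np.polynomial.legendre.leggauss(max(2, n // max(1, len(breaks) - 1)))
        for a, b in zip(breaks[:-1], breaks[1:]):
            if b <= a:
                continue
            x = 0.5 * (b - a) * gl_x + 0.5 * (a + b)
            w = 0.5 * (b - a) * gl_w * self.pdf(x)
            nodes.append(x)
            weights.append(w)
        x = np.concatenate(nodes)
        w = np.concatenate(weights)
        return x, w / w.sum()  # renormalise residual quadrature error

    def _breakpoints(self) -> np.ndarray:
        lo, hi = self.support
        return np.array([lo, hi])


@dataclass(frozen=True)
class PointQuality(QualityDensity):
    """Degenerate density: the quality is known exactly."""

    q: float

    def __post_init__(self):
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"quality {self.q} outside [0, 1]")
        object.__setattr__(self, "support", (self.q, self.q))

    def pdf(self, q):
        q = np.asarray(q, dtype=float)
        return np.where(q == self.q, np.inf, 0.0)

    def rvs(self, rng, size=None):
        return np.full(size, self.q) if size is not None else self.q

    def mean(self):
        return self.q

    def mode(self):
        return self.q

    def nodes_weights(self, n):
        return np.array([self.q]), np.array([1.0])


@dataclass(frozen=True)
class UniformQuality(QualityDensity):
    """Uniform(lo, hi) quality, the form used for published range scores."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError(f"invalid quality range ({self.lo}, {self.hi})")
        object.__setattr__(self, "support", (self.lo, self.hi))

    def pdf(self, q):
        q = np.asarray(q, dtype=float)
        return np.where((q >= self.lo) & (q <= self.hi), 1.0 / (self.hi - self.lo), 0.0)

    def rvs(self, rng, size=None):
        return rng.uniform(self.lo, self.hi, size=size)

    def mean(self):
        return 0.5 * (self.lo + self.hi)

    def midpoint(self):
        return self.mean()


@dataclass(frozen=True)
class TriangleDensity(QualityDensity):
    """Triangle density from one expert's (lower, best, upper) judgement."""

    lower: float
    best: float
    upper: float

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.best <= self.upper <= 1.0):
            raise ValueError(
                f"need 0 <= lower <= best <= upper <= 1; got "
                f"({self.lower}, {self.best}, {self.upper})"
            )
        object.__setattr__(self, "support", (self.lower, self.upper))

    @property
    def _frozen(self):
        scale = self.upper - self.lower
        c = 0.5 if scale == 0 else (self.best - self.lower) / scale
        return stats.triang(c, loc=self.lower, scale=scale)

    def pdf(self, q):
        if self.upper == self.lower:
            return PointQuality(self.best).pdf(q)
        return self._frozen.pdf(np.asarray(q, dtype=float))

    def rvs(self, rng, size=None):
        if self.upper == self.lower:
            return np.full(size, self.best) if size is not None else self.best
        return self._frozen.rvs(size=size, random_state=rng)

    def mean(self):
        return (self.lower + self.best + self.upper) / 3.0

    def mode(self):
        return self.best

    def _breakpoints(self):
        return np.array([self.lower, self.best, self.upper])

    def nodes_weights(self, n):
        if self.upper == self.lower:
            return np.array([self.best]), np.array([1.0])
        return super().nodes_weights(n)


@dataclass(frozen=True)
class BetaQuality(QualityDensity):
    """Beta(a, b) quality law (the parametric summary used by the models)."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shape parameters must be positive")

    def pdf(self, q):
        return stats.beta.pdf(np.asarray(q, dtype=float), self.a, self.b)

    def rvs(self, rng, size=None):
        return rng.beta(self.a, self.b, size=size)

    def mean(self):
        return self.a / (self.a + self.b)

    def mode(self):
        if self.a > 1 and self.b > 1:
            return (self.a - 1) / (self.a + self.b - 2)
        return float(_MODE_GRID[np.argmax(self.pdf(_MODE_GRID))])


class MixtureQuality(QualityDensity):
    """Weighted mixture of quality densities (a linear opinion pool)."""

    def __init__(self, components: Sequence[QualityDensity], weights=None):
        if len(components) == 0:
            raise ValueError("mixture needs at least one component")
        self.components = list(components)
        if weights is None:
            weights = np.ones(len(components))
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("mixture weights must be nonnegative")
        total = weights.sum()
        if total <= 0:
            raise ValueError("mixture weights must not all be zero")
        self.weights = weights / total
        self.support = (
            min(c.support[0] for c in self.components),
            max(c.support[1] for c in self.components),
        )

    def pdf(self, q):
        q = np.asarray(q, dtype=float)
        out = np.zeros_like(q, dtype=float)
        for w, c in zip(self.weights, self.components):
            out = out + w * c.pdf(q)
        return out

    def rvs(self, rng, size=None):
        n = 1 if size is None else int(np.prod(size))
        idx = rng.choice(len(self.components), size=n, p=self.weights)
        draws = np.empty(n)
        for i in np.unique(idx):
            sel = idx == i
            draws[sel] = self.components[i].rvs(rng, size=int(sel.sum()))
        if size is None:
            return float(draws[0])
        return draws.reshape(size)

    def mean(self):
        return float(np.sum(self.weights * np.array([c.mean() for c in self.components])))

    def nodes_weights(self, n):
        per = max(2, n // len(self.components))
        nodes, weights = [], []
        for w, c in zip(self.weights, self.components):
            x, wx = c.nodes_weights(per)
            nodes.append(x)
            weights.append(w * wx)
        x = np.concatenate(nodes)
        w = np.concatenate(weights)
        return x, w / w.sum()
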