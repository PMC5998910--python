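"""Triangular fuzzy numbers, alpha-cuts, and membership-curve composition.

A triangular fuzzy number (a, b, c) models an uncertain quantity whose most
plausible value is the mode b and whose support is the interval [a, c];
membership rises linearly from 0 at a to 1 at b and falls back to 0 at c.

Uncertainty is propagated through a model by *alpha-cut decomposition*
(Zadeh's extension principle): each fuzzy number is sliced into horizontal
cuts -- the crisp intervals of values with membership >= alpha -- crisp
samples drawn from the cuts are pushed through the model, and the resulting
output intervals are stacked back, level by level, into an output membership
curve.  This module provides the number type, the cut/discretization
primitives, and the re-composition step; the simulation machinery lives in
:mod:`fcpn.fuzzysim`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "TriangularFuzzyNumber",
    "AlphaLevelGrid",
    "MembershipCurve",
    "membership",
    "alpha_cut",
    "discretize_cut",
    "compose_membership",
]


@dataclass(frozen=True)
class Interval:
    """Closed real interval [lo, hi]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.hi):
            raise ValueError(f"invalid interval: lo={self.lo} > hi={self.hi}")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def is_degenerate(self) -> bool:
        return self.lo == self.hi

    def contains(self, x: float, tol: float = 0.0) -> bool:
        return self.lo - tol <= x <= self.hi + tol

    def union(self, other: "Interval") -> "Interval":
        return Interval(min(self.lo, other.lo), max(self.hi, other.hi))


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Triangular fuzzy number (a, b, c) with a <= b <= c.

    Degenerate shapes are allowed: a == b or b == c collapse the
    corresponding linear branch (membership jumps to 1 at the mode), and
    a == b == c is a crisp value wrapped as a fuzzy number.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ValueError(
                f"triangular fuzzy number requires a <= b <= c, got "
                f"({self.a}, {self.b}, {self.c})"
            )

    @classmethod
    def crisp(cls, value: float) -> "TriangularFuzzyNumber":
        return cls(value, value, value)

    @property
    def mode(self) -> float:
        return self.b

    @property
    def is_crisp(self) -> bool:
        return self.a == self.c

    @property
    def support(self) -> Interval:
        return Interval(self.a, self.c)

    def membership(self, x: float) -> float:
        """Piecewise-linear membership degree of ``x`` in [0, 1]."""
        if x < self.a or x > self.c:
            return 0.0
        if x == self.b:
            return 1.0
        if x < self.b:
            return (x - self.a) / (self.b - self.a)
        return (self.c - x) / (self.c - self.b)

    def alpha_cut(self, alpha: float) -> Interval:
        """Crisp interval of values with membership >= ``alpha``.

        The bounds are ``[a + alpha (b - a), c - alpha (c - b)]``; the two
        extreme levels are special-cased so that the support at alpha = 0 and
        the mode point at alpha = 1 are reproduced exactly (no floating-point
        round-off on the cut ends).
        """
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {alpha}")
        if alpha == 0.0:
            return Interval(self.a, self.c)
        if alpha == 1.0:
            return Interval(self.b, self.b)
        return Interval(
            self.a + alpha * (self.b - self.a),
            self.c - alpha * (self.c - self.b),
        )


def membership(tfn: TriangularFuzzyNumber, x: float) -> float:
    """Membership degree of ``x`` under the triangular number ``tfn``."""
    return tfn.membership(x)


def alpha_cut(tfn: TriangularFuzzyNumber, alpha: float) -> Interval:
    """Alpha-cut of ``tfn`` at level ``alpha``."""
    return tfn.alpha_cut(alpha)


def discretize_cut(cut: Interval, k: int) -> list[float]:
    """``k`` uniformly spaced crisp samples of ``cut`` including both ends.

    A degenerate (single-point) cut always yields its single value; a proper
    cut needs at least two samples so that both support corners are hit.
    """
    if k < 1:
        raise ValueError(f"sample count must be >= 1, got {k}")
    if cut.is_degenerate:
        return [cut.lo]
    if k < 2:
        raise ValueError("a non-degenerate cut requires K >= 2 samples")
    return [float(v) for v in np.linspace(cut.lo, cut.hi, k)]


@dataclass(frozen=True)
class AlphaLevelGrid:
    """Ordered grid of alpha levels spanning [0, 1].

    The grid always contains both 0 (the full support) and 1 (the crisp
    mode); levels are strictly increasing.
    """

    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        lv = self.levels
        if len(lv) < 2:
            raise ValueError("an alpha grid needs at least the levels 0 and 1")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError(f"alpha levels must be strictly increasing: {lv}")
        if lv[0] != 0.0 or lv[-1] != 1.0:
            raise ValueError(f"alpha grid must span [0, 1], got {lv}")

    @classmethod
    def uniform(cls, j: int) -> "AlphaLevelGrid":
        """Uniform grid of ``j`` levels from 0 to 1 inclusive."""
        if j < 2:
            raise ValueError(f"need at least 2 alpha levels, got {j}")
        return cls(tuple(float(a) for a in np.linspace(0.0, 1.0, j)))

    @classmethod
    def from_levels(cls, levels: Iterable[float]) -> "AlphaLevelGrid":
        return cls(tuple(sorted(float(a) for a in levels)))

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self) -> Iterator[float]:
        return iter(self.levels)


@dataclass(frozen=True)
class MembershipCurve:
    """A membership function represented as a stack of nested alpha-cuts.

    ``levels`` is an ordered list of (alpha, cut) pairs with strictly
    increasing alpha and cuts nested downward (the cut at a lower alpha
    contains every cut above it).  Linear interpolation between the cut
    bounds reconstructs the membership function.
    """

    levels: tuple[tuple[float, Interval], ...]

    def __post_init__(self) -> None:
        alphas = [a for a, _ in self.levels]
        if any(b <= a for a, b in zip(alphas, alphas[1:])):
            raise ValueError("alpha levels must be strictly increasing")
        for (_, lower), (_, upper) in zip(self.levels, self.levels[1:]):
            if upper.lo < lower.lo or upper.hi > lower.hi:
                raise ValueError("cuts must be nested: lower alpha contains higher")

    @property
    def alphas(self) -> tuple[float, ...]:
        return tuple(a for a, _ in self.levels)

    @property
    def cuts(self) -> tuple[Interval, ...]:
        return tuple(c for _, c in self.levels)

    @property
    def support(self) -> Interval:
        return self.levels[0][1]

    def cut_at(self, alpha: float, tol: float = 1e-12) -> Interval:
        for a, cut in self.levels:
            if math.isclose(a, alpha, rel_tol=0.0, abs_tol=tol):
                return cut
        raise KeyError(f"no cut stored at alpha={alpha}")

    def membership(self, x: float) -> float:
        """Piecewise-linear membership reconstructed from the cut stack."""
        lows = np.array([c.lo for c in self.cuts])
        highs = np.array([c.hi for c in self.cuts])
        alphas = np.array(self.alphas)
        if x < lows[0] or x > highs[0]:
            return 0.0
        left = float(np.interp(x, lows, alphas))
        right = float(np.interp(x, highs[::-1], alphas[::-1]))
        return min(left, right)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": list(self.alphas),
                "lo": [c.lo for c in self.cuts],
                "hi": [c.hi for c in self.cuts],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compose_membership(
    cuts: Iterable[tuple[float, Interval]]
) -> MembershipCurve:
    """Stack per-level output cuts into a membership curve.

    Sparse sampling can make a raw cut at a low alpha narrower than a cut
    above it, which would violate nesting; each cut is therefore widened to
    contain the union of all cuts at higher levels before stacking
    (union-with-above repair).
    """
    items = sorted(cuts, key=lambda ac: ac[0])
    alphas = [a for a, _ in items]
    if len(set(alphas)) != len(alphas):
        raise ValueError(f"duplicate alpha levels in cut stack: {alphas}")
    repaired: list[tuple[float, Interval]] = []
    running: Interval | None = None
    for alpha, cut in reversed(items):
        running = cut if running is None else cut.union(running)
        repaired.append((alpha, running))
    return MembershipCurve(tuple(reversed(repaired)))
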