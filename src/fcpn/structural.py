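"""Minimal T-invariant enumeration and coverage on the incidence matrix.

A T-invariant is a semi-positive integer transition vector x with
C x = 0, where C is the |P| x |T| incidence matrix: firing every
transition t exactly x_t times reproduces the marking, so each minimal
invariant is an elementary behavioural mode of the network (a reversible
reaction pair, a futile cycle, a production/degradation loop, ...).  A net
is *covered* when every transition participates in at least one invariant.

Enumeration uses the classical Farkas-style non-negative elimination on
[C^T | I] in exact Python integer arithmetic -- minimal-support kernel
enumeration is numerically unstable in floating point, and the invariants
are integer objects anyway.  Rows are gcd-reduced and support-pruned after
each elimination step, which keeps exactly the support-minimal solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import FuzzyContinuousPetriNet

__all__ = [
    "TInvariant",
    "UnsupportedAnalysisError",
    "minimal_t_invariants",
    "coverage",
]


class UnsupportedAnalysisError(ValueError):
    """Structural analysis requires integral arc weights."""


@dataclass(frozen=True)
class TInvariant:
    """Canonical minimal T-invariant: positive entries only, gcd 1."""

    counts: tuple[tuple[str, int], ...]  # (transition id, multiplicity)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(tid for tid, _ in self.counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def multiplicity(self, transition_id: str) -> int:
        return dict(self.counts).get(transition_id, 0)

    def vector(self, net: FuzzyContinuousPetriNet) -> list[int]:
        d = dict(self.counts)
        return [d.get(tid, 0) for tid in net.transition_ids]


def _integer_incidence(net: FuzzyContinuousPetriNet) -> list[list[int]]:
    for arc in net.arcs:
        if not float(arc.weight).is_integer():
            raise UnsupportedAnalysisError(
                f"T-invariant analysis needs integral arc weights; arc "
                f"{arc.source}->{arc.target} has weight {arc.weight}"
            )
    inc = net.incidence_matrix()
    return [[int(round(v)) for v in row] for row in inc]


def _gcd_reduce(row: tuple[int, ...]) -> tuple[int, ...]:
    g = 0
    for v in row:
        g = math.gcd(g, abs(v))
    return row if g <= 1 else tuple(v // g for v in row)


def _prune(rows: list[tuple[tuple[int, ...], tuple[int, ...]]]):
    """Drop duplicates and rows whose x-support strictly contains another's."""
    uniq = list(dict.fromkeys(rows))
    supports = [frozenset(i for i, v in enumerate(x) if v) for _, x in uniq]
    keep = []
    for i, (row, sup) in enumerate(zip(uniq, supports)):
        # only strict subsets dominate: equal supports with different
        # vectors must both survive intermediate elimination steps
        dominated = any(
            other < sup for j, other in enumerate(supports) if j != i
        )
        if not dominated:
            keep.append(row)
    return keep


def minimal_t_invariants(net: FuzzyContinuousPetriNet) -> list[TInvariant]:
    """All support-minimal semi-positive integer solutions of C x = 0.

    Deterministic output order: by support size, then lexicographically by
    the supported transitions' declaration indices.  Every returned vector
    is re-verified against the incidence matrix in exact arithmetic.
    """
    c = _integer_incidence(net)
    n_p, n_t = len(net.places), len(net.transitions)
    # rows of [C^T | I]: (residual place effect, transition multiplicities)
    rows: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    for t in range(n_t):
        effect = tuple(c[p][t] for p in range(n_p))
        x = tuple(1 if j == t else 0 for j in range(n_t))
        rows.append((effect, x))

    for p in range(n_p):
        zero = [r for r in rows if r[0][p] == 0]
        pos = [r for r in rows if r[0][p] > 0]
        neg = [r for r in rows if r[0][p] < 0]
        new = list(zero)
        for e1, x1 in pos:
            for e2, x2 in neg:
                c1, c2 = -e2[p], e1[p]
                merged = _gcd_reduce(
                    tuple(c1 * a + c2 * b for a, b in zip(e1 + x1, e2 + x2))
                )
                new.append((merged[:n_p], merged[n_p:]))
        rows = _prune(new)

    tids = net.transition_ids
    tidx = net.transition_index
    results: dict[frozenset[str], TInvariant] = {}
    for effect, x in rows:
        assert all(v == 0 for v in effect)
        x = _gcd_reduce(x)
        # exact re-verification, not trusted from the elimination
        for p in range(n_p):
            balance = sum(c[p][t] * x[t] for t in range(n_t))
            if balance != 0:
                raise RuntimeError(
                    f"internal error: candidate invariant violates C.x=0 at "
                    f"place {net.place_ids[p]}"
                )
        inv = TInvariant(
            tuple((tids[t], x[t]) for t in range(n_t) if x[t] > 0)
        )
        results.setdefault(inv.support, inv)

    final = [
        inv
        for inv in results.values()
        if not any(
            other.support < inv.support for other in results.values()
        )
    ]
    final.sort(
        key=lambda inv: (
            len(inv.support),
            tuple(sorted(tidx[t] for t in inv.support)),
        )
    )
    return final


def coverage(
    net: FuzzyContinuousPetriNet, invariants: Iterable[TInvariant]
) -> tuple[bool, tuple[str, ...]]:
    """Whether every transition has a positive entry in some invariant."""
    invs = list(invariants)
    uncovered = tuple(
        tid
        for tid in net.transition_ids
        if all(inv.multiplicity(tid) == 0 for inv in invs)
    )
    return (len(uncovered) == 0, uncovered)
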