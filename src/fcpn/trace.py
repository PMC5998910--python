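"""Derivative-based trace queries (simulative model checking fragment).

Two "eventually" patterns over the derivative sign of a simulated species
answer shape questions about a trace Tr:

* rise-then-fall  --  F( d[Tr] > 0  &  F( d[Tr] < 0 ) ):
  there is a time with positive derivative followed later by a time with
  negative derivative (the trace has a peak);
* second-rise  --  F( d[Tr] > 0  &  F( d[Tr] < 0  &  F( d[Tr] > 0 ) ) ):
  a rise, a later fall, and a still later rise (a second peak is forming).

A trace has a *single peak* iff rise-then-fall holds and second-rise does
not.  "Eventually" is evaluated over the discrete output grid in strict
index order.  The derivative is the model's own right-hand side evaluated
at each grid state -- exact with respect to the ODE system, not a finite
difference -- with a finite-difference fallback for traces whose model is
unavailable.  A sign deadband maps |d| <= eps to 0 so that numerical
jitter around an equilibrium cannot fabricate peaks.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .model import FuzzyContinuousPetriNet
from .odes import Trace, _mass_action_rates

__all__ = [
    "derivative_series",
    "finite_difference_series",
    "sign_series",
    "default_deadband",
    "eval_rise_fall",
    "eval_second_rise",
    "single_peak",
    "satisfaction_fraction",
]


def derivative_series(
    net: FuzzyContinuousPetriNet,
    trace: Trace,
    place_id: str,
    crisp_params: Mapping[str, float] | None = None,
) -> np.ndarray:
    """d(place)/dt at every grid point, via the ODE right-hand side."""
    if place_id not in net.place_ids:
        raise LookupError(f"unknown place '{place_id}'")
    j = net.place_index[place_id]
    theta = net.effective_constants(crisp_params)
    pre = net.pre_matrix()
    inc_row = net.incidence_matrix()[j]
    m = np.clip(trace.values, 0.0, None)
    # rates for all time points at once: (n_times, n_transitions)
    rates = theta[None, :] * np.prod(
        m[:, :, None] ** pre[None, :, :], axis=1
    )
    return rates @ inc_row


def finite_difference_series(trace: Trace, place_id: str) -> np.ndarray:
    """Central finite-difference derivative for model-free (imported) traces."""
    return np.gradient(trace.column(place_id), trace.times)


def default_deadband(series: Sequence[float], rel: float = 1e-6) -> float:
    """Deadband scaled to the series: rel x max |d| (0 for an all-zero series)."""
    arr = np.asarray(series, dtype=float)
    return float(rel * np.max(np.abs(arr), initial=0.0))


def sign_series(series: Sequence[float], eps: float = 0.0) -> np.ndarray:
    """Per-point derivative sign in {-1, 0, +1}; |d| <= eps maps to 0."""
    arr = np.asarray(series, dtype=float)
    return np.where(np.abs(arr) <= eps, 0, np.sign(arr)).astype(int)


def eval_rise_fall(signs: Sequence[int]) -> bool:
    """True iff some +1 is followed (strictly later) by a -1."""
    seen_rise = False
    for s in signs:
        if s > 0:
            seen_rise = True
        elif s < 0 and seen_rise:
            return True
    return False


def eval_second_rise(signs: Sequence[int]) -> bool:
    """True iff signs +1, -1, +1 occur at strictly increasing indices."""
    stage = 0  # 0: want rise, 1: want fall, 2: want second rise
    for s in signs:
        if stage == 0 and s > 0:
            stage = 1
        elif stage == 1 and s < 0:
            stage = 2
        elif stage == 2 and s > 0:
            return True
    return False


def single_peak(
    net: FuzzyContinuousPetriNet,
    trace: Trace,
    place_id: str,
    crisp_params: Mapping[str, float] | None = None,
    eps: float | None = None,
) -> bool:
    """Rise-then-fall and no second rise, on the RHS derivative signs."""
    series = derivative_series(net, trace, place_id, crisp_params)
    if eps is None:
        eps = default_deadband(series)
    signs = sign_series(series, eps)
    return eval_rise_fall(signs) and not eval_second_rise(signs)


def satisfaction_fraction(verdicts: Sequence[bool]) -> float:
    """Fraction of traces satisfying a query (the P=? estimate over traces)."""
    verdicts = list(verdicts)
    if not verdicts:
        raise ValueError("no verdicts given")
    return sum(bool(v) for v in verdicts) / len(verdicts)
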