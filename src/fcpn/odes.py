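"""Continuous place-balance semantics: ODE generation and crisp integration.

A continuous Petri net is a graphical notation for the ODE system

    d(p)/dt = sum_{t in pre(p)} f(t,p) v(t)  -  sum_{t in post(p)} f(p,t) v(t)

with mass-action rates ``v(t) = theta_t * prod_{p in pre(t)} m(p)^f(p,t)``:
the arc weight acts both as the kinetic exponent and as the stoichiometric
coefficient (continuous semantics; no discrete combinatorial correction).

Integration uses SciPy's LSODA by default -- the built-in heat shock system
mixes rate constants spanning nine orders of magnitude with a protein pool
of ~1e8 and is decidedly stiff -- with an analytic Jacobian assembled from
the same stoichiometric matrices as the right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import FuzzyContinuousPetriNet, ModelError

__all__ = [
    "SolverSettings",
    "SimulationError",
    "Trace",
    "rate_value",
    "derivatives",
    "ode_text",
    "simulate_crisp",
    "simulate_to_stationarity",
]


class SimulationError(RuntimeError):
    """Numerical integration failed or produced inadmissible values."""


@dataclass(frozen=True)
class SolverSettings:
    """Integration horizon, output grid, and tolerances.

    ``stiff=True`` selects LSODA with an analytic Jacobian; ``stiff=False``
    uses explicit RK45.  The output grid is uniform with ``n_points``
    samples including t=0 and ``t_end``.
    """

    t_end: float
    n_points: int = 201
    rtol: float = 1e-8
    atol: float = 1e-10
    stiff: bool = True

    def __post_init__(self) -> None:
        if not (self.t_end > 0.0):
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if not (self.rtol > 0.0 and self.atol > 0.0):
            raise ValueError("tolerances must be > 0")


@dataclass(frozen=True)
class Trace:
    """Simulation output on a uniform time grid, one column per place."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_places)
    places: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.times), len(self.places)):
            raise ValueError(
                f"trace shape {self.values.shape} does not match "
                f"{len(self.times)} times x {len(self.places)} places"
            )

    def column(self, place_id: str) -> np.ndarray:
        try:
            j = self.places.index(place_id)
        except ValueError:
            raise LookupError(f"unknown place '{place_id}'") from None
        return self.values[:, j]

    def index_at(self, tau: float) -> int:
        """Index of the grid point nearest to ``tau`` (ties go left)."""
        return int(np.argmin(np.abs(self.times - tau)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.places))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        places = tuple(c for c in df.columns if c != "time")
        return cls(df["time"].to_numpy(), df[list(places)].to_numpy(), places)


# -- rate evaluation ------------------------------------------------------


def _marking_vector(
    net: FuzzyContinuousPetriNet, marking: Mapping[str, float] | Sequence[float]
) -> np.ndarray:
    if isinstance(marking, Mapping):
        try:
            return np.array([float(marking[p]) for p in net.place_ids])
        except KeyError as exc:
            raise LookupError(f"marking missing place {exc}") from None
    m = np.asarray(marking, dtype=float)
    if m.shape != (len(net.places),):
        raise ValueError(
            f"marking length {m.shape} does not match {len(net.places)} places"
        )
    return m


def _mass_action_rates(
    theta: np.ndarray, pre: np.ndarray, marking: np.ndarray
) -> np.ndarray:
    m = np.clip(marking, 0.0, None)
    return theta * np.prod(m[:, None] ** pre, axis=0)


def rate_value(
    net: FuzzyContinuousPetriNet,
    transition_id: str,
    marking: Mapping[str, float] | Sequence[float],
    crisp_params: Mapping[str, float] | None = None,
) -> float:
    """Mass-action firing rate of one transition at a given marking."""
    try:
        j = net.transition_index[transition_id]
    except KeyError:
        raise LookupError(f"unknown transition '{transition_id}'") from None
    theta = net.effective_constants(crisp_params)
    m = _marking_vector(net, marking)
    pre = net.pre_matrix()
    return float(_mass_action_rates(theta, pre, m)[j])


def derivatives(
    net: FuzzyContinuousPetriNet,
    marking: Mapping[str, float] | Sequence[float],
    crisp_params: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Place-balance right-hand side: incidence matrix times rate vector."""
    theta = net.effective_constants(crisp_params)
    m = _marking_vector(net, marking)
    rates = _mass_action_rates(theta, net.pre_matrix(), m)
    return net.incidence_matrix() @ rates


# -- symbolic ODE listing -------------------------------------------------


def _fmt_weight(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(w)


def _rate_text(net: FuzzyContinuousPetriNet, j: int, pre: np.ndarray) -> str:
    tr = net.transitions[j]
    parts = [tr.rate.constant]
    for i, pid in enumerate(net.place_ids):
        w = pre[i, j]
        if w > 0:
            parts.append(pid if w == 1 else f"{pid}^{_fmt_weight(w)}")
    return "*".join(parts)


def ode_text(net: FuzzyContinuousPetriNet) -> str:
    """Canonical textual ODE system, one balance equation per place.

    Places appear in declaration order; within an equation, production
    terms come first and consumption terms second, each group in transition
    declaration order.  A transition that both consumes and produces a
    place with equal weight (a pure catalyst) contributes no term.
    """
    pre = net.pre_matrix()
    inc = net.incidence_matrix()
    lines = []
    for i, pid in enumerate(net.place_ids):
        pos_terms: list[str] = []
        neg_terms: list[str] = []
        for j in range(len(net.transitions)):
            k = inc[i, j]
            if k == 0:
                continue
            rate = _rate_text(net, j, pre)
            mag = abs(k)
            term = f"({rate})" if mag == 1 else f"{_fmt_weight(mag)}*({rate})"
            (pos_terms if k > 0 else neg_terms).append(term)
        if not pos_terms and not neg_terms:
            lines.append(f"d{pid}/dt = 0")
            continue
        expr = ""
        for term in pos_terms:
            expr = term if not expr else f"{expr} + {term}"
        for term in neg_terms:
            expr = f"-{term}" if not expr else f"{expr} - {term}"
        lines.append(f"d{pid}/dt = {expr}")
    return "\n".join(lines)


# -- integration ----------------------------------------------------------


def _rhs_and_jac(net: FuzzyContinuousPetriNet, theta: np.ndarray):
    pre = net.pre_matrix()
    inc = net.incidence_matrix()
    n_t = len(net.transitions)
    pre_idx = [np.nonzero(pre[:, j])[0] for j in range(n_t)]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return inc @ _mass_action_rates(theta, pre, y)

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        m = np.clip(y, 0.0, None)
        dv = np.zeros((n_t, len(y)))
        for j in range(n_t):
            for p in pre_idx[j]:
                w = pre[p, j]
                term = theta[j] * w * m[p] ** (w - 1.0)
                for q in pre_idx[j]:
                    if q != p:
                        term *= m[q] ** pre[q, j]
                dv[j, p] = term
        return inc @ dv

    return rhs, jac


def _finalize_values(values: np.ndarray, atol: float) -> np.ndarray:
    worst = float(values.min(initial=0.0))
    if worst < -10.0 * atol:
        raise SimulationError(
            f"trajectory undershot zero by {-worst:.3g}, beyond the "
            f"tolerance band; tighten atol or check the model"
        )
    return np.clip(values, 0.0, None)


def simulate_crisp(
    net: FuzzyContinuousPetriNet,
    crisp_params: Mapping[str, float] | None = None,
    settings: SolverSettings | None = None,
) -> Trace:
    """Integrate the crisply instantiated net over a uniform output grid.

    All fuzzy parameters must be given crisp samples via ``crisp_params``.
    Tiny negative undershoot (within 10x atol) is clipped to zero; anything
    worse raises.
    """
    if settings is None:
        raise ValueError("settings (at least t_end) are required")
    theta = net.effective_constants(crisp_params)
    rhs, jac = _rhs_and_jac(net, theta)
    t_eval = np.linspace(0.0, settings.t_end, settings.n_points)
    extra = {"jac": jac} if settings.stiff else {}
    sol = solve_ivp(
        rhs,
        (0.0, settings.t_end),
        net.initial_marking,
        method="LSODA" if settings.stiff else "RK45",
        t_eval=t_eval,
        rtol=settings.rtol,
        atol=settings.atol,
        **extra,
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}")
    values = _finalize_values(sol.y.T, settings.atol)
    return Trace(t_eval, values, net.place_ids)


def simulate_to_stationarity(
    net: FuzzyContinuousPetriNet,
    crisp_params: Mapping[str, float] | None = None,
    *,
    window: float = 100.0,
    rel_tol: float = 1e-6,
    n_points: int = 501,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_start: float = 2000.0,
    t_max: float = 1e9,
    stiff: bool = True,
) -> Trace:
    """Integrate with a doubling horizon until the state stops moving.

    The horizon starts at ``t_start`` and doubles until, for every species,
    the change over the trailing ``window`` seconds is below ``rel_tol``
    relative to the species' end value (species whose whole trajectory is
    negligible are compared against a small floor instead, so a population
    sitting at zero cannot stall detection).
    """
    theta = net.effective_constants(crisp_params)
    rhs, jac = _rhs_and_jac(net, theta)
    y0 = net.initial_marking
    t_end = float(t_start)
    while t_end <= t_max:
        extra = {"jac": jac} if stiff else {}
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            y0,
            method="LSODA" if stiff else "RK45",
            dense_output=True,
            rtol=rtol,
            atol=atol,
            **extra,
        )
        if not sol.success:
            raise SimulationError(f"integrator failed: {sol.message}")
        y_end = sol.sol(t_end)
        y_prev = sol.sol(max(0.0, t_end - window))
        coarse = np.abs(sol.sol(np.linspace(0.0, t_end, 129)))
        scale = np.maximum(
            np.abs(y_end), np.maximum(1e-9 * coarse.max(axis=1), 1e-300)
        )
        if float(np.max(np.abs(y_end - y_prev) / scale)) < rel_tol:
            t_eval = np.linspace(0.0, t_end, n_points)
            values = _finalize_values(sol.sol(t_eval).T, atol)
            return Trace(t_eval, values, net.place_ids)
        t_end *= 2.0
    raise SimulationError(f"no stationary state detected before t={t_max:g}")
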