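"""Fuzzy simulation: alpha-cut sampling, batch integration, band composition.

The fuzzy simulation of an FCPN propagates parameter uncertainty through
the ODE semantics by the extension principle:

1. slice every fuzzy kinetic constant into alpha-cuts on a shared level
   grid (J levels including 0 and 1);
2. discretize each cut into crisp samples and form the cross-product of
   samples over the I fuzzy parameters;
3. integrate the crisply instantiated net once per unique combination;
4. stack the per-level output extremes back into nested uncertain bands
   and, at any time point, into an output membership curve.

Two sampling strategies are provided.  ``full`` discretizes every cut into
K values (K^I x J combinations before the degenerate alpha=1 cut collapses
to the single mode).  ``efficient`` keeps the K-point discretization only
at the support level alpha=0 and samples just the two cut endpoints at
every other level (K^I + 2^I x (J-1) combinations), relying on trace
pooling to refill the interior: a trace computed at any level is reused at
level m whenever its parameter vector lies inside every parameter's
level-m cut.  Pooling is applied under both strategies, which also
guarantees band nesting across levels by construction of the pools
(the bands themselves are still asserted nested by the test suite, not
assumed).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import (
    AlphaLevelGrid,
    Interval,
    MembershipCurve,
    compose_membership,
    discretize_cut,
)
from .model import (
    FuzzyContinuousPetriNet,
    net_from_dict,
    net_to_dict,
)
from .odes import (
    SimulationError,
    SolverSettings,
    Trace,
    simulate_crisp,
    simulate_to_stationarity,
)

__all__ = [
    "SamplingPlan",
    "SampleCombination",
    "FuzzySimResult",
    "DegeneratePlanError",
    "FuzzySimulationError",
    "enumerate_samples",
    "run_fuzzy_simulation",
    "membership_at",
    "export_result",
    "replay_manifest",
]

STRATEGIES = ("full", "efficient")


class DegeneratePlanError(ValueError):
    """The net has no fuzzy parameters; fuzzy simulation is pointless."""


class FuzzySimulationError(RuntimeError):
    """A member simulation failed; the message names the combination."""


@dataclass(frozen=True)
class SamplingPlan:
    """Alpha-level grid, per-cut sample count K, and sampling strategy."""

    grid: AlphaLevelGrid
    samples_per_cut: int = 3
    strategy: str = "full"

    def __post_init__(self) -> None:
        if self.samples_per_cut < 2:
            raise ValueError(
                f"samples_per_cut must be >= 2, got {self.samples_per_cut}"
            )
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"strategy must be one of {STRATEGIES}, got '{self.strategy}'"
            )

    def nominal_combination_count(self, n_fuzzy: int) -> int:
        """Combination count before degenerate-cut collapsing.

        ``full``: K^I x J.  ``efficient``: K^I + 2^I x (J-1).
        """
        k, i, j = self.samples_per_cut, n_fuzzy, len(self.grid)
        if self.strategy == "full":
            return k**i * j
        return k**i + 2**i * (j - 1)


@dataclass(frozen=True)
class SampleCombination:
    """One crisp sample vector for the fuzzy parameters at one alpha level."""

    alpha: float
    values: tuple[tuple[str, float], ...]  # sorted by parameter id

    @property
    def vector(self) -> tuple[tuple[str, float], ...]:
        return self.values

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def enumerate_samples(
    net: FuzzyContinuousPetriNet, plan: SamplingPlan
) -> list[SampleCombination]:
    """Deterministic sample enumeration: levels ascending, then lexicographic.

    Degenerate cuts (always the alpha=1 cut, and every cut of a crisp-triple
    parameter) contribute their single point, so the returned list can be
    shorter than the nominal combination count.
    """
    fuzzy_ids = net.fuzzy_parameter_ids
    if not fuzzy_ids:
        raise DegeneratePlanError(
            "net has no fuzzy parameters; use simulate_crisp instead"
        )
    base_alpha = plan.grid.levels[0]
    combos: list[SampleCombination] = []
    for alpha in plan.grid:
        per_param: list[list[float]] = []
        for pid in fuzzy_ids:
            cut = net.parameters[pid].alpha_cut(alpha)
            if plan.strategy == "full" or alpha == base_alpha:
                vals = discretize_cut(cut, plan.samples_per_cut)
            else:
                vals = [cut.lo] if cut.is_degenerate else [cut.lo, cut.hi]
            per_param.append(vals)
        for tup in itertools.product(*per_param):
            combos.append(SampleCombination(alpha, tuple(zip(fuzzy_ids, tup))))
    return combos


@dataclass
class FuzzySimResult:
    """Traces, per-level uncertain bands, and membership composition.

    ``traces`` holds one crisp trace per unique parameter vector (identical
    combinations across levels are simulated once); ``level_pools`` maps
    each alpha level to the indices of the traces whose parameter vectors
    lie inside every parameter's cut at that level.
    """

    net: FuzzyContinuousPetriNet
    plan: SamplingPlan
    settings: SolverSettings
    combinations: list[SampleCombination]
    vectors: list[tuple[tuple[str, float], ...]]
    times: np.ndarray
    traces: np.ndarray  # (n_unique, n_times, n_places)
    level_pools: dict[float, tuple[int, ...]]

    @property
    def places(self) -> tuple[str, ...]:
        return self.net.place_ids

    def level_band(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) arrays of shape (n_times, n_places) at one alpha level."""
        pool = list(self.level_pools[alpha])
        sub = self.traces[pool]
        return sub.min(axis=0), sub.max(axis=0)

    def overall_band(self) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise min/max envelope over all traces (the alpha=0 band)."""
        return self.traces.min(axis=0), self.traces.max(axis=0)

    def band(
        self, place_id: str, alpha: float = 0.0
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times, lo, hi) band of one species at one alpha level."""
        j = self._place_col(place_id)
        lo, hi = self.level_band(alpha)
        return self.times, lo[:, j], hi[:, j]

    def _place_col(self, place_id: str) -> int:
        try:
            return self.places.index(place_id)
        except ValueError:
            raise LookupError(f"unknown place '{place_id}'") from None

    def trace_at(self, index: int) -> Trace:
        return Trace(self.times, self.traces[index], self.places)

    def membership_at(self, place_id: str, tau: float) -> MembershipCurve:
        """Output membership curve of one species at the grid point nearest tau."""
        j = self._place_col(place_id)
        idx = int(np.argmin(np.abs(self.times - tau)))
        cuts = []
        for alpha in self.plan.grid:
            pool = list(self.level_pools[alpha])
            vals = self.traces[pool, idx, j]
            cuts.append((alpha, Interval(float(vals.min()), float(vals.max()))))
        return compose_membership(cuts)


def membership_at(
    result: FuzzySimResult, place_id: str, tau: float
) -> MembershipCurve:
    """Functional alias for :meth:`FuzzySimResult.membership_at`."""
    return result.membership_at(place_id, tau)


def _containment_tol(cut: Interval) -> float:
    return 1e-12 * max(1.0, abs(cut.lo), abs(cut.hi))


def run_fuzzy_simulation(
    net: FuzzyContinuousPetriNet,
    plan: SamplingPlan,
    settings: SolverSettings | None = None,
    *,
    until_stationary: bool = False,
    horizon_factor: float = 1.0,
    crisp_overrides: Mapping[str, float] | None = None,
) -> FuzzySimResult:
    """Run one crisp simulation per unique sample combination and pool bands.

    With ``until_stationary`` the shared horizon is found first by running
    the all-modes (alpha=1) instantiation to stationarity and multiplying
    its horizon by ``horizon_factor``; all member simulations then share
    that grid, so bands are computable pointwise.  Sampling is fully
    deterministic -- there is no seed anywhere in the fuzzy machinery.
    """
    combos = enumerate_samples(net, plan)
    if until_stationary:
        base = dict(net.mode_parameters())
        if crisp_overrides:
            base.update(crisp_overrides)
        n_points = settings.n_points if settings is not None else 501
        mode_trace = simulate_to_stationarity(
            net,
            base,
            rtol=settings.rtol if settings else 1e-8,
            atol=settings.atol if settings else 1e-10,
        )
        settings = SolverSettings(
            t_end=float(mode_trace.times[-1]) * horizon_factor,
            n_points=n_points,
            rtol=settings.rtol if settings else 1e-8,
            atol=settings.atol if settings else 1e-10,
            stiff=settings.stiff if settings else True,
        )
    if settings is None:
        raise ValueError("settings are required unless until_stationary is set")

    vectors: list[tuple[tuple[str, float], ...]] = []
    seen: dict[tuple[tuple[str, float], ...], int] = {}
    for combo in combos:
        if combo.vector not in seen:
            seen[combo.vector] = len(vectors)
            vectors.append(combo.vector)

    trace_list = []
    for vec in vectors:
        params = dict(vec)
        if crisp_overrides:
            params.update(crisp_overrides)
        try:
            trace_list.append(simulate_crisp(net, params, settings).values)
        except SimulationError as exc:
            raise FuzzySimulationError(
                f"simulation failed for combination {params}: {exc}"
            ) from exc
    traces = np.array(trace_list)
    times = np.linspace(0.0, settings.t_end, settings.n_points)

    level_pools: dict[float, tuple[int, ...]] = {}
    for alpha in plan.grid:
        cuts = {
            pid: net.parameters[pid].alpha_cut(alpha)
            for pid in net.fuzzy_parameter_ids
        }
        pool = [
            i
            for i, vec in enumerate(vectors)
            if all(
                cuts[pid].contains(val, tol=_containment_tol(cuts[pid]))
                for pid, val in vec
            )
        ]
        if not pool:  # cannot happen: each level enumerates its own samples
            raise FuzzySimulationError(f"empty trace pool at alpha={alpha}")
        level_pools[alpha] = tuple(pool)

    return FuzzySimResult(
        net=net,
        plan=plan,
        settings=settings,
        combinations=combos,
        vectors=vectors,
        times=times,
        traces=traces,
        level_pools=level_pools,
    )


# -- export / replay ------------------------------------------------------


def _band_frame(result: FuzzySimResult, lo: np.ndarray, hi: np.ndarray) -> pd.DataFrame:
    data: dict[str, np.ndarray] = {"time": result.times}
    for j, pid in enumerate(result.places):
        data[f"{pid}_lo"] = lo[:, j]
        data[f"{pid}_hi"] = hi[:, j]
    return pd.DataFrame(data)


def export_result(
    result: FuzzySimResult,
    directory,
    membership_times: Sequence[float] = (),
) -> dict:
    """Write band CSVs, per-trace CSVs, membership CSVs, and a manifest.

    The manifest embeds the model document, plan, and solver settings, so
    :func:`replay_manifest` can reproduce the result bit-for-bit.  Returns
    the manifest dictionary.
    """
    directory = Path(directory)
    (directory / "traces").mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    for alpha in result.plan.grid:
        lo, hi = result.level_band(alpha)
        fname = f"band_alpha_{alpha:g}.csv"
        _band_frame(result, lo, hi).to_csv(directory / fname, index=False)
        files[f"band_alpha_{alpha:g}"] = fname
    lo, hi = result.overall_band()
    _band_frame(result, lo, hi).to_csv(directory / "band_overall.csv", index=False)
    files["band_overall"] = "band_overall.csv"

    for i, vec in enumerate(result.vectors):
        fname = f"traces/trace_{i:04d}.csv"
        result.trace_at(i).to_csv(directory / fname)
        files[f"trace_{i:04d}"] = fname

    for tau in membership_times:
        for pid in result.places:
            curve = result.membership_at(pid, tau)
            fname = f"membership_{pid}_t{tau:g}.csv"
            curve.to_csv(directory / fname)
            files[f"membership_{pid}_t{tau:g}"] = fname

    manifest = {
        "model": net_to_dict(result.net),
        "plan": {
            "levels": list(result.plan.grid.levels),
            "samples_per_cut": result.plan.samples_per_cut,
            "strategy": result.plan.strategy,
        },
        "settings": {
            "t_end": result.settings.t_end,
            "n_points": result.settings.n_points,
            "rtol": result.settings.rtol,
            "atol": result.settings.atol,
            "stiff": result.settings.stiff,
        },
        "n_fuzzy": len(result.net.fuzzy_parameter_ids),
        "combinations_nominal": result.plan.nominal_combination_count(
            len(result.net.fuzzy_parameter_ids)
        ),
        "combinations_enumerated": len(result.combinations),
        "combinations_unique": len(result.vectors),
        "combinations": [
            {"alpha": c.alpha, "values": c.as_dict()} for c in result.combinations
        ],
        "unique_vectors": [dict(vec) for vec in result.vectors],
        "membership_times": list(membership_times),
        "places": list(result.places),
        "files": files,
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def replay_manifest(path) -> FuzzySimResult:
    """Re-run the fuzzy simulation recorded in an exported manifest."""
    with open(path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    net = net_from_dict(manifest["model"])
    plan = SamplingPlan(
        grid=AlphaLevelGrid(tuple(manifest["plan"]["levels"])),
        samples_per_cut=manifest["plan"]["samples_per_cut"],
        strategy=manifest["plan"]["strategy"],
    )
    settings = SolverSettings(**manifest["settings"])
    return run_fuzzy_simulation(net, plan, settings)
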