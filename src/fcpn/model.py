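"""Fuzzy continuous Petri net (FCPN) data model, JSON I/O, and built-in nets.

An FCPN is the six-tuple ``N = <P, T, F, f, v, M0>``: continuous places P
with a non-negative real initial marking M0, continuous transitions T, a
bipartite set of weighted arcs F with positive weights f, and a rate
assignment v giving each transition a mass-action rate whose kinetic
constant is either a crisp positive real or a triangular fuzzy number with
positive support.  A constant may also be given by an arithmetic expression
over declared parameters (e.g. a temperature-dependent misfolding rate),
which is evaluated after crisp values have been sampled.

Models are exchanged as a small JSON dialect::

    {"name": "...",
     "places":      [{"id": "S1", "initial": 100.0}, ...],
     "parameters":  {"theta1": 0.2, "theta3": [0.45, 0.5, 0.55], ...},
     "transitions": [{"id": "r1", "rate": {"constant": "theta1"}}, ...],
     "arcs":        [{"from": "S1", "to": "r1", "weight": 1}, ...]}

Declaration order of places and transitions is significant: it fixes the
row/column order of the incidence matrix and the column order of exported
trace tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import sympy

from .fuzzy import TriangularFuzzyNumber

__all__ = [
    "ModelError",
    "Place",
    "Arc",
    "RateSpec",
    "Transition",
    "ParameterValue",
    "FuzzyContinuousPetriNet",
    "load_model",
    "load_model_file",
    "save_model",
    "net_to_dict",
    "net_from_dict",
    "decay_dimerization",
    "heat_shock_response",
    "random_mass_action_net",
    "HEAT_SHOCK_FUZZY_K8",
    "HEAT_SHOCK_FUZZY_T",
]


class ModelError(ValueError):
    """A structural or semantic defect in a net or model document."""


#: A kinetic constant: crisp positive real or triangular fuzzy number with
#: support bounded away from zero.
ParameterValue = Union[float, TriangularFuzzyNumber]


@dataclass(frozen=True)
class Place:
    id: str
    initial: float

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("place id must be non-empty")
        if not (self.initial >= 0.0):
            raise ModelError(
                f"place '{self.id}': initial marking must be >= 0, got {self.initial}"
            )


@dataclass(frozen=True)
class Arc:
    source: str
    target: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (self.weight > 0.0):
            raise ModelError(
                f"arc {self.source}->{self.target}: weight must be > 0, "
                f"got {self.weight}"
            )


@dataclass(frozen=True)
class RateSpec:
    """Mass-action rate specification of a transition.

    ``constant`` names the kinetic constant.  Without an ``expression`` it
    must be a declared parameter; with one, ``constant`` is the display
    label of the effective constant and ``expression`` is an arithmetic
    formula (+ - * / power, exp) over declared parameter ids that yields it
    once crisp values have been substituted.
    """

    constant: str
    expression: str | None = None


@dataclass(frozen=True)
class Transition:
    id: str
    rate: RateSpec


@lru_cache(maxsize=None)
def _parse_expression(text: str):
    """Parse a rate expression once; returns (parameter names, evaluator)."""
    try:
        expr = sympy.sympify(text.replace("^", "**"), locals={"exp": sympy.exp})
    except (sympy.SympifyError, SyntaxError, TypeError) as exc:
        raise ModelError(f"cannot parse rate expression '{text}': {exc}") from None
    for f in expr.atoms(sympy.Function):
        if not isinstance(f, sympy.exp):
            raise ModelError(
                f"rate expression '{text}': unsupported function '{f.func}'"
            )
    names = tuple(sorted(s.name for s in expr.free_symbols))
    fn = sympy.lambdify([sympy.Symbol(n) for n in names], expr, "math")
    return names, fn


@dataclass
class FuzzyContinuousPetriNet:
    """The FCPN six-tuple with validation and matrix views."""

    places: list[Place]
    transitions: list[Transition]
    arcs: list[Arc]
    parameters: dict[str, ParameterValue]
    name: str = "net"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        place_ids = [p.id for p in self.places]
        trans_ids = [t.id for t in self.transitions]
        if len(set(place_ids)) != len(place_ids):
            dup = sorted({i for i in place_ids if place_ids.count(i) > 1})
            raise ModelError(f"duplicate place ids: {dup}")
        if len(set(trans_ids)) != len(trans_ids):
            dup = sorted({i for i in trans_ids if trans_ids.count(i) > 1})
            raise ModelError(f"duplicate transition ids: {dup}")
        overlap = set(place_ids) & set(trans_ids)
        if overlap:
            raise ModelError(f"ids used for both a place and a transition: {sorted(overlap)}")
        pset, tset = set(place_ids), set(trans_ids)
        for arc in self.arcs:
            src_p, tgt_p = arc.source in pset, arc.target in pset
            src_t, tgt_t = arc.source in tset, arc.target in tset
            if not ((src_p and tgt_t) or (src_t and tgt_p)):
                raise ModelError(
                    f"arc {arc.source}->{arc.target}: must connect a place and "
                    f"a transition (unknown or same-kind endpoints)"
                )
        for pid, val in self.parameters.items():
            if isinstance(val, TriangularFuzzyNumber):
                if not (val.a > 0.0):
                    raise ModelError(
                        f"parameter '{pid}': fuzzy kinetic constants need a "
                        f"support bounded away from 0, got lower bound {val.a}"
                    )
            else:
                if not (isinstance(val, (int, float)) and val > 0.0):
                    raise ModelError(
                        f"parameter '{pid}': crisp kinetic constant must be a "
                        f"positive real, got {val!r}"
                    )
        declared = set(self.parameters)
        for tr in self.transitions:
            spec = tr.rate
            if spec.expression is None:
                if spec.constant not in declared:
                    raise ModelError(
                        f"transition '{tr.id}': undeclared parameter "
                        f"'{spec.constant}'"
                    )
            else:
                names, _ = _parse_expression(spec.expression)
                missing = sorted(set(names) - declared)
                if missing:
                    raise ModelError(
                        f"transition '{tr.id}': expression references "
                        f"undeclared parameters {missing}"
                    )

    # -- index helpers ---------------------------------------------------

    @property
    def place_ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.places)

    @property
    def transition_ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.transitions)

    @property
    def place_index(self) -> dict[str, int]:
        return {p.id: i for i, p in enumerate(self.places)}

    @property
    def transition_index(self) -> dict[str, int]:
        return {t.id: i for i, t in enumerate(self.transitions)}

    @property
    def fuzzy_parameter_ids(self) -> tuple[str, ...]:
        """Ids of fuzzy parameters, sorted for deterministic enumeration."""
        return tuple(
            sorted(
                pid
                for pid, v in self.parameters.items()
                if isinstance(v, TriangularFuzzyNumber)
            )
        )

    @property
    def initial_marking(self) -> np.ndarray:
        return np.array([p.initial for p in self.places], dtype=float)

    # -- matrix views ----------------------------------------------------

    def pre_matrix(self) -> np.ndarray:
        """|P| x |T| matrix of consumption weights f(p, t)."""
        pidx, tidx = self.place_index, self.transition_index
        w = np.zeros((len(self.places), len(self.transitions)))
        for arc in self.arcs:
            if arc.source in pidx:
                w[pidx[arc.source], tidx[arc.target]] += arc.weight
        return w

    def post_matrix(self) -> np.ndarray:
        """|P| x |T| matrix of production weights f(t, p)."""
        pidx, tidx = self.place_index, self.transition_index
        w = np.zeros((len(self.places), len(self.transitions)))
        for arc in self.arcs:
            if arc.source in tidx:
                w[pidx[arc.target], tidx[arc.source]] += arc.weight
        return w

    def incidence_matrix(self) -> np.ndarray:
        """Net stoichiometric change per firing: production minus consumption."""
        return self.post_matrix() - self.pre_matrix()

    # -- parameter instantiation -----------------------------------------

    def mode_parameters(self) -> dict[str, float]:
        """Crisp sample placing every fuzzy parameter at its mode."""
        return {
            pid: self.parameters[pid].mode for pid in self.fuzzy_parameter_ids
        }

    def effective_constants(
        self, crisp_params: Mapping[str, float] | None = None
    ) -> np.ndarray:
        """Effective kinetic constant per transition, in declaration order.

        ``crisp_params`` supplies crisp samples for fuzzy parameters (and may
        override crisp ones); expressions are evaluated on the resulting
        crisp assignment.  A constant that comes out non-positive or
        non-finite is an error.
        """
        crisp_params = crisp_params or {}
        values: dict[str, float] = {}
        for pid, val in self.parameters.items():
            if pid in crisp_params:
                values[pid] = float(crisp_params[pid])
            elif isinstance(val, TriangularFuzzyNumber):
                if val.is_crisp:
                    values[pid] = val.b
                else:
                    raise ModelError(
                        f"fuzzy parameter '{pid}' needs a crisp sample"
                    )
            else:
                values[pid] = float(val)
        theta = np.empty(len(self.transitions))
        for j, tr in enumerate(self.transitions):
            if tr.rate.expression is None:
                v = values[tr.rate.constant]
            else:
                names, fn = _parse_expression(tr.rate.expression)
                v = float(fn(*(values[n] for n in names)))
            if not (math.isfinite(v) and v > 0.0):
                raise ModelError(
                    f"transition '{tr.id}': rate constant evaluated to {v}"
                )
            theta[j] = v
        return theta

    def with_parameters(self, **overrides: ParameterValue) -> "FuzzyContinuousPetriNet":
        """Copy of the net with some parameter values replaced."""
        unknown = sorted(set(overrides) - set(self.parameters))
        if unknown:
            raise ModelError(f"unknown parameters: {unknown}")
        params = dict(self.parameters)
        params.update(overrides)
        return replace(self, parameters=params)


# -- JSON I/O ------------------------------------------------------------


def net_to_dict(net: FuzzyContinuousPetriNet) -> dict:
    params: dict[str, object] = {}
    for pid, val in net.parameters.items():
        if isinstance(val, TriangularFuzzyNumber):
            params[pid] = [val.a, val.b, val.c]
        else:
            params[pid] = val
    transitions = []
    for tr in net.transitions:
        rate: dict[str, object] = {"constant": tr.rate.constant}
        if tr.rate.expression is not None:
            rate["expression"] = tr.rate.expression
        transitions.append({"id": tr.id, "rate": rate})
    return {
        "name": net.name,
        "places": [{"id": p.id, "initial": p.initial} for p in net.places],
        "parameters": params,
        "transitions": transitions,
        "arcs": [
            {"from": a.source, "to": a.target, "weight": a.weight}
            for a in net.arcs
        ],
    }


def _require(doc: Mapping, key: str, where: str):
    if key not in doc:
        raise ModelError(f"{where}: missing required key '{key}'")
    return doc[key]


def net_from_dict(doc: Mapping) -> FuzzyContinuousPetriNet:
    if not isinstance(doc, Mapping):
        raise ModelError("model document must be a JSON object")
    places = []
    for i, pdoc in enumerate(_require(doc, "places", "model")):
        where = f"places[{i}]"
        places.append(
            Place(str(_require(pdoc, "id", where)), float(_require(pdoc, "initial", where)))
        )
    params: dict[str, ParameterValue] = {}
    for pid, val in _require(doc, "parameters", "model").items():
        if isinstance(val, (list, tuple)):
            if len(val) != 3:
                raise ModelError(
                    f"parameter '{pid}': a fuzzy value must be a triple [a, b, c]"
                )
            try:
                params[pid] = TriangularFuzzyNumber(*(float(v) for v in val))
            except ValueError as exc:
                raise ModelError(f"parameter '{pid}': {exc}") from None
        elif isinstance(val, (int, float)):
            params[pid] = float(val)
        else:
            raise ModelError(
                f"parameter '{pid}': expected a number or [a, b, c], got {val!r}"
            )
    transitions = []
    for i, tdoc in enumerate(_require(doc, "transitions", "model")):
        where = f"transitions[{i}]"
        rdoc = _require(tdoc, "rate", where)
        transitions.append(
            Transition(
                str(_require(tdoc, "id", where)),
                RateSpec(
                    str(_require(rdoc, "constant", f"{where}.rate")),
                    rdoc.get("expression"),
                ),
            )
        )
    arcs = []
    for i, adoc in enumerate(_require(doc, "arcs", "model")):
        where = f"arcs[{i}]"
        arcs.append(
            Arc(
                str(_require(adoc, "from", where)),
                str(_require(adoc, "to", where)),
                float(adoc.get("weight", 1.0)),
            )
        )
    return FuzzyContinuousPetriNet(
        places=places,
        transitions=transitions,
        arcs=arcs,
        parameters=params,
        name=str(doc.get("name", "net")),
    )


def load_model(document: str) -> FuzzyContinuousPetriNet:
    """Parse and validate a model JSON document (text)."""
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ModelError(f"invalid JSON: {exc}") from None
    return net_from_dict(doc)


def load_model_file(path) -> FuzzyContinuousPetriNet:
    with open(path, "r", encoding="utf-8") as fh:
        return load_model(fh.read())


def save_model(net: FuzzyContinuousPetriNet, indent: int = 2) -> str:
    """Serialize a net to its JSON document; round-trips structurally."""
    return json.dumps(net_to_dict(net), indent=indent)


# -- reaction-list construction helper ------------------------------------


def _net_from_reactions(
    name: str,
    species: Sequence[tuple[str, float]],
    reactions: Sequence[tuple[str, RateSpec, Mapping[str, float], Mapping[str, float]]],
    parameters: Mapping[str, ParameterValue],
) -> FuzzyContinuousPetriNet:
    """Build a net from (id, rate, reactants, products) reaction tuples."""
    places = [Place(sid, init) for sid, init in species]
    transitions = []
    arcs = []
    for tid, rate, pre, post in reactions:
        transitions.append(Transition(tid, rate))
        for sid, w in pre.items():
            arcs.append(Arc(sid, tid, float(w)))
        for sid, w in post.items():
            arcs.append(Arc(tid, sid, float(w)))
    return FuzzyContinuousPetriNet(
        places=places,
        transitions=transitions,
        arcs=arcs,
        parameters=dict(parameters),
        name=name,
    )


# -- built-in models ------------------------------------------------------


def decay_dimerization(
    initial_marking: Mapping[str, float] | None = None,
    fuzzy: bool = True,
) -> FuzzyContinuousPetriNet:
    """Decay-dimerization network: S1 decay, reversible dimerization, conversion.

    Reactions (mass action)::

        r1: S1        -> 0          theta1 = 0.2
        r2: S1 + S1   -> S2         theta2 = 0.04
        r3: S2        -> S1 + S1    theta3 = (0.45, 0.5, 0.55)
        r4: S2        -> S3         theta4 = (4.9, 5.0, 5.4)

    With ``fuzzy=False`` the two fuzzy constants are replaced by their modes
    (0.5 and 5.0).  The default initial marking (S1=100, S2=0, S3=0) is a
    package convention: the system is usually studied from a pure monomer
    pool, and any marking can be supplied explicitly.
    """
    marking = {"S1": 100.0, "S2": 0.0, "S3": 0.0}
    if initial_marking:
        marking.update(initial_marking)
    theta3: ParameterValue = TriangularFuzzyNumber(0.45, 0.5, 0.55)
    theta4: ParameterValue = TriangularFuzzyNumber(4.9, 5.0, 5.4)
    if not fuzzy:
        theta3, theta4 = 0.5, 5.0
    return _net_from_reactions(
        "decay_dimerization",
        [("S1", marking["S1"]), ("S2", marking["S2"]), ("S3", marking["S3"])],
        [
            ("r1", RateSpec("theta1"), {"S1": 1}, {}),
            ("r2", RateSpec("theta2"), {"S1": 2}, {"S2": 1}),
            ("r3", RateSpec("theta3"), {"S2": 1}, {"S1": 2}),
            ("r4", RateSpec("theta4"), {"S2": 1}, {"S3": 1}),
        ],
        {"theta1": 0.2, "theta2": 0.04, "theta3": theta3, "theta4": theta4},
    )


#: Fuzzy values used for the uncertain heat shock scenario.
HEAT_SHOCK_FUZZY_K8 = TriangularFuzzyNumber(2.457e-7, 2.73e-7, 3.003e-7)
HEAT_SHOCK_FUZZY_T = TriangularFuzzyNumber(41.8, 42.0, 42.2)

#: Temperature-dependent misfolding rate constant (per second).
_K10_EXPRESSION = "(1 - 0.4/exp(T - 37)) * 1.4**(T - 37) * 1.45e-5"


def heat_shock_response(
    temperature: ParameterValue = 42.0,
    k8: ParameterValue = 2.73e-7,
    fuzzy: bool = False,
) -> FuzzyContinuousPetriNet:
    """Eukaryotic heat shock response network (10 species, 17 reactions).

    The heat shock factor hsf trimerizes via hsf2/hsf3, the trimer binds the
    heat shock element (hse) to transactivate production of the chaperone
    hsp, hsp sequesters hsf and repairs heat-misfolded proteins (mfp)
    arising from the native pool (prot).  The misfolding rate constant k10
    depends on the temperature T through
    ``(1 - 0.4/exp(T-37)) * 1.4**(T-37) * 1.45e-5``.

    ``fuzzy=True`` switches k8 (hsp-mediated dissociation of the
    trimer-hse complex) and the temperature to their triangular fuzzy
    values ``(2.457e-7, 2.73e-7, 3.003e-7)`` and ``(41.8, 42.0, 42.2)``;
    alternatively pass any crisp or fuzzy ``temperature``/``k8`` directly.
    """
    if fuzzy:
        temperature = HEAT_SHOCK_FUZZY_T
        k8 = HEAT_SHOCK_FUZZY_K8
    species = [
        ("hsf", 0.67),
        ("hsf2", 8.7e-4),
        ("hsf3", 1.2e-4),
        ("hse", 29.73),
        ("hsf3_hse", 2.96),
        ("hsp", 766.88),
        ("hsp_hsf", 1403.13),
        ("mfp", 517.352),
        ("hsp_mfp", 71.65),
        ("prot", 1.15e8),
    ]
    reactions = [
        ("r1", RateSpec("k1p"), {"hsf": 2}, {"hsf2": 1}),
        ("r2", RateSpec("k1m"), {"hsf2": 1}, {"hsf": 2}),
        ("r3", RateSpec("k2p"), {"hsf": 1, "hsf2": 1}, {"hsf3": 1}),
        ("r4", RateSpec("k2m"), {"hsf3": 1}, {"hsf": 1, "hsf2": 1}),
        ("r5", RateSpec("k3p"), {"hsf3": 1, "hse": 1}, {"hsf3_hse": 1}),
        ("r6", RateSpec("k3m"), {"hsf3_hse": 1}, {"hsf3": 1, "hse": 1}),
        ("r7", RateSpec("k4"), {"hsf3_hse": 1}, {"hsf3_hse": 1, "hsp": 1}),
        ("r8", RateSpec("k5p"), {"hsp": 1, "hsf": 1}, {"hsp_hsf": 1}),
        ("r9", RateSpec("k5m"), {"hsp_hsf": 1}, {"hsp": 1, "hsf": 1}),
        ("r10", RateSpec("k6"), {"hsp": 1, "hsf2": 1}, {"hsp_hsf": 1, "hsf": 1}),
        ("r11", RateSpec("k7"), {"hsp": 1, "hsf3": 1}, {"hsp_hsf": 1, "hsf": 2}),
        (
            "r12",
            RateSpec("k8"),
            {"hsp": 1, "hsf3_hse": 1},
            {"hsp_hsf": 1, "hse": 1, "hsf": 2},
        ),
        ("r13", RateSpec("k9"), {"hsp": 1}, {}),
        ("r14", RateSpec("k10", _K10_EXPRESSION), {"prot": 1}, {"mfp": 1}),
        ("r15", RateSpec("k11p"), {"hsp": 1, "mfp": 1}, {"hsp_mfp": 1}),
        ("r16", RateSpec("k11m"), {"hsp_mfp": 1}, {"hsp": 1, "mfp": 1}),
        ("r17", RateSpec("k12"), {"hsp_mfp": 1}, {"hsp": 1, "prot": 1}),
    ]
    parameters: dict[str, ParameterValue] = {
        "k1p": 3.49,
        "k1m": 0.19,
        "k2p": 1.07,
        "k2m": 1e-9,
        "k3p": 0.17,
        "k3m": 1.21e-6,
        "k4": 8.3e-3,
        "k5p": 9.74,
        "k5m": 3.56,
        "k6": 2.33,
        "k7": 4.31e-5,
        "k8": k8,
        "k9": 3.2e-5,
        "k11p": 3.32e-3,
        "k11m": 4.44,
        "k12": 13.94,
        "T": temperature,
    }
    return _net_from_reactions("heat_shock_response", species, reactions, parameters)


# -- random fixture generator ---------------------------------------------


def random_mass_action_net(
    n_places: int,
    n_transitions: int,
    seed: int,
    fuzzy_fraction: float = 0.25,
    max_weight: int = 2,
) -> FuzzyContinuousPetriNet:
    """Seeded random valid mass-action net for property tests.

    Every transition has 1-2 preplaces and 0-2 postplaces with small integer
    arc weights; constants are positive, and each is fuzzy (a symmetric-ish
    triangle around its base value) with probability ``fuzzy_fraction``.
    The same seed always yields the same net.
    """
    if n_places < 1 or n_transitions < 1:
        raise ValueError("need at least one place and one transition")
    rng = np.random.default_rng(seed)
    species = [
        (f"P{i + 1}", round(float(rng.uniform(0.1, 2.0)), 4))
        for i in range(n_places)
    ]
    parameters: dict[str, ParameterValue] = {}
    reactions = []
    for j in range(n_transitions):
        tid = f"t{j + 1}"
        kid = f"k{j + 1}"
        base = round(float(rng.uniform(0.05, 1.5)), 4)
        if rng.random() < fuzzy_fraction:
            lo = round(base * float(rng.uniform(0.5, 0.9)), 6)
            hi = round(base * float(rng.uniform(1.1, 1.5)), 6)
            parameters[kid] = TriangularFuzzyNumber(lo, base, hi)
        else:
            parameters[kid] = base
        n_pre = 1 + int(rng.random() < 0.4)
        n_pre = min(n_pre, n_places)
        pre_places = rng.choice(n_places, size=n_pre, replace=False)
        pre = {
            f"P{p + 1}": int(rng.integers(1, max_weight + 1)) for p in pre_places
        }
        n_post = int(rng.integers(0, 3))
        n_post = min(n_post, n_places)
        post = {}
        if n_post:
            post_places = rng.choice(n_places, size=n_post, replace=False)
            post = {
                f"P{p + 1}": int(rng.integers(1, max_weight + 1))
                for p in post_places
            }
        reactions.append((tid, RateSpec(kid), pre, post))
    return _net_from_reactions(
        f"random_net_seed{seed}", species, reactions, parameters
    )
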