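# Methods

## Model class

A fuzzy continuous Petri net (FCPN) is the six-tuple N = ⟨P, T, F, f, v, M0⟩
of a continuous Petri net in which the kinetic constant of a transition may
be a triangular fuzzy number (a, b, c), a ≤ b ≤ c, a > 0. The underlying
crisp semantics is the mass-action ODE system

    d(p)/dt = Σ_{t∈•p} f(t,p)·v(t) − Σ_{t∈p•} f(p,t)·v(t),
    v(t)    = θ_t · Π_{p∈•t} m(p)^{f(p,t)}.

The arc weight is used both as the kinetic exponent and as the
stoichiometric coefficient (continuous semantics: a dimerization 2X → Y
contributes −2·θX² to dX/dt and +θX² to dY/dt). There is no discrete
combinatorial correction (no n(n−1)/2). A kinetic constant may also be an
arithmetic expression over declared parameters (+ − * / power, exp); it is
evaluated after crisp values have been sampled, never by interval
arithmetic, so fuzziness in an expression's inputs (e.g. a fuzzy
temperature) propagates through sampling exactly like a directly fuzzy
constant.

Assumptions: mass action for every reaction; reversible reactions split
into two irreversible transitions; catalysts written as explicit
consume+produce arc pairs; non-negative real markings; no events, delays,
or fuzzy initial markings (only kinetic constants are fuzzy).

## Fuzzy propagation

Propagation follows the extension principle via α-cut decomposition:

1. choose an α-level grid (J levels, always containing 0 and 1; uniform by
   default, any explicit list accepted);
2. per fuzzy parameter and level, compute the cut
   ξ̃_α = [a + α(b−a), c − α(c−b)] (α = 0 and α = 1 are special-cased to
   the exact support and the exact mode point, so no floating-point
   round-off leaks into the extreme cuts);
3. discretize each cut into K uniformly spaced samples **including both
   endpoints** (`full` strategy: every cut; `efficient` strategy: K samples
   only at α = 0, the two endpoints elsewhere), and form the cross-product
   over the I fuzzy parameters;
4. integrate the crisply instantiated system once per *unique* parameter
   vector (the mode, for instance, appears at every level but is simulated
   once); all member runs share one solver configuration and output grid;
5. for each level m, pool every computed trace whose parameter vector lies
   inside *all* level-m cuts, and take pointwise min/max: this is the
   level-m uncertain band. The overall band is the envelope over all
   traces and coincides with the α = 0 band. Stacking the per-level
   extremes at a fixed time point and enforcing nesting (each cut widened
   to contain the cuts above it) yields the output membership curve.

Design choices made where the procedure was genuinely open:

* **Trace pooling at every level, under both strategies.** The efficient
  strategy's filtering rule (reuse a support-level trace at level m when
  its parameter values lie in every level-m cut) is applied uniformly. It
  guarantees band nesting by construction — pools shrink as α grows — and
  reuses all computed work. Nesting is still asserted by the test suite
  rather than assumed.
* **Interior samples are kept at the support level (K ≥ 2).** Output
  extremes are *not* assumed to sit at cut corners, because outputs need
  not be monotone in the parameters; K controls how finely possible
  interior extrema are probed.
* **No randomness anywhere in the fuzzy machinery.** Sampling, ordering,
  deduplication, and reduction order are deterministic, so repeated runs
  are bit-identical; the only seeded component in the package is the
  random-net fixture generator.
* **Nominal vs enumerated counts.** The planning formulas K^I·J and
  K^I + 2^I·(J−1) count combinations before the degenerate α = 1 cut
  collapses to the single mode value; manifests record both the nominal
  and the enumerated/unique counts.

## Numerical integration

`scipy.integrate.solve_ivp` with LSODA and an analytic Jacobian assembled
from the same stoichiometric matrices as the right-hand side (default),
or RK45 for non-stiff use. Defaults: rtol 1e-8, atol 1e-10, uniform
output grid including t = 0 and t_end. The heat shock system spans rate
constants from 1e-9 to 13.94 s⁻¹ against a protein pool of ~1.15e8, and is
the reason stiff-capable integration is the default. Undershoot below
zero within 10× atol is clipped to 0; anything worse raises. A
stationarity helper doubles the horizon until every species' change over a
trailing 100 s window is below 1e-6 relative to its end value (species with
negligible trajectories are compared against a small floor instead).

## Built-in study models

**Decay-dimerization** (3 places, 4 transitions): θ1 = 0.2, θ2 = 0.04,
θ3 = (0.45, 0.5, 0.55), θ4 = (4.9, 5.0, 5.4). The initial marking is not
part of the published parameterization; the package default (S1 = 100,
S2 = S3 = 0, a pure monomer pool) is its own convention and any marking
can be passed in.

**Heat shock response** (10 places, 17 transitions): the conserved
eukaryotic defense against protein misfolding. hsf trimerizes via
hsf2/hsf3; the trimer binds the heat shock element (hse) and the complex
hsf3_hse transactivates production of the chaperone hsp; hsp sequesters
hsf and repairs misfolded proteins (mfp) produced from the native pool
(prot) at the temperature-dependent rate
k10 = (1 − 0.4/e^{T−37}) · 1.4^{T−37} · 1.45e-5 s⁻¹. Initial values are
the 37 °C steady state of the source kinetic model. The fuzzy study
scenario sets k8 = (2.457e-7, 2.73e-7, 3.003e-7) ml/(#·s) and
T = (41.8, 42, 42.2) °C.

**Study horizon.** The heat shock fuzzy study uses t_end = 14400 s (4 h),
the simulation span over which the source kinetic model's response was
published. This is a deliberate choice over running to stationarity: the
42 °C response consists of a fast rise of hsf3_hse (peak near t ≈ 1e3 s), a
long decline, a shallow undershoot near t ≈ 2e4 s, and a slow recovery to
a steady state (~2.9–3.0) reached only near t ≈ 1.3e5 s. The 4-hour window
covers the biologically reported response — single rise and fall of DNA
binding — whereas a stationarity horizon additionally includes the
recovery flank, where every trace acquires a second derivative sign change
and end-time uncertainty bands collapse toward the (nearly
temperature-independent) steady state. At the 4-hour end point the fuzzy
run's α = 0 range for the dimer hsf2 is ≈ [2.6e-4, 4.7e-4]; hsf3_hse
itself remains O(1) at all times for every parameter vector in the fuzzy
supports. The stationarity helper remains available
(`simulate_to_stationarity`, `--until-stationary`).

## Structural analysis

Minimal T-invariants are the support-minimal semi-positive integer vectors
x with C·x = 0 (C the |P|×|T| incidence matrix). Enumeration is the
classical Farkas-style non-negative elimination on [Cᵀ | I] in exact
Python integer arithmetic — floating-point kernels are useless for
support-minimal enumeration — with gcd reduction and strict-superset
support pruning after each elimination step. Every candidate is
re-verified against C·x = 0 by multiplication before being returned, and
output order (support size, then lexicographic by transition position) is
deterministic. Real-weighted nets are rejected for this analysis.
P-invariants are not computed.

## Trace queries

The derivative of a species along a trace is evaluated through the ODE
right-hand side at each grid state (exact with respect to the model), with
a finite-difference fallback for imported traces. Signs are taken with a
deadband ε (default 1e-6 × max |d| of the series) so jitter around
equilibria cannot fabricate peaks. "Eventually" is evaluated over the
discrete grid in strict index order: rise-then-fall requires a +1 strictly
before a −1; second-rise requires +1, −1, +1 at increasing indices; a
single peak is the first without the second. The probability operator
over a trace set is reported as the satisfying fraction.

## Synthetic fixture generator

`random_mass_action_net` emulates small mass-action networks: 1–2
reactants and 0–2 products per reaction, integer arc weights ≤ 2, positive
constants in [0.05, 1.5], a configurable fraction of fuzzy constants with
supports roughly −30 %/+30 % around the mode. It reproduces the
structural shape of biochemical networks (bipartiteness, small
stoichiometries, sink reactions) but none of the biology: no conservation
design, no stiffness spread, no parameter correlations. Property tests on
these nets therefore exercise the machinery (band nesting, kernel
exactness, oracle equivalence), not biological realism; the built-in
curated models carry that weight.

## Known limitations

* Only triangular fuzzy numbers; no trapezoidal/bell shapes and no direct
  fuzzy arithmetic — propagation is always via sampled crisp values.
* Cut extremes are sampled, not optimized: a sharp interior response in a
  parameter could be missed for small K.
* The two sampling strategies are the only ones provided; the sampler is
  an extension point.
* No SBML import/export; the JSON dialect is the only exchange format.
* Trace queries cover exactly the derivative/eventually fragment above —
  no general temporal-logic syntax, no until/next.
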