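# fcpn — fuzzy continuous Petri nets

`fcpn` models biochemical reaction networks whose kinetic constants are
**uncertain**: a constant may be a crisp positive real or a triangular
fuzzy number ξ̃ = (a, b, c) with membership rising linearly from 0 at a to
1 at the mode b and back to 0 at c (with a > 0 for kinetic use). The
package is aimed at systems biologists who have an ODE / continuous Petri
net model but lack precise values for some rate constants — because data
are insufficient, or because a parameter genuinely varies with conditions
such as temperature.

A continuous Petri net N = ⟨P, T, F, f, v, M0⟩ is a graphical notation for
the mass-action ODE system

    d(p)/dt = Σ_{t∈•p} f(t,p)·v(t) − Σ_{t∈p•} f(p,t)·v(t),
    v(t)    = θ_t · Π_{p∈•t} m(p)^{f(p,t)},

and a *fuzzy* continuous Petri net lets any θ_t be a fuzzy number.
Uncertainty is propagated by **α-cut decomposition** (Zadeh's extension
principle): each fuzzy constant is sliced into α-cuts
ξ̃_α = [a + α(b−a), c − α(c−b)], crisp samples from the cuts are pushed
through the ODE system one combination at a time, and the per-level output
extremes are stacked back into nested *uncertain bands* and, at any time
point, an output membership function. Two sampling strategies are
provided: `full` (K samples per cut, K^I·J combinations for I fuzzy
parameters and J levels) and `efficient` (full sampling only on the
support, endpoints elsewhere, K^I + 2^I·(J−1) combinations, with trace
pooling refilling the interior levels).

The package also computes minimal **T-invariants** (semi-positive integer
kernel vectors of the incidence matrix, enumerated in exact integer
arithmetic — each is an elementary behavioural mode of the network) and
evaluates **derivative-shape trace queries** (eventually-rise-then-fall,
eventually-second-rise) used to check, e.g., that every simulated trace of
a species has exactly one peak.

Two case-study models are built in:

* `decay_dimerization()` — S1 decay, reversible dimerization to S2,
  conversion to S3; θ3 = (0.45, 0.5, 0.55) and θ4 = (4.9, 5.0, 5.4) fuzzy.
* `heat_shock_response()` — the 10-species, 17-reaction eukaryotic heat
  shock response with a temperature-dependent misfolding rate; the fuzzy
  variant sets k8 = (2.457e-7, 2.73e-7, 3.003e-7) and T = (41.8, 42, 42.2).

## Worked example

```python
from fcpn import (AlphaLevelGrid, SamplingPlan, SolverSettings,
                  decay_dimerization, ode_text, run_fuzzy_simulation)

net = decay_dimerization()          # theta3, theta4 are fuzzy triples
print(ode_text(net))

plan = SamplingPlan(AlphaLevelGrid.from_levels([0, 0.5, 1]),
                    samples_per_cut=3, strategy="efficient")
res = run_fuzzy_simulation(net, plan, SolverSettings(t_end=2.0, n_points=201))

t, lo, hi = res.band("S2", alpha=0.0)
print(f"S2 support band at t=2: [{lo[-1]:.4f}, {hi[-1]:.4f}]")
print(res.membership_at("S2", 2.0).to_frame().to_string(index=False))
```

prints

```
dS1/dt = 2*(theta3*S2) - (theta1*S1) - 2*(theta2*S1^2)
dS2/dt = (theta2*S1^2) - (theta3*S2) - (theta4*S2)
dS3/dt = (theta4*S2)
S2 support band at t=2: [0.2505, 0.3015]
 alpha       lo       hi
   0.0 0.250544 0.301535
   0.5 0.267878 0.294460
   1.0 0.287631 0.287631
```

The three equations are the mass-action balance laws of the network. The
band `[0.2505, 0.3015]` is the full-support (α = 0) envelope of the dimer
concentration at t = 2 over all sampled values of the two fuzzy constants;
the table is the composed output membership function at that time point —
the α = 1 row is the crisp all-modes simulation, and lower α rows widen as
more parameter uncertainty is admitted.

The same machinery drives the command line:

```sh
fcpn fixtures --out fixtures            # write the built-in model JSONs
fcpn odes --model fixtures/decay_dimerization.json
fcpn invariants --model fixtures/heat_shock_response.json
fcpn fsim --model fixtures/heat_shock_response_fuzzy.json \
     --levels 0,0.4,0.7,1 --samples-per-cut 3 --strategy efficient \
     --t-end 14400 --points 721 --membership-at 14400 --out scratch/hsr
fcpn query --traces scratch/hsr --species hsf3_hse --check single-peak
```

`invariants` reports that the heat shock net is covered by 10 minimal
T-invariants; `query` reports that every trace of the fuzzy run has a
single peak in the DNA-binding complex.

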