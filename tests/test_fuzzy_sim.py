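"""Fuzzy simulation: sample enumeration, bands, membership, export."""

import json
import math

import numpy as np
import pytest

from fcpn.fuzzy import AlphaLevelGrid, TriangularFuzzyNumber
from fcpn.fuzzysim import (
    DegeneratePlanError,
    SamplingPlan,
    enumerate_samples,
    export_result,
    replay_manifest,
    run_fuzzy_simulation,
)
from fcpn.model import (
    Arc,
    FuzzyContinuousPetriNet,
    Place,
    RateSpec,
    Transition,
    decay_dimerization,
    random_mass_action_net,
)
from fcpn.odes import SolverSettings, simulate_crisp

from conftest import make_one_species_decay

TFN = TriangularFuzzyNumber


def chain_net(fuzzy_values):
    """Linear chain with one fuzzy degradation per parameter (I = len)."""
    places = [Place(f"X{i}", 1.0) for i in range(len(fuzzy_values))]
    transitions, arcs, params = [], [], {}
    for i, tfn in enumerate(fuzzy_values):
        tid, kid = f"t{i}", f"k{i}"
        transitions.append(Transition(tid, RateSpec(kid)))
        arcs.append(Arc(f"X{i}", tid))
        params[kid] = tfn
    return FuzzyContinuousPetriNet(
        places=places, transitions=transitions, arcs=arcs, parameters=params
    )


class TestEnumerateSamples:
    @pytest.mark.parametrize(
        "strategy, k, i, j, nominal",
        [
            ("full", 3, 2, 4, 36),       # K^I x J
            ("efficient", 3, 2, 4, 21),  # K^I + 2^I x (J-1)
            ("full", 2, 1, 2, 4),
            ("efficient", 4, 3, 5, 96),
        ],
    )
    def test_nominal_count_formulas(self, strategy, k, i, j, nominal):
        plan = SamplingPlan(AlphaLevelGrid.uniform(j), k, strategy)
        assert plan.nominal_combination_count(i) == nominal

    @pytest.mark.parametrize("strategy", ["full", "efficient"])
    @pytest.mark.parametrize("k, i, j", [(3, 2, 4), (2, 1, 2), (2, 3, 3), (4, 2, 5)])
    def test_enumerated_length_after_mode_collapse(self, strategy, k, i, j):
        """Recount independently: K^I per non-top level (full) or per the
        support level with 2^I at intermediate levels (efficient), and one
        single combination at the degenerate alpha=1 cut."""
        fuzzies = [TFN(0.1 * (n + 1), 0.2 * (n + 1), 0.3 * (n + 1)) for n in range(i)]
        net = chain_net(fuzzies)
        plan = SamplingPlan(AlphaLevelGrid.uniform(j), k, strategy)
        combos = enumerate_samples(net, plan)
        if strategy == "full":
            expected = k**i * (j - 1) + 1
        else:
            expected = k**i + 2**i * (j - 2) + 1
        assert len(combos) == expected

    def test_degenerate_top_cut_single_value(self):
        """I=1, J=2, K=2: support gives {a, c}, the top level gives {b}."""
        net = chain_net([TFN(0.1, 0.2, 0.3)])
        plan = SamplingPlan(AlphaLevelGrid.uniform(2), 2, "full")
        combos = enumerate_samples(net, plan)
        assert [(c.alpha, c.values[0][1]) for c in combos] == [
            (0.0, 0.1),
            (0.0, 0.3),
            (1.0, 0.2),
        ]

    def test_deterministic_ordering(self):
        net = chain_net([TFN(0.1, 0.2, 0.3), TFN(1.0, 2.0, 3.0)])
        plan = SamplingPlan(AlphaLevelGrid.uniform(3), 2, "full")
        a = enumerate_samples(net, plan)
        b = enumerate_samples(net, plan)
        assert a == b
        alphas = [c.alpha for c in a]
        assert alphas == sorted(alphas)

    def test_values_lie_inside_their_cut(self):
        net = chain_net([TFN(0.1, 0.2, 0.3), TFN(1.0, 2.0, 3.0)])
        plan = SamplingPlan(AlphaLevelGrid.uniform(4), 3, "efficient")
        for combo in enumerate_samples(net, plan):
            for pid, val in combo.values:
                cut = net.parameters[pid].alpha_cut(combo.alpha)
                assert cut.contains(val, tol=1e-12)

    def test_crisp_net_rejected(self):
        net = random_mass_action_net(2, 2, seed=1, fuzzy_fraction=0.0)
        with pytest.raises(DegeneratePlanError):
            enumerate_samples(net, SamplingPlan(AlphaLevelGrid.uniform(2)))


class TestRunFuzzySimulation:
    def settings(self, t_end=5.0):
        return SolverSettings(t_end=t_end, n_points=51, stiff=False)

    def test_degenerate_fuzzy_band_is_crisp_trace(self):
        """All-crisp triples: zero-width band equal to the crisp run."""
        net = make_one_species_decay(TFN.crisp(0.2))
        plan = SamplingPlan(AlphaLevelGrid.uniform(3))
        res = run_fuzzy_simulation(net, plan, self.settings())
        lo, hi = res.overall_band()
        crisp = simulate_crisp(net, {"theta": 0.2}, self.settings())
        assert np.array_equal(lo, hi)
        assert np.array_equal(lo, crisp.values)

    def test_closed_form_support_band(self):
        """theta=(0.1,0.2,0.3), x0=1: the support band is [e^-0.3t, e^-0.1t]."""
        net = make_one_species_decay(TFN(0.1, 0.2, 0.3))
        plan = SamplingPlan(AlphaLevelGrid.uniform(3))
        res = run_fuzzy_simulation(net, plan, self.settings())
        t, lo, hi = res.band("X", 0.0)
        assert lo == pytest.approx(np.exp(-0.3 * t), abs=1e-7)
        assert hi == pytest.approx(np.exp(-0.1 * t), abs=1e-7)
        assert lo[-1] == pytest.approx(math.exp(-1.5), abs=1e-7)
        assert hi[-1] == pytest.approx(math.exp(-0.5), abs=1e-7)

    def test_membership_cuts_match_closed_form_per_level(self):
        net = make_one_species_decay(TFN(0.1, 0.2, 0.3))
        plan = SamplingPlan(AlphaLevelGrid.uniform(3))
        res = run_fuzzy_simulation(net, plan, self.settings())
        curve = res.membership_at("X", 5.0)
        assert curve.cut_at(0.0).lo == pytest.approx(math.exp(-1.5), abs=1e-7)
        assert curve.cut_at(0.0).hi == pytest.approx(math.exp(-0.5), abs=1e-7)
        # alpha=0.5 cut of theta is [0.15, 0.25]
        assert curve.cut_at(0.5).lo == pytest.approx(math.exp(-1.25), abs=1e-7)
        assert curve.cut_at(0.5).hi == pytest.approx(math.exp(-0.75), abs=1e-7)
        assert curve.cut_at(1.0).lo == pytest.approx(math.exp(-1.0), abs=1e-7)
        assert curve.cut_at(1.0).is_degenerate

    @pytest.mark.parametrize("seed", [6, 12, 31])
    @pytest.mark.parametrize("strategy", ["full", "efficient"])
    def test_band_nesting_on_random_nets(self, seed, strategy):
        net = random_mass_action_net(3, 4, seed=seed, fuzzy_fraction=0.8)
        if not net.fuzzy_parameter_ids:
            pytest.skip("seed produced no fuzzy parameters")
        plan = SamplingPlan(AlphaLevelGrid.uniform(3), 3, strategy)
        res = run_fuzzy_simulation(net, plan, SolverSettings(t_end=3.0, n_points=31))
        levels = res.plan.grid.levels
        for a_low, a_high in zip(levels, levels[1:]):
            lo_l, hi_l = res.level_band(a_low)
            lo_h, hi_h = res.level_band(a_high)
            assert np.all(lo_l <= lo_h)
            assert np.all(hi_h <= hi_l)

    def test_alpha_one_band_is_mode_simulation_exactly(self):
        net = make_one_species_decay(TFN(0.1, 0.2, 0.3))
        plan = SamplingPlan(AlphaLevelGrid.uniform(4))
        s = self.settings()
        res = run_fuzzy_simulation(net, plan, s)
        crisp = simulate_crisp(net, {"theta": 0.2}, s)
        lo, hi = res.level_band(1.0)
        assert np.array_equal(lo, crisp.values)
        assert np.array_equal(hi, crisp.values)

    def test_overall_band_equals_support_band(self):
        net = make_one_species_decay(TFN(0.1, 0.2, 0.3))
        res = run_fuzzy_simulation(
            net, SamplingPlan(AlphaLevelGrid.uniform(3)), self.settings()
        )
        lo0, hi0 = res.level_band(0.0)
        lo, hi = res.overall_band()
        assert np.array_equal(lo, lo0) and np.array_equal(hi, hi0)

    def test_strategies_agree_on_monotone_one_parameter_net(self):
        """Extremes sit at cut endpoints, which both strategies sample."""
        net = make_one_species_decay(TFN(0.1, 0.2, 0.3))
        grid = AlphaLevelGrid.uniform(4)
        s = self.settings()
        full = run_fuzzy_simulation(net, SamplingPlan(grid, 3, "full"), s)
        eff = run_fuzzy_simulation(net, SamplingPlan(grid, 3, "efficient"), s)
        for alpha in grid:
            flo, fhi = full.level_band(alpha)
            elo, ehi = eff.level_band(alpha)
            assert flo == pytest.approx(elo, abs=1e-12)
            assert fhi == pytest.approx(ehi, abs=1e-12)

    def test_dense_sweep_oracle_per_level(self):
        """Level cuts agree with a 1000-point sweep of the parameter cut
        pushed through the closed-form solution."""
        tfn = TFN(0.1, 0.2, 0.3)
        net = make_one_species_decay(tfn)
        res = run_fuzzy_simulation(
            net, SamplingPlan(AlphaLevelGrid.uniform(5)), self.settings()
        )
        t_end = 5.0
        for alpha in (0.0, 0.25, 0.5, 0.75):
            cut = tfn.alpha_cut(alpha)
            sweep = np.exp(-np.linspace(cut.lo, cut.hi, 1000) * t_end)
            got = res.membership_at("X", t_end).cut_at(alpha)
            assert got.lo == pytest.approx(sweep.min(), rel=1e-5)
            assert got.hi == pytest.approx(sweep.max(), rel=1e-5)

    def test_decay_dimerization_nonzero_band_nested(self):
        """Fuzzy theta3/theta4 widen S2 into a genuine uncertain band."""
        net = decay_dimerization(initial_marking={"S1": 10.0})
        plan = SamplingPlan(AlphaLevelGrid.uniform(3), 2, "efficient")
        res = run_fuzzy_simulation(net, plan, SolverSettings(t_end=2.0, n_points=41))
        t, lo, hi = res.band("S2", 0.0)
        assert np.max(hi - lo) > 0.0
        t, lo1, hi1 = res.band("S2", 1.0)
        assert np.all(lo <= lo1) and np.all(hi1 <= hi)


class TestExport:
    def make_result(self):
        net = decay_dimerization(initial_marking={"S1": 10.0})
        plan = SamplingPlan(AlphaLevelGrid.uniform(4), 3, "efficient")
        return run_fuzzy_simulation(
            net, plan, SolverSettings(t_end=2.0, n_points=21)
        )

    def test_manifest_records_formula_counts(self, tmp_path):
        res = self.make_result()
        manifest = export_result(res, tmp_path, membership_times=[2.0])
        assert manifest["combinations_nominal"] == 3**2 + 2**2 * 3  # 21
        assert manifest["combinations_unique"] == len(res.vectors)
        assert (tmp_path / "manifest.json").exists()

    def test_band_csv_row_counts(self, tmp_path):
        res = self.make_result()
        export_result(res, tmp_path)
        import pandas as pd

        for alpha in res.plan.grid:
            df = pd.read_csv(tmp_path / f"band_alpha_{alpha:g}.csv")
            assert len(df) == res.settings.n_points
        df = pd.read_csv(tmp_path / "band_overall.csv")
        assert len(df) == res.settings.n_points

    def test_replay_reproduces_result_exactly(self, tmp_path):
        res = self.make_result()
        export_result(res, tmp_path)
        again = replay_manifest(tmp_path / "manifest.json")
        assert np.array_equal(res.traces, again.traces)
        assert res.vectors == again.vectors
        assert res.level_pools == again.level_pools

    def test_membership_csv_written_per_place(self, tmp_path):
        res = self.make_result()
        export_result(res, tmp_path, membership_times=[1.0])
        for pid in res.places:
            assert (tmp_path / f"membership_{pid}_t1.csv").exists()
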