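import numpy as np
import pytest

from oracles import enumerate_lp_max

from gyflux.ecfba import (
    EcFBAProblem,
    apply_enzyme_capacity,
    apply_rate_bounds,
    condition_flux,
    per_cell_to_specific,
    qp_to_igg_flux,
    rate_bounds_from_phase,
    solve_ecfba,
)
from gyflux.model import MetabolicModel, Metabolite, Reaction, split_reversible
from gyflux.rates import compute_phase_rates
from gyflux.synth import ConditionSpec, default_conditions, simulate_fedbatch


class TestUnitBridge:
    def test_reference_conversion(self):
        # 1 pmol/cell/day at 250 pg/cell dry weight
        assert per_cell_to_specific(1.0, 250.0) == pytest.approx(1.0 / 6.0, rel=1e-9)

    @pytest.mark.parametrize("rate", [0.0, -2.5, 3.0])
    def test_zero_and_sign_preserved(self, rate):
        out = per_cell_to_specific(rate, 250.0)
        assert np.sign(out) == np.sign(rate)
        if rate == 0:
            assert out == 0.0

    def test_nonpositive_dcw_rejected(self):
        with pytest.raises(ValueError):
            per_cell_to_specific(1.0, 0.0)

    def test_qp_conversion_magnitude(self):
        # 20 pg/cell/day at 250 pg/cell, 110 g/mol residues
        v = qp_to_igg_flux(20.0)
        assert v == pytest.approx(20.0 / 250.0 / 24.0 / 0.110)


class TestApplyRateBounds:
    def test_twenty_percent_window(self, toy_model):
        m = apply_rate_bounds(toy_model, {"EX_glc_D(e)": -1.0})
        rxn = m.reactions["EX_glc_D(e)"]
        assert rxn.lb == pytest.approx(-1.2)
        assert rxn.ub == pytest.approx(-0.8)

    def test_zero_rate_widened_by_epsilon(self, toy_model):
        m = apply_rate_bounds(toy_model, {"EX_glc_D(e)": 0.0})
        rxn = m.reactions["EX_glc_D(e)"]
        assert rxn.lb == pytest.approx(-1e-6)
        assert rxn.ub == pytest.approx(1e-6)

    def test_zero_relaxation_pins_rate(self, toy_model):
        m = apply_rate_bounds(toy_model, {"EX_glc_D(e)": -0.5}, relaxation=0.0)
        rxn = m.reactions["EX_glc_D(e)"]
        assert rxn.lb == rxn.ub == -0.5

    def test_unknown_exchange_raises(self, toy_model):
        with pytest.raises(KeyError):
            apply_rate_bounds(toy_model, {"EX_nothing(e)": -1.0})

    def test_rate_beyond_physical_bounds_rejected(self, toy_model):
        # the relaxed window [-24, -16] cannot intersect the physical cap -10
        with pytest.raises(ValueError, match="incompatible"):
            apply_rate_bounds(toy_model, {"EX_glc_D(e)": -20.0})

    def test_phase_rates_map_only_measured_set(self, toy_model):
        cond = ConditionSpec("c", 0.5, noise_cv=0.0, n_replicates=1,
                             rate_heterogeneity=0.0)
        pr = compute_phase_rates(simulate_fedbatch(cond)[0])[4]  # phase [6,7)
        bounds = rate_bounds_from_phase(pr, model=toy_model)
        assert set(bounds) <= {
            r.id for r in toy_model.reactions.values() if r.is_exchange
        }
        assert "EX_glc_D(e)" in bounds and bounds["EX_glc_D(e)"] < 0


class TestEnzymeCapacity:
    def test_single_annotated_reaction_caps_flux(self):
        model = MetabolicModel()
        for mid in ("a[e]", "a[c]"):
            model.add_metabolite(Metabolite(mid))
        model.add_reaction(Reaction("EX_a(e)", {"a[e]": -1.0}, reversible=True, lb=-10))
        # MW/kcat = 2 g*h/mmol
        model.add_reaction(
            Reaction("UP", {"a[e]": -1.0, "a[c]": 1.0}, kcat=1.0, mw=2.0)
        )
        model.add_reaction(Reaction("SINK", {"a[c]": -1.0}))
        model.objective = "SINK"
        sol = solve_ecfba(model, p_total=1.0)
        assert sol.objective == pytest.approx(0.5, abs=1e-9)

    def test_infinite_budget_recovers_plain_fba(self, toy_model):
        uncapped = toy_model.copy()
        uncapped.p_total = None
        plain = solve_ecfba(uncapped)
        huge = solve_ecfba(toy_model, p_total=1e9)
        assert huge.objective == pytest.approx(plain.objective, rel=1e-9)

    def test_default_budget_binds_under_open_bounds(self, toy_model):
        uncapped = toy_model.copy()
        uncapped.p_total = None
        assert solve_ecfba(toy_model).objective < solve_ecfba(uncapped).objective

    def test_monotone_nonincreasing_over_budget_sweep(self, toy_model):
        budgets = [1e-5, 3e-5, 1e-4, 1e-3, 1e-2]
        optima = [solve_ecfba(toy_model, p_total=p).objective for p in budgets]
        assert all(a <= b + 1e-12 for a, b in zip(optima, optima[1:]))
        assert optima[0] < optima[-1]  # the tight end actually binds

    def test_unannotated_model_warns_and_skips(self, tiny_model, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="gyflux.ecfba"):
            out = apply_enzyme_capacity(tiny_model, 0.1)
        assert out.p_total is None
        assert any("no kcat" in r.message for r in caplog.records)


class TestSolveAgainstEnumeration:
    def assemble(self, model):
        split, _ = split_reversible(model)
        S, met_idx, rxn_idx = split.s_matrix()
        lb = np.array([split.reactions[r].lb for r in rxn_idx])
        ub = np.array([split.reactions[r].ub for r in rxn_idx])
        c = np.zeros(len(rxn_idx))
        c[list(rxn_idx).index(model.objective)] = 1.0
        return S, lb, ub, c

    def test_tiny_network_matches_vertex_enumeration(self, tiny_model):
        """LP optimum equals brute-force basic-feasible-solution optimum."""
        S, lb, ub, c = self.assemble(tiny_model)
        best, _ = enumerate_lp_max(c, S, lb, ub)
        sol = solve_ecfba(tiny_model, p_total=None)
        assert sol.objective == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_bounded_tiny_networks_match(self, tiny_model, seed):
        rng = np.random.default_rng(seed)
        model = tiny_model.copy()
        model.reactions["EX_a(e)"].lb = -float(rng.uniform(1, 6))
        model.reactions["A2B"].ub = float(rng.uniform(0.5, 4))
        model.reactions["LOSS"].lb = float(rng.uniform(0, 0.4))
        model.reactions["GROW"].ub = float(rng.uniform(0.5, 6))
        S, lb, ub, c = self.assemble(model)
        best, _ = enumerate_lp_max(c, S, lb, ub)
        sol = solve_ecfba(model, p_total=None)
        assert sol.objective == pytest.approx(best, abs=1e-9)

    def test_steady_state_and_bounds_tolerances(self, toy_model):
        sol = solve_ecfba(toy_model, igg_flux=0.01, p_total=0.05)
        split = sol.model
        S, met_idx, rxn_idx = split.s_matrix()
        v = np.array([sol.fluxes[r] for r in rxn_idx])
        assert np.abs(S @ v).max() < 1e-6
        for rid, j in rxn_idx.items():
            rxn = split.reactions[rid]
            assert rxn.lb - 1e-8 <= v[j] <= rxn.ub + 1e-8


class TestParsimonyAndDeterminism:
    def test_repeat_solves_identical(self, toy_model):
        a = solve_ecfba(toy_model, igg_flux=0.01)
        b = solve_ecfba(toy_model, igg_flux=0.01)
        assert a.fluxes == b.fluxes

    def test_parsimony_removes_futile_cycles(self, toy_model):
        sol = solve_ecfba(toy_model, igg_flux=0.0, p_total=None)
        # forward and backward copies of one reversible reaction never both run
        for rid, (fwd, bwd) in sol.mapping.items():
            if bwd is not None:
                assert min(sol.fluxes[fwd], sol.fluxes[bwd]) < 1e-6, rid

    def test_zero_igg_at_least_as_good_as_positive(self, toy_model):
        free = solve_ecfba(toy_model, igg_flux=0.0, p_total=None)
        loaded = solve_ecfba(toy_model, igg_flux=0.05, p_total=None)
        assert free.objective >= loaded.objective - 1e-9

    def test_igg_flux_outside_bounds_rejected(self, toy_model):
        with pytest.raises(ValueError):
            EcFBAProblem(toy_model, igg_flux=-1.0).solve()

    def test_growth_cap_respected(self, toy_model):
        sol = solve_ecfba(toy_model, growth_rate_cap=0.005, p_total=None)
        assert sol.objective == pytest.approx(0.005, abs=1e-9)


@pytest.fixture(scope="module")
def phase_rates():
    cond = default_conditions(seed=3)[2]  # the 0.5x condition
    batches = simulate_fedbatch(cond)
    return [
        next(p for p in compute_phase_rates(b) if p.phase == (6.0, 7.0))
        for b in batches
    ]


class TestConditionFlux:
    def test_identical_replicates_equal_single_solution(self, gy_model, phase_rates):
        single = condition_flux([phase_rates[0]], gy_model)
        double = condition_flux([phase_rates[0], phase_rates[0]], gy_model)
        for rid, v in single.fluxes.items():
            assert double.fluxes[rid] == pytest.approx(v, abs=1e-9)

    def test_average_within_replicate_envelope(self, gy_model, phase_rates):
        singles = [condition_flux([pr], gy_model) for pr in phase_rates]
        mean = condition_flux(phase_rates, gy_model)
        for rid in mean.fluxes:
            values = [s.fluxes[rid] for s in singles]
            assert min(values) - 1e-9 <= mean.fluxes[rid] <= max(values) + 1e-9

    def test_condition_solution_respects_measured_growth(self, gy_model, phase_rates):
        sol = condition_flux(phase_rates, gy_model)
        mean_sgr = np.mean([pr.sgr for pr in phase_rates]) / 24.0
        assert sol.objective >= 0.8 * mean_sgr - 1e-9

    def test_empty_replicates_rejected(self, gy_model):
        with pytest.raises(ValueError):
            condition_flux([], gy_model)
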