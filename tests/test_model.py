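import json

import numpy as np
import pytest

from gyflux.ecfba import solve_ecfba
from gyflux.model import (
    GY_REACTION_IDS,
    IGG_COMPOSITION_MOLPCT,
    MetabolicModel,
    Metabolite,
    Reaction,
    augment_with_gy,
    build_igg_reaction,
    net_fluxes,
    read_model,
    split_reversible,
    write_model,
)
from gyflux.toynet import toy_cho_network


class TestContainers:
    def test_metabolite_compartment_from_id_tag(self):
        met = Metabolite("glytyr[e]")
        assert met.compartment == "e"
        assert met.name == "glytyr"

    def test_metabolite_without_tag_rejected(self):
        with pytest.raises(ValueError):
            Metabolite("glucose")

    def test_reaction_invariants(self):
        with pytest.raises(ValueError):
            Reaction("r", {})
        with pytest.raises(ValueError):
            Reaction("r", {"a[c]": -1.0}, lb=2.0, ub=1.0)
        with pytest.raises(ValueError):
            Reaction("r", {"a[c]": -1.0}, reversible=False, lb=-1.0)

    def test_unknown_metabolite_reference_names_reaction(self):
        model = MetabolicModel()
        model.add_metabolite(Metabolite("a[c]"))
        with pytest.raises(KeyError, match="bad_rxn"):
            model.add_reaction(Reaction("bad_rxn", {"a[c]": -1.0, "ghost[c]": 1.0}))


class TestModelIO:
    def test_json_round_trip_lossless(self, tmp_path, toy_model):
        path = tmp_path / "net.json"
        write_model(toy_model, path)
        back = read_model(path)
        assert back.to_dict() == toy_model.to_dict()

    def test_shipped_fixture_matches_builder(self):
        from importlib.resources import files

        shipped = json.loads(
            files("gyflux").joinpath("data/toy_cho.json").read_text()
        )
        assert shipped == toy_cho_network().to_dict()

    def test_sbml_round_trip_identical_s_matrix(self, tmp_path, toy_model):
        path = tmp_path / "net.xml"
        write_model(toy_model, path)
        back = read_model(path)
        S1, mi1, ri1 = toy_model.s_matrix()
        S2, mi2, ri2 = back.s_matrix()
        perm_m = [mi2[k] for k in mi1]
        perm_r = [ri2[k] for k in ri1]
        assert np.allclose(S1, S2[np.ix_(perm_m, perm_r)])
        assert back.objective == toy_model.objective
        assert back.p_total == toy_model.p_total
        for rid, rxn in toy_model.reactions.items():
            assert back.reactions[rid].lb == rxn.lb
            assert back.reactions[rid].kcat == rxn.kcat
            assert back.reactions[rid].subsystem == rxn.subsystem

    def test_sbml_readable_by_cobra(self, tmp_path, toy_model):
        cobra = pytest.importorskip("cobra")
        path = tmp_path / "net.xml"
        write_model(toy_model, path)
        cm = cobra.io.read_sbml_model(str(path))
        assert len(cm.reactions) == len(toy_model.reactions)
        assert len(cm.metabolites) == len(toy_model.metabolites)

    def test_ill_formed_json_reports_location(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{ not json")
        with pytest.raises(ValueError, match="bad.json"):
            read_model(bad)


class TestGyAugmentation:
    def test_adds_exactly_three_reactions(self, toy_model):
        before = len(toy_model.reactions)
        out = augment_with_gy(toy_model)
        assert len(out.reactions) == before + 3
        for rid in GY_REACTION_IDS:
            assert rid in out.reactions

    def test_hydrolysis_is_equimolar_and_irreversible(self, gy_model):
        rxn = gy_model.reactions["GLYTYRHYDRO"]
        assert rxn.stoichiometry == {
            "h2o[c]": -1.0, "glytyr[c]": -1.0, "gly[c]": 1.0, "tyr_L[c]": 1.0,
        }
        assert not rxn.reversible and rxn.lb == 0.0

    def test_exchange_and_transport_reversible(self, gy_model):
        assert gy_model.reactions["EX_glytyr(e)"].reversible
        assert gy_model.reactions["GLYTYRPEPT1t"].reversible

    def test_idempotent_with_warning(self, gy_model, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="gyflux.model"):
            again = augment_with_gy(gy_model)
        assert len(again.reactions) == len(gy_model.reactions)
        assert any("augmentation skipped" in r.message for r in caplog.records)

    def test_missing_prerequisites_raise(self):
        model = MetabolicModel()
        model.add_metabolite(Metabolite("gly[c]"))
        with pytest.raises(KeyError, match="tyr_L"):
            augment_with_gy(model)


class TestIggReaction:
    def test_printed_composition_sums_to_100_10(self):
        assert sum(IGG_COMPOSITION_MOLPCT.values()) == pytest.approx(100.10)

    def test_serine_coefficient_renormalized(self):
        rxn = build_igg_reaction()
        assert -rxn.stoichiometry["ser_L[c]"] == pytest.approx(13.25 / 100.10, abs=5e-6)

    def test_amino_acid_coefficients_sum_to_one(self):
        rxn = build_igg_reaction()
        aa_total = -sum(
            c for m, c in rxn.stoichiometry.items()
            if m not in ("atp[c]", "adp[c]", "pi[c]", "h2o[c]", "igg[c]") and c < 0
        )
        assert aa_total == pytest.approx(1.0, abs=1e-12)

    def test_energy_cost_zero_drops_atp(self):
        rxn = build_igg_reaction(energy_cost=0.0)
        assert "atp[c]" not in rxn.stoichiometry

    def test_default_energy_cost_hydrolyzes_atp(self):
        rxn = build_igg_reaction()
        assert rxn.stoichiometry["atp[c]"] == -4.3
        assert rxn.stoichiometry["adp[c]"] == 4.3
        assert rxn.stoichiometry["pi[c]"] == 4.3

    def test_missing_amino_acid_rejected(self):
        comp = dict(IGG_COMPOSITION_MOLPCT)
        comp.pop("serine")
        with pytest.raises(ValueError, match="serine"):
            build_igg_reaction(comp)

    def test_negative_molpct_rejected(self):
        comp = dict(IGG_COMPOSITION_MOLPCT)
        comp["serine"] = -1.0
        with pytest.raises(ValueError):
            build_igg_reaction(comp)


class TestSplitReversible:
    def test_reaction_count_is_n_plus_r(self, toy_model):
        n = len(toy_model.reactions)
        r = sum(1 for x in toy_model.reactions.values() if x.reversible)
        split, mapping = split_reversible(toy_model)
        assert len(split.reactions) == n + r
        assert all(not x.reversible for x in split.reactions.values())
        assert all(x.lb >= 0 for x in split.reactions.values())

    def test_irreversible_only_model_unchanged(self, tiny_model):
        only_fwd = tiny_model.copy()
        rxn = only_fwd.reactions["EX_a(e)"]
        rxn.reversible, rxn.lb, rxn.ub = False, 0.0, 5.0
        split, mapping = split_reversible(only_fwd)
        assert set(split.reactions) == set(only_fwd.reactions)

    def test_net_flux_reassembly_reproduces_optimum(self, toy_model):
        sol = solve_ecfba(toy_model, igg_flux=0.0, p_total=None)
        net = net_fluxes(sol.fluxes, sol.mapping)
        assert set(net) == set(toy_model.reactions)
        assert net["BIOMASS_cho"] == pytest.approx(sol.objective)
        # net exchange fluxes respect the original model's bounds
        for rid, v in net.items():
            rxn = toy_model.reactions[rid]
            assert rxn.lb - 1e-6 <= v <= rxn.ub + 1e-6


class TestToyNetwork:
    def test_positive_biomass_under_default_bounds(self, toy_model):
        sol = solve_ecfba(toy_model, igg_flux=0.0, p_total=None)
        assert sol.objective > 0.01

    def test_closing_glucose_strictly_reduces_biomass(self, toy_model):
        closed = toy_model.copy()
        closed.reactions["EX_glc_D(e)"].lb = 0.0
        sol = solve_ecfba(closed, igg_flux=0.0, p_total=None)
        ref = solve_ecfba(toy_model, igg_flux=0.0, p_total=None)
        assert sol.objective < ref.objective - 1e-6

    def test_no_mass_from_closed_exchanges(self, toy_model):
        closed = toy_model.copy()
        for ex in closed.exchanges():
            closed.reactions[ex].lb = 0.0
            closed.reactions[ex].ub = 0.0
        sol = solve_ecfba(closed, igg_flux=0.0, p_total=None)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        assert sol.total_flux == pytest.approx(0.0, abs=1e-6)

    def test_tyrosine_essential_without_gy(self, gy_model):
        m = gy_model.copy()
        m.reactions["EX_tyr_L(e)"].lb = 0.0
        m.reactions["EX_tyr_L(e)"].ub = 0.0
        m.reactions["EX_glytyr(e)"].lb = 0.0
        m.reactions["EX_glytyr(e)"].ub = 0.0
        sol = solve_ecfba(m, igg_flux=0.0, p_total=None)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_gy_rescues_growth_when_tyrosine_closed(self, gy_model):
        m = gy_model.copy()
        m.reactions["EX_tyr_L(e)"].lb = 0.0
        m.reactions["EX_tyr_L(e)"].ub = 0.0
        sol = solve_ecfba(m, igg_flux=0.01, p_total=None)
        assert sol.objective > 0.01
        net = sol.net()
        assert net["EX_glytyr(e)"] < -1e-4      # GY taken up
        assert net["GLYTYRHYDRO"] > 1e-4        # and cleaved

    def test_subsystems_cover_figure_pathways(self, toy_model):
        subs = {r.subsystem for r in toy_model.reactions.values()}
        for expected in (
            "Pentose phosphate pathway", "TCA cycle", "Glycolysis/Gluconeogenesis",
            "Glutamate metabolism", "Alanine and aspartate metabolism",
            "Oxidative phosphorylation",
        ):
            assert expected in subs

    def test_key_reaction_ids_addressable(self, toy_model):
        for rid in ("G6PDH", "AKGD", "MDH", "GLNS", "ASPTA", "ORNTA", "LEUTA",
                    "ASNN", "PCm"):
            assert rid in toy_model.reactions
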