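"""Model I/O, medium application, LP growth, and the producibility screen."""

import math

import pytest

from ibdevo import ValidationError
from ibdevo import fba
from ibdevo import synthetic_data as sd

from oracles import cobra_max_growth, cobra_producible


class TestModelIO:
    def test_json_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "model.json"
        toy_model.save_json(path)
        loaded = fba.load_model(path)
        assert loaded.metabolites == toy_model.metabolites
        assert {r.id: r.stoich for r in loaded.reactions} == {
            r.id: r.stoich for r in toy_model.reactions
        }
        assert loaded.exchanges == toy_model.exchanges

    def test_sbml_subset_round_trip_preserves_stoichiometry(self, toy_model, tmp_path):
        path = tmp_path / "model.xml"
        toy_model.save_sbml(path)
        loaded = fba.load_model(path, dialect="sbml-subset")
        assert {r.id: r.stoich for r in loaded.reactions} == {
            r.id: r.stoich for r in toy_model.reactions
        }
        assert {r.id: (r.lb, r.ub) for r in loaded.reactions} == {
            r.id: (r.lb, r.ub) for r in toy_model.reactions
        }

    def test_exchanges_autodetected_when_unannotated(self, tmp_path):
        model = sd.generate_toy_model("linear_chain")
        model.exchanges = {}
        model.save_json(tmp_path / "m.json")
        loaded = fba.load_model(tmp_path / "m.json")
        assert loaded.exchanges == {"A": "EX_A"}

    def test_invalid_bounds_rejected(self, tmp_path):
        model = sd.generate_toy_model("linear_chain")
        model.reaction("R_AB").lb = 5
        model.reaction("R_AB").ub = 1
        model.save_json(tmp_path / "m.json")
        with pytest.raises(ValidationError):
            fba.load_model(tmp_path / "m.json")

    def test_missing_biomass_and_dangling_metabolite_rejected(self, tmp_path):
        import json

        model = sd.generate_toy_model("linear_chain")
        raw = model.to_dict()
        del raw["biomass"]
        (tmp_path / "m.json").write_text(json.dumps(raw))
        with pytest.raises(ValidationError):
            fba.load_model(tmp_path / "m.json")
        model.metabolites.append("orphan")
        model.save_json(tmp_path / "m2.json")
        with pytest.raises(ValidationError, match="orphan"):
            fba.load_model(tmp_path / "m2.json")


class TestApplyMedium:
    def test_anoxic_scenario_closes_oxygen(self):
        model = sd.generate_toy_model("branched")
        cfg = fba.FvaConfig()
        constrained = fba.apply_medium(model, cfg, "anoxic", "A")
        assert constrained.reaction("EX_o2").lb == 0.0
        aerobic = fba.apply_medium(model, cfg, "aerobic", "A")
        assert aerobic.reaction("EX_o2").lb == -10.0

    def test_source_uptake_opened_at_configured_rate(self):
        model = sd.generate_toy_model("linear_chain")
        constrained = fba.apply_medium(model, fba.FvaConfig(), "anoxic", "A")
        assert constrained.reaction("EX_A").lb == -100.0

    def test_glucose_removed_from_medium(self):
        model = sd.generate_toy_model("linear_chain")
        model.metabolites.append("glc__D")
        model.reactions.append(fba.Reaction("EX_glc", {"glc__D": -1}, -10, 1000))
        model.exchanges["glc__D"] = "EX_glc"
        cfg = fba.FvaConfig(medium={"glc__D": 10.0})
        constrained = fba.apply_medium(model, cfg, "anoxic", "A")
        assert constrained.reaction("EX_glc").lb == 0.0
        keep = fba.FvaConfig(medium={"glc__D": 10.0}, remove_glucose=False)
        assert fba.apply_medium(model, keep, "anoxic", "A").reaction("EX_glc").lb == -10.0

    def test_unknown_source_rejected(self):
        model = sd.generate_toy_model("linear_chain")
        with pytest.raises(ValidationError):
            fba.apply_medium(model, fba.FvaConfig(), "anoxic", "Z")


class TestMaxGrowth:
    def test_linear_chain_growth_equals_uptake(self):
        model = sd.generate_toy_model("linear_chain")
        constrained = fba.apply_medium(model, fba.FvaConfig(), "anoxic", "A")
        mu, status = fba.max_growth(constrained)
        assert status == "optimal" and mu == pytest.approx(100.0)

    def test_closed_exchanges_give_zero_growth(self):
        model = sd.generate_toy_model("linear_chain")
        model.reaction("EX_A").lb = 0.0
        mu, status = fba.max_growth(model)
        assert status == "optimal" and mu == pytest.approx(0.0)

    def test_infeasible_bounds_reported_not_raised(self):
        model = sd.generate_toy_model("blocked_target")
        model.reaction("R_TB").lb = 1.0  # demands flux through a dead branch
        mu, status = fba.max_growth(model)
        assert status == "infeasible" and math.isnan(mu)

    def test_agrees_with_cobra_on_all_toys(self, toy_model):
        cfg = fba.FvaConfig()
        constrained = fba.apply_medium(toy_model, cfg, "aerobic", toy_model.notes["sources"][0])
        mu, status = fba.max_growth(constrained)
        oracle = cobra_max_growth(toy_model, cfg, "aerobic", toy_model.notes["sources"][0])
        assert status == "optimal"
        assert mu == pytest.approx(oracle, abs=1e-6)


class TestProductionScreen:
    def test_blocked_target_never_producible(self):
        model = sd.generate_toy_model("blocked_target")
        results = fba.production_screen(model, fba.FvaConfig(), ["A"], ["T"])
        assert len(results) == 3  # all oxygen scenarios always reported
        assert all(not r.producible and r.max_production_flux == 0.0 for r in results)

    def test_growth_constraint_halves_chain_production(self):
        model = sd.generate_toy_model("linear_chain")
        results = fba.production_screen(model, fba.FvaConfig(), ["A"], ["B"])
        assert all(r.max_production_flux == pytest.approx(50.0) for r in results)

    def test_oxygen_gates_the_aerobic_branch(self):
        model = sd.generate_toy_model("branched")
        results = {
            r.oxygen_scenario: r
            for r in fba.production_screen(model, fba.FvaConfig(), ["A"], ["D"])
        }
        assert not results["anoxic"].producible
        assert results["microaerobic"].max_production_flux == pytest.approx(1.0)
        assert results["aerobic"].max_production_flux == pytest.approx(10.0)

    def test_disconnected_source_is_a_no_op_control(self):
        # P1 is only ever produced, so feeding it changes nothing: targets are
        # producible iff they are producible from the medium alone
        model = sd.generate_toy_model("currency_hub")
        cfg = fba.FvaConfig(medium={"A": 10.0})
        with_source = fba.production_screen(model, cfg, ["P1"], ["C", "D"])
        no_source = fba.production_screen(
            model,
            fba.FvaConfig(medium={"A": 10.0}, source_uptake=0.0),
            ["P1"],
            ["C", "D"],
        )
        assert [(r.target, r.oxygen_scenario, r.producible) for r in with_source] == [
            (r.target, r.oxygen_scenario, r.producible) for r in no_source
        ]

    def test_infeasible_medium_flags_all_targets(self):
        model = sd.generate_toy_model("linear_chain")
        model.reaction("R_BC").lb = 2000.0  # above its own upper bound
        results = fba.production_screen(model, fba.FvaConfig(), ["A"], ["B"])
        assert all(r.status == "infeasible" and not r.producible for r in results)

    def test_zero_growth_flagged_but_screen_continues(self):
        model = sd.generate_toy_model("linear_chain")
        model.reaction("BIOMASS").ub = 0.0
        results = fba.production_screen(model, fba.FvaConfig(), ["A"], ["B"])
        assert all(r.status == "zero_growth" for r in results)
        assert all(r.max_production_flux == pytest.approx(100.0) for r in results)

    def test_matches_cobra_oracle_on_all_toys(self, toy_model):
        cfg = fba.FvaConfig()
        sources = toy_model.notes["sources"]
        targets = [
            m for m in toy_model.metabolites if m not in sources and m != cfg.oxygen_id
        ]
        ours = {
            (r.source, r.target, r.oxygen_scenario): r.producible
            for r in fba.production_screen(toy_model, cfg, sources, targets)
        }
        for source in sources:
            for scenario in cfg.oxygen_levels:
                oracle = cobra_producible(toy_model, cfg, source, scenario, targets)
                for target in targets:
                    assert ours[(source, target, scenario)] == oracle[target]

    def test_raising_growth_fraction_never_raises_production(self, toy_model):
        sources = toy_model.notes["sources"]
        targets = [m for m in toy_model.metabolites if m not in sources and m != "o2"]
        lo = fba.production_screen(toy_model, fba.FvaConfig(growth_fraction=0.25), sources, targets)
        hi = fba.production_screen(toy_model, fba.FvaConfig(growth_fraction=0.9), sources, targets)
        for a, b in zip(lo, hi):
            assert b.max_production_flux <= a.max_production_flux + 1e-9

    def test_oxygen_only_relaxes_on_toys_without_inhibition(self, toy_model):
        cfg = fba.FvaConfig()
        sources = toy_model.notes["sources"]
        targets = [m for m in toy_model.metabolites if m not in sources and m != cfg.oxygen_id]
        results = {
            (r.target, r.oxygen_scenario): r.producible
            for r in fba.production_screen(toy_model, cfg, sources, targets)
        }
        for target in targets:
            if results[(target, "anoxic")]:
                assert results[(target, "aerobic")]


class TestFluxEpsilonCall:
    def test_strict_threshold_and_noise_clamp(self):
        cfg = fba.FvaConfig()
        assert not fba.flux_epsilon_call(1e-6, cfg)
        assert fba.flux_epsilon_call(2e-6, cfg)
        assert not fba.flux_epsilon_call(-1e-9 + 1e-12, cfg)

    def test_invalid_growth_fraction_rejected(self):
        with pytest.raises(ValidationError):
            fba.FvaConfig(growth_fraction=0.0)
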