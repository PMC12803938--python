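"""FBA / pFBA / FVA / loop removal, against hand values and the LP oracle."""

import numpy as np
import pytest

from difflux import (
    FVASettings,
    FluxDistribution,
    InfeasibleError,
    MetabolicModel,
    Metabolite,
    Reaction,
    UnboundedError,
    fba,
    fva,
    pfba,
    remove_loops,
)

from .oracle import brute_fba, brute_min_total, max_mass_imbalance


def as_distribution(model, fluxes: dict) -> FluxDistribution:
    import pandas as pd

    series = pd.Series(
        {r.id: fluxes.get(r.id, 0.0) for r in model.reactions}, name="flux"
    )
    c = model.objective_array()
    v = series.to_numpy()
    return FluxDistribution(
        fluxes=series,
        objective_value=float(c @ v),
        total_flux=float(np.abs(v).sum()),
    )


class TestFba:
    def test_chain_optimum_is_uptake_limited(self, chain):
        sol = fba(chain)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_toy_optimum_is_amino_acid_limited(self, toy_model):
        # biomass needs 1 glycine/serine/arginine per unit, uptakes cap at 5
        assert fba(toy_model).objective_value == pytest.approx(5.0, abs=1e-6)

    def test_all_zero_bounds_give_zero_optimum(self, chain):
        for r in chain.reactions:
            r.lower_bound = r.upper_bound = 0.0
        sol = fba(chain)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sol.fluxes.to_numpy(), 0.0)

    def test_infeasible_model_raises(self, chain):
        ex = chain.get_reaction("EX_A")
        ex.lower_bound = ex.upper_bound = -10.0
        chain.get_reaction("R1").upper_bound = 5.0  # A accumulates
        with pytest.raises(InfeasibleError):
            fba(chain)

    def test_unbounded_objective_raises(self, chain):
        chain.get_reaction("EX_A").lower_bound = -np.inf
        chain.get_reaction("R1").upper_bound = np.inf
        chain.get_reaction("EX_B").upper_bound = np.inf
        with pytest.raises(UnboundedError):
            fba(chain)

    def test_empty_objective_rejected(self, chain):
        chain.objective = {}
        with pytest.raises(ValueError, match="objective"):
            fba(chain)


class TestPfba:
    def test_diamond_prefers_short_route(self, diamond):
        sol = pfba(diamond)
        assert sol.total_flux == pytest.approx(30.0, abs=1e-6)
        assert sol["R1"] == pytest.approx(10.0, abs=1e-6)
        assert sol["R2"] == pytest.approx(0.0, abs=1e-6)
        assert sol["R3"] == pytest.approx(0.0, abs=1e-6)

    def test_chain_pfba_equals_fba(self, chain):
        f, p = fba(chain), pfba(chain)
        assert np.allclose(f.fluxes.to_numpy(), p.fluxes.to_numpy(), atol=1e-6)

    def test_zero_fraction_gives_zero_flux(self, diamond):
        sol = pfba(diamond, fraction_of_optimum=0.0)
        assert sol.total_flux == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("fixture", ["toy_model", "diamond", "chain", "two_cycle"])
    def test_mass_balance(self, fixture, request):
        model = request.getfixturevalue(fixture)
        sol = pfba(model)
        assert max_mass_imbalance(model, dict(sol.fluxes)) < 1e-6


class TestFva:
    def test_diamond_uncapped_either_route_carries_all(self, diamond, plain_settings):
        ranges = fva(diamond, plain_settings)
        assert ranges["R1"] == pytest.approx((0.0, 10.0), abs=1e-6)
        assert ranges["R3"] == pytest.approx((0.0, 10.0), abs=1e-6)

    def test_diamond_flux_cap_algebra(self, diamond):
        # pFBA total 30, cap 33: long-route flux x obeys 30 + x <= 33
        settings = FVASettings(fraction_of_optimum=1.0, pfba_factor=1.1, loopless=False)
        ranges = fva(diamond, settings)
        assert ranges["R3"] == pytest.approx((0.0, 3.0), abs=1e-6)
        assert ranges["R2"] == pytest.approx((0.0, 3.0), abs=1e-6)
        assert ranges["R1"] == pytest.approx((7.0, 10.0), abs=1e-6)

    def test_two_cycle_standard_vs_loopless(self, two_cycle):
        standard = fva(
            two_cycle, FVASettings(fraction_of_optimum=0.9, pfba_factor=None, loopless=False)
        )
        loopless = fva(
            two_cycle, FVASettings(fraction_of_optimum=0.9, pfba_factor=None, loopless=True)
        )
        assert standard["CYCF"][1] == pytest.approx(two_cycle.default_bound, abs=1e-6)
        assert standard["CYCR"][1] == pytest.approx(two_cycle.default_bound, abs=1e-6)
        assert loopless["CYCF"] == pytest.approx((0.0, 0.0), abs=1e-6)
        assert loopless["CYCR"] == pytest.approx((0.0, 0.0), abs=1e-6)
        # productive chain untouched by loop handling
        assert loopless["R1"] == pytest.approx(standard["R1"], abs=1e-6)

    def test_sandwich_pfba_flux_inside_ranges(self, ensured_toy):
        settings = FVASettings()  # 0.9 / 1.1 / loopless
        ranges = fva(ensured_toy, settings)
        sol = pfba(ensured_toy, fraction_of_optimum=settings.fraction_of_optimum)
        for rid in ensured_toy.reaction_ids:
            lo, hi = ranges[rid]
            assert lo - 1e-6 <= sol[rid] <= hi + 1e-6

    def test_raising_fraction_never_widens(self, ensured_toy):
        loose = fva(ensured_toy, FVASettings(0.9, None, False))
        tight = fva(ensured_toy, FVASettings(1.0, None, False))
        assert (tight.minimum >= loose.minimum - 1e-6).all()
        assert (tight.maximum <= loose.maximum + 1e-6).all()

    def test_lowering_pfba_factor_never_widens(self, ensured_toy):
        loose = fva(ensured_toy, FVASettings(0.9, 1.1, False))
        tight = fva(ensured_toy, FVASettings(0.9, 1.05, False))
        assert (tight.minimum >= loose.minimum - 1e-6).all()
        assert (tight.maximum <= loose.maximum + 1e-6).all()

    @pytest.mark.parametrize("fixture", ["ensured_toy", "two_cycle", "diamond"])
    def test_loopless_ranges_are_subsets(self, fixture, request):
        model = request.getfixturevalue(fixture)
        standard = fva(model, FVASettings(0.9, 1.1, False))
        loopless = fva(model, FVASettings(0.9, 1.1, True))
        assert (loopless.minimum >= standard.minimum - 1e-6).all()
        assert (loopless.maximum <= standard.maximum + 1e-6).all()


class TestRemoveLoops:
    def test_loop_free_solution_is_fixed_point(self, diamond):
        sol = pfba(diamond)
        out = remove_loops(diamond, sol)
        assert np.allclose(out.fluxes.to_numpy(), sol.fluxes.to_numpy(), atol=1e-9)

    def test_superimposed_cycle_is_subtracted(self, two_cycle):
        k = 7.0
        sol = as_distribution(
            two_cycle, {"EX_A": -10, "R1": 10, "CYCF": k, "CYCR": k, "EX_B": 10}
        )
        out = remove_loops(two_cycle, sol)
        assert out["CYCF"] == pytest.approx(0.0, abs=1e-9)
        assert out["CYCR"] == pytest.approx(0.0, abs=1e-9)
        assert out["R1"] == pytest.approx(10.0, abs=1e-9)
        assert out.objective_value == pytest.approx(sol.objective_value, abs=1e-9)
        assert out["EX_A"] == pytest.approx(sol["EX_A"], abs=1e-12)

    def test_pinned_cycle_survives_others_removed(self):
        # two independent futile 2-cycles hanging off one chain
        model = MetabolicModel(
            metabolites=[Metabolite(x) for x in "ABCD"],
            reactions=[
                Reaction("EX_A", {"A": -1}, -10, 0, is_exchange=True),
                Reaction("R1", {"A": -1, "B": 1}, 0, 1000),
                Reaction("EX_B", {"B": -1}, 0, 1000, is_exchange=True),
                Reaction("C1F", {"B": -1, "C": 1}, 0, 1000),
                Reaction("C1R", {"C": -1, "B": 1}, 0, 1000),
                Reaction("C2F", {"B": -1, "D": 1}, 0, 1000),
                Reaction("C2R", {"D": -1, "B": 1}, 0, 1000),
            ],
            objective={"EX_B": 1.0},
        )
        sol = as_distribution(
            model,
            {"EX_A": -10, "R1": 10, "EX_B": 10, "C1F": 4, "C1R": 4, "C2F": 6, "C2R": 6},
        )
        out = remove_loops(model, sol, pinned_reaction="C1R")
        assert out["C1R"] == pytest.approx(4.0, abs=1e-9)  # pin honoured
        assert out["C1F"] == pytest.approx(4.0, abs=1e-9)  # balance forces partner
        assert out["C2F"] == pytest.approx(0.0, abs=1e-9)  # free cycle removed
        assert out["C2R"] == pytest.approx(0.0, abs=1e-9)
        out_unpinned = remove_loops(model, sol)
        for rid in ("C1F", "C1R", "C2F", "C2R"):
            assert out_unpinned[rid] == pytest.approx(0.0, abs=1e-9)


class TestOracleEquivalence:
    def test_fba_objective_matches_bruteforce(self, ensured_toy):
        z, _ = brute_fba(ensured_toy)
        assert fba(ensured_toy).objective_value == pytest.approx(z, abs=1e-6)

    def test_pfba_solution_matches_bruteforce(self, ensured_toy):
        z, _ = brute_fba(ensured_toy)
        total, fluxes = brute_min_total(ensured_toy, z)
        sol = pfba(ensured_toy)
        assert sol.total_flux == pytest.approx(total, abs=1e-6)
        for rid, value in fluxes.items():
            assert sol[rid] == pytest.approx(value, abs=1e-6), rid


class TestCobraCrossCheck:
    """The installed COBRA toolkit as a second, independent implementation."""

    cobra = pytest.importorskip("cobra")

    def test_pfba_total_flux_agrees(self, ensured_toy):
        from cobra.flux_analysis import pfba as cobra_pfba

        from .oracle import to_cobra

        cm = to_cobra(ensured_toy)
        csol = cobra_pfba(cm)
        ours = pfba(ensured_toy)
        assert ours.total_flux == pytest.approx(
            float(np.abs(csol.fluxes).sum()), abs=1e-5
        )
        for rid in ensured_toy.reaction_ids:
            assert ours[rid] == pytest.approx(float(csol.fluxes[rid]), abs=1e-5), rid

    @pytest.mark.parametrize("loopless", [False, True])
    def test_fva_ranges_agree(self, ensured_toy, loopless):
        from cobra.flux_analysis import flux_variability_analysis

        from .oracle import to_cobra

        cm = to_cobra(ensured_toy)
        ref = flux_variability_analysis(
            cm,
            fraction_of_optimum=0.9,
            pfba_factor=1.1,
            loopless="cycleFreeFlux" if loopless else None,
            processes=1,
        )
        ours = fva(ensured_toy, FVASettings(0.9, 1.1, loopless))
        for rid in ensured_toy.reaction_ids:
            lo, hi = ours[rid]
            assert lo == pytest.approx(float(ref.loc[rid, "minimum"]), abs=1e-5), rid
            assert hi == pytest.approx(float(ref.loc[rid, "maximum"]), abs=1e-5), rid
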