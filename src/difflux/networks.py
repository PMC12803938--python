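"""Bundled hand-analyzable fixture networks.

``build_toy_model`` is the desk-scale stand-in for a genome-scale mammalian
reconstruction: a glucose-fed central-carbon network with glycolysis, the
oxidative + non-oxidative pentose phosphate pathway (PPP) producing an NADPH
pseudo-metabolite, a TCA cycle with anaplerosis, amino-acid exchanges
(glutamine, glycine, serine, arginine), a biomass sink consuming precursors,
and one deliberately loop-forming internal reaction pair (a futile 2-cycle)
for testing loopless analysis.  All stoichiometry is small-integer so every
optimum can be verified by hand or by brute-force LP.

The smaller fixtures (`linear_chain`, `diamond_network`, `two_cycle_network`)
isolate single behaviours: bound-limited optima, parsimonious route
selection and total-flux-cap algebra, and thermodynamically infeasible
cycles.
"""

from __future__ import annotations

from typing import Dict

from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

GLYCOLYSIS = "Glycolysis"
PPP = "Pentose phosphate pathway"
TCA = "TCA cycle"
AA = "Amino acid metabolism"
EXCHANGE = "Exchange"
BIOMASS = "Biomass"
FUTILE = "Futile cycle"

#: the closed set of subsystem labels used by the bundled fixtures
SUBSYSTEMS = (GLYCOLYSIS, PPP, TCA, AA, EXCHANGE, BIOMASS, FUTILE)


def _ex(mid: str, lb: float, ub: float = DEFAULT_BOUND) -> Reaction:
    return Reaction(
        id=f"EX_{mid}",
        stoichiometry={mid: -1.0},
        lower_bound=lb,
        upper_bound=ub,
        subsystem=EXCHANGE,
        is_exchange=True,
    )


def build_toy_model() -> MetabolicModel:
    """Deterministic toy central-carbon model (18 metabolites, 24 reactions).

    Key design facts (all hand-verifiable):

    * glucose uptake is bounded at 10; amino-acid uptakes at 5;
    * biomass consumes G3P, acetyl-CoA, AKG, glycine, serine, arginine and
      half a glutamine per unit, so growth is amino-acid-limited with an
      FBA optimum of exactly 5;
    * the PPP (G6PDH → TKT, plus an NADPH demand sink) carries no flux in
      the parsimonious reference and acts as pure surplus capacity whose
      FVA maximum is glucose-limited;
    * AKG is biomass-essential but has no exchange reaction, so the
      metabolomics-integration stage must add an artificial one;
    * CYCF/CYCR form a futile 2-cycle through the dead-ended pseudo
      metabolite ``cycm``: any flux on them is a thermodynamically
      infeasible loop.
    """
    mets = [
        Metabolite("glc", "D-glucose", "e"),
        Metabolite("gln", "L-glutamine", "e"),
        Metabolite("gly", "glycine", "e"),
        Metabolite("ser", "L-serine", "e"),
        Metabolite("arg", "L-arginine", "e"),
        Metabolite("lac", "L-lactate", "e"),
        Metabolite("co2", "carbon dioxide", "c"),
        Metabolite("g6p", "glucose 6-phosphate", "c"),
        Metabolite("f6p", "fructose 6-phosphate", "c"),
        Metabolite("g3p", "glyceraldehyde 3-phosphate", "c"),
        Metabolite("pyr", "pyruvate", "c"),
        Metabolite("r5p", "ribose 5-phosphate", "c"),
        Metabolite("nadph", "NADPH (reducing equivalent)", "c"),
        Metabolite("accoa", "acetyl-CoA", "c"),
        Metabolite("oaa", "oxaloacetate", "c"),
        Metabolite("cit", "citrate", "c"),
        Metabolite("akg", "alpha-ketoglutarate", "c"),
        Metabolite("cycm", "futile-cycle pseudo-metabolite", "c"),
    ]

    def irr(rid, stoich, subsystem):
        return Reaction(rid, stoich, 0.0, DEFAULT_BOUND, subsystem)

    rxns = [
        _ex("glc", -10.0),
        _ex("gln", -5.0),
        _ex("gly", -5.0),
        _ex("ser", -5.0),
        _ex("arg", -5.0),
        _ex("lac", 0.0),
        _ex("co2", 0.0),
        # glycolysis
        irr("HEX", {"glc": -1, "g6p": 1}, GLYCOLYSIS),
        irr("PGI", {"g6p": -1, "f6p": 1}, GLYCOLYSIS),
        irr("PFK", {"f6p": -1, "g3p": 2}, GLYCOLYSIS),
        irr("PYK", {"g3p": -1, "pyr": 1}, GLYCOLYSIS),
        irr("LDH", {"pyr": -1, "lac": 1}, GLYCOLYSIS),
        # pentose phosphate pathway (oxidative, non-oxidative, NADPH demand)
        irr("G6PDH", {"g6p": -1, "r5p": 1, "nadph": 2, "co2": 1}, PPP),
        irr("TKT", {"r5p": -3, "f6p": 2, "g3p": 1}, PPP),
        irr("NADPHOX", {"nadph": -1}, PPP),
        # TCA cycle and anaplerosis
        irr("PDH", {"pyr": -1, "accoa": 1, "co2": 1}, TCA),
        irr("PC", {"pyr": -1, "co2": -1, "oaa": 1}, TCA),
        irr("CS", {"accoa": -1, "oaa": -1, "cit": 1}, TCA),
        irr("IDH", {"cit": -1, "akg": 1, "co2": 1}, TCA),
        irr("AKGDH", {"akg": -1, "oaa": 1, "co2": 1}, TCA),
        # glutaminolysis
        irr("GLS", {"gln": -1, "akg": 1}, AA),
        # biomass sink
        irr(
            "BIOMASS",
            {
                "g3p": -1,
                "accoa": -1,
                "akg": -1,
                "gly": -1,
                "ser": -1,
                "arg": -1,
                "gln": -0.5,
            },
            BIOMASS,
        ),
        # futile 2-cycle through a dead-ended pseudo-metabolite
        irr("CYCF", {"oaa": -1, "cycm": 1}, FUTILE),
        irr("CYCR", {"cycm": -1, "oaa": 1}, FUTILE),
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective={"BIOMASS": 1.0},
        id="toy_central_carbon",
    )


def toy_metabolite_map() -> Dict[str, str]:
    """Measured-metabolite-name → toy-model metabolite id mapping.

    Alpha-ketoglutarate has no exchange reaction in the toy model, so it
    exercises the artificial-exchange path.
    """
    return {
        "glucose": "glc",
        "glutamine": "gln",
        "glycine": "gly",
        "serine": "ser",
        "arginine": "arg",
        "lactate": "lac",
        "alpha-ketoglutarate": "akg",
    }


def linear_chain() -> MetabolicModel:
    """Uptake ∅→A (cap 10), A→B, export B→∅ (objective). Optimum = 10."""
    mets = [Metabolite("A", compartment="c"), Metabolite("B", compartment="c")]
    rxns = [
        _ex("A", -10.0, 0.0),
        Reaction("R1", {"A": -1, "B": 1}, 0.0, DEFAULT_BOUND, "Chain"),
        _ex("B", 0.0),
    ]
    return MetabolicModel(mets, rxns, {"EX_B": 1.0}, id="linear_chain")


def diamond_network() -> MetabolicModel:
    """Two routes A→B: direct (R1) vs via C (R2, R3); export B is objective.

    The parsimonious solution routes everything through R1 (total flux 30,
    versus 40 for the long route); with a 10% total-flux allowance the long
    route can carry at most 3.
    """
    mets = [
        Metabolite("A", compartment="c"),
        Metabolite("B", compartment="c"),
        Metabolite("C", compartment="c"),
    ]
    rxns = [
        _ex("A", -10.0, 0.0),
        Reaction("R1", {"A": -1, "B": 1}, 0.0, DEFAULT_BOUND, "Short"),
        Reaction("R2", {"A": -1, "C": 1}, 0.0, DEFAULT_BOUND, "Long"),
        Reaction("R3", {"C": -1, "B": 1}, 0.0, DEFAULT_BOUND, "Long"),
        _ex("B", 0.0),
    ]
    return MetabolicModel(mets, rxns, {"EX_B": 1.0}, id="diamond")


def two_cycle_network() -> MetabolicModel:
    """A productive chain plus a futile 2-cycle B⇄C with C dead-ended.

    Standard FVA reports the default bound for both cycle reactions (they
    can spin freely); any loopless solution has both at zero.
    """
    mets = [
        Metabolite("A", compartment="c"),
        Metabolite("B", compartment="c"),
        Metabolite("C", compartment="c"),
    ]
    rxns = [
        _ex("A", -10.0, 0.0),
        Reaction("R1", {"A": -1, "B": 1}, 0.0, DEFAULT_BOUND, "Chain"),
        Reaction("CYCF", {"B": -1, "C": 1}, 0.0, DEFAULT_BOUND, "Futile cycle"),
        Reaction("CYCR", {"C": -1, "B": 1}, 0.0, DEFAULT_BOUND, "Futile cycle"),
        _ex("B", 0.0),
    ]
    return MetabolicModel(mets, rxns, {"EX_B": 1.0}, id="two_cycle")
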