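"""A reduced CHO-like metabolic network for desk-scale flux analysis.

A ~115-reaction stand-in for a CHO genome-scale model covering the pathways
the comparative flux analysis interrogates: glucose uptake and glycolysis,
the oxidative pentose phosphate pathway entering through G6PDH (the NADPH
source), a full TCA cycle with AKGD and MDH (mitochondrial NADH sources) and
FADH2 via succinate dehydrogenase, oxidative phosphorylation, glutamine
synthetase (GLNS), the amino-acid transaminases ASPTA / ALATA / ORNTA /
LEUTA, asparaginase (ASNN), pyruvate carboxylase (PCm), GABA (4abut)
synthesis and secretion, exchanges and transporters for all 20 proteinogenic
amino acids plus ornithine, lactate and ammonia, an ATP maintenance
reaction, a generic CHO biomass pseudo-reaction and the sequence-derived IgG
synthesis reaction.

Multi-step pathway segments without condition-diagnostic branch points are
lumped (e.g. lower glycolysis, the oxidative PPP into ``G6PDH``, the
AKGDH + succinyl-CoA ligase pair into ``AKGD``); every lump conserves carbon
and redox bookkeeping, so the closed network cannot generate mass or ATP
from nothing.  Amino acids with no explicit catabolic route here carry a
demand (``DM_``) sink standing in for the catabolism a genome-scale model
would provide.  A subset of enzymatic reactions is annotated with plausible
turnover numbers (kcat, 1/h) and enzyme masses (MW, g/mmol) to drive the
pooled enzyme-capacity constraint.
"""

from __future__ import annotations

from gyflux.model import AA_METABOLITES, MetabolicModel, Metabolite, Reaction, build_igg_reaction

#: (amino acid name, base id) for the 20 proteinogenic amino acids
_AA_BASES = sorted((name, met_id[:-3]) for name, met_id in AA_METABOLITES.items())

#: biomass amino-acid demand, mmol/gDCW (generic CHO protein composition)
_BIOMASS_AA = {
    "ala_L": 0.45, "arg_L": 0.25, "asn_L": 0.20, "asp_L": 0.30, "cys_L": 0.08,
    "gln_L": 0.25, "glu_L": 0.30, "gly": 0.40, "his_L": 0.10, "ile_L": 0.25,
    "leu_L": 0.45, "lys_L": 0.35, "met_L": 0.10, "phe_L": 0.18, "pro_L": 0.25,
    "ser_L": 0.30, "thr_L": 0.30, "trp_L": 0.05, "tyr_L": 0.12, "val_L": 0.30,
}

#: amino acids with an explicit catabolic entry in this network
_AA_WITH_ROUTE = {"ala_L", "arg_L", "asn_L", "asp_L", "gln_L", "glu_L", "leu_L"}

#: kcat (1/h) and MW (g/mmol) annotations for the enzyme-capacity pool
_ENZYME_DATA = {
    "HEX1": (200 * 3600, 102.0),
    "GLYC": (100 * 3600, 250.0),
    "LDH_L": (300 * 3600, 140.0),
    "G6PDH": (150 * 3600, 59.0),
    "PPPNOX": (60 * 3600, 70.0),
    "ACCOASYN": (50 * 3600, 160.0),
    "PDHm": (30 * 3600, 300.0),
    "PCm": (60 * 3600, 130.0),
    "CSm": (100 * 3600, 100.0),
    "ICDHm": (40 * 3600, 80.0),
    "AKGD": (30 * 3600, 300.0),
    "SUCD": (80 * 3600, 130.0),
    "FUM": (400 * 3600, 200.0),
    "MDH": (500 * 3600, 70.0),
    "NADHOR": (50 * 3600, 1000.0),
    "FADH2OR": (50 * 3600, 500.0),
    "GLNS": (20 * 3600, 45.0),
    "GLUN": (25 * 3600, 65.0),
    "GLUDxm": (40 * 3600, 330.0),
    "GLUDC": (15 * 3600, 65.0),
    "ASPTA": (150 * 3600, 95.0),
    "ALATA": (100 * 3600, 110.0),
    "ASNN": (30 * 3600, 140.0),
    "ORNTA": (40 * 3600, 100.0),
    "G5SADH": (30 * 3600, 60.0),
    "ARGORN": (100 * 3600, 120.0),
    "LEUTA": (80 * 3600, 90.0),
}

INF = 1000.0


def toy_cho_network(p_total: float = 0.05) -> MetabolicModel:
    """Build the reduced CHO-like network (biomass objective, mmol/gDCW/h).

    ``p_total`` is the pooled enzyme budget in g/gDCW used when the capacity
    constraint is enabled.
    """
    model = MetabolicModel(model_id="toy_cho", p_total=p_total)

    def met(mid: str, name: str = "") -> None:
        model.add_metabolite(Metabolite(mid, name))

    # --- metabolites ------------------------------------------------------
    for _, base in _AA_BASES:
        met(f"{base}[e]")
        met(f"{base}[c]")
    for mid in (
        "glc_D[e]", "lac_L[e]", "nh4[e]", "o2[e]", "co2[e]", "h2o[e]",
        "4abut[e]", "4mop[e]", "orn[e]",
    ):
        met(mid)
    for mid in (
        "glc_D[c]", "g6p[c]", "ru5p_D[c]", "pyr[c]", "lac_L[c]", "accoa[c]",
        "atp[c]", "adp[c]", "pi[c]", "h2o[c]", "nad[c]", "nadh[c]",
        "nadp[c]", "nadph[c]", "co2[c]", "o2[c]", "nh4[c]", "akg[c]",
        "oaa[c]", "glu5sa[c]", "4abut[c]", "4mop[c]", "orn[c]", "igg[c]",
    ):
        met(mid)
    for mid in (
        "pyr[m]", "accoa[m]", "oaa[m]", "cit[m]", "akg[m]", "succ[m]",
        "fum[m]", "mal_L[m]", "glu_L[m]", "nh4[m]", "atp[m]", "adp[m]",
        "pi[m]", "nad[m]", "nadh[m]", "fad[m]", "fadh2[m]", "o2[m]",
        "co2[m]", "h2o[m]",
    ):
        met(mid)

    def rxn(
        rid: str,
        stoich: dict[str, float],
        rev: bool = False,
        lb: float | None = None,
        ub: float = INF,
        sub: str = "",
        name: str = "",
    ) -> None:
        kcat, mw = _ENZYME_DATA.get(rid, (None, None))
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=rev,
                lb=(-INF if rev else 0.0) if lb is None else lb,
                ub=ub,
                subsystem=sub,
                name=name or rid,
                kcat=kcat,
                mw=mw,
            )
        )

    # --- exchanges --------------------------------------------------------
    for _, base in _AA_BASES:
        rxn(f"EX_{base}(e)", {f"{base}[e]": -1.0}, rev=True, lb=-10.0, sub="Exchange")
    rxn("EX_glc_D(e)", {"glc_D[e]": -1.0}, rev=True, lb=-10.0, sub="Exchange")
    rxn("EX_lac_L(e)", {"lac_L[e]": -1.0}, rev=True, lb=-10.0, sub="Exchange")
    rxn("EX_nh4(e)", {"nh4[e]": -1.0}, rev=True, lb=-10.0, sub="Exchange")
    rxn("EX_o2(e)", {"o2[e]": -1.0}, rev=True, lb=-INF, sub="Exchange")
    rxn("EX_co2(e)", {"co2[e]": -1.0}, rev=True, lb=-INF, sub="Exchange")
    rxn("EX_h2o(e)", {"h2o[e]": -1.0}, rev=True, lb=-INF, sub="Exchange")
    rxn("EX_orn(e)", {"orn[e]": -1.0}, rev=True, lb=-10.0, sub="Exchange")
    rxn("EX_4abut(e)", {"4abut[e]": -1.0}, lb=0.0, sub="Exchange")
    rxn("EX_4mop(e)", {"4mop[e]": -1.0}, lb=0.0, sub="Exchange")

    # --- transporters -----------------------------------------------------
    for _, base in _AA_BASES:
        rxn(f"{base.upper()}t", {f"{base}[e]": -1.0, f"{base}[c]": 1.0}, rev=True,
            sub="Transport")
    rxn("GLCt1", {"glc_D[e]": -1.0, "glc_D[c]": 1.0}, sub="Transport")
    rxn("LACt", {"lac_L[c]": -1.0, "lac_L[e]": 1.0}, rev=True, sub="Transport")
    rxn("NH4t", {"nh4[c]": -1.0, "nh4[e]": 1.0}, rev=True, sub="Transport")
    rxn("O2t", {"o2[e]": -1.0, "o2[c]": 1.0}, rev=True, sub="Transport")
    rxn("O2tm", {"o2[c]": -1.0, "o2[m]": 1.0}, rev=True, sub="Transport")
    rxn("CO2t", {"co2[c]": -1.0, "co2[e]": 1.0}, rev=True, sub="Transport")
    rxn("CO2tm", {"co2[m]": -1.0, "co2[c]": 1.0}, rev=True, sub="Transport")
    rxn("H2Ot", {"h2o[e]": -1.0, "h2o[c]": 1.0}, rev=True, sub="Transport")
    rxn("H2Otm", {"h2o[c]": -1.0, "h2o[m]": 1.0}, rev=True, sub="Transport")
    rxn("ABUTt", {"4abut[c]": -1.0, "4abut[e]": 1.0}, sub="Transport")
    rxn("4MOPt", {"4mop[c]": -1.0, "4mop[e]": 1.0}, sub="Transport")
    rxn("ORNt", {"orn[e]": -1.0, "orn[c]": 1.0}, rev=True, sub="Transport")
    rxn("PYRtm", {"pyr[c]": -1.0, "pyr[m]": 1.0}, sub="Transport")
    rxn("ATPtm", {"atp[m]": -1.0, "adp[c]": -1.0, "atp[c]": 1.0, "adp[m]": 1.0},
        sub="Transport", name="adenine nucleotide translocase")
    rxn("PItm", {"pi[c]": -1.0, "pi[m]": 1.0}, rev=True, sub="Transport")
    rxn("GLUtm", {"glu_L[c]": -1.0, "glu_L[m]": 1.0}, rev=True, sub="Transport")
    rxn("AKGtm", {"akg[c]": -1.0, "akg[m]": 1.0}, rev=True, sub="Transport")
    rxn("OAAtm", {"oaa[c]": -1.0, "oaa[m]": 1.0}, rev=True, sub="Transport")
    rxn("NH4tm", {"nh4[m]": -1.0, "nh4[c]": 1.0}, rev=True, sub="Transport")

    # --- glycolysis and pyruvate ------------------------------------------
    # sugar phosphates are tracked without their phosphate group here, so the
    # kinase returns Pi to the pool and the phosphate moiety stays closed
    rxn("HEX1", {"glc_D[c]": -1.0, "atp[c]": -1.0, "g6p[c]": 1.0, "adp[c]": 1.0,
                 "pi[c]": 1.0},
        sub="Glycolysis/Gluconeogenesis", name="hexokinase")
    rxn("GLYC",
        {"g6p[c]": -1.0, "adp[c]": -3.0, "pi[c]": -3.0, "nad[c]": -2.0,
         "pyr[c]": 2.0, "atp[c]": 3.0, "nadh[c]": 2.0, "h2o[c]": 2.0},
        sub="Glycolysis/Gluconeogenesis", name="lower glycolysis (lumped)")
    rxn("LDH_L", {"pyr[c]": -1.0, "nadh[c]": -1.0, "lac_L[c]": 1.0, "nad[c]": 1.0},
        rev=True, sub="Glycolysis/Gluconeogenesis", name="L-lactate dehydrogenase")
    rxn("ACCOASYN", {"pyr[c]": -1.0, "nad[c]": -1.0, "accoa[c]": 1.0, "co2[c]": 1.0,
                     "nadh[c]": 1.0},
        sub="Fatty acid synthesis", name="cytosolic acetyl-CoA supply (lumped)")

    # --- pentose phosphate pathway ----------------------------------------
    rxn("G6PDH",
        {"g6p[c]": -1.0, "nadp[c]": -2.0, "h2o[c]": -1.0,
         "ru5p_D[c]": 1.0, "nadph[c]": 2.0, "co2[c]": 1.0},
        sub="Pentose phosphate pathway", name="oxidative PPP (G6PDH, lumped)")
    rxn("PPPNOX", {"ru5p_D[c]": -1.0, "g6p[c]": 5.0 / 6.0},
        sub="Pentose phosphate pathway", name="non-oxidative PPP (lumped)")

    # --- mitochondrial pyruvate and TCA cycle ------------------------------
    rxn("PDHm", {"pyr[m]": -1.0, "nad[m]": -1.0, "accoa[m]": 1.0, "co2[m]": 1.0,
                 "nadh[m]": 1.0},
        sub="Pyruvate metabolism", name="pyruvate dehydrogenase")
    rxn("PCm", {"pyr[m]": -1.0, "co2[m]": -1.0, "atp[m]": -1.0,
                "oaa[m]": 1.0, "adp[m]": 1.0, "pi[m]": 1.0},
        sub="Pyruvate metabolism", name="pyruvate carboxylase, mitochondrial")
    rxn("CSm", {"accoa[m]": -1.0, "oaa[m]": -1.0, "h2o[m]": -1.0, "cit[m]": 1.0},
        sub="TCA cycle", name="citrate synthase")
    rxn("ICDHm", {"cit[m]": -1.0, "nad[m]": -1.0, "akg[m]": 1.0, "co2[m]": 1.0,
                  "nadh[m]": 1.0},
        sub="TCA cycle", name="aconitase + isocitrate dehydrogenase (lumped)")
    rxn("AKGD",
        {"akg[m]": -1.0, "nad[m]": -1.0, "adp[m]": -1.0, "pi[m]": -1.0,
         "succ[m]": 1.0, "co2[m]": 1.0, "nadh[m]": 1.0, "atp[m]": 1.0},
        sub="TCA cycle", name="2-oxoglutarate dehydrogenase + succinyl-CoA ligase (lumped)")
    rxn("SUCD", {"succ[m]": -1.0, "fad[m]": -1.0, "fum[m]": 1.0, "fadh2[m]": 1.0},
        sub="TCA cycle", name="succinate dehydrogenase")
    rxn("FUM", {"fum[m]": -1.0, "h2o[m]": -1.0, "mal_L[m]": 1.0}, rev=True,
        sub="TCA cycle", name="fumarase")
    rxn("MDH", {"mal_L[m]": -1.0, "nad[m]": -1.0, "oaa[m]": 1.0, "nadh[m]": 1.0},
        rev=True, sub="TCA cycle", name="malate dehydrogenase")

    # --- oxidative phosphorylation and redox ------------------------------
    rxn("NADHOR",
        {"nadh[m]": -1.0, "o2[m]": -0.5, "adp[m]": -2.5, "pi[m]": -2.5,
         "nad[m]": 1.0, "atp[m]": 2.5, "h2o[m]": 3.5},
        sub="Oxidative phosphorylation", name="NADH respiration (P/O 2.5, lumped)")
    rxn("FADH2OR",
        {"fadh2[m]": -1.0, "o2[m]": -0.5, "adp[m]": -1.5, "pi[m]": -1.5,
         "fad[m]": 1.0, "atp[m]": 1.5, "h2o[m]": 2.5},
        sub="Oxidative phosphorylation", name="FADH2 respiration (P/O 1.5, lumped)")
    # closed by default: cytosolic NADPH turnover is then set by biosynthetic
    # demand; open this valve (ub > 0) to study forced PPP flux scenarios
    rxn("NADPHOX", {"nadph[c]": -1.0, "o2[c]": -0.5, "nadp[c]": 1.0, "h2o[c]": 1.0},
        lb=0.0, ub=0.0, sub="Redox metabolism", name="NADPH oxidase (disposal valve)")

    # --- amino-acid metabolism --------------------------------------------
    rxn("GLNS", {"glu_L[c]": -1.0, "nh4[c]": -1.0, "atp[c]": -1.0,
                 "gln_L[c]": 1.0, "adp[c]": 1.0, "pi[c]": 1.0},
        sub="Glutamate metabolism", name="glutamine synthetase")
    rxn("GLUN", {"gln_L[c]": -1.0, "h2o[c]": -1.0, "glu_L[c]": 1.0, "nh4[c]": 1.0},
        sub="Glutamate metabolism", name="glutaminase")
    rxn("GLUDxm", {"glu_L[m]": -1.0, "nad[m]": -1.0, "h2o[m]": -1.0,
                   "akg[m]": 1.0, "nh4[m]": 1.0, "nadh[m]": 1.0},
        rev=True, sub="Glutamate metabolism", name="glutamate dehydrogenase (NAD, mito)")
    rxn("GLUDC", {"glu_L[c]": -1.0, "4abut[c]": 1.0, "co2[c]": 1.0},
        sub="Glutamate metabolism", name="glutamate decarboxylase (4abut synthesis)")
    rxn("ASPTA", {"asp_L[c]": -1.0, "akg[c]": -1.0, "oaa[c]": 1.0, "glu_L[c]": 1.0},
        rev=True, sub="Alanine and aspartate metabolism", name="aspartate transaminase")
    rxn("ALATA", {"pyr[c]": -1.0, "glu_L[c]": -1.0, "ala_L[c]": 1.0, "akg[c]": 1.0},
        rev=True, sub="Alanine and aspartate metabolism", name="alanine transaminase")
    rxn("ASNN", {"asn_L[c]": -1.0, "h2o[c]": -1.0, "asp_L[c]": 1.0, "nh4[c]": 1.0},
        sub="Alanine and aspartate metabolism", name="asparaginase")
    rxn("ORNTA", {"orn[c]": -1.0, "akg[c]": -1.0, "glu5sa[c]": 1.0, "glu_L[c]": 1.0},
        sub="Arginine and proline metabolism", name="ornithine transaminase")
    rxn("G5SADH", {"glu5sa[c]": -1.0, "nad[c]": -1.0, "h2o[c]": -1.0,
                   "glu_L[c]": 1.0, "nadh[c]": 1.0},
        sub="Arginine and proline metabolism",
        name="glutamate-5-semialdehyde dehydrogenase")
    rxn("ARGORN", {"arg_L[c]": -1.0, "h2o[c]": -1.0,
                   "orn[c]": 1.0, "nh4[c]": 2.0, "co2[c]": 1.0},
        sub="Arginine and proline metabolism", name="arginase + urea disposal (lumped)")
    rxn("LEUTA", {"leu_L[c]": -1.0, "akg[c]": -1.0, "4mop[c]": 1.0, "glu_L[c]": 1.0},
        rev=True, sub="Valine, leucine and isoleucine metabolism",
        name="leucine transaminase")

    # --- demands for amino acids without an explicit route here -----------
    for _, base in _AA_BASES:
        if base not in _AA_WITH_ROUTE:
            rxn(f"DM_{base}", {f"{base}[c]": -1.0}, sub="Demand",
                name=f"{base} catabolism stand-in (demand)")

    # --- maintenance, biomass, antibody -----------------------------------
    rxn("ATPM", {"atp[c]": -1.0, "h2o[c]": -1.0, "adp[c]": 1.0, "pi[c]": 1.0},
        lb=0.0, sub="Maintenance", name="non-growth ATP maintenance")

    biomass_stoich: dict[str, float] = {f"{base}[c]": -coef for base, coef in _BIOMASS_AA.items()}
    biomass_stoich.update(
        {
            "g6p[c]": -0.30,
            "ru5p_D[c]": -0.05,
            "accoa[c]": -0.25,
            "atp[c]": -30.0,
            "h2o[c]": -30.0,
            "nadph[c]": -1.0,
            "adp[c]": 30.0,
            "pi[c]": 30.0,
            "nadp[c]": 1.0,
        }
    )
    rxn("BIOMASS_cho", biomass_stoich, sub="Biomass",
        name="CHO biomass pseudo-reaction (1/h)")

    model.add_reaction(build_igg_reaction())
    rxn("EX_igg", {"igg[c]": -1.0}, lb=0.0, sub="Antibody synthesis",
        name="IgG secretion")

    model.objective = "BIOMASS_cho"
    return model
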