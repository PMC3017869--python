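"""Shipped stoichiometric fixtures.

A ~25-reaction toy central-carbon network for the glyoxylate-bypass
growth experiment: glucose uptake and glycolysis to pyruvate and
acetyl-CoA, palmitate uptake with lumped beta-oxidation to acetyl-CoA,
the TCA cycle, the glyoxylate shunt (R386 isocitrate lyase, R388 malate
synthase, tagged with their S. coelicolor genes), a lumped
ethylmalonyl-CoA module as the alternative C2-assimilation route, and a
biomass drain on oxaloacetate + ATP + NADPH. On glucose the network
grows via anaplerosis; on palmitate, carbon enters only as acetyl-CoA,
so net C4 synthesis — hence growth — requires either the glyoxylate
shunt or the ethylmalonyl-CoA module.

Also provides the full ten-row table of metabolic reactions whose genes
the CGH analysis finds absent from S. lividans, for reaction-removal
experiments against a larger network.

Genome-scale models in the same reaction-table format are supported via
`cghkit.fba.read_model`; nothing here requires one.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from cghkit.fba import Medium, MetabolicModel, make_reaction, read_model

BIOMASS_ID = "BIOMASS_SYN"

#: reaction table of the toy network (id, formula, ec, genes)
TOY_MODEL_TSV = """\
id\tformula\tec\tgenes
EX_GLC\tGLC =\t\t
EX_PALM\tPALM =\t\t
EX_O2\tO2 =\t\t
EX_CO2\tCO2 =\t\t
EX_BIOMASS\tBIOMASS =\t\t
GLYCOLYSIS\tGLC + 2 ADP + 2 NAD -> 2 PYR + 2 ATP + 2 NADH\t\t
PDH\tPYR + COA + NAD -> ACCOA + CO2 + NADH\t1.2.4.1\t
PYC\tPYR + CO2 + ATP -> OAA + ADP\t6.4.1.1\t
BETA_OX\tPALM + 8 COA + 2 ATP + 7 NAD -> 8 ACCOA + 2 ADP + 7 NADH\t\t
CS\tACCOA + OAA -> CIT + COA\t2.3.3.1\t
ACN\tCIT = ICIT\t4.2.1.3\t
ICD\tICIT + NADP -> AKG + CO2 + NADPH\t1.1.1.42\t
AKGDH\tAKG + COA + NAD -> SUCCOA + CO2 + NADH\t1.2.4.2\t
SCS\tSUCCOA + ADP -> SUCC + ATP + COA\t6.2.1.5\t
SDH\tSUCC + NAD -> FUM + NADH\t1.3.5.1\t
FUMARASE\tFUM = MAL\t4.2.1.2\t
MDH\tMAL + NAD = OAA + NADH\t1.1.1.37\t
R386\tICIT = GLX + SUCC\t4.1.3.1\tSCO0982
R388\tACCOA + GLX = COA + MAL\t2.3.3.9\tSCO0983
OXPHOS\tNADH + ADP -> NAD + ATP\t\t
THD\tNADH + NADP -> NAD + NADPH\t1.6.1.2\t
BIOMASS_SYN\tOAA + 4 ATP + 2 NADPH -> BIOMASS + 4 ADP + 2 NADP\t\t
"""

#: lumped ethylmalonyl-CoA route: net C4 from two acetyl-CoA units
ETHYLMALONYL_TSV = """\
id\tformula\tec\tgenes
EMC_LUMP\t2 ACCOA + 2 NADPH -> SUCC + 2 COA + 2 NADP\t\t
"""

#: reactions requiring gene products absent from S. lividans by CGH
TABLE1_TSV = """\
id\tformula\tec\tgenes
R60\tLACTAL + NAD = LLAC + NADH\t1.2.1.22\tSCO3486
R71\tLACTOSE = GLAC + GLC\t3.2.1.23\tSCO3479
R377\tKDPG = PYR + G3P\t4.1.2.14\tSCO3473
R394\tHYDROXYAKG = PYR + GLX\t4.1.3.16\tSCO3473
R379\tKDG + ATP = KDPG + ADP\t2.7.1.45\tSCO3494
R381\tKDG + ATP = KDPG + ADP\t2.7.1.45\tSCO3474
R386\tICIT = GLX + SUCC\t4.1.3.1\tSCO0982
R388\tACCOA + GLX = COA + MAL\t2.3.3.9\tSCO0983
R491\tHCYS + MTHPTGLU = THPTGLU + MET\t2.1.1.14\tSCO0985
R576\tOTHIOxt + NADPH = RTHIO + NAD\t1.8.1.9\tSCO6834
"""

#: the nine metabolic genes called absent from S. lividans 66 by CGH
CGH_ABSENT_METABOLIC_GENES = frozenset({
    "SCO3486", "SCO3479", "SCO3473", "SCO3494", "SCO3474",
    "SCO0982", "SCO0983", "SCO0985", "SCO6834",
})


def _reactions_from_tsv(tsv: str) -> list:
    table = pd.read_csv(StringIO(tsv), sep="\t", dtype=str).fillna("")
    return [make_reaction(row.id, row.formula, ec=row.ec,
                          genes=[g for g in row.genes.split(";") if g])
            for row in table.itertuples()]


def toy_model(with_ethylmalonyl: bool = False) -> MetabolicModel:
    """The shipped central-carbon toy network (optionally with the
    ethylmalonyl-CoA module added)."""
    reactions = _reactions_from_tsv(TOY_MODEL_TSV)
    if with_ethylmalonyl:
        reactions += _reactions_from_tsv(ETHYLMALONYL_TSV)
    return MetabolicModel(reactions, BIOMASS_ID)


def table1_reactions() -> list:
    """The ten removable reactions with their absent-gene associations."""
    return _reactions_from_tsv(TABLE1_TSV)


def glucose_minimal_medium(uptake: float = 10.0) -> Medium:
    return Medium({"EX_GLC": uptake, "EX_O2": 1000.0, "EX_CO2": 1000.0})


def palmitate_minimal_medium(uptake: float = 2.0) -> Medium:
    return Medium({"EX_PALM": uptake, "EX_O2": 1000.0, "EX_CO2": 1000.0})


def empty_medium() -> Medium:
    """No carbon source; oxygen and CO2 exchange only."""
    return Medium({"EX_O2": 1000.0, "EX_CO2": 1000.0})
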