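"""Generators for every input the pipeline needs.

Three families of synthetic objects are produced here:

1. :func:`make_textbook_respiration_network` — a lumped aerobic-respiration
   network whose stoichiometry realises the classical textbook ATP yield
   (36 ATP per glucose: 2 glycolytic + 2 TCA substrate-level + 32 oxidative
   phosphorylation, with 6 CO2 per glucose aerobically and none
   anaerobically).  It is the deterministic yield oracle for the LP stack.

2. :func:`make_brain_toy_network` — a small (<200 reactions) brain-cortex-like
   network: glycolysis, an individual-reaction TCA cycle, electron transport
   chain complexes I–V around a proton-motive pseudo-metabolite, the
   glutamine–glutamate–GABA cycle, glutathione redox (GPx/GSR, SOD, CAT),
   a linear sphingolipid chain ending in sphingomyelin, glucosylceramide and
   sphingosine-1-phosphate, a PLA2-style lipid cleavage feeding eicosanoids,
   and exchange reactions for every marker metabolite in the packaged panel.
   Every enzymatic and transport reaction carries a synthetic gene rule.

3. :func:`simulate_expression` — bimodal log2-scale expression (two-Gaussian
   mixture, component fixed per gene) with group-specific shifts for selected
   genes, plus the analytic ground truth (mixture density minimum, implanted
   effects) used as parameter-recovery oracle.

Stoichiometric coefficients follow classical textbook values; where the
biology leaves cofactor choices open (sphingolipid chain, eicosanoid
synthesis) coefficients are chosen minimal and mass-consistent — the
quantitative surface of these networks is yields and flux directions, not
kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .model_core import GeneRule, MetabolicModel, Metabolite, Reaction, assert_valid

__all__ = [
    "ExpressionProfile",
    "GroundTruth",
    "DegenerateMixtureError",
    "make_textbook_respiration_network",
    "make_brain_toy_network",
    "simulate_expression",
    "make_two_group_scenario",
    "mixture_density_minimum",
    "default_marker_panel",
    "DEFAULT_MIXTURE",
]

#: Default two-component log2-expression mixture: modes well separated
#: (>4 sd) so the inter-mode density minimum is well defined, mimicking the
#: bimodal shape of quantile-normalized microarray expression.
DEFAULT_MIXTURE = {
    "low_mean": 6.0,
    "high_mean": 11.0,
    "low_sd": 0.8,
    "high_sd": 0.8,
    "weight": 0.5,  # weight of the low component
}


class DegenerateMixtureError(ValueError):
    """The two mixture modes overlap so much that no density minimum exists."""


@dataclass
class ExpressionProfile:
    """Log2 expression values (genes × samples) with group and age metadata."""

    values: pd.DataFrame
    group: pd.Series  # sample id -> {"ASD", "control"}
    age: pd.Series  # sample id -> years

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression profile contains missing values")
        counts = self.group.value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError("need at least 2 samples per group")


@dataclass
class GroundTruth:
    """What the generator implanted, for parameter-recovery tests."""

    threshold_true: float
    shifted_genes: dict[str, float] = field(default_factory=dict)
    marker_effects: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Network builders
# ---------------------------------------------------------------------------


def _met(mid: str, comp: str, name: str = "") -> Metabolite:
    return Metabolite(id=mid, name=name or mid, compartment=comp)


def _rxn(rid, stoich, lb=0.0, ub=1000.0, subsystem="", gene="", name=""):
    return Reaction(id=rid, name=name or rid, stoich=dict(stoich), lb=lb, ub=ub,
                    subsystem=subsystem, gene_rule=GeneRule(gene))


def make_textbook_respiration_network() -> MetabolicModel:
    """Lumped glucose respiration with the classical 36-ATP yield.

    Glycolysis nets 2 ATP + 2 cytosolic NADH per glucose; the cytosolic NADH
    enters the chain at the 2-ATP-equivalent (FADH2) level via a lumped
    shuttle; pyruvate dehydrogenase and a lumped per-acetyl-CoA TCA produce
    1 ATP-equivalent, 3 mitochondrial NADH, 1 FADH2 and 2 CO2; the chain
    oxidations pay 3 ATP per NADH and 2 per FADH2.  Maximizing the ATP
    demand with glucose uptake fixed at 1 and oxygen unbounded therefore
    yields 36 = 2 + 2 + 32, secreting 6 CO2; with oxygen uptake forced to
    zero only glycolysis + lactate fermentation runs (2 ATP, 0 CO2).
    """
    mets = [
        _met("glc_e", "e"), _met("o2_e", "e"), _met("co2_e", "e"),
        _met("lac_e", "e"), _met("h2o_e", "e"), _met("pi_e", "e"),
        _met("glc_c", "c"), _met("pyr_c", "c"), _met("lac_c", "c"),
        _met("atp_c", "c"), _met("adp_c", "c"), _met("pi_c", "c"),
        _met("nad_c", "c"), _met("nadh_c", "c"), _met("h2o_c", "c"),
        _met("co2_c", "c"), _met("o2_c", "c"),
        _met("accoa_m", "m"), _met("coa_m", "m"), _met("nad_m", "m"),
        _met("nadh_m", "m"), _met("fad_m", "m"), _met("fadh2_m", "m"),
    ]
    rxns = [
        _rxn("EX_glc", {"glc_e": -1}, lb=-10, subsystem="exchange"),
        _rxn("EX_o2", {"o2_e": -1}, lb=-1000, subsystem="exchange"),
        _rxn("EX_co2", {"co2_e": -1}, lb=0, subsystem="exchange"),
        _rxn("EX_lac", {"lac_e": -1}, lb=0, subsystem="exchange"),
        _rxn("EX_h2o", {"h2o_e": -1}, lb=-1000, subsystem="exchange"),
        _rxn("EX_pi", {"pi_e": -1}, lb=-1000, subsystem="exchange"),
        _rxn("GLCt", {"glc_e": -1, "glc_c": 1}, subsystem="transport", gene="G_GLCT"),
        _rxn("O2t", {"o2_e": -1, "o2_c": 1}, subsystem="transport", gene="G_O2T"),
        _rxn("CO2t", {"co2_c": -1, "co2_e": 1}, subsystem="transport", gene="G_CO2T"),
        _rxn("LACt", {"lac_c": -1, "lac_e": 1}, lb=-1000, subsystem="transport", gene="G_LACT"),
        _rxn("H2Ot", {"h2o_c": -1, "h2o_e": 1}, lb=-1000, subsystem="transport", gene="G_H2OT"),
        _rxn("PIt", {"pi_e": -1, "pi_c": 1}, lb=-1000, subsystem="transport", gene="G_PIT"),
        _rxn("GLYC",
             {"glc_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
              "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h2o_c": 2},
             subsystem="glycolysis", gene="G_GLYC"),
        _rxn("LDH", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1},
             lb=-1000, subsystem="glycolysis", gene="G_LDH"),
        _rxn("SHUTTLE", {"nadh_c": -1, "fad_m": -1, "nad_c": 1, "fadh2_m": 1},
             subsystem="oxidative phosphorylation", gene="G_SHUT"),
        _rxn("PDH",
             {"pyr_c": -1, "coa_m": -1, "nad_m": -1,
              "accoa_m": 1, "co2_c": 1, "nadh_m": 1},
             subsystem="TCA", gene="G_PDH"),
        _rxn("TCA",
             {"accoa_m": -1, "nad_m": -3, "fad_m": -1, "adp_c": -1, "pi_c": -1,
              "h2o_c": -2, "coa_m": 1, "co2_c": 2, "nadh_m": 3, "fadh2_m": 1,
              "atp_c": 1},
             subsystem="TCA", gene="G_TCA"),
        _rxn("ETC_NADH",
             {"nadh_m": -1, "o2_c": -0.5, "adp_c": -3, "pi_c": -3,
              "nad_m": 1, "atp_c": 3, "h2o_c": 4},
             subsystem="oxidative phosphorylation", gene="G_ETCN"),
        _rxn("ETC_FADH2",
             {"fadh2_m": -1, "o2_c": -0.5, "adp_c": -2, "pi_c": -2,
              "fad_m": 1, "atp_c": 2, "h2o_c": 3},
             subsystem="oxidative phosphorylation", gene="G_ETCF"),
        _rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
             subsystem="maintenance"),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           id="textbook_respiration")
    return assert_valid(model)


#: Exchange ids whose secretion flux defines the marker metabolites.
_MARKER_EXCHANGES = {
    "pyruvate": "EX_pyr", "lactate": "EX_lac", "ammonia": "EX_nh4",
    "choline": "EX_chol", "acetylcholine": "EX_ach", "inositol": "EX_inos",
    "DHA": "EX_dha", "EPA": "EX_epa", "PGE1": "EX_pge1", "PGE2": "EX_pge2",
    "leukotriene": "EX_ltb4", "carnitine": "EX_carn", "S1P": "EX_s1p",
    "ceramide": "EX_cer", "glucosylceramide": "EX_glccer",
}

#: Gln–Glu–GABA cycle (the models' objective and default protected core).
GLN_GLU_GABA_REACTIONS = ("GLS", "GLNS", "GAD")

#: Sphingolipid chain + its dedicated transport genes (the implant target of
#: the two-group scenario).
SPHINGOLIPID_REACTIONS = (
    "FACOAL160", "FACOAL", "SPT", "KDSR", "CERS", "DEGS", "SMS", "UGCG",
    "UDPGS", "CDASE", "SPHK", "S1Pt", "CERt", "GLCCERt", "SMt",
    "SERt", "PALMt", "FAt",
)


def make_brain_toy_network() -> MetabolicModel:
    """Brain-cortex-like toy network covering all packaged marker pathways.

    Extends the respiration fixture with an individual-reaction TCA cycle,
    electron transport complexes I–V coupled through a proton-motive
    pseudo-metabolite (4 charges pumped by complexes I and III, 2 by IV,
    4 consumed per ATP by complex V), the glutamine–glutamate–GABA cycle
    with pyruvate-carboxylase anaplerosis, transaminases (ALT/AST),
    glutathione redox, ROS handling (SOD/CAT), choline/acetylcholine and
    inositol synthesis, PLA2-driven eicosanoid release (PGE1/PGE2/
    leukotriene, DHA/EPA), carnitine transport, and the de-novo sphingolipid
    chain (serine + palmitoyl-CoA → ... → ceramide → {sphingomyelin,
    glucosylceramide, sphingosine → S1P}).
    """
    met_ids = [
        # extracellular
        "glc_e", "o2_e", "co2_e", "lac_e", "h2o_e", "pi_e", "pyr_e", "nh4_e",
        "gln_e", "glu_e", "gaba_e", "ala_e", "asp_e", "chol_e", "ach_e",
        "inos_e", "pl_e", "lyso_e", "dha_e", "epa_e", "ara_e", "dgla_e",
        "pge1_e", "pge2_e", "ltb4_e", "carn_e", "ser_e", "palm_e", "fa_e",
        "s1p_e", "cer_e", "glccer_e", "sm_e",
        # cytosol
        "glc_c", "pyr_c", "lac_c", "atp_c", "adp_c", "pi_c", "nad_c",
        "nadh_c", "nadp_c", "nadph_c", "h2o_c", "co2_c", "o2_c", "cit_c",
        "oaa_c", "mal_c", "accoa_c", "coa_c", "akg_c", "glu_c", "gln_c",
        "gaba_c", "nh4_c", "ala_c", "asp_c", "gsh_c", "gssg_c", "h2o2_c",
        "chol_c", "cholp_c", "ach_c", "inos_c", "pl_c", "lyso_c", "ara_c",
        "dha_c", "epa_c", "dgla_c", "pge1_c", "pge2_c", "ltb4_c", "carn_c",
        "ser_c", "palm_c", "palmcoa_c", "fa_c", "facoa_c", "kdhsph_c",
        "dhsph_c", "dhcer_c", "cer_c", "sph_c", "s1p_c", "sm_c", "udpglc_c",
        "udp_c", "glccer_c",
        # mitochondria
        "accoa_m", "coa_m", "nad_m", "nadh_m", "nadp_m", "nadph_m", "oaa_m",
        "cit_m", "acon_m", "icit_m", "akg_m", "succoa_m", "succ_m", "fum_m",
        "mal_m", "q_m", "qh2_m", "cytcox_m", "cytcred_m", "hx_m", "co2_m",
        "h2o_m", "o2s_m", "h2o2_m", "gsh_m", "gssg_m",
    ]
    mets = [_met(mid, mid.rsplit("_", 1)[1]) for mid in met_ids]

    free_nutrients = {  # exchange id -> uptake allowance (lb)
        "EX_glc": -10, "EX_o2": -1000, "EX_h2o": -1000, "EX_pi": -1000,
        "EX_lac": -1, "EX_nh4": -1, "EX_gln": -1, "EX_chol": -1, "EX_pl": -1,
        "EX_dgla": -1, "EX_carn": -1, "EX_ser": -1, "EX_palm": -1, "EX_fa": -1,
    }
    secretion_only = [
        "EX_co2", "EX_pyr", "EX_glu", "EX_gaba", "EX_ala", "EX_asp",
        "EX_ach", "EX_inos", "EX_lyso", "EX_dha", "EX_epa", "EX_ara",
        "EX_pge1", "EX_pge2", "EX_ltb4", "EX_s1p", "EX_cer", "EX_glccer",
        "EX_sm",
    ]
    ex_met = {
        "EX_glc": "glc_e", "EX_o2": "o2_e", "EX_co2": "co2_e",
        "EX_lac": "lac_e", "EX_h2o": "h2o_e", "EX_pi": "pi_e",
        "EX_pyr": "pyr_e", "EX_nh4": "nh4_e", "EX_gln": "gln_e",
        "EX_glu": "glu_e", "EX_gaba": "gaba_e", "EX_ala": "ala_e",
        "EX_asp": "asp_e", "EX_chol": "chol_e", "EX_ach": "ach_e",
        "EX_inos": "inos_e", "EX_pl": "pl_e", "EX_lyso": "lyso_e",
        "EX_dha": "dha_e", "EX_epa": "epa_e", "EX_ara": "ara_e",
        "EX_dgla": "dgla_e", "EX_pge1": "pge1_e", "EX_pge2": "pge2_e",
        "EX_ltb4": "ltb4_e", "EX_carn": "carn_e", "EX_ser": "ser_e",
        "EX_palm": "palm_e", "EX_fa": "fa_e", "EX_s1p": "s1p_e",
        "EX_cer": "cer_e", "EX_glccer": "glccer_e", "EX_sm": "sm_e",
    }
    rxns: list[Reaction] = []
    for ex_id, met in ex_met.items():
        lb = free_nutrients.get(ex_id, 0.0)
        rxns.append(_rxn(ex_id, {met: -1}, lb=lb, subsystem="exchange"))

    T = "transport"
    rxns += [
        _rxn("GLCt", {"glc_e": -1, "glc_c": 1}, subsystem=T, gene="G_SLC2A1"),
        _rxn("O2t", {"o2_e": -1, "o2_c": 1}, lb=-1000, subsystem=T, gene="G_O2T"),
        _rxn("CO2t", {"co2_c": -1, "co2_e": 1}, lb=-1000, subsystem=T, gene="G_CO2T"),
        _rxn("CO2tm", {"co2_m": -1, "co2_c": 1}, lb=-1000, subsystem=T, gene="G_CO2TM"),
        _rxn("LACt", {"lac_c": -1, "lac_e": 1}, lb=-1000, subsystem=T, gene="G_MCT1"),
        _rxn("PYRt", {"pyr_c": -1, "pyr_e": 1}, subsystem=T, gene="G_MCT2"),
        _rxn("H2Ot", {"h2o_c": -1, "h2o_e": 1}, lb=-1000, subsystem=T, gene="G_AQP4"),
        _rxn("H2Otm", {"h2o_c": -1, "h2o_m": 1}, lb=-1000, subsystem=T, gene="G_H2OTM"),
        _rxn("PIt", {"pi_e": -1, "pi_c": 1}, lb=-1000, subsystem=T, gene="G_PIT"),
        _rxn("NH4t", {"nh4_c": -1, "nh4_e": 1}, lb=-1000, subsystem=T, gene="G_RHCG"),
        _rxn("GLNt", {"gln_e": -1, "gln_c": 1}, lb=-1000, subsystem=T, gene="G_SLC38A1"),
        _rxn("GLUt", {"glu_c": -1, "glu_e": 1}, subsystem=T, gene="G_SLC1A2"),
        _rxn("GABAt", {"gaba_c": -1, "gaba_e": 1}, subsystem=T, gene="G_SLC6A1"),
        _rxn("ALAt", {"ala_c": -1, "ala_e": 1}, subsystem=T, gene="G_ALAT"),
        _rxn("ASPt", {"asp_c": -1, "asp_e": 1}, subsystem=T, gene="G_ASPT"),
        _rxn("CHOLt", {"chol_e": -1, "chol_c": 1}, lb=-1000, subsystem=T, gene="G_CTL1"),
        _rxn("ACHt", {"ach_c": -1, "ach_e": 1}, subsystem=T, gene="G_ACHT"),
        _rxn("INOSt", {"inos_c": -1, "inos_e": 1}, lb=-1000, subsystem=T, gene="G_SMIT1"),
        _rxn("PLt", {"pl_e": -1, "pl_c": 1}, subsystem=T, gene="G_PLT"),
        _rxn("LYSOt", {"lyso_c": -1, "lyso_e": 1}, subsystem=T, gene="G_LYSOT"),
        _rxn("DHAt", {"dha_c": -1, "dha_e": 1}, lb=-1000, subsystem=T, gene="G_MFSD2A"),
        _rxn("EPAt", {"epa_c": -1, "epa_e": 1}, lb=-1000, subsystem=T, gene="G_EPAT"),
        _rxn("ARAt", {"ara_c": -1, "ara_e": 1}, subsystem=T, gene="G_ARAT"),
        _rxn("DGLAt", {"dgla_e": -1, "dgla_c": 1}, subsystem=T, gene="G_DGLAT"),
        _rxn("PGE1t", {"pge1_c": -1, "pge1_e": 1}, subsystem=T, gene="G_PGT1"),
        _rxn("PGE2t", {"pge2_c": -1, "pge2_e": 1}, subsystem=T, gene="G_PGT2"),
        _rxn("LTB4t", {"ltb4_c": -1, "ltb4_e": 1}, subsystem=T, gene="G_LTB4T"),
        _rxn("CARNt", {"carn_e": -1, "carn_c": 1}, lb=-1000, subsystem=T, gene="G_OCTN2"),
        _rxn("SERt", {"ser_e": -1, "ser_c": 1}, subsystem=T, gene="G_SERT"),
        _rxn("PALMt", {"palm_e": -1, "palm_c": 1}, subsystem=T, gene="G_CD36"),
        _rxn("FAt", {"fa_e": -1, "fa_c": 1}, lb=-1000, subsystem=T, gene="G_FATP"),
        _rxn("S1Pt", {"s1p_c": -1, "s1p_e": 1}, subsystem=T, gene="G_SPNS2"),
        _rxn("CERt", {"cer_c": -1, "cer_e": 1}, subsystem=T, gene="G_CERT"),
        _rxn("GLCCERt", {"glccer_c": -1, "glccer_e": 1}, subsystem=T, gene="G_GLCCERT"),
        _rxn("SMt", {"sm_c": -1, "sm_e": 1}, subsystem=T, gene="G_SMT"),
        _rxn("CITtm", {"cit_m": -1, "cit_c": 1}, subsystem=T, gene="G_SLC25A1"),
        _rxn("MALtm", {"mal_c": -1, "mal_m": 1}, subsystem=T, gene="G_SLC25A11"),
        _rxn("AKGtm", {"akg_m": -1, "akg_c": 1}, lb=-1000, subsystem=T, gene="G_SLC25A10"),
        _rxn("H2O2tm", {"h2o2_m": -1, "h2o2_c": 1}, lb=-1000, subsystem=T, gene="G_H2O2TM"),
    ]

    GLY = "glycolysis"
    TCA = "TCA"
    OXP = "oxidative phosphorylation"
    rxns += [
        _rxn("GLYC",
             {"glc_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
              "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h2o_c": 2},
             subsystem=GLY, gene="G_HK1 AND G_PFKM AND G_PKM"),
        _rxn("LDH", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1},
             lb=-1000, subsystem=GLY, gene="G_LDHA OR G_LDHB"),
        _rxn("SHUTTLE", {"nadh_c": -1, "q_m": -1, "nad_c": 1, "qh2_m": 1},
             subsystem=OXP, gene="G_GPD2"),
        _rxn("PDH",
             {"pyr_c": -1, "coa_m": -1, "nad_m": -1,
              "accoa_m": 1, "co2_m": 1, "nadh_m": 1},
             subsystem=TCA, gene="G_PDHA1 AND G_PDHB"),
        _rxn("PC", {"pyr_c": -1, "co2_c": -1, "atp_c": -1,
                    "oaa_c": 1, "adp_c": 1, "pi_c": 1},
             subsystem=TCA, gene="G_PCX"),
        _rxn("CS", {"accoa_m": -1, "oaa_m": -1, "h2o_m": -1,
                    "cit_m": 1, "coa_m": 1},
             subsystem=TCA, gene="G_CS"),
        _rxn("ACONTA", {"cit_m": -1, "acon_m": 1, "h2o_m": 1},
             lb=-1000, subsystem=TCA, gene="G_ACO2"),
        _rxn("ACONTB", {"acon_m": -1, "h2o_m": -1, "icit_m": 1},
             lb=-1000, subsystem=TCA, gene="G_ACO2"),
        _rxn("IDH", {"icit_m": -1, "nad_m": -1,
                     "akg_m": 1, "co2_m": 1, "nadh_m": 1},
             subsystem=TCA, gene="G_IDH3A AND G_IDH3B"),
        _rxn("AKGDH", {"akg_m": -1, "coa_m": -1, "nad_m": -1,
                       "succoa_m": 1, "co2_m": 1, "nadh_m": 1},
             subsystem=TCA, gene="G_OGDH"),
        _rxn("SUCOAS", {"succoa_m": -1, "adp_c": -1, "pi_c": -1,
                        "succ_m": 1, "coa_m": 1, "atp_c": 1},
             subsystem=TCA, gene="G_SUCLA2"),
        _rxn("FUMARASE", {"fum_m": -1, "h2o_m": -1, "mal_m": 1},
             lb=-1000, subsystem=TCA, gene="G_FH"),
        _rxn("MDH", {"mal_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1},
             lb=-1000, subsystem=TCA, gene="G_MDH2"),
        # electron transport chain, complexes I-V
        _rxn("ETC1", {"nadh_m": -1, "q_m": -1, "nad_m": 1, "qh2_m": 1, "hx_m": 4},
             subsystem=OXP, gene="G_NDUFS1 AND G_NDUFV1"),
        _rxn("ETC2", {"succ_m": -1, "q_m": -1, "fum_m": 1, "qh2_m": 1},
             subsystem=OXP, gene="G_SDHA AND G_SDHB"),
        _rxn("ETC3", {"qh2_m": -1, "cytcox_m": -2,
                      "q_m": 1, "cytcred_m": 2, "hx_m": 4},
             subsystem=OXP, gene="G_UQCRC1 AND G_UQCRC2"),
        _rxn("ETC4", {"cytcred_m": -2, "o2_c": -0.5,
                      "cytcox_m": 2, "h2o_m": 1, "hx_m": 2},
             subsystem=OXP, gene="G_COX4I1 AND G_COX5A"),
        _rxn("ETC5", {"adp_c": -1, "pi_c": -1, "hx_m": -4,
                      "atp_c": 1, "h2o_m": 1},
             subsystem=OXP, gene="G_ATP5F1A AND G_ATP5F1B"),
        _rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
             subsystem="maintenance"),
    ]

    GGG = "glutamine-glutamate-GABA cycle"
    rxns += [
        _rxn("GLS", {"gln_c": -1, "h2o_c": -1, "glu_c": 1, "nh4_c": 1},
             subsystem=GGG, gene="G_GLS"),
        _rxn("GLNS", {"glu_c": -1, "nh4_c": -1, "atp_c": -1,
                      "gln_c": 1, "adp_c": 1, "pi_c": 1},
             subsystem=GGG, gene="G_GLUL"),
        _rxn("GAD", {"glu_c": -1, "gaba_c": 1, "co2_c": 1},
             subsystem=GGG, gene="G_GAD1 OR G_GAD2"),
        _rxn("GDH", {"akg_c": -1, "nh4_c": -1, "nadh_c": -1,
                     "glu_c": 1, "nad_c": 1, "h2o_c": 1},
             lb=-1000, subsystem=GGG, gene="G_GLUD1"),
    ]

    AA = "amino acid metabolism"
    rxns += [
        _rxn("ALT", {"pyr_c": -1, "glu_c": -1, "ala_c": 1, "akg_c": 1},
             lb=-1000, subsystem=AA, gene="G_GPT"),
        _rxn("AST", {"oaa_c": -1, "glu_c": -1, "asp_c": 1, "akg_c": 1},
             lb=-1000, subsystem=AA, gene="G_GOT1 OR G_GOT2"),
        _rxn("ACL", {"cit_c": -1, "atp_c": -1, "coa_c": -1,
                     "accoa_c": 1, "oaa_c": 1, "adp_c": 1, "pi_c": 1},
             subsystem=AA, gene="G_ACLY"),
        _rxn("MDHc", {"oaa_c": -1, "nadh_c": -1, "mal_c": 1, "nad_c": 1},
             subsystem=AA, gene="G_MDH1"),
    ]

    REDOX = "glutathione redox"
    rxns += [
        _rxn("ROSGEN", {"nadh_m": -1, "o2_c": -2, "nad_m": 1, "o2s_m": 2},
             subsystem=REDOX, gene="G_ROSLEAK"),
        _rxn("SOD", {"o2s_m": -2, "h2o2_m": 1, "o2_c": 1},
             subsystem=REDOX, gene="G_SOD1 OR G_SOD2"),
        _rxn("CAT", {"h2o2_c": -2, "h2o_c": 2, "o2_c": 1},
             subsystem=REDOX, gene="G_CAT"),
        _rxn("GPXc", {"gsh_c": -2, "h2o2_c": -1, "gssg_c": 1, "h2o_c": 2},
             subsystem=REDOX, gene="G_GPX1 OR G_GPX4"),
        _rxn("GPXm", {"gsh_m": -2, "h2o2_m": -1, "gssg_m": 1, "h2o_m": 2},
             subsystem=REDOX, gene="G_GPX1 OR G_GPX4"),
        _rxn("GSRc", {"gssg_c": -1, "nadph_c": -1, "gsh_c": 2, "nadp_c": 1},
             subsystem=REDOX, gene="G_GSR"),
        _rxn("GSRm", {"gssg_m": -1, "nadph_m": -1, "gsh_m": 2, "nadp_m": 1},
             subsystem=REDOX, gene="G_GSR"),
        _rxn("THDc", {"nadh_c": -1, "nadp_c": -1, "nad_c": 1, "nadph_c": 1},
             subsystem=REDOX, gene="G_NNTC"),
        _rxn("THDm", {"nadh_m": -1, "nadp_m": -1, "nad_m": 1, "nadph_m": 1},
             subsystem=REDOX, gene="G_NNT"),
    ]

    INFL = "neuroinflammation"
    rxns += [
        _rxn("CHK", {"chol_c": -1, "atp_c": -1, "cholp_c": 1, "adp_c": 1},
             subsystem=INFL, gene="G_CHKA"),
        _rxn("CHAT", {"chol_c": -1, "accoa_c": -1, "ach_c": 1, "coa_c": 1},
             subsystem=INFL, gene="G_CHAT"),
        _rxn("INOSYN", {"glc_c": -1, "atp_c": -1,
                        "inos_c": 1, "adp_c": 1, "pi_c": 1},
             subsystem=INFL, gene="G_ISYNA1"),
        _rxn("PLA2", {"pl_c": -1, "h2o_c": -1, "lyso_c": 1,
                      "ara_c": 0.6, "dha_c": 0.2, "epa_c": 0.2},
             subsystem=INFL, gene="G_PLA2G4A OR G_PLA2G6"),
        _rxn("COX1", {"dgla_c": -1, "o2_c": -2, "pge1_c": 1},
             subsystem=INFL, gene="G_PTGS1"),
        _rxn("COX2", {"ara_c": -1, "o2_c": -2, "pge2_c": 1},
             subsystem=INFL, gene="G_PTGS2"),
        _rxn("LOX", {"ara_c": -1, "o2_c": -1, "ltb4_c": 1},
             subsystem=INFL, gene="G_ALOX5"),
    ]

    SPH = "sphingolipid metabolism"
    rxns += [
        _rxn("FACOAL160", {"palm_c": -1, "coa_c": -1, "atp_c": -1,
                           "palmcoa_c": 1, "adp_c": 1, "pi_c": 1},
             subsystem=SPH, gene="G_ACSL1"),
        _rxn("FACOAL", {"fa_c": -1, "coa_c": -1, "atp_c": -1,
                        "facoa_c": 1, "adp_c": 1, "pi_c": 1},
             subsystem=SPH, gene="G_ACSL3"),
        _rxn("SPT", {"ser_c": -1, "palmcoa_c": -1,
                     "kdhsph_c": 1, "coa_c": 1, "co2_c": 1},
             subsystem=SPH, gene="G_SPTLC1 AND G_SPTLC2"),
        _rxn("KDSR", {"kdhsph_c": -1, "nadph_c": -1, "dhsph_c": 1, "nadp_c": 1},
             subsystem=SPH, gene="G_KDSR"),
        _rxn("CERS", {"dhsph_c": -1, "facoa_c": -1, "dhcer_c": 1, "coa_c": 1},
             subsystem=SPH, gene="G_CERS1 OR G_CERS2"),
        _rxn("DEGS", {"dhcer_c": -1, "nadph_c": -1, "o2_c": -1,
                      "cer_c": 1, "nadp_c": 1, "h2o_c": 2},
             subsystem=SPH, gene="G_DEGS1"),
        _rxn("SMS", {"cer_c": -1, "cholp_c": -1, "sm_c": 1},
             subsystem=SPH, gene="G_SGMS1"),
        _rxn("UDPGS", {"glc_c": -1, "atp_c": -1, "udp_c": -1,
                       "udpglc_c": 1, "adp_c": 1, "pi_c": 1},
             subsystem=SPH, gene="G_UGP2"),
        _rxn("UGCG", {"cer_c": -1, "udpglc_c": -1, "glccer_c": 1, "udp_c": 1},
             subsystem=SPH, gene="G_UGCG"),
        _rxn("CDASE", {"cer_c": -1, "h2o_c": -1, "sph_c": 1, "fa_c": 1},
             subsystem=SPH, gene="G_ASAH1"),
        _rxn("SPHK", {"sph_c": -1, "atp_c": -1, "s1p_c": 1, "adp_c": 1},
             subsystem=SPH, gene="G_SPHK1 OR G_SPHK2"),
    ]

    model = MetabolicModel(metabolites=mets, reactions=rxns, id="brain_toy",
                           annotations={"description": "synthetic brain cortex toy network"})
    return assert_valid(model)


def default_marker_panel() -> list[dict]:
    """The packaged marker panel, one entry per biomarker readout.

    Metabolite markers are secretion fluxes of their exchange reaction;
    enzyme markers are the summed net flux of the enzyme's reactions across
    compartments; the respiration ratio is CO2 secretion per unit glucose
    uptake magnitude.
    """
    panel: list[dict] = []
    energy = [
        ("glycolysis", ["GLYC"]), ("CS", ["CS"]), ("PDH", ["PDH"]),
        ("ETC_I", ["ETC1"]), ("ETC_II", ["ETC2"]), ("ETC_III", ["ETC3"]),
        ("ETC_IV", ["ETC4"]), ("ETC_V", ["ETC5"]),
    ]
    for mid, rxns in energy:
        panel.append({"id": mid, "category": "energy",
                      "type": "enzyme_sum", "reactions": rxns})
    for mid in ("ammonia", "lactate", "pyruvate"):
        panel.append({"id": mid, "category": "oxidative_stress",
                      "type": "secretion", "reactions": [_MARKER_EXCHANGES[mid]]})
    panel.append({"id": "co2_per_glucose", "category": "oxidative_stress",
                  "type": "ratio", "numerator": "EX_co2", "denominator": "EX_glc"})
    mito = [
        ("ALT", ["ALT"]), ("AST", ["AST"]), ("GSR", ["GSRc", "GSRm"]),
        ("GPx", ["GPXc", "GPXm"]), ("SOD", ["SOD"]), ("CAT", ["CAT"]),
    ]
    for mid, rxns in mito:
        panel.append({"id": mid, "category": "mitochondrial_dysfunction",
                      "type": "enzyme_sum", "reactions": rxns})
    for mid in ("leukotriene", "PGE2", "PGE1", "DHA", "EPA", "inositol",
                "choline", "acetylcholine", "carnitine"):
        panel.append({"id": mid, "category": "neuroinflammation",
                      "type": "secretion", "reactions": [_MARKER_EXCHANGES[mid]]})
    panel.append({"id": "PLA2", "category": "neuroinflammation",
                  "type": "enzyme_sum", "reactions": ["PLA2"]})
    for mid in ("S1P", "ceramide", "glucosylceramide"):
        panel.append({"id": mid, "category": "sphingolipid",
                      "type": "secretion", "reactions": [_MARKER_EXCHANGES[mid]]})
    return panel


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def mixture_density_minimum(mixture: dict) -> float:
    """Analytic local minimum of the two-Gaussian mixture density between
    the two modes (1-D root finding on the density derivative).

    Raises :class:`DegenerateMixtureError` when the mixture is effectively
    unimodal (no interior minimum between the component means).
    """
    mu1, mu2 = mixture["low_mean"], mixture["high_mean"]
    s1, s2 = mixture["low_sd"], mixture["high_sd"]
    w = mixture["weight"]
    if not mu1 < mu2:
        raise ValueError("low_mean must be below high_mean")

    def dpdf(x):
        return (-w * (x - mu1) / s1**2 * norm.pdf(x, mu1, s1)
                - (1 - w) * (x - mu2) / s2**2 * norm.pdf(x, mu2, s2))

    grid = np.linspace(mu1, mu2, 2001)[1:-1]
    vals = dpdf(grid)
    crossings = np.where((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if len(crossings) == 0:
        raise DegenerateMixtureError(
            "mixture has no interior density minimum (modes overlap)")
    i = crossings[0]
    return float(brentq(dpdf, grid[i], grid[i + 1]))


def simulate_expression(
    n_genes: int,
    n_per_group: int,
    mixture: dict | None = None,
    effects: dict[str, float] | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    baselines: dict[str, float] | None = None,
    child_fraction: float = 0.75,
) -> tuple[ExpressionProfile, GroundTruth]:
    """Simulate a two-group bimodal log2 expression table.

    Each gene is assigned to the low or high mixture component (probability
    ``weight`` for low); its per-sample values are then drawn i.i.d. from
    that component, so the pooled value distribution is exactly the stated
    mixture and the analytic density minimum is the ground-truth threshold.
    Genes named in *effects* are shifted by the given log2 amount in the ASD
    group only; *baselines* pins selected genes' component means (scenario
    plumbing).  A ``child_fraction`` of samples per group receives ages in
    the 2–14 y range, the rest 15–56 y, to exercise age filtering.
    """
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    mixture = dict(DEFAULT_MIXTURE, **(mixture or {}))
    effects = effects or {}
    baselines = baselines or {}
    threshold_true = mixture_density_minimum(mixture)

    rng = np.random.default_rng(seed)
    genes = gene_ids if gene_ids is not None else [f"g{i:04d}" for i in range(n_genes)]
    if len(genes) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    unknown = set(effects) - set(genes)
    if unknown:
        raise ValueError(f"effects name genes outside the gene set: {sorted(unknown)}")

    low = rng.random(n_genes) < mixture["weight"]
    means = np.where(low, mixture["low_mean"], mixture["high_mean"]).astype(float)
    sds = np.where(low, mixture["low_sd"], mixture["high_sd"]).astype(float)
    for g, b in baselines.items():
        i = genes.index(g)
        means[i] = b
        sds[i] = mixture["low_sd"]

    samples = [f"ASD_{i:02d}" for i in range(n_per_group)] + \
              [f"CTL_{i:02d}" for i in range(n_per_group)]
    groups = ["ASD"] * n_per_group + ["control"] * n_per_group
    values = rng.normal(means[:, None], sds[:, None],
                        size=(n_genes, 2 * n_per_group))
    asd_cols = np.array([g == "ASD" for g in groups])
    for g, shift in effects.items():
        values[genes.index(g), asd_cols] += shift

    n_child = max(2, int(round(child_fraction * n_per_group)))
    ages = []
    for _ in range(2):  # per group
        a = np.concatenate([
            rng.uniform(2, 14, size=n_child),
            rng.uniform(15, 56, size=n_per_group - n_child),
        ])
        ages.append(a)
    age = pd.Series(np.concatenate(ages), index=samples, name="age")

    profile = ExpressionProfile(
        values=pd.DataFrame(values, index=genes, columns=samples),
        group=pd.Series(groups, index=samples, name="group"),
        age=age,
    )
    truth = GroundTruth(threshold_true=threshold_true,
                        shifted_genes=dict(effects))
    return profile, truth


# Core pathways whose genes the scenario pins to the high expression mode —
# a brain cortex transcriptome always expresses its energy and
# neurotransmitter-cycling machinery.
_CORE_SUBSYSTEMS = (
    "glycolysis", "TCA", "oxidative phosphorylation",
    "glutamine-glutamate-GABA cycle", "transport", "amino acid metabolism",
    "glutathione redox", "neuroinflammation",
)


def make_two_group_scenario(
    seed: int,
    n_per_group: int = 12,
    implant_shift: float = 2.0,
    n_filler_genes: int = 300,
) -> tuple[MetabolicModel, ExpressionProfile, GroundTruth]:
    """Brain toy network + expression with an implanted sphingolipid up-shift.

    Sphingolipid-chain genes (enzymes and their dedicated exporters) start
    one log2 unit *below* the inter-mode density minimum and are shifted up
    by ``implant_shift`` in the ASD group, so contextualization keeps the
    chain in the ASD model and prunes it from the control model; the
    pipeline should then report the sphingolipid secretion markers (S1P,
    ceramide, glucosylceramide) as "up".  ``implant_shift=0`` gives the
    matched null scenario (no implanted effect anywhere).  Filler genes not
    mapped to any reaction pad the pooled distribution so kernel density
    threshold selection sees a smooth bimodal histogram.
    """
    model = make_brain_toy_network()
    mixture = dict(DEFAULT_MIXTURE)
    theta = mixture_density_minimum(mixture)

    core_genes: set[str] = set()
    sphingo_genes: set[str] = set()
    sphingo_set = set(SPHINGOLIPID_REACTIONS)
    for r in model.reactions:
        if r.id in sphingo_set:
            sphingo_genes |= r.gene_rule.genes
        elif r.subsystem in _CORE_SUBSYSTEMS or r.id in GLN_GLU_GABA_REACTIONS:
            core_genes |= r.gene_rule.genes
    core_genes -= sphingo_genes

    model_genes = sorted(model.genes)
    genes = model_genes + [f"filler{i:04d}" for i in range(n_filler_genes)]
    baselines = {g: mixture["high_mean"] for g in core_genes}
    baselines.update({g: theta - 1.0 for g in sphingo_genes})
    effects = {g: implant_shift for g in sorted(sphingo_genes)} if implant_shift else {}

    profile, truth = simulate_expression(
        n_genes=len(genes), n_per_group=n_per_group, mixture=mixture,
        effects=effects, seed=seed, gene_ids=genes, baselines=baselines,
    )
    if implant_shift:
        truth.marker_effects = {
            "S1P": "up", "ceramide": "up", "glucosylceramide": "up",
        }
    else:
        truth.marker_effects = {}
    return model, profile, truth
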