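"""Programmatic reconstruction of the full macrophage-polarization network.

The network integrates three pathways — IFN-γ/JAK/STAT1/IRF-1, IL-4/JAK/
STAT6/IRF-4/AKT and oxygen/PHD/HIF-1/2 — with SOCS negative feedback, miR
post-transcriptional regulation (miR-93, miR-3473b), the IRG-1/itaconate/ROS
metabolic loop, and transcription of the M1/M2 marker panel.  It comprises
80 state nodes drawn from 34 functionally unique species groups connected by
130 reactions in mass-action and Hill kinetics.

This module is a reconstruction built from the published mechanistic
description of the network: the wiring follows the described reaction
structure and the structural counts, while rate-constant values are
order-of-magnitude estimates calibrated to the network's documented
qualitative behaviors (transient STAT phosphorylation, SOCS suppression,
IFN-γ/IL-4 mutual antagonism, hypoxic induction of both iNOS and Arg-1).
They are synthetic stand-ins, not the deposited optimized values.

Conventions: state in molecules per cell, time in hours.  Oxygen is a
buffered species whose value is percent O2 (21 = normoxia).  Conserved
pools (receptors, JAK, STAT1, STAT6, AKT, HIF-1β) cycle among their forms
without synthesis/degradation on the signaling timescale.
"""

from __future__ import annotations

from .model import (ModelDefinition, ParameterSet, RateLaw, ReactionDef,
                    SpeciesDef)
from .simulate import NORMOXIA_PERCENT

__all__ = [
    "build_full_model",
    "default_copy_number_priors",
    "M1_PANEL",
    "M2_PANEL",
    "SENSITIVITY_LABELS_POSITIVE",
    "SENSITIVITY_LABELS_NEGATIVE",
    "BOOTSTRAP_SUBSET_11",
    "MW_IFNG",
    "MW_IL4",
]

#: molecular weights (g/mol) used for ng/ml dose conversion of the stimuli
MW_IFNG = 17_000.0
MW_IL4 = 14_000.0

#: default M1/M2 marker panels (six M1, three M2).  The panel membership is
#: an inference from the marker set tracked across the perturbation figures;
#: it is configurable wherever a panel is accepted.  CXCL10 is read out at
#: mRNA level; cytokines at their secreted pools.
M1_PANEL = {
    "iNOS": "iNOS",
    "TNFa": "TNFa_sec",
    "IL12": "IL12_sec",
    "CXCL9": "CXCL9_sec",
    "CXCL10": "CXCL10_mRNA",
    "IFNg": "IFNg_ext",
}
M2_PANEL = {
    "Arg1": "Arg1",
    "IL10": "IL10_sec",
    "VEGF": "VEGF_sec",
}

#: parameter labels reported with positive / negative PRCC against the
#: M1/M2 score under hypoxia in the published sensitivity ranking
SENSITIVITY_LABELS_POSITIVE = (
    "k127", "kf63", "kr70", "kf64", "kf17", "k33", "k61", "k77", "k45",
    "kf44", "kf42", "k37",
)
SENSITIVITY_LABELS_NEGATIVE = (
    "k99", "kr42", "k78", "kf8", "kr44", "kf95", "k71", "kf13", "ka77",
    "kf7", "kf52", "kf70", "kr64",
)

#: default 11-parameter high-sensitivity subset used for bootstrap refits
BOOTSTRAP_SUBSET_11 = (
    "k127", "kf63", "kf17", "k33", "k61", "k77", "k45",
    "k99", "k78", "kf8", "kf95",
)


def _sp(id_, group, comp="cytoplasm", init=0.0, buffered=False, name=""):
    return SpeciesDef(id_, group_id=group, compartment=comp,
                      initial_copies=init, is_buffered=buffered,
                      display_name=name or id_)


def _ma(rid, reactants, products, k, modifiers=(), note=""):
    return ReactionDef(rid, tuple(reactants), tuple(products),
                       RateLaw("mass_action_irreversible", (k,),
                               modifiers=tuple(modifiers)),
                       annotation=note)


def _rev(rid, reactants, products, kf, kr, note=""):
    return ReactionDef(rid, tuple(reactants), tuple(products),
                       RateLaw("mass_action_reversible", (kf, kr)),
                       annotation=note)


def _hill(rid, products, v, K, regulator, kind="hill_activation",
          reactants=(), modifiers=(), note=""):
    return ReactionDef(rid, tuple(reactants), tuple(products),
                       RateLaw(kind, (v, K), regulator=regulator,
                               modifiers=tuple(modifiers)),
                       annotation=note)


def build_full_model() -> ModelDefinition:
    """Assemble the 80-node / 130-reaction / 34-group polarization network."""
    species = [
        # IFN-γ ligand (autocrine-capable) and its receptor arm
        _sp("IFNg_mRNA", "IFNg", name="IFN-γ mRNA", init=5.0),
        _sp("IFNg_cyt", "IFNg", name="IFN-γ (intracellular)", init=5.0),
        _sp("IFNg_ext", "IFNg", comp="extracellular", init=20.0,
            name="IFN-γ (secreted)"),
        _sp("IFNgR", "IFNgR", comp="membrane", init=2000.0,
            name="IFN-γ receptor (with JAK1/2)"),
        _sp("IFNg_RC", "IFNgR", comp="membrane", name="IFN-γ receptor complex"),
        _sp("IFNg_RCp", "IFNgR", comp="membrane",
            name="activated IFN-γ receptor complex"),
        _sp("S1_IgRC", "SOCS1", comp="membrane", name="SOCS1:IFN-γ RC"),
        _sp("S3_IgRC", "SOCS3", comp="membrane", name="SOCS3:IFN-γ RC"),
        _sp("JAK", "JAK", init=20000.0, name="JAK pool"),
        # IL-4 arm (internalizing receptor)
        _sp("IL4", "IL4", comp="extracellular", init=5.0, name="IL-4"),
        _sp("IL4R", "IL4R", comp="membrane", init=2000.0, name="IL-4 receptor"),
        _sp("IL4_RC", "IL4R", comp="membrane", name="IL-4 receptor complex"),
        _sp("IL4_RCp", "IL4R", comp="membrane",
            name="activated IL-4 receptor complex"),
        _sp("IL4_RCi", "IL4R", name="internalized IL-4 receptor complex"),
        _sp("S1_I4RC", "SOCS1", comp="membrane", name="SOCS1:IL-4 RC"),
        _sp("S1_I4RCi", "SOCS1", name="SOCS1:internalized IL-4 RC"),
        _sp("S3_I4RC", "SOCS3", comp="membrane", name="SOCS3:IL-4 RC"),
        # STAT cascades
        _sp("STAT1", "STAT1", init=100000.0),
        _sp("pSTAT1", "STAT1", name="phospho-STAT1"),
        _sp("pSTAT1_dim", "STAT1", name="pSTAT1 dimer"),
        _sp("pSTAT1_n", "STAT1", comp="nucleus", name="nuclear pSTAT1 dimer"),
        _sp("STAT6", "STAT6", init=100000.0),
        _sp("pSTAT6", "STAT6", name="phospho-STAT6"),
        _sp("pSTAT6_dim", "STAT6", name="pSTAT6 dimer"),
        _sp("pSTAT6_n", "STAT6", comp="nucleus", name="nuclear pSTAT6 dimer"),
        # SOCS feedback
        _sp("SOCS1_mRNA", "SOCS1", init=5.0),
        _sp("SOCS1", "SOCS1", init=200.0),
        _sp("SOCS3", "SOCS3", init=200.0),
        # interferon regulatory factors
        _sp("IRF1_mRNA", "IRF1", init=20.0),
        _sp("IRF1", "IRF1", init=2000.0),
        _sp("IRF4_mRNA", "IRF4", init=20.0),
        _sp("IRF4", "IRF4", init=2000.0),
        _sp("IRF9_mRNA", "IRF9", init=50.0),
        _sp("IRF9", "IRF9", init=3000.0),
        _sp("m93_IRF9", "IRF9", name="miR-93:IRF-9 mRNA"),
        # PPARγ / AKT / PTEN / miRs
        _sp("PPARg_mRNA", "PPARg", init=20.0),
        _sp("PPARg", "PPARg", init=3000.0),
        _sp("AKT", "AKT", init=100000.0),
        _sp("pAKT", "AKT", init=100.0, name="phospho-AKT"),
        _sp("PTEN_mRNA", "PTEN", init=50.0),
        _sp("PTEN", "PTEN", init=10000.0),
        _sp("m3473_PTEN", "PTEN", name="miR-3473b:PTEN mRNA"),
        _sp("miR3473b", "miR3473b", init=500.0, name="miR-3473b"),
        _sp("miR93", "miR93", init=500.0, name="miR-93"),
        # oxygen sensing / HIF module
        _sp("PHD_mRNA", "PHD", init=20.0),
        _sp("PHD", "PHD", init=10000.0, name="PHD/FIH (lumped)"),
        _sp("PHD_O2", "PHD", name="PHD:O2 (active hydroxylase)"),
        _sp("O2", "O2", comp="extracellular", init=NORMOXIA_PERCENT,
            buffered=True, name="oxygen (percent)"),
        _sp("HIF1a_mRNA", "HIF1a", init=100.0),
        _sp("HIF1a", "HIF1a", init=500.0, name="HIF-1α"),
        _sp("HIF1a_OH", "HIF1a", name="hydroxylated/ubiquitinated HIF-1α"),
        _sp("HIF1_n", "HIF1a", comp="nucleus", name="nuclear HIF-1 (α:β)"),
        _sp("m93_HIF1a", "HIF1a", name="miR-93:HIF-1α mRNA"),
        _sp("HIF2a_mRNA", "HIF2a", init=100.0),
        _sp("HIF2a", "HIF2a", init=500.0, name="HIF-2α"),
        _sp("HIF2a_OH", "HIF2a", name="hydroxylated HIF-2α"),
        _sp("HIF2_n", "HIF2a", comp="nucleus", name="nuclear HIF-2 (α:β)"),
        _sp("HIF1b", "HIF1b", init=10000.0, name="HIF-1β"),
        _sp("ROS", "ROS", init=1000.0),
        # IRG-1 / itaconate metabolic axis
        _sp("IRG1_mRNA", "IRG1", init=20.0),
        _sp("IRG1", "IRG1", init=1000.0, name="IRG-1"),
        _sp("ITA", "ITA", init=10000.0, name="itaconate"),
        # M1 markers
        _sp("iNOS_mRNA", "iNOS", init=20.0),
        _sp("iNOS", "iNOS", init=1000.0),
        _sp("TNFa_mRNA", "TNFa", init=20.0),
        _sp("TNFa", "TNFa", init=200.0, name="TNFα (intracellular)"),
        _sp("TNFa_sec", "TNFa", comp="extracellular", init=500.0,
            name="TNFα (secreted)"),
        _sp("IL12_mRNA", "IL12", init=20.0),
        _sp("IL12_sec", "IL12", comp="extracellular", init=500.0,
            name="IL-12 (secreted)"),
        _sp("CXCL9_mRNA", "CXCL9", init=20.0),
        _sp("CXCL9_sec", "CXCL9", comp="extracellular", init=500.0,
            name="CXCL9 (secreted)"),
        _sp("CXCL10_mRNA", "CXCL10", init=50.0, name="CXCL10 mRNA"),
        # M2 markers
        _sp("Arg1_mRNA", "Arg1", init=20.0),
        _sp("Arg1", "Arg1", init=2000.0, name="arginase-1"),
        _sp("IL10_mRNA", "IL10", init=20.0),
        _sp("IL10_sec", "IL10", comp="extracellular", init=500.0,
            name="IL-10 (secreted)"),
        _sp("VEGF_mRNA", "VEGF", init=20.0),
        _sp("VEGF_sec", "VEGF", comp="extracellular", init=500.0,
            name="VEGF (secreted)"),
        _sp("MRC1_mRNA", "MRC1", init=20.0),
        _sp("MRC1", "MRC1", init=2000.0, name="MRC1/CD206"),
    ]

    reactions = [
        # --- IFN-γ receptor arm ------------------------------------------
        _rev("lig_IFNg", [("IFNg_ext", 1), ("IFNgR", 1)], [("IFNg_RC", 1)],
             "kf5", "kr5", "IFN-γ receptor ligation"),
        _ma("phos_IFNgRC", [("IFNg_RC", 1), ("JAK", 1)], [("IFNg_RCp", 1)],
            "kf17", note="JAK association/phosphorylation of the complex"),
        _ma("recyc_IFNgRC", [("IFNg_RCp", 1)], [("IFNgR", 1), ("JAK", 1)],
            "k6", note="complex turnover: receptor/JAK recycled, ligand degraded"),
        _rev("socs1_IFNgRC", [("SOCS1", 1), ("IFNg_RCp", 1)], [("S1_IgRC", 1)],
             "kf7", "kr7", "SOCS1 sequesters the activated complex"),
        _rev("socs3_IFNgRC", [("SOCS3", 1), ("IFNg_RCp", 1)], [("S3_IgRC", 1)],
             "kf9", "kr9", "SOCS3 sequesters the activated complex"),
        _hill("tx_IFNg", [("IFNg_mRNA", 1)], "k10", "ka10", "HIF1_n",
              note="hypoxia-driven autocrine IFN-γ transcription"),
        _ma("deg_IFNg_mRNA", [("IFNg_mRNA", 1)], [], "k11"),
        _ma("tl_IFNg", [], [("IFNg_cyt", 1)], "k127", modifiers=("IFNg_mRNA",),
            note="IFN-γ production (translation)"),
        _ma("sec_IFNg", [("IFNg_cyt", 1)], [("IFNg_ext", 1)], "k12",
            note="secretion to the medium pool"),
        # --- STAT1 cascade ------------------------------------------------
        _ma("phos_STAT1", [("STAT1", 1)], [("pSTAT1", 1)], "kf63",
            modifiers=("IFNg_RCp",),
            note="STAT1 recruitment/phosphorylation by the activated complex"),
        _ma("dephos_STAT1", [("pSTAT1", 1)], [("STAT1", 1)], "k25"),
        _rev("dim_STAT1", [("pSTAT1", 2)], [("pSTAT1_dim", 1)], "kf44", "kr44",
             "pSTAT1 dimerization"),
        _rev("nuc_STAT1", [("pSTAT1_dim", 1)], [("pSTAT1_n", 1)], "kf42", "kr42",
             "nuclear import/export of the dimer"),
        # --- IL-4 receptor arm -------------------------------------------
        _ma("sec_IL4", [], [("IL4", 1)], "k26", note="basal IL-4 tone"),
        _rev("lig_IL4", [("IL4", 1), ("IL4R", 1)], [("IL4_RC", 1)],
             "kf8", "kr8", "IL-4 receptor ligation"),
        _ma("phos_IL4RC", [("IL4_RC", 1), ("JAK", 1)], [("IL4_RCp", 1)], "kf13",
            note="JAK association/phosphorylation of the complex"),
        _ma("int_IL4RC", [("IL4_RCp", 1)], [("IL4_RCi", 1)], "k31",
            note="internalization (IL-4 receptor only)"),
        _ma("recyc_IL4RC", [("IL4_RCi", 1)], [("IL4R", 1), ("JAK", 1)], "k32",
            note="recycling; ligand degraded"),
        _rev("socs1_IL4RC", [("SOCS1", 1), ("IL4_RCp", 1)], [("S1_I4RC", 1)],
             "kf38", "kr38", "SOCS1 binds the uninternalized complex"),
        _rev("socs1_IL4RCi", [("SOCS1", 1), ("IL4_RCi", 1)], [("S1_I4RCi", 1)],
             "kf40", "kr40", "SOCS1 binds the internalized complex"),
        _rev("socs3_IL4RC", [("SOCS3", 1), ("IL4_RCp", 1)], [("S3_I4RC", 1)],
             "kf46", "kr46", "SOCS3 binds the uninternalized complex"),
        # --- STAT6 cascade ------------------------------------------------
        _ma("phos_STAT6", [("STAT6", 1)], [("pSTAT6", 1)], "kf95",
            modifiers=("IL4_RCp",),
            note="STAT6 recruitment/phosphorylation by the activated complex"),
        _ma("dephos_STAT6", [("pSTAT6", 1)], [("STAT6", 1)], "k50"),
        _rev("dim_STAT6", [("pSTAT6", 2)], [("pSTAT6_dim", 1)], "kf53", "kr53"),
        _rev("nuc_STAT6", [("pSTAT6_dim", 1)], [("pSTAT6_n", 1)], "kf52", "kr52"),
        # --- SOCS feedback -------------------------------------------------
        _hill("tx_SOCS1_s1", [("SOCS1_mRNA", 1)], "k56", "ka56", "pSTAT1_n",
              note="STAT1-induced SOCS1"),
        _hill("tx_SOCS1_s6", [("SOCS1_mRNA", 1)], "k57", "ka57", "pSTAT6_n",
              note="STAT6-induced SOCS1 (IL-4 inducible)"),
        _ma("deg_SOCS1_mRNA", [("SOCS1_mRNA", 1)], [], "k59"),
        _ma("tl_SOCS1", [], [("SOCS1", 1)], "k60", modifiers=("SOCS1_mRNA",)),
        _ma("deg_SOCS1", [("SOCS1", 1)], [], "k62", note="short half-life"),
        _hill("tx_SOCS3", [("SOCS3", 1)], "k65", "ka65", "pSTAT1_n",
              note="STAT1-induced SOCS3 (not IL-4 inducible)"),
        _ma("deg_SOCS3", [("SOCS3", 1)], [], "k69", note="short half-life"),
        # --- IRF-1 ---------------------------------------------------------
        _hill("tx_IRF1", [("IRF1_mRNA", 1)], "k70", "ka70", "pSTAT1_n"),
        _ma("deg_IRF1_mRNA", [("IRF1_mRNA", 1)], [], "k74"),
        _hill("deg_IRF1_mRNA_s6", [], "k75", "ka75", "pSTAT6_n",
              reactants=[("IRF1_mRNA", 1)],
              note="STAT6-mediated suppression of the STAT1/IRF-1 axis"),
        _ma("tl_IRF1", [], [("IRF1", 1)], "k33", modifiers=("IRF1_mRNA",),
            note="IRF-1 production"),
        _ma("deg_IRF1", [("IRF1", 1)], [], "k76"),
        # --- IRF-4 ---------------------------------------------------------
        _hill("tx_IRF4", [("IRF4_mRNA", 1)], "k80", "ka80", "pSTAT6_n"),
        _ma("deg_IRF4_mRNA", [("IRF4_mRNA", 1)], [], "k82"),
        _ma("tl_IRF4", [], [("IRF4", 1)], "k83", modifiers=("IRF4_mRNA",)),
        _ma("deg_IRF4", [("IRF4", 1)], [], "k84"),
        # --- IRF-9 and miR-93 ---------------------------------------------
        _ma("tx_IRF9", [], [("IRF9_mRNA", 1)], "k85"),
        _ma("deg_IRF9_mRNA", [("IRF9_mRNA", 1)], [], "k86"),
        _ma("bind_m93_IRF9", [("miR93", 1), ("IRF9_mRNA", 1)],
            [("m93_IRF9", 1)], "kf87", note="miR-93 targets IRF-9 mRNA"),
        _ma("degc_m93_IRF9", [("m93_IRF9", 1)], [("miR93", 1)], "k88",
            note="target mRNA degraded, miR recycled"),
        _ma("tl_IRF9", [], [("IRF9", 1)], "k89", modifiers=("IRF9_mRNA",)),
        _ma("deg_IRF9", [("IRF9", 1)], [], "k90"),
        _hill("tx_miR93", [("miR93", 1)], "k98", "ka98", "TNFa_sec",
              kind="hill_inhibition",
              note="pro-inflammatory signaling suppresses miR-93"),
        _ma("deg_miR93", [("miR93", 1)], [], "k118"),
        # --- PPARγ ---------------------------------------------------------
        _hill("tx_PPARg", [("PPARg_mRNA", 1)], "k91", "ka91", "pSTAT6_n"),
        _ma("deg_PPARg_mRNA", [("PPARg_mRNA", 1)], [], "k93"),
        _ma("tl_PPARg", [], [("PPARg", 1)], "k94", modifiers=("PPARg_mRNA",)),
        _ma("deg_PPARg", [("PPARg", 1)], [], "k97"),
        # --- AKT / PTEN / miR-3473b ---------------------------------------
        _ma("act_AKT", [("AKT", 1)], [("pAKT", 1)], "kf102",
            modifiers=("IL4_RCp",), note="one-step AKT activation"),
        _ma("deact_AKT", [("pAKT", 1)], [("AKT", 1)], "k105",
            modifiers=("PTEN",), note="PTEN-dependent deactivation"),
        _ma("tx_PTEN", [], [("PTEN_mRNA", 1)], "k107"),
        _ma("deg_PTEN_mRNA", [("PTEN_mRNA", 1)], [], "k108"),
        _ma("bind_m3473_PTEN", [("miR3473b", 1), ("PTEN_mRNA", 1)],
            [("m3473_PTEN", 1)], "kf109", note="miR-3473b targets PTEN mRNA"),
        _ma("degc_m3473_PTEN", [("m3473_PTEN", 1)], [("miR3473b", 1)], "k110"),
        _ma("tl_PTEN", [], [("PTEN", 1)], "k111", modifiers=("PTEN_mRNA",)),
        _ma("deg_PTEN", [("PTEN", 1)], [], "k112"),
        _hill("tx_miR3473b", [("miR3473b", 1)], "k113", "ka113", "pSTAT1_n",
              kind="hill_inhibition",
              note="IFN-γ signaling inhibits miR-3473b expression"),
        _ma("deg_miR3473b", [("miR3473b", 1)], [], "k114"),
        # --- oxygen sensing / HIF module ----------------------------------
        _hill("tx_PHD", [("PHD_mRNA", 1)], "k115", "ka115", "HIF1_n",
              note="HIF-induced PHD feedback"),
        _ma("deg_PHD_mRNA", [("PHD_mRNA", 1)], [], "k119"),
        _ma("tl_PHD", [], [("PHD", 1)], "k120", modifiers=("PHD_mRNA",)),
        _ma("deg_PHD", [("PHD", 1)], [], "k121"),
        _rev("bind_PHD_O2", [("PHD", 1), ("O2", 1)], [("PHD_O2", 1)],
             "kf70", "kr70", "oxygen binding activates the hydroxylase"),
        _ma("tx_HIF1a", [], [("HIF1a_mRNA", 1)], "k123"),
        _ma("deg_HIF1a_mRNA", [("HIF1a_mRNA", 1)], [], "k125"),
        _ma("bind_m93_HIF1a", [("miR93", 1), ("HIF1a_mRNA", 1)],
            [("m93_HIF1a", 1)], "kf126", note="miR-93 targets HIF-1α mRNA"),
        _ma("degc_m93_HIF1a", [("m93_HIF1a", 1)], [("miR93", 1)], "k128"),
        _ma("tl_HIF1a", [], [("HIF1a", 1)], "k61", modifiers=("HIF1a_mRNA",),
            note="HIF-1α production"),
        _hill("hydrox_HIF1a", [("HIF1a_OH", 1)], "k130", "ka130", "ROS",
              kind="hill_inhibition", reactants=[("HIF1a", 1)],
              modifiers=("PHD_O2",),
              note="PHD-mediated hydroxylation; ROS blocks PHD activity"),
        _ma("deg_HIF1a_OH", [("HIF1a_OH", 1)], [], "k131",
            note="ubiquitin-proteasome degradation"),
        _ma("deub_HIF1a", [("HIF1a_OH", 1)], [("HIF1a", 1)], "k132",
            note="de-ubiquitination/rescue"),
        _rev("dim_HIF1", [("HIF1a", 1), ("HIF1b", 1)], [("HIF1_n", 1)],
             "kf64", "kr64", "nuclear HIF-1 assembly"),
        _ma("tx_HIF2a", [], [("HIF2a_mRNA", 1)], "k134"),
        _hill("tx_HIF2a_pparg", [("HIF2a_mRNA", 1)], "k135", "ka135", "PPARg",
              note="PPARγ-controlled HIF-2α synthesis (IL-4 axis link)"),
        _ma("deg_HIF2a_mRNA", [("HIF2a_mRNA", 1)], [], "k136"),
        _ma("tl_HIF2a", [], [("HIF2a", 1)], "k137", modifiers=("HIF2a_mRNA",)),
        _hill("hydrox_HIF2a", [("HIF2a_OH", 1)], "k139", "ka139", "ROS",
              kind="hill_inhibition", reactants=[("HIF2a", 1)],
              modifiers=("PHD_O2",)),
        _ma("deg_HIF2a_OH", [("HIF2a_OH", 1)], [], "k140"),
        _rev("dim_HIF2", [("HIF2a", 1), ("HIF1b", 1)], [("HIF2_n", 1)],
             "kf142", "kr142", "nuclear HIF-2 assembly"),
        _hill("prod_ROS", [("ROS", 1)], "k146", "ka146", "ITA",
              kind="hill_inhibition",
              note="itaconate limits mitochondrial ROS production"),
        _ma("deg_ROS", [("ROS", 1)], [], "k147"),
        # --- IRG-1 / itaconate --------------------------------------------
        _hill("tx_IRG1", [("IRG1_mRNA", 1)], "k149", "ka149", "IRF9",
              note="IRF-9 (with IRF-1 axis) drives IRG-1"),
        _ma("deg_IRG1_mRNA", [("IRG1_mRNA", 1)], [], "k150"),
        _ma("tl_IRG1", [], [("IRG1", 1)], "k151", modifiers=("IRG1_mRNA",)),
        _ma("deg_IRG1", [("IRG1", 1)], [], "k152"),
        _ma("prod_ITA", [], [("ITA", 1)], "k153", modifiers=("IRG1",),
            note="IRG-1 catalyzes itaconate production"),
        _ma("deg_ITA", [("ITA", 1)], [], "k154"),
        # --- M1 markers ----------------------------------------------------
        _hill("tx_iNOS_s1", [("iNOS_mRNA", 1)], "k77", "ka77", "pSTAT1_n"),
        _hill("tx_iNOS_hif", [("iNOS_mRNA", 1)], "k155", "ka155", "HIF1_n"),
        _ma("deg_iNOS_mRNA", [("iNOS_mRNA", 1)], [], "k156"),
        _ma("tl_iNOS", [], [("iNOS", 1)], "k157", modifiers=("iNOS_mRNA",)),
        _ma("deg_iNOS", [("iNOS", 1)], [], "k158"),
        _hill("tx_TNFa", [("TNFa_mRNA", 1)], "k45", "ka45", "IRF1",
              note="hypoxic induction flows via the autocrine IFN-γ/IRF-1 route"),
        _ma("deg_TNFa_mRNA", [("TNFa_mRNA", 1)], [], "k160"),
        _ma("tl_TNFa", [], [("TNFa", 1)], "k161", modifiers=("TNFa_mRNA",)),
        _ma("sec_TNFa", [("TNFa", 1)], [("TNFa_sec", 1)], "k162"),
        _ma("deg_TNFa_sec", [("TNFa_sec", 1)], [], "k163"),
        _hill("tx_IL12", [("IL12_mRNA", 1)], "k37", "ka37", "IRF1"),
        _ma("deg_IL12_mRNA", [("IL12_mRNA", 1)], [], "k164"),
        _ma("tl_IL12", [], [("IL12_sec", 1)], "k165", modifiers=("IL12_mRNA",),
            note="translation and secretion lumped"),
        _ma("deg_IL12_sec", [("IL12_sec", 1)], [], "k166"),
        _hill("tx_CXCL9", [("CXCL9_mRNA", 1)], "k167", "ka167", "IRF1"),
        _ma("deg_CXCL9_mRNA", [("CXCL9_mRNA", 1)], [], "k168"),
        _ma("tl_CXCL9", [], [("CXCL9_sec", 1)], "k169",
            modifiers=("CXCL9_mRNA",)),
        _ma("deg_CXCL9_sec", [("CXCL9_sec", 1)], [], "k170"),
        _hill("tx_CXCL10", [("CXCL10_mRNA", 1)], "k171", "ka171", "pSTAT1_n",
              note="CXCL10 tracked at mRNA level"),
        _ma("deg_CXCL10_mRNA", [("CXCL10_mRNA", 1)], [], "k172"),
        # --- M2 markers ----------------------------------------------------
        _hill("tx_Arg1_s6", [("Arg1_mRNA", 1)], "k173", "ka173", "pSTAT6_n"),
        _hill("tx_Arg1_hif", [("Arg1_mRNA", 1)], "k99", "ka99", "HIF2_n"),
        _ma("deg_Arg1_mRNA", [("Arg1_mRNA", 1)], [], "k174"),
        _ma("tl_Arg1", [], [("Arg1", 1)], "k175", modifiers=("Arg1_mRNA",)),
        _ma("deg_Arg1", [("Arg1", 1)], [], "k176"),
        _hill("tx_IL10", [("IL10_mRNA", 1)], "k78", "ka78", "pSTAT6_n"),
        _hill("tx_IL10_akt", [("IL10_mRNA", 1)], "k183", "ka183", "pAKT",
              note="AKT promotes IL-10 synthesis"),
        _ma("deg_IL10_mRNA", [("IL10_mRNA", 1)], [], "k177"),
        _ma("tl_IL10", [], [("IL10_sec", 1)], "k178", modifiers=("IL10_mRNA",)),
        _ma("deg_IL10_sec", [("IL10_sec", 1)], [], "k179"),
        _hill("tx_VEGF", [("VEGF_mRNA", 1)], "k71", "ka71", "HIF1_n"),
        _ma("deg_VEGF_mRNA", [("VEGF_mRNA", 1)], [], "k180"),
        _ma("tl_VEGF", [], [("VEGF_sec", 1)], "k181", modifiers=("VEGF_mRNA",)),
        _ma("deg_VEGF_sec", [("VEGF_sec", 1)], [], "k182"),
        _hill("tx_MRC1", [("MRC1_mRNA", 1)], "k185", "ka185", "pSTAT6_n"),
        _ma("deg_MRC1_mRNA", [("MRC1_mRNA", 1)], [], "k186"),
        _ma("tl_MRC1", [], [("MRC1", 1)], "k187", modifiers=("MRC1_mRNA",)),
        _ma("deg_MRC1", [("MRC1", 1)], [], "k188"),
    ]

    params = ParameterSet(_default_parameters())
    for label in params:
        params.provenance.setdefault(label, "S1_table")
    model = ModelDefinition(species, reactions, params,
                            marker_panels={"M1": dict(M1_PANEL),
                                           "M2": dict(M2_PANEL)},
                            name="macrophage_polarization_full")
    return model


def _default_parameters() -> dict[str, float]:
    """Nominal rate constants (per hour; second-order per molecule per hour).

    Order-of-magnitude estimates tuned to the documented qualitative
    behaviors; see the module docstring for their provenance status.
    """
    return {
        # IFN-γ receptor arm
        "kf5": 2e-5, "kr5": 0.2,     # ligation
        "kf17": 5e-4,                # complex phosphorylation (per JAK)
        "k6": 0.6,                   # active-complex turnover/recycling
        "kf7": 2e-3, "kr7": 0.1,     # SOCS1 binding
        "kf9": 5e-4, "kr9": 0.1,     # SOCS3 binding
        "k10": 40.0, "ka10": 500.0,  # hypoxia-driven IFN-γ transcription
        "k11": 0.5,                  # IFN-γ mRNA degradation
        "k127": 2.0,                 # IFN-γ translation (per mRNA)
        "k12": 2.0,                  # secretion
        # STAT1
        "kf63": 3e-4, "k25": 2.0,
        "kf44": 1e-4, "kr44": 1.0,
        "kf42": 5.0, "kr42": 0.5,
        # IL-4 arm
        "k26": 40.0,                 # basal IL-4 tone
        "kf8": 2e-5, "kr8": 0.2,
        "kf13": 5e-4,
        "k31": 1.0, "k32": 0.6,
        "kf38": 5e-4, "kr38": 0.1,
        "kf40": 5e-4, "kr40": 0.1,
        "kf46": 5e-4, "kr46": 0.1,
        # STAT6
        "kf95": 2e-4, "k50": 2.0,
        "kf53": 1e-4, "kr53": 1.0,
        "kf52": 5.0, "kr52": 0.5,
        # SOCS
        "k56": 200.0, "ka56": 5000.0,
        "k57": 100.0, "ka57": 5000.0,
        "k59": 1.0,
        "k60": 10.0, "k62": 1.5,     # SOCS1: short half-life
        "k65": 400.0, "ka65": 5000.0,
        "k69": 1.5,
        # IRF-1
        "k70": 60.0, "ka70": 3000.0,
        "k74": 0.4,
        "k75": 4.0, "ka75": 1000.0,
        "k33": 20.0, "k76": 0.3,
        # IRF-4
        "k80": 30.0, "ka80": 3000.0,
        "k82": 0.4, "k83": 20.0, "k84": 0.3,
        # IRF-9 / miR-93
        "k85": 25.0, "k86": 0.4,
        "kf87": 2e-4, "k88": 1.0,
        "k89": 25.0, "k90": 0.2,
        "k98": 150.0, "ka98": 2000.0,
        "k118": 0.2,
        # PPARγ
        "k91": 30.0, "ka91": 3000.0,
        "k93": 0.4, "k94": 40.0, "k97": 0.25,
        # AKT / PTEN / miR-3473b
        "kf102": 1e-5, "k105": 2e-4,
        "k107": 25.0, "k108": 0.4,
        "kf109": 2e-4, "k110": 1.0,
        "k111": 80.0, "k112": 0.25,
        "k113": 120.0, "ka113": 2000.0,
        "k114": 0.2,
        # oxygen / HIF
        "k115": 30.0, "ka115": 100.0,
        "k119": 0.4, "k120": 250.0, "k121": 0.3,
        "kf70": 1e-2, "kr70": 2.0,
        "k123": 20.0, "k125": 0.4,
        "kf126": 2e-4, "k128": 1.0,
        "k61": 10.0,
        "k130": 1.2e-2, "ka130": 3000.0,
        "k131": 8.0, "k132": 0.5,
        "kf64": 7.5e-5, "kr64": 1.0,
        "k134": 20.0, "k135": 60.0, "ka135": 8000.0,
        "k136": 0.4, "k137": 10.0,
        "k139": 1.2e-2, "ka139": 3000.0,
        "k140": 8.0,
        "kf142": 7.5e-5, "kr142": 1.0,
        "k146": 600.0, "ka146": 20000.0,
        "k147": 0.4,
        # IRG-1 / itaconate
        "k149": 20.0, "ka149": 5000.0,
        "k150": 0.4, "k151": 30.0, "k152": 0.3,
        "k153": 2.0, "k154": 0.2,
        # M1 markers
        "k77": 50.0, "ka77": 4000.0,
        "k155": 25.0, "ka155": 2000.0,
        "k156": 0.4, "k157": 25.0, "k158": 0.25,
        "k45": 40.0, "ka45": 6000.0,
        "k160": 0.5, "k161": 15.0, "k162": 1.5, "k163": 0.3,
        "k37": 40.0, "ka37": 6000.0,
        "k164": 0.5, "k165": 15.0, "k166": 0.3,
        "k167": 40.0, "ka167": 6000.0,
        "k168": 0.5, "k169": 15.0, "k170": 0.3,
        "k171": 60.0, "ka171": 4000.0,
        "k172": 0.35,
        # M2 markers
        "k173": 60.0, "ka173": 4000.0,
        "k99": 60.0, "ka99": 500.0,
        "k174": 0.4, "k175": 25.0, "k176": 0.25,
        "k78": 40.0, "ka78": 4000.0,
        "k183": 20.0, "ka183": 2000.0,
        "k177": 0.5, "k178": 15.0, "k179": 0.3,
        "k71": 40.0, "ka71": 2000.0,
        "k180": 0.5, "k181": 15.0, "k182": 0.3,
        "k185": 40.0, "ka185": 4000.0,
        "k186": 0.4, "k187": 25.0, "k188": 0.25,
    }


def default_copy_number_priors() -> dict[str, float]:
    """Baseline (unpolarized, normoxic) copy-number targets per species group.

    Round-number literature-scale values against which the equilibrated
    steady state is checked with the 0.5x-2x admissibility band; see
    docs/methods.md for how the reconstruction set them.
    """
    return {
        "AKT": 1.0e5, "Arg1": 1500.0, "CXCL10": 1.5, "CXCL9": 30.0,
        "HIF1a": 150.0, "HIF1b": 1.0e4, "HIF2a": 200.0, "IFNg": 200.0,
        "IFNgR": 2000.0, "IL10": 150.0, "IL12": 30.0, "IL4": 1000.0,
        "IL4R": 2000.0, "IRF1": 50.0, "IRF4": 250.0, "IRF9": 6000.0,
        "IRG1": 2500.0, "ITA": 2.5e4, "JAK": 2.0e4, "MRC1": 400.0,
        "O2": 21.0, "PHD": 1.3e4, "PPARg": 600.0, "PTEN": 1.5e4,
        "ROS": 600.0, "SOCS1": 50.0, "SOCS3": 2.0, "STAT1": 1.0e5,
        "STAT6": 1.0e5, "TNFa": 35.0, "VEGF": 50.0, "iNOS": 175.0,
        "miR3473b": 600.0, "miR93": 750.0,
    }
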