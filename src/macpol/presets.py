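"""Named scenario presets for the polarization analyses.

Each preset reproduces one of the standard perturbation protocols:
SOCS overexpression/silencing under single-cytokine stimulation, sequential
and simultaneous co-stimulation, hypoxia with axis-specific inhibitions
(production rates to 10%, binding rates to 10%), and the high-IL-4 tumor
context with receptor/STAT6/PHD blockade.  Doses follow the published
protocols (ng/ml); inhibition factors are 0.1, overexpression 50x.
"""

from __future__ import annotations

from .fullmodel import MW_IFNG, MW_IL4
from .scenarios import PerturbationSpec, Scenario
from .simulate import OxygenCondition, StimulusEvent

__all__ = ["SCENARIO_PRESETS", "get_preset", "scenario_to_config",
           "scenario_from_config"]


def _ifng(dose, t=0.0):
    return StimulusEvent("IFNg_ext", dose, MW_IFNG, t)


def _il4(dose, t=0.0):
    return StimulusEvent("IL4", dose, MW_IL4, t)


def _make_presets() -> dict[str, Scenario]:
    presets = {
        "socs1_overexpression": Scenario(
            name="socs1_overexpression",
            stimuli=[_ifng(10.0)],
            perturbations=[PerturbationSpec("overexpress", "SOCS1")],
            horizon=48.0, readouts=["pSTAT1", "pSTAT1_n"]),
        "socs3_overexpression": Scenario(
            name="socs3_overexpression",
            stimuli=[_ifng(10.0)],
            perturbations=[PerturbationSpec("overexpress", "SOCS3")],
            horizon=48.0, readouts=["pSTAT1", "pSTAT1_n"]),
        "socs3_silencing": Scenario(
            name="socs3_silencing",
            stimuli=[_ifng(10.0)],
            perturbations=[PerturbationSpec("silence", "SOCS3")],
            horizon=48.0),
        "sequential_ifng_then_il4": Scenario(
            name="sequential_ifng_then_il4",
            stimuli=[_ifng(10.0), _il4(20.0, 4.0)],
            horizon=48.0, readouts=["IRF1"]),
        "sequential_il4_then_ifng": Scenario(
            name="sequential_il4_then_ifng",
            stimuli=[_il4(20.0), _ifng(10.0, 1.0)],
            horizon=48.0, readouts=["pAKT"]),
        "costimulation": Scenario(
            name="costimulation",
            stimuli=[_ifng(10.0), _il4(5.0)],
            horizon=48.0),
        "hypoxia_control": Scenario(
            name="hypoxia_control",
            oxygen=OxygenCondition(2.0), horizon=48.0),
        "hypoxia_ifng_inh": Scenario(
            name="hypoxia_ifng_inh",
            oxygen=OxygenCondition(2.0),
            perturbations=[PerturbationSpec("production_scale", "IFNg", 0.1)],
            horizon=48.0),
        "hypoxia_hif1a_inh": Scenario(
            name="hypoxia_hif1a_inh",
            oxygen=OxygenCondition(2.0),
            perturbations=[PerturbationSpec("production_scale", "HIF1a", 0.1)],
            horizon=48.0),
        "hypoxia_stat1_inh": Scenario(
            name="hypoxia_stat1_inh",
            oxygen=OxygenCondition(2.0),
            # 90% decrease in the binding rate between STAT1 and the
            # activated receptor complex
            perturbations=[PerturbationSpec("rate_scale", "kf63", 0.1)],
            horizon=48.0),
        "hypoxia_irf1_inh": Scenario(
            name="hypoxia_irf1_inh",
            oxygen=OxygenCondition(2.0),
            perturbations=[PerturbationSpec("production_scale", "IRF1", 0.1)],
            horizon=48.0),
        "il4high_control": Scenario(
            name="il4high_control",
            perturbations=[PerturbationSpec("production_scale", "IL4", 10.0)],
            horizon=48.0),
        "il4high_il4r_block": Scenario(
            name="il4high_il4r_block",
            perturbations=[PerturbationSpec("production_scale", "IL4", 10.0),
                           PerturbationSpec("rate_scale", "kf8", 0.1)],
            horizon=48.0),
        "il4high_stat6_inh": Scenario(
            name="il4high_stat6_inh",
            perturbations=[PerturbationSpec("production_scale", "IL4", 10.0),
                           PerturbationSpec("rate_scale", "kf95", 0.1)],
            horizon=48.0),
        "il4high_phd_inh": Scenario(
            name="il4high_phd_inh",
            perturbations=[PerturbationSpec("production_scale", "IL4", 10.0),
                           PerturbationSpec("rate_scale", "kf70", 0.1)],
            horizon=48.0),
    }
    return presets


SCENARIO_PRESETS = _make_presets()


def get_preset(name: str) -> Scenario:
    try:
        return SCENARIO_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario preset {name!r}; available: "
            f"{', '.join(sorted(SCENARIO_PRESETS))}") from None


def scenario_to_config(scenario: Scenario) -> dict:
    """Plain-dict (YAML-ready) form of a scenario."""
    cfg: dict = {"name": scenario.name, "horizon": scenario.horizon}
    if scenario.stimuli:
        cfg["stimuli"] = [{
            "ligand": e.ligand, "dose": e.dose, "mol_weight": e.mol_weight,
            "time_added": e.time_added, "in_copies": e.in_copies,
        } for e in scenario.stimuli]
    if scenario.oxygen is not None:
        cfg["oxygen"] = {"percent_O2": scenario.oxygen.percent_O2,
                         "time_applied": scenario.oxygen.time_applied}
    if scenario.perturbations:
        cfg["perturbations"] = [{
            "kind": p.kind, "target": p.target,
            **({} if p.factor is None else {"factor": p.factor}),
        } for p in scenario.perturbations]
    if scenario.readouts:
        cfg["readouts"] = list(scenario.readouts)
    return cfg


def scenario_from_config(cfg: dict) -> Scenario:
    if "preset" in cfg:
        return get_preset(cfg["preset"])
    stimuli = [StimulusEvent(
        ligand=e["ligand"], dose=float(e["dose"]),
        mol_weight=e.get("mol_weight"),
        time_added=float(e.get("time_added", 0.0)),
        in_copies=bool(e.get("in_copies", False)),
    ) for e in cfg.get("stimuli", [])]
    oxygen = None
    if "oxygen" in cfg:
        oxygen = OxygenCondition(
            percent_O2=float(cfg["oxygen"]["percent_O2"]),
            time_applied=float(cfg["oxygen"].get("time_applied", 0.0)))
    perturbations = [PerturbationSpec(
        kind=p["kind"], target=p["target"],
        factor=None if "factor" not in p else float(p["factor"]),
    ) for p in cfg.get("perturbations", [])]
    return Scenario(
        name=cfg.get("name", "scenario"), stimuli=stimuli, oxygen=oxygen,
        perturbations=perturbations, horizon=float(cfg.get("horizon", 48.0)),
        readouts=list(cfg.get("readouts", [])))
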