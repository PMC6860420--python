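"""Toy networks with known behavior and synthetic calibration data.

These small models carry closed-form or oracle solutions and are the primary
correctness surface for the integration engine, the perturbation semantics
and the calibration machinery; they also let every pipeline stage run
without the full polarization network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import CalibDataset
from .model import (ModelDefinition, ParameterSet, RateLaw, ReactionDef,
                    SpeciesDef)
from .scenarios import NormalizationMode, Scenario
from .simulate import equilibrate, run_scenario

__all__ = ["ToySpec", "make_toy", "make_synthetic_datasets",
           "with_decoy_subnetwork"]

TOPOLOGIES = ("production_degradation", "linear_cascade",
              "ligand_receptor_stat", "conserved_cycle")


@dataclass(frozen=True)
class ToySpec:
    topology: str
    size: int = 3
    rates: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unsupported topology {self.topology!r}")


def _ma(k: str, modifiers=()) -> RateLaw:
    return RateLaw("mass_action_irreversible", (k,), modifiers=tuple(modifiers))


def make_toy(spec: ToySpec) -> tuple[ModelDefinition, dict]:
    """Build the toy model and attach analytic references where they exist.

    The returned dict may contain ``steady_state`` (id -> value),
    ``trajectory`` (callable t -> dict), and ``conserved_total``.
    """
    rates = dict(spec.rates or {})
    if spec.topology == "production_degradation":
        s = rates.get("s", 100.0)
        d = rates.get("d", 0.1)
        model = ModelDefinition(
            species=[SpeciesDef("X", group_id="X", initial_copies=0.0)],
            reactions=[
                ReactionDef("synth", (), (("X", 1),), _ma("s")),
                ReactionDef("deg", (("X", 1),), (), _ma("d")),
            ],
            parameters=ParameterSet({"s": s, "d": d}),
            name="production_degradation",
        )
        ss = s / d

        def trajectory(t, x0=0.0):
            return {"X": ss + (x0 - ss) * np.exp(-d * np.asarray(t))}

        return model, {"steady_state": {"X": ss}, "trajectory": trajectory}

    if spec.topology == "linear_cascade":
        n = max(2, spec.size)
        k_act = rates.get("k_act", 1.0)
        k_deg = rates.get("k_deg", 0.5)
        s0 = rates.get("s0", 10.0)
        species = [SpeciesDef(f"A{i}", group_id=f"A{i}") for i in range(n)]
        reactions = [ReactionDef("src", (), (("A0", 1),), _ma("s0"))]
        params = {"s0": s0, "k_deg": k_deg}
        for i in range(n - 1):
            params[f"k{i}"] = k_act
            reactions.append(ReactionDef(
                f"act{i}", (), ((f"A{i+1}", 1),), _ma(f"k{i}", modifiers=(f"A{i}",)),
                annotation=f"A{i} catalyzes synthesis of A{i+1}"))
        for i in range(n):
            reactions.append(ReactionDef(
                f"deg{i}", ((f"A{i}", 1),), (), _ma("k_deg")))
        model = ModelDefinition(species, reactions, ParameterSet(params),
                                name="linear_cascade")
        # steady state: A0 = s0/k_deg; A_{i+1} = k_i A_i / k_deg
        ss = {"A0": s0 / k_deg}
        for i in range(n - 1):
            ss[f"A{i+1}"] = k_act * ss[f"A{i}"] / k_deg
        return model, {"steady_state": ss}

    if spec.topology == "conserved_cycle":
        n = max(3, spec.size)
        k = rates.get("k", 1.0)
        total = rates.get("total", 300.0)
        species = [SpeciesDef(f"C{i}", group_id="cycle",
                              initial_copies=(total if i == 0 else 0.0))
                   for i in range(n)]
        params = {}
        reactions = []
        for i in range(n):
            params[f"k{i}"] = k * (1.0 + 0.1 * i)
            reactions.append(ReactionDef(
                f"step{i}", ((f"C{i}", 1),), ((f"C{(i+1) % n}", 1),),
                _ma(f"k{i}")))
        model = ModelDefinition(species, reactions, ParameterSet(params),
                                name="conserved_cycle")
        return model, {"conserved_total": total,
                       "conserved_species": [s.id for s in species]}

    # ligand_receptor_stat: L + R <-> C; C catalyzes S -> pS; pS induces the
    # SOCS-like inhibitor I which removes C — a negative feedback that gives
    # the peak-then-decay of the terminal active species under step input.
    kf = rates.get("kf", 1e-3)
    kr = rates.get("kr", 0.1)
    k_phos = rates.get("k_phos", 5e-3)
    k_dephos = rates.get("k_dephos", 0.5)
    k_fb = rates.get("k_fb", 0.05)
    k_inh = rates.get("k_inh", 5e-3)
    k_ideg = rates.get("k_ideg", 0.2)
    r_tot = rates.get("r_tot", 1000.0)
    s_tot = rates.get("s_tot", 5000.0)
    species = [
        SpeciesDef("L", group_id="ligand", compartment="extracellular"),
        SpeciesDef("R", group_id="receptor", compartment="membrane",
                   initial_copies=r_tot),
        SpeciesDef("C", group_id="receptor", compartment="membrane"),
        SpeciesDef("S", group_id="stat", initial_copies=s_tot),
        SpeciesDef("pS", group_id="stat"),
        SpeciesDef("I", group_id="inhibitor"),
    ]
    reactions = [
        ReactionDef("bind", (("L", 1), ("R", 1)), (("C", 1),),
                    RateLaw("mass_action_reversible", ("kf", "kr"))),
        ReactionDef("phos", (("S", 1),), (("pS", 1),),
                    _ma("k_phos", modifiers=("C",)),
                    annotation="receptor complex phosphorylates STAT"),
        ReactionDef("dephos", (("pS", 1),), (("S", 1),), _ma("k_dephos")),
        ReactionDef("induce_I", (), (("I", 1),), _ma("k_fb", modifiers=("pS",)),
                    annotation="SOCS-like feedback induction"),
        ReactionDef("inhibit", (("C", 1),), (("R", 1),),
                    _ma("k_inh", modifiers=("I",)),
                    annotation="inhibitor strips the active complex"),
        ReactionDef("deg_I", (("I", 1),), (), _ma("k_ideg")),
    ]
    params = ParameterSet({"kf": kf, "kr": kr, "k_phos": k_phos,
                           "k_dephos": k_dephos, "k_fb": k_fb,
                           "k_inh": k_inh, "k_ideg": k_ideg})
    model = ModelDefinition(species, reactions, params,
                            name="ligand_receptor_stat")
    return model, {"terminal_species": "pS",
                   "conserved_total": s_tot,
                   "conserved_species": ["S", "pS"]}


def with_decoy_subnetwork(model: ModelDefinition,
                          species_id: str = "Z",
                          synth_label: str = "sz",
                          deg_label: str = "dz") -> ModelDefinition:
    """Append a disconnected synthesis/degradation pair to a model.

    The decoy species is unreachable from every observable, so its rates are
    structurally non-identifiable — useful as a negative control in
    sensitivity and bootstrap-identifiability experiments.
    """
    species = list(model.species) + [
        SpeciesDef(species_id, group_id=species_id, initial_copies=5.0)]
    params = ParameterSet(model.parameters, model.parameters.units,
                          model.parameters.provenance)
    params[synth_label] = 1.0
    params[deg_label] = 0.2
    reactions = list(model.reactions) + [
        ReactionDef(f"syn_{species_id}", (), ((species_id, 1),),
                    _ma(synth_label)),
        ReactionDef(f"deg_{species_id}", ((species_id, 1),), (),
                    _ma(deg_label)),
    ]
    return ModelDefinition(species, reactions, params,
                           {k: dict(v) for k, v in model.marker_panels.items()},
                           name=f"{model.name}+decoy")


def make_synthetic_datasets(
    model: ModelDefinition,
    scenarios: list[tuple[Scenario, str, np.ndarray]],
    noise_cv: float = 0.05,
    seed: int = 0,
    normalization: NormalizationMode | None = None,
    baseline: np.ndarray | None = None,
) -> list[CalibDataset]:
    """Simulate scenarios at nominal parameters and package noisy datasets.

    ``scenarios`` is a list of (Scenario, observable species id, time grid).
    Noise is multiplicative lognormal with coefficient of variation
    ``noise_cv`` (expression measurements are positive and typically
    normalized, so the noise floor scales with the signal).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    norm = normalization or NormalizationMode("to_max")
    if baseline is None:
        baseline = equilibrate(model, residual_tol=1e-6)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))  # lognormal sigma for given CV
    out = []
    for i, (scen, observable, grid) in enumerate(scenarios):
        result = run_scenario(model, events=scen.stimuli, oxygen=scen.oxygen,
                              horizon=scen.horizon, state0=baseline)
        from .scenarios import normalize_series

        utr = None
        if norm.mode == "to_untreated":
            utr = float(baseline[model.species_index[observable]])
        series = normalize_series(result[observable], result.time, norm,
                                  untreated=utr, species=observable)
        values = np.interp(grid, result.time, series)
        if noise_cv > 0:
            noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                                  size=len(grid))
            values = values * noise
        out.append(CalibDataset(
            id=f"{scen.name}:{observable}:{i}",
            scenario=scen, observable=observable,
            points=tuple(zip(grid, values)),
            normalization=norm,
            source="synthetic (model-generated)",
        ))
    return out
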