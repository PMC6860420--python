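"""Perturbation engine, output normalization and M1/M2 marker scoring.

Perturbation semantics follow the genetic/pharmacological edit conventions
used throughout the polarization analyses:

- ``overexpress``: target group's initial level x50 (configurable factor),
  production unchanged (1x).
- ``silence``: initial level 0 and all production rates of the group set to 0,
  so the target stays identically zero under any stimulus.
- ``production_scale``: synthesis/transcription rates of the group scaled by
  the factor (0.1 = the "90% decrease in production" inhibition convention).
- ``rate_scale``: one named kinetic parameter scaled (0.1 = the "90% decrease
  in binding rate" convention).
- ``initial_scale``: initial level scaled without touching production.

Edits are composable and order-independent; conflicting edits of the same
parameter raise instead of silently last-winning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import ModelDefinition
from .simulate import OxygenCondition, SimulationResult, StimulusEvent

__all__ = [
    "PerturbationSpec",
    "PerturbationError",
    "NormalizationMode",
    "NormalizationError",
    "ScoreError",
    "Scenario",
    "production_reactions",
    "apply_perturbations",
    "normalize_series",
    "extract_markers",
    "m1m2_score",
]

PERTURBATION_KINDS = ("overexpress", "silence", "production_scale",
                      "rate_scale", "initial_scale")


class PerturbationError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


class ScoreError(ValueError):
    pass


@dataclass(frozen=True)
class PerturbationSpec:
    """Typed edit of initial conditions and/or rate parameters."""

    kind: str
    target: str  # species group id, or parameter label for rate_scale
    factor: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise PerturbationError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "silence":
            if self.factor is not None:
                raise PerturbationError("silence admits no factor (implies 0/0)")
        else:
            f = self.factor if self.factor is not None else \
                (50.0 if self.kind == "overexpress" else None)
            if f is None or not math.isfinite(f) or f < 0:
                raise PerturbationError(
                    f"{self.kind} needs a finite non-negative factor")

    @property
    def effective_factor(self) -> float:
        if self.kind == "silence":
            return 0.0
        if self.factor is None and self.kind == "overexpress":
            return 50.0
        return float(self.factor)


@dataclass(frozen=True)
class NormalizationMode:
    """How a trajectory is reduced to the normalized scale of a figure/dataset."""

    mode: str  # to_t0 | to_untreated | to_max | to_reference_time | log2_fold
    reference: float | None = None  # time for to_reference_time

    def __post_init__(self) -> None:
        valid = ("to_t0", "to_untreated", "to_max", "to_reference_time",
                 "log2_fold")
        if self.mode not in valid:
            raise NormalizationError(f"unknown normalization mode {self.mode!r}")
        if self.mode == "to_reference_time" and self.reference is None:
            raise NormalizationError("to_reference_time needs a reference time")


@dataclass
class Scenario:
    """One stimulation condition: stimuli, oxygen, perturbations, horizon."""

    name: str = "scenario"
    stimuli: list[StimulusEvent] = field(default_factory=list)
    oxygen: OxygenCondition | None = None
    perturbations: list[PerturbationSpec] = field(default_factory=list)
    horizon: float = 48.0
    readouts: list[str] = field(default_factory=list)
    normalization: NormalizationMode | None = None


def production_reactions(model: ModelDefinition, group_id: str) -> list[str]:
    """Reactions that synthesize group members from outside the group.

    These are the "production" channels (basal synthesis, transcription,
    translation fed by non-group reactants) that silencing zeroes and
    ``production_scale`` rescales.  Intra-group conversions (phosphorylation,
    translocation, complex assembly) are left untouched.
    """
    members = set(model.groups.get(group_id, ()))
    if not members:
        raise PerturbationError(f"unknown species group {group_id!r}")
    out = []
    for r in model.reactions:
        makes_member = any(s in members for s, _ in r.products)
        from_inside = any(s in members for s, _ in r.reactants)
        if makes_member and not from_inside:
            out.append(r.id)
    return out


def apply_perturbations(
    model: ModelDefinition,
    state0: np.ndarray,
    specs: list[PerturbationSpec],
) -> tuple[ModelDefinition, np.ndarray]:
    """Return (edited model, edited state) for a list of perturbations.

    ``state0`` is the equilibrated baseline; initial-condition edits scale
    every node of the target group in both the state vector and the model's
    stored initials.  Parameter edits multiply rate constants.  The edits of
    disjoint targets commute; two edits touching the same parameter label
    raise a :class:`PerturbationError`.
    """
    edited = model.copy()
    state = np.asarray(state0, dtype=float).copy()
    index = edited.species_index
    groups = edited.groups
    touched: dict[str, str] = {}  # parameter label -> perturbation description

    def scale_params(labels: list[str], factor: float, who: str) -> None:
        for label in labels:
            if label in touched:
                raise PerturbationError(
                    f"conflicting edits on parameter {label!r}: "
                    f"{touched[label]} vs {who}")
            touched[label] = who
            edited.parameters[label] = edited.parameters[label] * factor

    def scale_initials(group: str, factor: float) -> None:
        for sp in groups.get(group, ()):
            state[index[sp]] *= factor

    for spec in specs:
        f = spec.effective_factor
        who = f"{spec.kind}({spec.target})"
        if spec.kind == "rate_scale":
            if spec.target not in edited.parameters:
                raise PerturbationError(
                    f"unknown parameter label {spec.target!r}")
            scale_params([spec.target], f, who)
            continue
        if spec.target not in groups:
            raise PerturbationError(f"unknown species group {spec.target!r}")
        if spec.kind in ("overexpress", "initial_scale"):
            scale_initials(spec.target, f)
        elif spec.kind == "silence":
            scale_initials(spec.target, 0.0)
            rxns = production_reactions(edited, spec.target)
            labels = sorted({r.rate_law.param_labels[0]
                             for r in edited.reactions if r.id in rxns})
            scale_params(labels, 0.0, who)
        elif spec.kind == "production_scale":
            rxns = production_reactions(edited, spec.target)
            labels = sorted({r.rate_law.param_labels[0]
                             for r in edited.reactions if r.id in rxns})
            scale_params(labels, f, who)

    edited = edited.with_initial_state(state)
    return edited, state


def normalize_series(values: np.ndarray, time: np.ndarray,
                     mode: NormalizationMode,
                     untreated: np.ndarray | float | None = None,
                     species: str = "") -> np.ndarray:
    """Normalize one trajectory per the dataset/figure convention."""
    v = np.asarray(values, dtype=float)

    def _denom(x: float) -> float:
        if not np.isfinite(x) or x <= 0:
            raise NormalizationError(
                f"non-positive normalization denominator for {species or 'series'}")
        return x

    if mode.mode == "to_t0":
        return v / _denom(v[0])
    if mode.mode == "log2_fold":
        return np.log2(np.maximum(v, 1e-300) / _denom(v[0]))
    if mode.mode == "to_max":
        return v / _denom(float(np.max(v)))
    if mode.mode == "to_reference_time":
        ref = float(np.interp(mode.reference, time, v))
        return v / _denom(ref)
    # to_untreated
    if untreated is None:
        raise NormalizationError("to_untreated needs the untreated series/level")
    if np.isscalar(untreated):
        return v / _denom(float(untreated))
    u = np.asarray(untreated, dtype=float)
    if np.any(u <= 0):
        raise NormalizationError(
            f"non-positive untreated denominator for {species or 'series'}")
    return v / u


def extract_markers(
    result: SimulationResult,
    panel: dict[str, str],
    mode: NormalizationMode,
    untreated: SimulationResult | dict[str, float] | None = None,
):
    """Normalized trajectories for every marker of a panel.

    ``panel`` maps marker display name -> species id.  Returns a tidy
    DataFrame (time, marker, value).
    """
    import pandas as pd

    rows = []
    for marker, sp in panel.items():
        utr = None
        if untreated is not None:
            utr = (untreated[sp] if isinstance(untreated, SimulationResult)
                   else untreated.get(sp))
        norm = normalize_series(result[sp], result.time, mode,
                                untreated=utr, species=marker)
        rows.append(pd.DataFrame({"time": result.time, "marker": marker,
                                  "value": norm}))
    return pd.concat(rows, ignore_index=True)


def m1m2_score(
    result: SimulationResult,
    m1_panel: dict[str, str],
    m2_panel: dict[str, str],
    t_eval: float = 24.0,
) -> float:
    """Composite polarization score at ``t_eval`` (default 24 h).

    score = product of the six M1 marker levels / product of the three M2
    marker levels, on raw copy-number scale.
    """
    if len(m1_panel) != 6 or len(m2_panel) != 3:
        raise ScoreError("score needs exactly six M1 and three M2 markers")
    num, den = 1.0, 1.0
    for marker, sp in m1_panel.items():
        x = result.value(sp, t_eval)
        if x <= 0:
            raise ScoreError(f"non-positive M1 marker {marker!r} at t={t_eval}")
        num *= x
    for marker, sp in m2_panel.items():
        x = result.value(sp, t_eval)
        if x <= 0:
            raise ScoreError(f"non-positive M2 marker {marker!r} at t={t_eval}")
        den *= x
    return num / den
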