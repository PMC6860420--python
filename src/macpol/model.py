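"""Declarative reaction-network representation and ODE right-hand-side assembly.

The model is a list of species (molecules-per-cell state variables, grouped
into functionally "unique" species groups), a list of reactions with
mass-action or Hill-type rate laws, and a parameter set keyed by short labels
(``kf8``, ``k127`` ...).  :func:`assemble_rhs` compiles the network into a
vectorizable derivative function suitable for stiff integration.

Units: state is molecules per cell (secreted species: molecules per
cell-equivalent medium volume); time is hours; first-order rate constants are
per hour, second-order per molecule per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SpeciesDef",
    "RateLaw",
    "ReactionDef",
    "ParameterSet",
    "ModelDefinition",
    "ModelDefinitionError",
    "assemble_rhs",
    "structural_report",
]

COMPARTMENTS = ("cytoplasm", "nucleus", "membrane", "extracellular")

RATE_LAW_KINDS = (
    "mass_action_irreversible",
    "mass_action_reversible",
    "hill_activation",
    "hill_inhibition",
)


class ModelDefinitionError(ValueError):
    """Raised when a model definition fails validation."""


@dataclass(frozen=True)
class SpeciesDef:
    """One model node (state variable).

    ``group_id`` links the node to its parent "unique" species group: a
    protein, its mRNA, its phosphorylated/nuclear forms and the complexes it
    nucleates all share one group.  ``is_buffered`` marks species held
    constant during integration (e.g. oxygen under a fixed condition).
    """

    id: str
    group_id: str
    compartment: str = "cytoplasm"
    initial_copies: float = 0.0
    display_name: str = ""
    is_buffered: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelDefinitionError(
                f"species {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if not np.isfinite(self.initial_copies) or self.initial_copies < 0:
            raise ModelDefinitionError(
                f"species {self.id!r}: initial_copies must be finite and >= 0"
            )


@dataclass(frozen=True)
class RateLaw:
    """Rate law of one reaction.

    kinds and their ordered ``param_labels``:

    - ``mass_action_irreversible``: ``(k,)``; rate = k * prod(reactant^coeff)
    - ``mass_action_reversible``: ``(kf, kr)``; net rate =
      kf * prod(reactant^coeff) - kr * prod(product^coeff)
    - ``hill_activation``: ``(v, K, n)``; rate =
      v * X^n / (K^n + X^n) * prod(reactant^coeff)
    - ``hill_inhibition``: ``(v, K, n)``; rate =
      v * K^n / (K^n + X^n) * prod(reactant^coeff)

    where ``X`` is the concentration of ``regulator``.  Catalytic
    ``modifiers`` multiply the forward rate linearly and are never consumed.
    The Hill ``n`` label may be omitted (two labels), in which case n = 1
    (Michaelis-type saturation).
    """

    kind: str
    param_labels: tuple[str, ...]
    regulator: str | None = None
    modifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "param_labels", tuple(self.param_labels))
        object.__setattr__(self, "modifiers", tuple(self.modifiers))
        if self.kind not in RATE_LAW_KINDS:
            raise ModelDefinitionError(f"unknown rate-law kind {self.kind!r}")
        n = len(self.param_labels)
        if self.kind == "mass_action_irreversible" and n != 1:
            raise ModelDefinitionError("mass_action_irreversible needs exactly 1 label")
        if self.kind == "mass_action_reversible" and n != 2:
            raise ModelDefinitionError("mass_action_reversible needs exactly (kf, kr)")
        if self.kind.startswith("hill"):
            if n not in (2, 3):
                raise ModelDefinitionError(
                    f"{self.kind} needs (v, K[, n]) labels, got {n}"
                )
            if self.regulator is None:
                raise ModelDefinitionError(f"{self.kind} requires a regulator species")


@dataclass(frozen=True)
class ReactionDef:
    """Stoichiometry plus rate law.

    ``reactants``/``products`` are tuples of (species id, positive integer
    coefficient).  Pure synthesis (no reactants) and pure degradation (no
    products) are both allowed, but not an empty reaction.
    """

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_law: RateLaw
    annotation: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple((s, int(c)) for s, c in self.reactants))
        object.__setattr__(self, "products", tuple((s, int(c)) for s, c in self.products))
        for side in (self.reactants, self.products):
            for sp, coeff in side:
                if coeff <= 0:
                    raise ModelDefinitionError(
                        f"reaction {self.id!r}: coefficient for {sp!r} must be positive"
                    )
        if not self.reactants and not self.products:
            raise ModelDefinitionError(f"reaction {self.id!r}: empty stoichiometry")
        overlap = {s for s, _ in self.reactants} & set(self.rate_law.modifiers)
        if overlap:
            raise ModelDefinitionError(
                f"reaction {self.id!r}: modifiers {sorted(overlap)} are consumed; "
                "modifiers must be catalytic"
            )


class ParameterSet(dict):
    """Mapping label -> positive rate-constant value with light metadata.

    Behaves as a plain dict; ``units`` and ``provenance`` are optional
    per-label metadata (``'S1_table' | 'optimized' | 'user'``).
    """

    def __init__(self, values=None, units=None, provenance=None):
        super().__init__(values or {})
        self.units: dict[str, str] = dict(units or {})
        self.provenance: dict[str, str] = dict(provenance or {})

    def copy(self) -> "ParameterSet":
        return ParameterSet(self, self.units, self.provenance)

    def validate(self) -> None:
        for label, value in self.items():
            if not np.isfinite(value) or value < 0:
                raise ModelDefinitionError(
                    f"parameter {label!r} must be finite and >= 0, got {value}"
                )


@dataclass
class ModelDefinition:
    """A validated reaction network with parameters and marker panels."""

    species: list[SpeciesDef]
    reactions: list[ReactionDef]
    parameters: ParameterSet
    marker_panels: dict[str, dict[str, str]] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.species:
            out.setdefault(s.group_id, []).append(s.id)
        return out

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_copies for s in self.species], dtype=float)

    def with_initial_state(self, state: np.ndarray) -> "ModelDefinition":
        species = [replace(s, initial_copies=float(x)) for s, x in zip(self.species, state)]
        return ModelDefinition(
            species, list(self.reactions), self.parameters.copy(),
            dict(self.marker_panels), self.name,
        )

    def copy(self) -> "ModelDefinition":
        return ModelDefinition(
            list(self.species), list(self.reactions), self.parameters.copy(),
            {k: dict(v) for k, v in self.marker_panels.items()}, self.name,
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        for s in self.species:
            if s.id in seen:
                raise ModelDefinitionError(f"duplicate species id {s.id!r}")
            seen.add(s.id)
        rseen: set[str] = set()
        self.parameters.validate()
        for r in self.reactions:
            if r.id in rseen:
                raise ModelDefinitionError(f"duplicate reaction id {r.id!r}")
            rseen.add(r.id)
            refs = [s for s, _ in r.reactants] + [s for s, _ in r.products]
            refs += list(r.rate_law.modifiers)
            if r.rate_law.regulator is not None:
                refs.append(r.rate_law.regulator)
            for sp in refs:
                if sp not in seen:
                    raise ModelDefinitionError(
                        f"reaction {r.id!r} references unknown species {sp!r}"
                    )
            for label in r.rate_law.param_labels:
                if label not in self.parameters:
                    raise ModelDefinitionError(
                        f"reaction {r.id!r}: unresolved parameter label {label!r}"
                    )
        for panel_name, panel in self.marker_panels.items():
            for marker, sp in panel.items():
                if sp not in seen:
                    raise ModelDefinitionError(
                        f"marker panel {panel_name!r}: {marker!r} -> unknown species {sp!r}"
                    )


# ---------------------------------------------------------------------------
# RHS assembly
# ---------------------------------------------------------------------------

def _hill_params(law: RateLaw, params: ParameterSet) -> tuple[float, float, float]:
    labels = law.param_labels
    v, K = params[labels[0]], params[labels[1]]
    n = params[labels[2]] if len(labels) == 3 else 1.0
    if K <= 0:
        raise ModelDefinitionError(f"Hill half-saturation {labels[1]!r} must be > 0")
    if n < 1:
        raise ModelDefinitionError("Hill coefficient must be >= 1")
    return v, K, n


def reaction_rate(
    reaction: ReactionDef,
    state_of: Callable[[str], float],
    params: ParameterSet,
) -> float:
    """Net rate of one reaction at the state given by ``state_of`` (id -> value).

    Reference path shared by the compiled RHS and the brute-force tests'
    conventions; negative concentrations are floored at zero before
    evaluation to preserve mass-action positivity.
    """
    law = reaction.rate_law

    def conc(sp: str) -> float:
        return max(state_of(sp), 0.0)

    fwd_mass = 1.0
    for sp, coeff in reaction.reactants:
        fwd_mass *= conc(sp) ** coeff
    mod = 1.0
    for sp in law.modifiers:
        mod *= conc(sp)

    if law.kind == "mass_action_irreversible":
        return params[law.param_labels[0]] * fwd_mass * mod
    if law.kind == "mass_action_reversible":
        kf, kr = (params[l] for l in law.param_labels)
        rev_mass = 1.0
        for sp, coeff in reaction.products:
            rev_mass *= conc(sp) ** coeff
        return (kf * fwd_mass - kr * rev_mass) * mod
    v, K, n = _hill_params(law, params)
    x = conc(law.regulator)
    xn, Kn = x ** n, K ** n
    if law.kind == "hill_activation":
        hill = xn / (Kn + xn) if (Kn + xn) > 0 else 0.0
    else:
        hill = Kn / (Kn + xn)
    return v * hill * fwd_mass * mod


def assemble_rhs(
    model: ModelDefinition,
    parameters: ParameterSet | None = None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the network into ``f(t, state) -> dstate/dt``.

    Each species' derivative is the stoichiometry-weighted sum of reaction
    rates; buffered species are pinned to zero derivative.  An optional
    ``parameters`` override allows re-assembly at sampled/perturbed values
    without copying the model.
    """
    params = parameters if parameters is not None else model.parameters
    index = model.species_index
    n = len(model.species)
    buffered = np.array([s.is_buffered for s in model.species], dtype=bool)

    compiled = []
    for r in model.reactions:
        law = r.rate_law
        react_idx = np.array([index[s] for s, _ in r.reactants], dtype=int)
        react_coef = np.array([c for _, c in r.reactants], dtype=float)
        prod_idx = np.array([index[s] for s, _ in r.products], dtype=int)
        prod_coef = np.array([c for _, c in r.products], dtype=float)
        mod_idx = np.array([index[s] for s in law.modifiers], dtype=int)
        if law.kind == "mass_action_irreversible":
            spec = ("ma", params[law.param_labels[0]], None, None, None)
        elif law.kind == "mass_action_reversible":
            spec = ("mar", params[law.param_labels[0]], params[law.param_labels[1]],
                    None, None)
        else:
            v, K, nh = _hill_params(law, params)
            spec = ("ha" if law.kind == "hill_activation" else "hi",
                    v, K ** nh, nh, index[law.regulator])
        compiled.append((spec, react_idx, react_coef, prod_idx, prod_coef, mod_idx))

    def rhs(t: float, state: np.ndarray) -> np.ndarray:
        x = np.maximum(state, 0.0)
        dx = np.zeros(n)
        for (spec, ridx, rcoef, pidx, pcoef, midx) in compiled:
            kind = spec[0]
            fwd = np.prod(x[ridx] ** rcoef) if ridx.size else 1.0
            if midx.size:
                fwd *= np.prod(x[midx])
            if kind == "ma":
                rate = spec[1] * fwd
            elif kind == "mar":
                rev = np.prod(x[pidx] ** pcoef) if pidx.size else 1.0
                if midx.size:
                    rev *= np.prod(x[midx])
                rate = spec[1] * fwd - spec[2] * rev
            else:
                v, Kn, nh, reg = spec[1], spec[2], spec[3], spec[4]
                xn = x[reg] ** nh
                denom = Kn + xn
                hill = (xn / denom if kind == "ha" else Kn / denom) if denom > 0 else 0.0
                rate = v * hill * fwd
            np.add.at(dx, ridx, -rcoef * rate)
            np.add.at(dx, pidx, pcoef * rate)
        dx[buffered] = 0.0
        return dx

    return rhs


def structural_report(model: ModelDefinition) -> dict:
    """Counts and cross-reference listing for a validated model."""
    used_labels: set[str] = set()
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in model.reactions:
        used_labels.update(r.rate_law.param_labels)
        produced.update(s for s, _ in r.products)
        consumed.update(s for s, _ in r.reactants)
        if r.rate_law.kind == "mass_action_reversible":
            # reverse direction produces reactants and consumes products
            produced.update(s for s, _ in r.reactants)
            consumed.update(s for s, _ in r.products)
    all_ids = set(model.species_ids)
    return {
        "n_nodes": len(model.species),
        "n_reactions": len(model.reactions),
        "n_groups": len(model.groups),
        "parameter_labels_used": sorted(used_labels),
        "parameter_labels_unused": sorted(set(model.parameters) - used_labels),
        "species_without_production": sorted(all_ids - produced),
        "species_without_degradation": sorted(all_ids - consumed),
    }
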