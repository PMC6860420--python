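"""SBML level 3 version 1 export and import of model definitions.

The writer emits a core-conformant L3V1 document: compartments, species
(initialAmount in molecules, ``boundaryCondition``/``constant`` for buffered
species), global parameters, and reactions with reactant/product/modifier
references and a MathML kinetic law.  Species group membership and the rate-
law descriptor are carried in a namespaced annotation so that reading our
own documents is exact; for documents written by other tools the reader
falls back to recognizing the mass-action and Hill MathML templates emitted
here and raises a definition error for kinetic laws it cannot interpret.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .model import (ModelDefinition, ModelDefinitionError, ParameterSet,
                    RateLaw, ReactionDef, SpeciesDef)

__all__ = ["write_sbml", "read_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:macpol:model-annotations"

_COMPARTMENTS = ("cytoplasm", "nucleus", "membrane", "extracellular")


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


def _mathml_rate(reaction: ReactionDef) -> etree._Element:
    """MathML expression for the reaction's net rate."""
    law = reaction.rate_law
    M = lambda tag: etree.Element(_q(tag, MATHML_NS))

    def ci(name):
        el = M("ci")
        el.text = f" {name} "
        return el

    def cn(value):
        el = M("cn")
        el.text = f" {value} "
        return el

    def apply_(op, *args):
        el = M("apply")
        el.append(M(op))
        for a in args:
            el.append(a)
        return el

    def power(base, exponent):
        return apply_("power", base, cn(exponent)) if exponent != 1 else base

    def product(factors):
        factors = list(factors)
        if not factors:
            return cn(1)
        if len(factors) == 1:
            return factors[0]
        return apply_("times", *factors)

    mods = [ci(m) for m in law.modifiers]
    fwd_mass = [power(ci(s), c) for s, c in reaction.reactants]

    if law.kind == "mass_action_irreversible":
        expr = product([ci(law.param_labels[0])] + fwd_mass + mods)
    elif law.kind == "mass_action_reversible":
        kf, kr = law.param_labels
        rev_mass = [power(ci(s), c) for s, c in reaction.products]
        expr = apply_(
            "minus",
            product([ci(kf)] + fwd_mass + [ci(m) for m in law.modifiers]),
            product([ci(kr)] + rev_mass + [ci(m) for m in law.modifiers]))
    else:
        v, K = law.param_labels[0], law.param_labels[1]
        n = law.param_labels[2] if len(law.param_labels) == 3 else None
        x = ci(law.regulator)
        xn = apply_("power", x, ci(n)) if n else x
        Kn = apply_("power", ci(K), ci(n)) if n else ci(K)
        num = xn if law.kind == "hill_activation" else Kn
        hill = apply_("divide", num, apply_("plus", Kn, xn))
        expr = product([ci(v), hill] + fwd_mass + mods)
    math = etree.Element(_q("math", MATHML_NS))
    math.append(expr)
    return math


def write_sbml(model: ModelDefinition, path: str | Path) -> Path:
    path = Path(path)
    nsmap = {None: SBML_NS}
    root = etree.Element(_q("sbml"), nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "1")
    sbml_model = etree.SubElement(root, _q("model"))
    sbml_model.set("id", model.name or "model")

    if model.species:
        comps = etree.SubElement(sbml_model, _q("listOfCompartments"))
        used = {s.compartment for s in model.species}
        for comp in _COMPARTMENTS:
            if comp in used:
                c = etree.SubElement(comps, _q("compartment"))
                c.set("id", comp)
                c.set("constant", "true")
                c.set("spatialDimensions", "3")
                c.set("size", "1")

        sp_list = etree.SubElement(sbml_model, _q("listOfSpecies"))
        for s in model.species:
            el = etree.SubElement(sp_list, _q("species"))
            el.set("id", s.id)
            el.set("name", s.display_name or s.id)
            el.set("compartment", s.compartment)
            el.set("initialAmount", repr(float(s.initial_copies)))
            el.set("hasOnlySubstanceUnits", "true")
            el.set("boundaryCondition", "true" if s.is_buffered else "false")
            el.set("constant", "true" if s.is_buffered else "false")
            ann = etree.SubElement(el, _q("annotation"))
            meta = etree.SubElement(ann, _q("speciesGroup", ANNOT_NS),
                                    nsmap={"mp": ANNOT_NS})
            meta.set("group", s.group_id)
            if s.notes:
                meta.set("notes", s.notes)

    if model.parameters:
        par_list = etree.SubElement(sbml_model, _q("listOfParameters"))
        for label, value in model.parameters.items():
            p = etree.SubElement(par_list, _q("parameter"))
            p.set("id", label)
            p.set("value", repr(float(value)))
            p.set("constant", "true")

    if model.reactions:
        rx_list = etree.SubElement(sbml_model, _q("listOfReactions"))
        for r in model.reactions:
            el = etree.SubElement(rx_list, _q("reaction"))
            el.set("id", r.id)
            el.set("reversible",
                   "true" if r.rate_law.kind == "mass_action_reversible"
                   else "false")
            ann = etree.SubElement(el, _q("annotation"))
            meta = etree.SubElement(ann, _q("rateLaw", ANNOT_NS),
                                    nsmap={"mp": ANNOT_NS})
            meta.set("kind", r.rate_law.kind)
            meta.set("params", ",".join(r.rate_law.param_labels))
            if r.rate_law.regulator:
                meta.set("regulator", r.rate_law.regulator)
            if r.rate_law.modifiers:
                meta.set("modifiers", ",".join(r.rate_law.modifiers))
            if r.annotation:
                meta.set("note", r.annotation)
            if r.reactants:
                lst = etree.SubElement(el, _q("listOfReactants"))
                for sp, coeff in r.reactants:
                    ref = etree.SubElement(lst, _q("speciesReference"))
                    ref.set("species", sp)
                    ref.set("stoichiometry", repr(float(coeff)))
                    ref.set("constant", "true")
            if r.products:
                lst = etree.SubElement(el, _q("listOfProducts"))
                for sp, coeff in r.products:
                    ref = etree.SubElement(lst, _q("speciesReference"))
                    ref.set("species", sp)
                    ref.set("stoichiometry", repr(float(coeff)))
                    ref.set("constant", "true")
            mods = set(r.rate_law.modifiers)
            if r.rate_law.regulator:
                mods.add(r.rate_law.regulator)
            mods -= {s for s, _ in r.reactants} | {s for s, _ in r.products}
            if mods:
                lst = etree.SubElement(el, _q("listOfModifiers"))
                for sp in sorted(mods):
                    ref = etree.SubElement(lst, _q("modifierSpeciesReference"))
                    ref.set("species", sp)
            kl = etree.SubElement(el, _q("kineticLaw"))
            kl.append(_mathml_rate(r))

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)
    return path


def _species_refs(el, tag):
    out = []
    lst = el.find(_q(tag))
    if lst is None:
        return out
    for ref in lst.findall(_q("speciesReference")):
        coeff = float(ref.get("stoichiometry", "1"))
        if abs(coeff - round(coeff)) > 1e-9:
            raise ModelDefinitionError(
                f"non-integer stoichiometry {coeff} on {ref.get('species')}")
        out.append((ref.get("species"), int(round(coeff))))
    return out


def read_sbml(path: str | Path, name: str | None = None) -> ModelDefinition:
    """Read an SBML L2/L3 core document written by this package (exact via
    its rate-law annotations) or a compatible plain mass-action document."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise ModelDefinitionError(f"cannot parse SBML: {exc}") from exc
    root = tree.getroot()
    ns = etree.QName(root).namespace
    if "sbml" not in (ns or ""):
        raise ModelDefinitionError(f"not an SBML document: {path}")

    def q(tag):
        return f"{{{ns}}}{tag}"

    sbml_model = root.find(q("model"))
    if sbml_model is None:
        raise ModelDefinitionError("SBML document has no <model>")

    species = []
    sp_list = sbml_model.find(q("listOfSpecies"))
    if sp_list is not None:
        for el in sp_list.findall(q("species")):
            meta = el.find(f"{q('annotation')}/{{{ANNOT_NS}}}speciesGroup")
            group = meta.get("group") if meta is not None else el.get("id")
            notes = meta.get("notes", "") if meta is not None else ""
            amount = float(el.get("initialAmount") or 0.0)
            comp = el.get("compartment", "cytoplasm")
            if comp not in _COMPARTMENTS:
                comp = "cytoplasm"
            species.append(SpeciesDef(
                id=el.get("id"), group_id=group, compartment=comp,
                initial_copies=amount,
                is_buffered=el.get("boundaryCondition") == "true",
                display_name=el.get("name", ""), notes=notes))

    values = {}
    par_list = sbml_model.find(q("listOfParameters"))
    if par_list is not None:
        for el in par_list.findall(q("parameter")):
            values[el.get("id")] = float(el.get("value") or 0.0)

    reactions = []
    rx_list = sbml_model.find(q("listOfReactions"))
    if rx_list is not None:
        for el in rx_list.findall(q("reaction")):
            rid = el.get("id")
            reactants = _species_refs(el, "listOfReactants")
            products = _species_refs(el, "listOfProducts")
            meta = el.find(f"{q('annotation')}/{{{ANNOT_NS}}}rateLaw")
            if meta is not None:
                law = RateLaw(
                    kind=meta.get("kind"),
                    param_labels=tuple(meta.get("params").split(",")),
                    regulator=meta.get("regulator"),
                    modifiers=tuple(m for m in
                                    (meta.get("modifiers") or "").split(",")
                                    if m))
                note = meta.get("note", "")
            else:
                law, note = _law_from_mathml(el, q, rid, values)
            # promote any local parameters to the global set
            kl = el.find(q("kineticLaw"))
            if kl is not None:
                for lp_tag in ("listOfLocalParameters", "listOfParameters"):
                    lp = kl.find(q(lp_tag))
                    if lp is None:
                        continue
                    for p in lp:
                        values.setdefault(p.get("id"),
                                          float(p.get("value") or 0.0))
            reactions.append(ReactionDef(rid, tuple(reactants),
                                         tuple(products), law, note))

    return ModelDefinition(species, reactions, ParameterSet(values),
                           name=name or sbml_model.get("id", path.stem))


def _law_from_mathml(reaction_el, q, rid, values):
    """Fallback interpretation of a kinetic law without our annotation.

    Recognizes plain products of identifiers (mass action): ``k*A*B`` and
    ``kf*A*B - kr*C``.  Anything else is rejected with the reaction id.
    """
    kl = reaction_el.find(q("kineticLaw"))
    if kl is None:
        raise ModelDefinitionError(f"reaction {rid!r}: no kinetic law")
    math = kl.find(f"{{{MATHML_NS}}}math")
    if math is None or len(math) == 0:
        raise ModelDefinitionError(f"reaction {rid!r}: empty kinetic law")

    def flatten_times(node):
        tag = etree.QName(node).localname
        if tag == "ci":
            return [node.text.strip()]
        if tag == "apply":
            children = list(node)
            op = etree.QName(children[0]).localname
            if op == "times":
                out = []
                for child in children[1:]:
                    out.extend(flatten_times(child))
                return out
            if op == "power":
                base = flatten_times(children[1])
                exp_el = children[2]
                exp = int(float(exp_el.text.strip()))
                return base * exp
        raise ModelDefinitionError(
            f"reaction {rid!r}: unsupported kinetic law term")

    reactant_ids = {s for s, _ in _species_refs(reaction_el, "listOfReactants")}
    product_ids = {s for s, _ in _species_refs(reaction_el, "listOfProducts")}

    expr = math[0]
    tag = etree.QName(expr).localname
    if tag == "apply" and etree.QName(list(expr)[0]).localname == "minus":
        fwd_ids = flatten_times(list(expr)[1])
        rev_ids = flatten_times(list(expr)[2])
        kf = [i for i in fwd_ids if i not in reactant_ids]
        kr = [i for i in rev_ids if i not in product_ids]
        if len(kf) != 1 or len(kr) != 1:
            raise ModelDefinitionError(
                f"reaction {rid!r}: cannot identify kf/kr in kinetic law")
        return RateLaw("mass_action_reversible", (kf[0], kr[0])), ""
    ids = flatten_times(expr)
    non_species = [i for i in ids if i not in reactant_ids]
    species_mods = tuple(i for i in non_species if i not in values)
    ks = [i for i in non_species if i in values]
    if len(ks) != 1:
        raise ModelDefinitionError(
            f"reaction {rid!r}: cannot identify the rate constant")
    return RateLaw("mass_action_irreversible", (ks[0],),
                   modifiers=species_mods), ""
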