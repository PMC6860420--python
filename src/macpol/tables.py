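"""Tabular (TSV) model-definition dialect.

Three tab-separated tables describe a model so that reaction/species/
parameter listings can be transcribed cell-by-cell:

- ``<stem>.species.tsv``: id, group, compartment, initial, buffered, name, notes
- ``<stem>.reactions.tsv``: id, reactants, products, kind, params, regulator,
  modifiers, annotation — reactant/product lists are "A + 2 B" strings
- ``<stem>.parameters.tsv``: label, value, units, provenance

``write_model_tables``/``load_model_tables`` round-trip a ModelDefinition.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import (ModelDefinition, ModelDefinitionError, ParameterSet,
                    RateLaw, ReactionDef, SpeciesDef)

__all__ = ["write_model_tables", "load_model_tables",
           "parse_species_list", "format_species_list"]


def format_species_list(pairs) -> str:
    """(id, coeff) pairs -> "A + 2 B" notation; empty side -> "-"."""
    if not pairs:
        return "-"
    terms = []
    for sp, coeff in pairs:
        terms.append(sp if coeff == 1 else f"{coeff} {sp}")
    return " + ".join(terms)


def parse_species_list(text: str) -> tuple[tuple[str, int], ...]:
    text = (text or "").strip()
    if text in ("", "-"):
        return ()
    out = []
    for term in text.split("+"):
        parts = term.strip().split()
        if len(parts) == 1:
            out.append((parts[0], 1))
        elif len(parts) == 2:
            out.append((parts[1], int(parts[0])))
        else:
            raise ModelDefinitionError(f"malformed species term {term!r}")
    return tuple(out)


def write_model_tables(model: ModelDefinition, stem: str | Path) -> list[Path]:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    sp = pd.DataFrame([{
        "id": s.id, "group": s.group_id, "compartment": s.compartment,
        "initial": s.initial_copies, "buffered": int(s.is_buffered),
        "name": s.display_name, "notes": s.notes,
    } for s in model.species])
    rx = pd.DataFrame([{
        "id": r.id,
        "reactants": format_species_list(r.reactants),
        "products": format_species_list(r.products),
        "kind": r.rate_law.kind,
        "params": ",".join(r.rate_law.param_labels),
        "regulator": r.rate_law.regulator or "-",
        "modifiers": ",".join(r.rate_law.modifiers) or "-",
        "annotation": r.annotation,
    } for r in model.reactions])
    pm = pd.DataFrame([{
        "label": k, "value": v,
        "units": model.parameters.units.get(k, ""),
        "provenance": model.parameters.provenance.get(k, "user"),
    } for k, v in model.parameters.items()])
    paths = []
    for frame, suffix in ((sp, "species"), (rx, "reactions"), (pm, "parameters")):
        path = stem.with_suffix(f".{suffix}.tsv")
        frame.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def load_model_tables(stem: str | Path, name: str | None = None) -> ModelDefinition:
    stem = Path(stem)
    try:
        sp = pd.read_csv(stem.with_suffix(".species.tsv"), sep="\t",
                         keep_default_na=False)
        rx = pd.read_csv(stem.with_suffix(".reactions.tsv"), sep="\t",
                         keep_default_na=False)
        pm = pd.read_csv(stem.with_suffix(".parameters.tsv"), sep="\t",
                         keep_default_na=False)
    except FileNotFoundError as exc:
        raise ModelDefinitionError(f"missing model table: {exc}") from exc

    species = [SpeciesDef(
        id=row["id"], group_id=row["group"], compartment=row["compartment"],
        initial_copies=float(row["initial"]), is_buffered=bool(int(row["buffered"])),
        display_name=str(row.get("name", "")), notes=str(row.get("notes", "")),
    ) for _, row in sp.iterrows()]

    reactions = []
    for _, row in rx.iterrows():
        regulator = None if row["regulator"] in ("-", "") else row["regulator"]
        modifiers = () if row["modifiers"] in ("-", "") else \
            tuple(row["modifiers"].split(","))
        try:
            law = RateLaw(kind=row["kind"],
                          param_labels=tuple(row["params"].split(",")),
                          regulator=regulator, modifiers=modifiers)
            reactions.append(ReactionDef(
                id=row["id"],
                reactants=parse_species_list(row["reactants"]),
                products=parse_species_list(row["products"]),
                rate_law=law, annotation=str(row.get("annotation", "")),
            ))
        except ModelDefinitionError as exc:
            raise ModelDefinitionError(
                f"reaction {row['id']!r}: {exc}") from exc

    params = ParameterSet(
        {row["label"]: float(row["value"]) for _, row in pm.iterrows()},
        units={row["label"]: row["units"] for _, row in pm.iterrows()
               if row["units"]},
        provenance={row["label"]: row["provenance"] for _, row in pm.iterrows()
                    if row["provenance"]},
    )
    return ModelDefinition(species, reactions, params,
                           name=name or stem.name)
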