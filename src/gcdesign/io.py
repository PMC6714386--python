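"""Model serialization: the genome-model JSON dialect and SBML L3 (FBC).

The JSON dialect follows the widely used schema of public genome-scale model
repositories (``id`` / ``metabolites`` / ``reactions`` with ``lower_bound`` /
``upper_bound`` / ``objective_coefficient``), so published models load
unmodified. Package-specific information (reaction tags, explicit carbon
counts) rides in each entry's ``annotation`` object and round-trips exactly.
Unbounded rates are encoded as JSON ``null``.

SBML goes through cobra/libsbml; FBC objectives identify the biomass
reaction unless ``biomass_id`` is given explicitly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from .core import INF, GroundTruth, MetabolicModel, Metabolite, ModelError, Reaction


class FormatError(ValueError):
    """The input file does not parse as the expected model format."""


def _num_out(x: float) -> float | None:
    if x == INF or x == -INF:
        return None
    return x


def _num_in(x, default: float) -> float:
    return default if x is None else float(x)


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    mets = []
    for m in model.metabolites:
        entry: dict = {"id": m.id, "name": m.name, "compartment": m.compartment}
        if m.formula:
            entry["formula"] = m.formula
        if m.n_carbon is not None:
            entry.setdefault("annotation", {})["n_carbon"] = m.n_carbon
        mets.append(entry)
    rxns = []
    for r in model.reactions:
        entry = {
            "id": r.id,
            "name": r.name,
            "metabolites": dict(r.stoichiometry),
            "lower_bound": _num_out(r.lb),
            "upper_bound": _num_out(r.ub),
            "subsystem": r.subsystem,
            "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
        }
        if r.tags:
            entry["annotation"] = {"tags": sorted(r.tags)}
        rxns.append(entry)
    return {
        "id": model.id,
        "metabolites": mets,
        "reactions": rxns,
        "biomass_id": model.biomass_id,
    }


def model_from_dict(data: dict, biomass_id: str | None = None) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                n_carbon=(m.get("annotation") or {}).get("n_carbon"),
            )
            for m in data["metabolites"]
        ]
        rxns = []
        objective_id = None
        for r in data["reactions"]:
            tags = frozenset((r.get("annotation") or {}).get("tags", []))
            rxns.append(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                    lb=_num_in(r.get("lower_bound"), -INF),
                    ub=_num_in(r.get("upper_bound"), INF),
                    subsystem=r.get("subsystem") or "",
                    tags=tags,
                )
            )
            if r.get("objective_coefficient"):
                objective_id = r["id"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed model JSON near element: {exc}") from exc

    model = MetabolicModel(
        id=data.get("id", "model"), metabolites=mets, reactions=rxns
    )
    _finalize(model, biomass_id or data.get("biomass_id"), objective_id)
    return model


def _finalize(
    model: MetabolicModel, biomass_override: str | None, objective_id: str | None
) -> None:
    biomass = biomass_override or objective_id
    if biomass is None:
        for r in model.reactions:
            if "biomass" in r.tags:
                biomass = r.id
                break
    if biomass is None:
        raise ModelError(
            "no biomass reaction: the model declares no objective and no "
            "biomass_id override was given"
        )
    model.biomass_id = biomass
    model.objective_id = objective_id or biomass
    rxn = model.reaction(biomass)
    rxn.tags = rxn.tags | {"biomass"}
    _infer_tags(model)
    model.validate()


def _infer_tags(model: MetabolicModel) -> None:
    """Tag exchanges (single-metabolite), transports (same species in two
    compartments) and the conventional ATPM maintenance reaction when the
    source file carried no explicit tags."""
    for r in model.reactions:
        if r.tags - {"biomass"}:
            continue
        tags = set(r.tags)
        if len(r.stoichiometry) == 1:
            tags.add("exchange")
        else:
            bases = {model.metabolite(mid).base_id() for mid in r.stoichiometry}
            comps = {model.metabolite(mid).compartment for mid in r.stoichiometry}
            if len(comps) > 1 and len(bases) < len(r.stoichiometry):
                tags.add("transport")
        if r.id.upper() in {"ATPM", "NGAM"} or "maintenance" in r.name.lower():
            tags.add("maintenance")
        r.tags = frozenset(tags)


# ---------------------------------------------------------------------------
# SBML via cobra
# ---------------------------------------------------------------------------

def _from_cobra(cmodel, biomass_id: str | None) -> MetabolicModel:
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            formula=m.formula or None,
        )
        for m in cmodel.metabolites
    ]
    rxns = []
    objective_id = None
    for r in cmodel.reactions:
        if r.objective_coefficient:
            objective_id = r.id
        rxns.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lb=float(r.lower_bound),
                ub=float(r.upper_bound),
                subsystem=r.subsystem or "",
            )
        )
    model = MetabolicModel(id=cmodel.id or "model", metabolites=mets, reactions=rxns)
    _finalize(model, biomass_id, objective_id)
    return model


def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cm = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment, formula=m.formula
        )
        cmets[m.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    big = 999999.0  # SBML has no infinity; conventional large bound
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(
            r.id,
            name=r.name,
            lower_bound=max(r.lb, -big),
            upper_bound=min(r.ub, big),
        )
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for r in model.reactions:
        cmodel.reactions.get_by_id(r.id).add_metabolites(
            {cmets[mid]: c for mid, c in r.stoichiometry.items()}
        )
    if model.objective_id:
        cmodel.objective = model.objective_id
    return cmodel


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def load_model(
    path: str | Path, format: str | None = None, biomass_id: str | None = None
) -> MetabolicModel:
    """Load a model from SBML L3-FBC or the JSON genome-model dialect.

    ``format`` is inferred from the suffix when omitted (.xml/.sbml -> sbml,
    .json -> json). The biomass reaction is taken from the declared objective
    unless ``biomass_id`` overrides it; a model with neither raises
    :class:`~gcdesign.core.ModelError`.
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
        return model_from_dict(data, biomass_id=biomass_id)
    if format == "sbml":
        from cobra.io import read_sbml_model

        try:
            cmodel = read_sbml_model(str(path))
        except Exception as exc:
            raise FormatError(f"{path}: SBML parse failure ({exc})") from exc
        return _from_cobra(cmodel, biomass_id)
    raise ValueError(f"unknown format {format!r}")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))
    elif format == "sbml":
        from cobra.io import write_sbml_model

        write_sbml_model(_to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def save_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    data = asdict(gt)
    data["optimal_deletions"] = sorted(gt.optimal_deletions)
    Path(path).write_text(json.dumps(data, indent=1))


def load_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    data["optimal_deletions"] = set(data["optimal_deletions"])
    return GroundTruth(**data)
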