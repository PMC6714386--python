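"""Core stoichiometric-model containers.

A :class:`MetabolicModel` is a plain in-memory description of a metabolic
network: metabolites, reactions with flux bounds (mmol gDW^-1 h^-1), a sparse
stoichiometric matrix ``S`` (|M| x |R|), and a designated biomass reaction.
Negative stoichiometric coefficients denote consumption. A reaction is
reversible iff its lower bound is negative.

Reactions carry a set of tags (``exchange``, ``transport``, ``diffusion``,
``spontaneous``, ``biomass``, ``maintenance``) and a subsystem string; both
drive the deletion-candidate filters used by the strain-design search.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse

INF = math.inf

#: allowed reaction tags
REACTION_TAGS = frozenset(
    {"exchange", "transport", "diffusion", "spontaneous", "biomass", "maintenance"}
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(ValueError):
    """Structural problem in a model (unknown id, bad bounds, ...)."""


def carbon_count(formula: str | None) -> int:
    """Number of carbon atoms in a chemical formula, 0 if absent/unparsable.

    Element tokenization: ``C6H12O6`` -> 6, ``CO2`` -> 1. Charges and group
    parentheses are not supported; genome-model formulas are flat strings.
    """
    if not formula:
        return 0
    n = 0
    for element, count in _FORMULA_TOKEN.findall(formula):
        if element == "C":
            n += int(count) if count else 1
    return n


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    n_carbon: int | None = None  # explicit override; else parsed from formula

    def carbons(self) -> int:
        if self.n_carbon is not None:
            return self.n_carbon
        return carbon_count(self.formula)

    def base_id(self) -> str:
        """Metabolite id with a trailing ``_<compartment>`` suffix stripped."""
        suffix = f"_{self.compartment}"
        if self.compartment and self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        return self.id


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = INF
    tags: frozenset[str] = frozenset()
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ModelError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")
        bad = set(self.tags) - REACTION_TAGS
        if bad:
            raise ModelError(f"reaction {self.id}: unknown tags {sorted(bad)}")
        self.tags = frozenset(self.tags)

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class GroundTruth:
    """Certified optimum of a synthetic fixture's strain-design problem."""

    optimal_deletions: set[str]
    optimal_objective: float
    coupling_class: str  # none | wGC | hGC | sGC
    target_id: str = ""
    mu_fix: float = 0.0
    max_deletions: int = 0


class MetabolicModel:
    """Stoichiometric model with id-indexed metabolites and reactions."""

    def __init__(
        self,
        id: str = "model",
        metabolites: list[Metabolite] | None = None,
        reactions: list[Reaction] | None = None,
        biomass_id: str | None = None,
        objective_id: str | None = None,
    ) -> None:
        self.id = id
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self._met_index: dict[str, int] = {}
        self._rxn_index: dict[str, int] = {}
        for m in metabolites or []:
            self.add_metabolite(m)
        for r in reactions or []:
            self.add_reaction(r)
        self.biomass_id = biomass_id
        self.objective_id = objective_id or biomass_id

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self._met_index[met.id] = len(self.metabolites)
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self._met_index:
                raise ModelError(
                    f"reaction {rxn.id} references unknown metabolite {mid!r}"
                )
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)

    def remove_reactions(self, ids: set[str] | list[str]) -> None:
        drop = set(ids)
        missing = drop - set(self._rxn_index)
        if missing:
            raise ModelError(f"cannot remove unknown reactions {sorted(missing)}")
        self.reactions = [r for r in self.reactions if r.id not in drop]
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if self.biomass_id in drop:
            self.biomass_id = None
        if self.objective_id in drop:
            self.objective_id = None

    def remove_orphan_metabolites(self) -> None:
        used = {mid for r in self.reactions for mid in r.stoichiometry}
        self.metabolites = [m for m in self.metabolites if m.id in used]
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}

    # -- lookup ------------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[mid]]
        except KeyError:
            raise ModelError(f"unknown metabolite {mid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise ModelError(f"unknown reaction {rid!r}") from None

    def has_metabolite(self, mid: str) -> bool:
        return mid in self._met_index

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def metabolite_index(self, mid: str) -> int:
        return self._met_index[mid]

    def reaction_index(self, rid: str) -> int:
        return self._rxn_index[rid]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    # -- matrix views ------------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S as |M| x |R| CSR matrix (rows metabolites, columns reactions)."""
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coeff in rxn.stoichiometry.items():
                rows.append(self._met_index[mid])
                cols.append(j)
                vals.append(float(coeff))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub

    # -- semantics ---------------------------------------------------------
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if "exchange" in r.tags]

    def exchange_for(self, metabolite_id: str) -> Reaction | None:
        """Existing exchange/demand reaction whose sole metabolite matches."""
        for r in self.exchange_reactions():
            if set(r.stoichiometry) == {metabolite_id}:
                return r
        return None

    def import_capacity(self, rxn: Reaction) -> float:
        """Maximum rate at which an exchange reaction can feed its metabolite
        into the network (0 for pure secretion reactions)."""
        (coeff,) = rxn.stoichiometry.values()
        return max(rxn.ub, 0.0) if coeff > 0 else max(-rxn.lb, 0.0)

    def default_uptake_bound(self) -> float:
        """Largest import capacity among carbon-carrying exchange metabolites,
        falling back to the largest capacity of any exchange."""
        caps_c, caps = [], []
        for r in self.exchange_reactions():
            cap = self.import_capacity(r)
            if cap <= 0 or not math.isfinite(cap):
                continue
            (mid,) = r.stoichiometry
            caps.append(cap)
            if self.metabolite(mid).carbons() > 0:
                caps_c.append(cap)
        pool = caps_c or caps
        if not pool:
            raise ModelError("model has no bounded uptake exchange")
        return max(pool)

    def validate(self) -> None:
        for r in self.reactions:
            if "exchange" in r.tags and len(r.stoichiometry) != 1:
                raise ModelError(
                    f"exchange reaction {r.id} touches {len(r.stoichiometry)} metabolites"
                )
        if self.biomass_id is not None and not self.has_reaction(self.biomass_id):
            raise ModelError(f"biomass reaction {self.biomass_id!r} not in model")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            biomass_id=self.biomass_id,
            objective_id=self.objective_id,
        )

    def find_by_base_id(self, base: str, prefer_compartment: str = "c") -> Metabolite | None:
        """Locate a species by compartment-stripped id (e.g. ``atp`` -> atp_c)."""
        hits = [m for m in self.metabolites if m.base_id().lower() == base.lower()]
        if not hits:
            return None
        for m in hits:
            if m.compartment == prefer_compartment:
                return m
        return hits[0]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


def ensure_target_export(
    model: MetabolicModel, metabolite_id: str
) -> tuple[MetabolicModel, str]:
    """Return a model guaranteed to export ``metabolite_id`` and the export id.

    If an exchange/demand reaction for the metabolite already exists the model
    is returned unchanged. Otherwise an irreversible cytosolic demand
    ``met ->`` with bounds [0, +inf) is appended and tagged ``exchange`` (and
    therefore excluded from deletion candidates).
    """
    model.metabolite(metabolite_id)  # raises on unknown id
    existing = model.exchange_for(metabolite_id)
    if existing is not None:
        return model, existing.id
    new = model.copy()
    rid = f"DM_{metabolite_id}"
    if new.has_reaction(rid):  # avoid collision with a non-exchange reaction
        rid = f"DM_{metabolite_id}_gc"
    new.add_reaction(
        Reaction(
            id=rid,
            stoichiometry={metabolite_id: -1.0},
            lb=0.0,
            ub=INF,
            tags=frozenset({"exchange"}),
            name=f"demand ({metabolite_id})",
        )
    )
    return new, rid
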