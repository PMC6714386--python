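"""Model preparation for the strain-design search.

Covers: splitting reversible reactions into irreversible forward/backward
pairs (the max-min reformulation requires all fluxes nonnegative), blocked-
reaction removal by flux variability analysis, deletion-candidate selection
with the standard exclusion rules (exchange / transport / diffusion /
spontaneous / maintenance reactions, excluded subsystems, essential
reactions), and the maintenance-demand edits used in the coupling screens:
the ATP non-growth-associated maintenance (NGAM) bound, virtual NAD(P)H
turnover demands, and the relaxation reactions (unbounded reversible ATP
hydrolysis, free NAD(P)H interconversion, free proton translocation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .core import INF, MetabolicModel, ModelError, Reaction
from .lp import InfeasibleError, optimize_flux

#: subsystems excluded from deletion candidates by default
DEFAULT_EXCLUDED_SUBSYSTEMS = frozenset(
    {
        "cell envelope biosynthesis",
        "membrane lipid metabolism",
        "murein biosynthesis",
        "trna charging",
        "glycerophospholipid metabolism",
    }
)

#: tags that disqualify a reaction from deletion
_NON_DELETABLE_TAGS = {"exchange", "diffusion", "transport", "spontaneous", "maintenance"}

ZERO_TOL = 1e-9
ESSENTIALITY_THRESHOLD = 1e-6  # h^-1; below this a knockout counts as lethal


# ---------------------------------------------------------------------------
# irreversible split
# ---------------------------------------------------------------------------

@dataclass
class IrreversibleModel:
    """Nonnegative-flux model of N reactions mapped onto R reversible parents.

    ``B`` is the {0,1}-valued N x R matrix with ``B[i, k] = 1`` iff
    irreversible reaction i descends from reversible-model reaction k; every
    row has exactly one entry, columns have one (irreversible parent) or two
    (split parent). ``sign[i]`` is +1 for forward copies and -1 for backward
    copies, so net parent flux = sum_i B[i,k] * sign[i] * v[i].
    """

    base: MetabolicModel
    parent_ids: list[str]
    parent_of: dict[str, str]  # irreversible id -> parent id
    sign: dict[str, float]  # irreversible id -> +1 / -1

    @property
    def n_reactions(self) -> int:
        return len(self.base.reactions)

    def mapping_matrix(self) -> sparse.csr_matrix:
        k_index = {k: j for j, k in enumerate(self.parent_ids)}
        rows, cols = [], []
        for i, rxn in enumerate(self.base.reactions):
            rows.append(i)
            cols.append(k_index[self.parent_of[rxn.id]])
        data = np.ones(len(rows))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_reactions, len(self.parent_ids))
        )

    def children(self, parent_id: str) -> list[str]:
        return [rid for rid, pid in self.parent_of.items() if pid == parent_id]

    def net_flux_coefficients(self, parent_id: str) -> dict[str, float]:
        """Functional {irr id: +/-1} whose value is the parent's net flux."""
        return {rid: self.sign[rid] for rid in self.children(parent_id)}


def split_reversible(model: MetabolicModel) -> IrreversibleModel:
    """Split every reversible reaction (lb < 0) into ``<id>_fwd``/``<id>_rev``.

    The backward copy carries the negated stoichiometry with bounds
    [max(-ub, 0), -lb]; the forward copy keeps [max(lb, 0), max(ub, 0)].
    Irreversible reactions (including those with a positive lower bound such
    as the maintenance demand) are copied unchanged.
    """
    out = MetabolicModel(id=model.id, metabolites=[m for m in model.copy().metabolites])
    parent_of: dict[str, str] = {}
    sign: dict[str, float] = {}
    for r in model.reactions:
        if r.lb >= 0:
            out.add_reaction(r.copy())
            parent_of[r.id] = r.id
            sign[r.id] = 1.0
        else:
            fwd = r.copy()
            fwd.id = f"{r.id}_fwd"
            fwd.lb, fwd.ub = 0.0, max(r.ub, 0.0)
            rev = Reaction(
                id=f"{r.id}_rev",
                name=r.name,
                stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                lb=max(-r.ub, 0.0),
                ub=-r.lb,
                tags=r.tags,
                subsystem=r.subsystem,
            )
            out.add_reaction(fwd)
            out.add_reaction(rev)
            parent_of[fwd.id] = r.id
            parent_of[rev.id] = r.id
            sign[fwd.id] = 1.0
            sign[rev.id] = -1.0
    biomass = model.biomass_id
    if biomass is not None and not out.has_reaction(biomass):
        biomass = f"{biomass}_fwd"
    out.biomass_id = biomass
    out.objective_id = biomass
    return IrreversibleModel(
        base=out, parent_ids=model.reaction_ids, parent_of=parent_of, sign=sign
    )


# ---------------------------------------------------------------------------
# FVA and blocked-reaction removal
# ---------------------------------------------------------------------------

def flux_variability(
    model: MetabolicModel, fixed: dict[str, float] | None = None
) -> pd.DataFrame:
    """Per-reaction feasibility flux ranges (no objective is optimized).

    Returns a DataFrame indexed by reaction id with ``min``/``max`` columns.
    Raises :class:`~gcdesign.lp.InfeasibleError` when the model admits no
    steady-state flux under the fixed assignments.
    """
    rows = {}
    for r in model.reactions:
        lo = optimize_flux(model, r.id, "min", fixed=fixed).objective
        hi = optimize_flux(model, r.id, "max", fixed=fixed).objective
        rows[r.id] = (lo, hi)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["min", "max"])


def remove_blocked(model: MetabolicModel, tol: float = ZERO_TOL) -> MetabolicModel:
    """Drop reactions whose FVA range is (0, 0), then orphaned metabolites."""
    ranges = flux_variability(model)
    blocked = ranges.index[
        (ranges["min"].abs() < tol) & (ranges["max"].abs() < tol)
    ].tolist()
    out = model.copy()
    if blocked:
        out.remove_reactions(blocked)
        out.remove_orphan_metabolites()
    return out


# ---------------------------------------------------------------------------
# deletion candidates
# ---------------------------------------------------------------------------

@dataclass
class ExclusionRules:
    excluded_subsystems: frozenset[str] = DEFAULT_EXCLUDED_SUBSYSTEMS
    excluded_tags: frozenset[str] = frozenset(_NON_DELETABLE_TAGS)
    viability_threshold: float = ESSENTIALITY_THRESHOLD


def select_candidates(
    model: MetabolicModel, rules: ExclusionRules | None = None
) -> set[str]:
    """Reactions eligible for deletion in the strain-design search.

    Excluded: tagged exchange/diffusion/transport/spontaneous/maintenance,
    members of excluded subsystems, reactions with a positive lower bound
    (deletion would contradict the bound), the biomass reaction, and
    essential reactions (single knockout drops maximal growth below the
    viability threshold).
    """
    rules = rules or ExclusionRules()
    excluded_subsystems = {s.lower() for s in rules.excluded_subsystems}
    candidates = set()
    for r in model.reactions:
        if r.tags & rules.excluded_tags or "biomass" in r.tags:
            continue
        if r.id == model.biomass_id:
            continue
        if r.subsystem.lower() in excluded_subsystems:
            continue
        if r.lb > 0:
            continue
        try:
            growth = optimize_flux(model, model.biomass_id, "max", knockouts={r.id})
        except InfeasibleError:
            continue  # knockout lethal outright (e.g. maintenance unsatisfiable)
        if growth.objective < rules.viability_threshold:
            continue
        candidates.add(r.id)
    return candidates


# ---------------------------------------------------------------------------
# maintenance demands and relaxations
# ---------------------------------------------------------------------------

#: conventional species base ids
_ATP, _ADP, _H2O, _PI, _H = "atp", "adp", "h2o", "pi", "h"

STANDARD_NGAM = 8.39  # mmol gDW^-1 h^-1, E. coli default ATP maintenance


def find_maintenance_reaction(model: MetabolicModel) -> Reaction | None:
    for r in model.reactions:
        if "maintenance" in r.tags:
            return r
    return None


def set_ngam(model: MetabolicModel, lower: float) -> MetabolicModel:
    """Set (or create) the ATP maintenance demand and pin its lower bound.

    A fresh ATPM reaction is the hydrolysis ``atp + h2o -> adp + h + pi``
    when those species exist, else a bare ATP drain.
    """
    if lower < 0:
        raise ValueError(f"NGAM lower bound must be nonnegative, got {lower}")
    out = model.copy()
    rxn = find_maintenance_reaction(out)
    if rxn is None:
        atp = out.find_by_base_id(_ATP)
        if atp is None:
            raise ModelError("cannot create ATPM: no ATP species in model")
        partners = {
            base: out.find_by_base_id(base, prefer_compartment=atp.compartment)
            for base in (_ADP, _H2O, _PI, _H)
        }
        if all(partners.values()):
            stoich = {
                atp.id: -1.0,
                partners[_H2O].id: -1.0,
                partners[_ADP].id: 1.0,
                partners[_H].id: 1.0,
                partners[_PI].id: 1.0,
            }
        else:
            stoich = {atp.id: -1.0}
        rxn = Reaction(
            id="ATPM",
            name="ATP maintenance requirement",
            stoichiometry=stoich,
            lb=0.0,
            ub=INF,
            tags=frozenset({"maintenance"}),
        )
        out.add_reaction(rxn)
    rxn.lb = lower
    if rxn.ub < lower:
        rxn.ub = INF
    return out


_REDOX_PAIRS = {
    "NADH": ("nadh", "nad", -1.0),  # consume NADH: NADH -> NAD+ + H+
    "NAD": ("nad", "nadh", 1.0),  # consume NAD+: NAD+ + H+ -> NADH
    "NADPH": ("nadph", "nadp", -1.0),
    "NADP": ("nadp", "nadph", 1.0),
}


def add_redox_ngam(
    model: MetabolicModel, cofactor: str, lo: float, hi: float
) -> MetabolicModel:
    """Add a virtual NAD(P)H turnover demand consuming the named cofactor.

    The half-reaction is mass- but not charge-balanced (electrons go to an
    imaginary acceptor/donor): e.g. for ``NADH`` an irreversible
    ``nadh -> nad + h`` with flux in [lo, hi]. Raises when the cofactor
    species is absent from the model.
    """
    if lo > hi:
        raise ValueError(f"invalid flux range [{lo}, {hi}]")
    key = cofactor.upper()
    if key not in _REDOX_PAIRS:
        raise ValueError(f"unknown cofactor {cofactor!r}; expected one of {sorted(_REDOX_PAIRS)}")
    consumed_base, produced_base, h_coeff = _REDOX_PAIRS[key]
    consumed = model.find_by_base_id(consumed_base)
    if consumed is None:
        raise ModelError(f"cofactor species {consumed_base!r} absent from model")
    produced = model.find_by_base_id(produced_base, prefer_compartment=consumed.compartment)
    if produced is None:
        raise ModelError(f"cofactor species {produced_base!r} absent from model")
    out = model.copy()
    stoich = {consumed.id: -1.0, produced.id: 1.0}
    proton = out.find_by_base_id(_H, prefer_compartment=consumed.compartment)
    if proton is not None:
        # nad(p) + h -> nad(p)h direction consumes the proton, reverse releases it
        stoich[proton.id] = -h_coeff
    out.add_reaction(
        Reaction(
            id=f"NGAM_{key}",
            name=f"virtual {key} turnover demand",
            stoichiometry=stoich,
            lb=lo,
            ub=hi,
            tags=frozenset({"maintenance"}),
        )
    )
    return out


@dataclass
class RelaxationSpec:
    """Which energy/redox/proton constraints to relax in a screen."""

    atpm_reversible_unbounded: bool = False
    free_nadh: bool = False
    free_nadph: bool = False
    free_proton_translocation: bool = False

    def any(self) -> bool:
        return (
            self.atpm_reversible_unbounded
            or self.free_nadh
            or self.free_nadph
            or self.free_proton_translocation
        )

    def label(self) -> str:
        parts = []
        if self.atpm_reversible_unbounded:
            parts.append("atpm")
        if self.free_nadh:
            parts.append("nadh")
        if self.free_nadph:
            parts.append("nadph")
        if self.free_proton_translocation:
            parts.append("h+")
        return "+".join(parts) or "none"


def _free_interconversion(model: MetabolicModel, red_base: str, ox_base: str, rid: str) -> None:
    red = model.find_by_base_id(red_base)
    ox = model.find_by_base_id(ox_base, prefer_compartment=red.compartment if red else "c")
    if red is None or ox is None:
        raise ModelError(f"species for {rid} missing ({red_base}/{ox_base})")
    stoich = {ox.id: -1.0, red.id: 1.0}
    proton = model.find_by_base_id(_H, prefer_compartment=red.compartment)
    if proton is not None:
        stoich[proton.id] = -1.0
    model.add_reaction(
        Reaction(id=rid, stoichiometry=stoich, lb=-INF, ub=INF, name=rid)
    )


def apply_relaxations(model: MetabolicModel, spec: RelaxationSpec) -> MetabolicModel:
    """Relax energy/redox/proton constraints per the spec flags.

    * ``atpm_reversible_unbounded``: ATPM bounds set to (-inf, +inf), i.e.
      the network may freely phosphorylate ADP to ATP and vice versa.
    * ``free_nadh`` / ``free_nadph``: unbounded reversible interconversion
      ``nad(p) + h <-> nad(p)h`` added.
    * ``free_proton_translocation``: unbounded ``h_ex <-> h_in`` exchange
      across the membrane added.
    """
    if not spec.any():
        raise ValueError("RelaxationSpec has no flag set")
    out = model.copy()
    if spec.atpm_reversible_unbounded:
        rxn = find_maintenance_reaction(out)
        if rxn is None:
            raise ModelError("no maintenance (ATPM) reaction to relax")
        rxn.ub = INF
        rxn.lb = -INF
    if spec.free_nadh:
        _free_interconversion(out, "nadh", "nad", "FREE_NADH")
    if spec.free_nadph:
        _free_interconversion(out, "nadph", "nadp", "FREE_NADPH")
    if spec.free_proton_translocation:
        h_in = out.find_by_base_id(_H, prefer_compartment="c")
        h_ex = None
        if h_in is not None:
            for m in out.metabolites:
                if m.base_id().lower() == _H and m.compartment != h_in.compartment:
                    h_ex = m
                    break
        if h_in is None or h_ex is None:
            raise ModelError("proton species in two compartments required for H+ relaxation")
        out.add_reaction(
            Reaction(
                id="FREE_H_TRANSLOCATION",
                stoichiometry={h_ex.id: -1.0, h_in.id: 1.0},
                lb=-INF,
                ub=INF,
                name="free proton translocation",
            )
        )
    return out
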