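"""Mechanistic probes for growth-coupling designs.

Three questions about *why* a deletion set couples production to growth:

1. **Biomass precursor availability** — after singularizing the biomass
   equation into independent precursor drains, can the mutant still make
   each precursor when target production is forced to zero? A blocked
   precursor means the design couples production directly to biomass
   synthesis.
2. **ATP synthesis capability (ATPsc)** — the change of the maximal flux
   through the ATP maintenance reaction per unit of target production rate;
   positive values mark products whose synthesis pathway is a net ATP
   source. Normalizing by the product's carbon count (ATPcsc) makes values
   comparable across metabolites and induces the "energy hierarchy".
3. **Relaxation screen** — recompute the coupling strength of each design
   after relaxing the energy/redox/proton constraints (unbounded reversible
   ATP hydrolysis, free NAD(P)H interconversion, free proton translocation);
   couplings that survive are stoichiometric rather than cofactor-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MetabolicModel, ModelError, Reaction, ensure_target_export
from .envelope import GcsResult, gcs, production_envelope
from .lp import InfeasibleError, max_growth, optimize_flux
from .prep import RelaxationSpec, apply_relaxations, find_maintenance_reaction

#: reactant -> product couplings merged into one mass-balanced drain
DEFAULT_COUPLED_PAIRS = {
    "atp": "adp",
    "nad": "nadh",
    "nadp": "nadph",
}

#: byproducts of biomass synthesis treated as freely available
DEFAULT_FREE_PRODUCTS = frozenset({"h2o", "pi", "h", "ppi"})

_ACCESS_TOL = 1e-9


@dataclass
class BiomassPrecursor:
    metabolite_id: str
    coeff: float
    side: str  # reactant | product
    paired_with: str | None = None
    drain_id: str = ""


@dataclass
class AtpscResult:
    metabolite_id: str
    atpsc: float  # mean slope d(max ATPM)/d(v_target) across growth grid
    atpcsc: float  # atpsc / carbon count
    per_growth: dict[float, float] = field(default_factory=dict)
    mean: float = 0.0
    sd: float = 0.0
    n_carbon: int = 0
    skipped_mu: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# biomass singularization + precursor probe
# ---------------------------------------------------------------------------

def singularize_biomass(
    model: MetabolicModel,
    coupled_pairs: dict[str, str] | None = None,
    free_products: frozenset[str] | None = None,
) -> tuple[MetabolicModel, list[BiomassPrecursor]]:
    """Replace the biomass equation by independent precursor drains.

    Every reactant M (coefficient v_m) becomes an unbounded drain
    ``v_m M ->``; when its consumption is paired with production of a
    partner N (e.g. ATP/ADP) the drain is the mass-balanced
    ``v_m M -> v_n N``. Remaining products become sources ``-> v_n N``.
    The original biomass reaction is removed.
    """
    if model.biomass_id is None or not model.has_reaction(model.biomass_id):
        raise ModelError("no biomass reaction present to singularize")
    pairs = DEFAULT_COUPLED_PAIRS if coupled_pairs is None else coupled_pairs
    free = DEFAULT_FREE_PRODUCTS if free_products is None else free_products

    out = model.copy()
    biomass = out.reaction(out.biomass_id)
    reactants = {m: -c for m, c in biomass.stoichiometry.items() if c < 0}
    products = {m: c for m, c in biomass.stoichiometry.items() if c > 0}

    base_of = {m.id: m.base_id().lower() for m in out.metabolites}
    precursors: list[BiomassPrecursor] = []
    used_products: set[str] = set()

    for mid, v_m in sorted(reactants.items()):
        partner = None
        want = pairs.get(base_of[mid])
        if want:
            for pid in products:
                if base_of[pid] == want and pid not in used_products:
                    partner = pid
                    break
        stoich = {mid: -v_m}
        if partner is not None:
            stoich[partner] = products[partner]
            used_products.add(partner)
        drain_id = f"BPS_{mid}"
        out.add_reaction(
            Reaction(
                id=drain_id,
                stoichiometry=stoich,
                lb=0.0,
                ub=float("inf"),
                name=f"precursor drain ({mid})",
            )
        )
        precursors.append(
            BiomassPrecursor(
                metabolite_id=mid,
                coeff=v_m,
                side="reactant",
                paired_with=partner,
                drain_id=drain_id,
            )
        )

    for pid, v_n in sorted(products.items()):
        if pid in used_products or base_of[pid] in free:
            if pid not in used_products:
                out.add_reaction(
                    Reaction(
                        id=f"BPS_src_{pid}",
                        stoichiometry={pid: v_n},
                        lb=0.0,
                        ub=float("inf"),
                        name=f"biomass byproduct source ({pid})",
                    )
                )
            continue
        src_id = f"BPS_src_{pid}"
        out.add_reaction(
            Reaction(
                id=src_id,
                stoichiometry={pid: v_n},
                lb=0.0,
                ub=float("inf"),
                name=f"biomass byproduct source ({pid})",
            )
        )
        precursors.append(
            BiomassPrecursor(
                metabolite_id=pid, coeff=v_n, side="product", drain_id=src_id
            )
        )

    bm_id = out.biomass_id
    out.remove_reactions({bm_id})
    out.remove_orphan_metabolites()
    out.biomass_id = None
    out.objective_id = None
    return out, [p for p in precursors if p.side == "reactant"]


def precursor_availability(
    model: MetabolicModel,
    deletions: set[str] | frozenset[str],
    target_id: str,
) -> tuple[pd.Series, float]:
    """Which biomass precursors remain synthesizable when the target cannot
    be produced, under the given deletions.

    Accepts either a model still carrying its biomass reaction (it is
    singularized here) or an already singularized model plus its drains. The
    ATP maintenance lower bound is relaxed to zero during the probe so that
    the maintenance demand itself cannot mask the deletions' effect. Returns
    a boolean Series per precursor metabolite and the accessible fraction.
    """
    if model.biomass_id is not None and model.has_reaction(model.biomass_id):
        probe, precursors = singularize_biomass(model)
    else:
        probe = model.copy()
        precursors = [
            BiomassPrecursor(
                metabolite_id=r.id[len("BPS_"):], coeff=1.0, side="reactant",
                drain_id=r.id,
            )
            for r in probe.reactions
            if r.id.startswith("BPS_") and not r.id.startswith("BPS_src_")
        ]
        if not precursors:
            raise ModelError("model is neither biomass-carrying nor singularized")
    maint = find_maintenance_reaction(probe)
    if maint is not None and maint.lb > 0:
        maint.lb = 0.0
    if not probe.has_reaction(target_id):
        raise ModelError(f"target export {target_id!r} not in model")

    fixed = {target_id: 0.0}
    knockouts = set(deletions)
    access = {}
    for prec in precursors:
        try:
            vmax = optimize_flux(
                probe, prec.drain_id, "max", fixed=fixed, knockouts=knockouts
            ).objective
        except InfeasibleError:
            vmax = 0.0
        access[prec.metabolite_id] = bool(vmax > _ACCESS_TOL)
    series = pd.Series(access, name="accessible")
    fraction = float(series.mean()) if len(series) else 1.0
    return series, fraction


# ---------------------------------------------------------------------------
# ATP synthesis capability
# ---------------------------------------------------------------------------

def atpsc(
    model: MetabolicModel,
    target_id: str,
    mu_grid: list[float] | np.ndarray | None = None,
    step: float = 1.0,
    n_carbon: int | None = None,
) -> AtpscResult:
    """ATP synthesis capability of a target export reaction.

    For each growth rate mu in the grid, biomass is pinned to mu and the
    maximal ATP-maintenance flux is computed with the target rate fixed to 0
    and to ``step``; the slope of the two is the ATPsc at that growth rate.
    The default grid is 11 evenly spaced points over [0, 0.95 mu_max].
    Growth rates at which the target rate ``step`` is infeasible are skipped
    and recorded.
    """
    maint = find_maintenance_reaction(model)
    if maint is None:
        raise ModelError("model has no ATP maintenance reaction")
    if not np.isinf(maint.ub):
        raise ModelError("ATPM upper bound must be free for the ATPsc probe")
    target = model.reaction(target_id)
    (target_met,) = target.stoichiometry
    if n_carbon is None:
        n_carbon = model.metabolite(target_met).carbons()
    if mu_grid is None:
        mu_max = max_growth(model)
        mu_grid = np.linspace(0.0, 0.95 * mu_max, 11)

    per_growth: dict[float, float] = {}
    skipped: list[float] = []
    for mu in np.asarray(mu_grid, dtype=float):
        try:
            at_zero = optimize_flux(
                model, maint.id, "max",
                fixed={model.biomass_id: float(mu), target_id: 0.0},
            ).objective
            at_step = optimize_flux(
                model, maint.id, "max",
                fixed={model.biomass_id: float(mu), target_id: step},
            ).objective
        except InfeasibleError:
            skipped.append(float(mu))
            continue
        per_growth[float(mu)] = (at_step - at_zero) / step
    if not per_growth:
        raise InfeasibleError(
            f"target {target_id} infeasible at every growth rate probed"
        )
    slopes = np.array(list(per_growth.values()))
    mean = float(slopes.mean())
    sd = float(slopes.std())
    atpcsc = mean / n_carbon if n_carbon > 0 else float("nan")
    return AtpscResult(
        metabolite_id=target_met,
        atpsc=mean,
        atpcsc=atpcsc,
        per_growth=per_growth,
        mean=mean,
        sd=sd,
        n_carbon=n_carbon,
        skipped_mu=skipped,
    )


def energy_hierarchy(
    model: MetabolicModel,
    metabolite_ids: list[str],
    mu_grid: list[float] | None = None,
    step: float = 1.0,
    carbon_overrides: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Rank metabolites by ATPcsc (rank 1 = highest; ties share a rank).

    Each metabolite is given an export via :func:`ensure_target_export`
    before probing. Returns a DataFrame indexed by metabolite id with
    ``atpsc``, ``atpcsc``, ``sd`` and dense ``rank`` columns, ordered by
    rank then id.
    """
    carbon_overrides = carbon_overrides or {}
    rows = {}
    for mid in metabolite_ids:
        probed, export_id = ensure_target_export(model, mid)
        res = atpsc(
            probed, export_id, mu_grid=mu_grid, step=step,
            n_carbon=carbon_overrides.get(mid),
        )
        rows[mid] = {"atpsc": res.atpsc, "atpcsc": res.atpcsc, "sd": res.sd}
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    # dense ranks on rounded values so LP noise cannot split a tie
    frame["rank"] = (-frame["atpcsc"].round(9)).rank(method="dense").astype(int)
    return frame.sort_values("rank", kind="stable")


# ---------------------------------------------------------------------------
# relaxation screen
# ---------------------------------------------------------------------------

def relaxation_screen(
    model: MetabolicModel,
    strategies: list[frozenset[str]] | list[set[str]],
    specs: list[RelaxationSpec],
    target_id: str,
    n_points: int = 51,
    uptake_bound: float | None = None,
) -> pd.DataFrame:
    """GCS of each deletion strategy under each constraint relaxation.

    For every spec the wild-type envelope is recomputed on the *relaxed*
    model so mutant and baseline see identical constraints. Cells whose
    relaxation cannot be applied (missing species) hold NaN; the full
    :class:`~gcdesign.envelope.GcsResult` objects are attached in
    ``frame.attrs["results"]``.
    """
    if not specs:
        raise ValueError("at least one relaxation spec required")
    if uptake_bound is None:
        uptake_bound = model.default_uptake_bound()
    labels = [spec.label() for spec in specs]
    strategy_keys = ["+".join(sorted(s)) or "WT" for s in strategies]
    values = pd.DataFrame(
        np.nan, index=strategy_keys, columns=labels, dtype=float
    )
    results: dict[tuple[str, str], GcsResult | None] = {}
    for spec, label in zip(specs, labels):
        try:
            relaxed = apply_relaxations(model, spec)
            wt_env = production_envelope(
                relaxed, target_id, n_points=n_points, uptake_bound=uptake_bound
            )
        except (ModelError, InfeasibleError):
            for key in strategy_keys:
                results[(key, label)] = None
            continue
        for strat, key in zip(strategies, strategy_keys):
            try:
                mut_env = production_envelope(
                    relaxed, target_id, deletions=set(strat),
                    n_points=n_points, uptake_bound=uptake_bound,
                )
                res = gcs(wt_env, mut_env)
            except (InfeasibleError, ValueError):
                results[(key, label)] = None
                continue
            results[(key, label)] = res
            values.loc[key, label] = res.gcs
    values.attrs["results"] = results
    return values
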