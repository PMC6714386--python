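"""Synthetic fixture networks with certified ground-truth coupling designs.

The named fixtures embody the minimal mechanism behind strong growth
coupling: a substrate feeding both biomass formation (which consumes ATP)
and parallel ATP-regeneration routes, one of them emitting a byproduct P,
plus a positive ATP maintenance demand. Deleting the byproduct-free ATP
route forces all maintenance and growth ATP through the byproduct route, so
P secretion becomes unavoidable at every metabolic state — strong coupling.

* ``T1`` — byproduct route yields 1 ATP + 1 P per substrate. Optimum for
  target P at mu_fix = 2, K = 1: delete R_atp_clean, guaranteed rate
  1 + mu = 3.
* ``T2`` — byproduct route yields 2 ATP + 1 P; the optimum halves to
  (1 + mu) / 2 = 1.5.
* ``T3`` — T1 plus an ATP-costing export S + ATP -> Q (negative ATP
  synthesis capability for Q).
* ``random`` — seeded compositions of the same motifs (parallel ATP routes
  with varying yields/byproducts, optional reversible shuttle, optional
  costly export).

Every returned :class:`~gcdesign.core.GroundTruth` is certified at build
time by the exhaustive enumeration oracle; generation fails on mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import INF, GroundTruth, MetabolicModel, Metabolite, Reaction
from .envelope import classify, production_envelope
from .gcopt import GcOptProblem, brute_force
from .lp import InfeasibleError
from .prep import select_candidates, split_reversible

FIXTURE_NAMES = ("T1", "T2", "T3", "random")


@dataclass
class RandomFixtureParams:
    n_atp_routes: int = 3
    max_reactions: int = 15
    uptake: float = 10.0
    mu_fix: float | None = None  # default: 50% of WT max growth
    max_deletions: int = 1
    with_shuttle: bool = True
    with_costly_export: bool = False


def _base_fixture(name: str, atp_per_by: float) -> MetabolicModel:
    mets = [
        Metabolite("S", name="substrate", formula="C6H12O6"),
        Metabolite("ATP", name="energy carrier"),
        Metabolite("P", name="byproduct", formula="C3H6O3"),
        Metabolite("BM", name="biomass"),
    ]
    rxns = [
        Reaction("uptake", {"S": 1.0}, lb=0.0, ub=10.0, tags=frozenset({"exchange"})),
        Reaction("R_bm", {"S": -1.0, "ATP": -1.0, "BM": 1.0}, lb=0.0, ub=INF,
                 tags=frozenset({"biomass"})),
        Reaction("R_atp_clean", {"S": -1.0, "ATP": 1.0}, lb=0.0, ub=INF),
        Reaction("R_atp_by", {"S": -1.0, "ATP": atp_per_by, "P": 1.0}, lb=0.0, ub=INF),
        Reaction("ATPM", {"ATP": -1.0}, lb=1.0, ub=INF,
                 tags=frozenset({"maintenance"})),
        Reaction("EX_P", {"P": -1.0}, lb=0.0, ub=INF, tags=frozenset({"exchange"})),
        Reaction("EX_BM", {"BM": -1.0}, lb=0.0, ub=INF, tags=frozenset({"exchange"})),
    ]
    return MetabolicModel(id=name, metabolites=mets, reactions=rxns,
                          biomass_id="R_bm", objective_id="R_bm")


def _random_fixture(seed: int, params: RandomFixtureParams) -> tuple[MetabolicModel, float, int]:
    rng = np.random.default_rng(seed)
    mets = [
        Metabolite("S", name="substrate", formula="C6H12O6"),
        Metabolite("ATP", name="energy carrier"),
        Metabolite("P", name="byproduct", formula="C3H6O3"),
        Metabolite("BM", name="biomass"),
    ]
    uptake = float(rng.choice([8.0, 10.0, 12.0]))
    atpm_lb = float(rng.choice([0.5, 1.0, 2.0]))
    bm_atp = float(rng.choice([1.0, 2.0]))
    rxns = [
        Reaction("uptake", {"S": 1.0}, lb=0.0, ub=uptake, tags=frozenset({"exchange"})),
        Reaction("R_bm", {"S": -1.0, "ATP": -bm_atp, "BM": 1.0}, lb=0.0, ub=INF,
                 tags=frozenset({"biomass"})),
        Reaction("ATPM", {"ATP": -1.0}, lb=atpm_lb, ub=INF,
                 tags=frozenset({"maintenance"})),
        Reaction("EX_P", {"P": -1.0}, lb=0.0, ub=INF, tags=frozenset({"exchange"})),
        Reaction("EX_BM", {"BM": -1.0}, lb=0.0, ub=INF, tags=frozenset({"exchange"})),
    ]
    n_routes = int(rng.integers(2, params.n_atp_routes + 1))
    by_route = int(rng.integers(0, n_routes))  # at least one route emits P
    for r in range(n_routes):
        atp_yield = float(rng.choice([1.0, 2.0, 3.0]))
        stoich = {"S": -1.0, "ATP": atp_yield}
        if r == by_route or rng.random() < 0.3:
            stoich["P"] = 1.0
        rxns.append(Reaction(f"R_atp_{r}", stoich, lb=0.0, ub=INF))
    model = MetabolicModel(id=f"random_{seed}", metabolites=mets, reactions=rxns,
                           biomass_id="R_bm", objective_id="R_bm")
    if params.with_shuttle and rng.random() < 0.7:
        model.add_metabolite(Metabolite("C", name="shuttle intermediate"))
        model.add_reaction(Reaction("shuttle", {"S": -1.0, "C": 1.0}, lb=-uptake, ub=uptake))
        model.add_reaction(Reaction("R_atp_shuttle", {"C": -1.0, "ATP": 1.0}, lb=0.0, ub=INF))
    if params.with_costly_export and rng.random() < 0.5:
        model.add_metabolite(Metabolite("Q", name="costly export", formula="C2H4O2"))
        model.add_reaction(Reaction("R_q", {"S": -1.0, "ATP": -1.0, "Q": 1.0}, lb=0.0, ub=INF))
        model.add_reaction(Reaction("EX_Q", {"Q": -1.0}, lb=0.0, ub=INF,
                                    tags=frozenset({"exchange"})))
    if len(model.reactions) > params.max_reactions:
        raise ValueError("random fixture exceeds the reaction budget")
    return model, uptake, int(rng.integers(1, params.max_deletions + 1))


def _certify(
    model: MetabolicModel, target_id: str, mu_fix: float, max_deletions: int
) -> GroundTruth:
    """Compute and certify the fixture's optimum with the enumeration oracle."""
    irr = split_reversible(model)
    candidates = select_candidates(model)
    problem = GcOptProblem(
        model=irr,
        target_id=target_id,
        biomass_id=model.biomass_id,
        mu_fix=mu_fix,
        max_deletions=max_deletions,
        candidates=candidates,
    )
    best, objective = brute_force(problem)
    env = production_envelope(model, target_id, deletions=set(best.deleted), n_points=21)
    klass = classify(env)
    return GroundTruth(
        optimal_deletions=set(best.deleted),
        optimal_objective=objective,
        coupling_class=klass,
        target_id=target_id,
        mu_fix=mu_fix,
        max_deletions=max_deletions,
    )


def make_fixture(
    name: str,
    seed: int = 0,
    params: RandomFixtureParams | None = None,
) -> tuple[MetabolicModel, GroundTruth]:
    """Build a named or random fixture plus its certified ground truth."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    params = params or RandomFixtureParams()

    if name in {"T1", "T2"}:
        model = _base_fixture(name, atp_per_by=1.0 if name == "T1" else 2.0)
        gt = _certify(model, "EX_P", mu_fix=2.0, max_deletions=1)
        expected = {
            "T1": ({"R_atp_clean"}, 3.0),
            "T2": ({"R_atp_clean"}, 1.5),
        }[name]
        if gt.optimal_deletions != expected[0] or not math.isclose(
            gt.optimal_objective, expected[1], abs_tol=1e-6
        ):
            raise AssertionError(
                f"{name} ground truth failed certification: got "
                f"{gt.optimal_deletions} @ {gt.optimal_objective}"
            )
        return model, gt

    if name == "T3":
        model = _base_fixture("T3", atp_per_by=1.0)
        model.add_metabolite(Metabolite("Q", name="costly export", formula="C2H4O2"))
        model.add_reaction(
            Reaction("R_q", {"S": -1.0, "ATP": -1.0, "Q": 1.0}, lb=0.0, ub=INF)
        )
        model.add_reaction(
            Reaction("EX_Q", {"Q": -1.0}, lb=0.0, ub=INF, tags=frozenset({"exchange"}))
        )
        gt = _certify(model, "EX_P", mu_fix=2.0, max_deletions=1)
        return model, gt

    # random
    for attempt in range(20):
        try:
            model, uptake, k = _random_fixture(seed + 1_000_003 * attempt, params)
            mu_fix = params.mu_fix
            if mu_fix is None:
                from .lp import max_growth

                mu_max = max_growth(model)
                if mu_max < 1e-3:
                    continue
                mu_fix = 0.5 * mu_max
            gt = _certify(model, "EX_P", mu_fix=mu_fix, max_deletions=k)
            return model, gt
        except (InfeasibleError, ValueError):
            continue
    raise RuntimeError(f"could not build a feasible random fixture for seed {seed}")
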