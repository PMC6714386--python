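"""The bilevel strain-design search: maximize the minimally guaranteed
production rate at a fixed growth rate over reaction-deletion sets.

The outer problem picks a boolean activity vector ``y`` over the reversible
model's reactions (at most K zeros, restricted to a candidate set); the inner
problem is the LP

    min v_t   s.t.  S v = 0,  v_bm = mu_fix,  lb_i z_i <= v_i <= ub_i z_i,

on the irreversible (split) model, where ``z = B y`` maps reaction activity
onto the split copies. The bilevel max-min collapses to a single-level MILP
by embedding the inner LP's dual and tying primal and dual objectives with a
strong-duality equality; products of duals with the binary activities are
linearized with big-M constraints. Every incumbent is re-verified by an
independent inner LP solve to guard against big-M artifacts.

An exhaustive :func:`brute_force` enumerator over deletion subsets serves as
the independent oracle for small problems.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .lp import InfeasibleError, solve_lp
from .prep import IrreversibleModel

VERIFY_TOL = 1e-5
_DEFAULT_FALLBACK_CAP = 1000.0


@dataclass
class GcOptProblem:
    """A strain-design instance on an irreversible model.

    ``target_id``, ``biomass_id`` and ``candidates`` refer to reactions of
    the *reversible* parent model; deletion of a parent zeroes all of its
    split copies simultaneously.
    """

    model: IrreversibleModel
    target_id: str
    biomass_id: str
    mu_fix: float
    max_deletions: int
    candidates: set[str]

    def __post_init__(self) -> None:
        known = set(self.model.parent_ids)
        for rid in (self.target_id, self.biomass_id):
            if rid not in known:
                raise ValueError(f"{rid!r} is not a reversible-model reaction id")
        stray = self.candidates - known
        if stray:
            raise ValueError(f"candidates not in model: {sorted(stray)}")
        if self.mu_fix < 0:
            raise ValueError("mu_fix must be nonnegative")
        if self.max_deletions < 0:
            raise ValueError("max_deletions must be nonnegative")
        for rid in self.candidates:
            for child in self.model.children(rid):
                if self.model.base.reaction(child).lb > 0:
                    raise ValueError(
                        f"candidate {rid} carries a positive lower bound and is not deletable"
                    )


@dataclass
class DeletionStrategy:
    deleted: frozenset[str]
    objective: float

    def y(self, parent_ids: list[str]) -> np.ndarray:
        return np.array([0.0 if k in self.deleted else 1.0 for k in parent_ids])


@dataclass
class SolveReport:
    status: str  # optimal | feasible_gap | infeasible | no_coupling
    strategies: list[DeletionStrategy] = field(default_factory=list)
    gap: float = 0.0
    wall_time: float = 0.0
    solver: str = "highs"

    @property
    def best(self) -> DeletionStrategy | None:
        return self.strategies[0] if self.strategies else None


# ---------------------------------------------------------------------------
# inner LP
# ---------------------------------------------------------------------------

def _system(irr: IrreversibleModel, biomass_id: str):
    base = irr.base
    S = base.stoichiometric_matrix()
    n = len(base.reactions)
    bm_row = np.zeros(n)
    for rid, coeff in irr.net_flux_coefficients(biomass_id).items():
        bm_row[base.reaction_index(rid)] = coeff
    return S, bm_row


def _target_vector(irr: IrreversibleModel, target_id: str) -> np.ndarray:
    c = np.zeros(len(irr.base.reactions))
    for rid, coeff in irr.net_flux_coefficients(target_id).items():
        c[irr.base.reaction_index(rid)] = coeff
    return c


def inner_min_rate(
    irr: IrreversibleModel,
    deleted: set[str] | frozenset[str],
    mu_fix: float,
    target_id: str,
    biomass_id: str | None = None,
) -> float:
    """Minimum guaranteed target rate for a fixed deletion set at ``mu_fix``.

    Solves ``min v_t`` over the split model with the deleted parents' copies
    forced to zero and biomass pinned to ``mu_fix``. Raises
    :class:`~gcdesign.lp.InfeasibleError` when the deletions make the growth
    rate unreachable (a lethal strategy).
    """
    base = irr.base
    if biomass_id is None:
        if base.biomass_id is None:
            raise ValueError("no biomass reaction configured")
        biomass_id = irr.parent_of[base.biomass_id]
    S, bm_row = _system(irr, biomass_id)
    lb, ub = base.bounds_arrays()
    for parent in deleted:
        for rid in irr.children(parent):
            j = base.reaction_index(rid)
            lb[j] = ub[j] = 0.0
    c = _target_vector(irr, target_id)
    A_eq = sparse.vstack([S, sparse.csr_matrix(bm_row)])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [mu_fix]])
    value, _ = solve_lp(c, A_eq, b_eq, np.column_stack([lb, ub]))
    return value


# ---------------------------------------------------------------------------
# single-level MILP
# ---------------------------------------------------------------------------

@dataclass
class SingleLevelMILP:
    """Assembled MILP: min c.x s.t. row_lb <= A x <= row_ub, bounds, y integer."""

    c: np.ndarray
    A: sparse.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    integrality: np.ndarray
    candidate_ids: list[str]  # order of the y block
    y_offset: int
    big_m: float

    def extract_deleted(self, x: np.ndarray) -> frozenset[str]:
        y = x[self.y_offset : self.y_offset + len(self.candidate_ids)]
        return frozenset(
            k for k, val in zip(self.candidate_ids, y) if val < 0.5
        )


def _tightened_upper_bounds(
    irr: IrreversibleModel, fallback_cap: float
) -> np.ndarray:
    """Finite per-reaction upper bounds valid for every deletion subset.

    Wild-type FVA maxima bound the flux of any knockout mutant because
    deletions only shrink the flux polytope; infinite FVA maxima (unbounded
    internal cycles) fall back to a fixed cap.
    """
    base = irr.base
    S = base.stoichiometric_matrix()
    lb, ub = base.bounds_arrays()
    n = len(base.reactions)
    tight = np.empty(n)
    b_eq = np.zeros(S.shape[0])
    bounds = np.column_stack([lb, np.minimum(ub, fallback_cap * 10)])
    for j in range(n):
        if math.isfinite(ub[j]):
            tight[j] = ub[j]
            continue
        c = np.zeros(n)
        c[j] = -1.0
        try:
            value, _ = solve_lp(c, S, b_eq, bounds)
            fva_max = -value
        except InfeasibleError:
            fva_max = 0.0
        tight[j] = fva_max if fva_max < fallback_cap * 5 else fallback_cap
    return tight


def build_single_level(
    problem: GcOptProblem,
    big_m: float | None = None,
    tighten_bounds: bool = True,
    fallback_cap: float = _DEFAULT_FALLBACK_CAP,
) -> SingleLevelMILP:
    """Assemble the strong-duality MILP equivalent of the max-min program.

    Layout of the variable vector: primal fluxes v (N), metabolite duals
    lambda (|M|), growth-fix dual (1), upper-bound duals u (N), lower-bound
    duals w (N), linearization products g = u*y (one per split copy of a
    candidate), activities y (one per candidate, binary).
    """
    irr = problem.model
    base = irr.base
    n = len(base.reactions)
    S, bm_row = _system(irr, problem.biomass_id)
    m_rows = S.shape[0]
    lb, ub = base.bounds_arrays()
    if tighten_bounds:
        ub = np.minimum(ub, _tightened_upper_bounds(irr, fallback_cap))
    else:
        ub = np.minimum(ub, fallback_cap)
    ub = np.maximum(ub, lb)  # keep lb <= ub after capping

    cand_ids = sorted(problem.candidates)
    cand_pos = {k: j for j, k in enumerate(cand_ids)}
    cand_irr = [
        i
        for i, r in enumerate(base.reactions)
        if irr.parent_of[r.id] in problem.candidates
    ]
    n_g = len(cand_irr)
    n_y = len(cand_ids)
    if big_m is None:
        finite_ub = ub[np.isfinite(ub)]
        big_m = 2.0 * float(finite_ub.max()) if finite_ub.size else 2.0 * fallback_cap
        big_m = max(big_m, 1.0)

    # variable offsets
    off_v = 0
    off_lam = off_v + n
    off_mu = off_lam + m_rows
    off_u = off_mu + 1
    off_w = off_u + n
    off_g = off_w + n
    off_y = off_g + n_g
    n_var = off_y + n_y

    c_t = _target_vector(irr, problem.target_id)

    rows = []  # (coeffs dict, lo, hi)

    def add_row(coeffs: dict[int, float], lo: float, hi: float) -> None:
        rows.append((coeffs, lo, hi))

    # primal: S v = 0
    S_coo = S.tocoo()
    eq_rows: list[dict[int, float]] = [dict() for _ in range(m_rows)]
    for i, j, val in zip(S_coo.row, S_coo.col, S_coo.data):
        eq_rows[i][off_v + j] = val
    for r in eq_rows:
        add_row(r, 0.0, 0.0)
    # primal: biomass net flux = mu_fix
    add_row(
        {off_v + j: bm_row[j] for j in np.nonzero(bm_row)[0]},
        problem.mu_fix,
        problem.mu_fix,
    )
    # primal knockout coupling: v_i - ub_i y_k <= 0 for candidate copies
    for i in cand_irr:
        k = cand_pos[irr.parent_of[base.reactions[i].id]]
        add_row({off_v + i: 1.0, off_y + k: -ub[i]}, -np.inf, 0.0)

    # dual feasibility: S^T lam + bm_row * lam_mu - u + w = c_t
    ST = S.tocsc()
    for i in range(n):
        col = ST.getcol(i).tocoo()
        coeffs = {off_lam + int(r): float(v) for r, v in zip(col.row, col.data)}
        if bm_row[i]:
            coeffs[off_mu] = bm_row[i]
        coeffs[off_u + i] = -1.0
        coeffs[off_w + i] = 1.0
        add_row(coeffs, c_t[i], c_t[i])

    # strong duality: c.v = mu_fix*lam_mu - sum ub_i u_i z_i + sum lb_i w_i z_i
    # (z_i = 1 for non-candidates; candidate copies use g_i = u_i y_k; all
    # candidate copies have lb = 0 so the w-term stays linear)
    sd: dict[int, float] = {}
    for j in np.nonzero(c_t)[0]:
        sd[off_v + int(j)] = sd.get(off_v + int(j), 0.0) + c_t[j]
    sd[off_mu] = sd.get(off_mu, 0.0) - problem.mu_fix
    cand_set = set(cand_irr)
    for i in range(n):
        if i in cand_set:
            continue
        if ub[i]:
            sd[off_u + i] = sd.get(off_u + i, 0.0) + ub[i]
        if lb[i]:
            sd[off_w + i] = sd.get(off_w + i, 0.0) - lb[i]
    for gi, i in enumerate(cand_irr):
        if ub[i]:
            sd[off_g + gi] = sd.get(off_g + gi, 0.0) + ub[i]
    add_row(sd, 0.0, 0.0)

    # linearization of g = u * y per candidate copy
    for gi, i in enumerate(cand_irr):
        k = cand_pos[irr.parent_of[base.reactions[i].id]]
        add_row({off_g + gi: 1.0, off_u + i: -1.0}, -np.inf, 0.0)
        add_row({off_g + gi: 1.0, off_y + k: -big_m}, -np.inf, 0.0)
        add_row({off_u + i: 1.0, off_g + gi: -1.0, off_y + k: big_m}, -np.inf, big_m)

    # deletion budget: sum_k (1 - y_k) <= K
    if n_y:
        add_row({off_y + k: -1.0 for k in range(n_y)}, -np.inf, problem.max_deletions - n_y)

    # assemble sparse A
    r_idx, c_idx, vals = [], [], []
    row_lb = np.empty(len(rows))
    row_ub = np.empty(len(rows))
    for ri, (coeffs, lo, hi) in enumerate(rows):
        row_lb[ri] = lo
        row_ub[ri] = hi
        for ci, v in coeffs.items():
            r_idx.append(ri)
            c_idx.append(ci)
            vals.append(v)
    A = sparse.csr_matrix((vals, (r_idx, c_idx)), shape=(len(rows), n_var))

    var_lb = np.zeros(n_var)
    var_ub = np.full(n_var, big_m)
    var_lb[off_v : off_v + n] = lb
    var_ub[off_v : off_v + n] = ub
    for i in cand_irr:  # candidate copies may be knocked out
        var_lb[off_v + i] = 0.0
    var_lb[off_lam : off_u] = -big_m  # metabolite + growth duals are free, boxed
    var_ub[off_lam : off_u] = big_m
    var_lb[off_y :] = 0.0
    var_ub[off_y :] = 1.0

    obj = np.zeros(n_var)
    obj[off_v : off_v + n] = -c_t  # maximize v_t

    integrality = np.zeros(n_var)
    integrality[off_y :] = 1.0

    return SingleLevelMILP(
        c=obj,
        A=A,
        row_lb=row_lb,
        row_ub=row_ub,
        var_lb=var_lb,
        var_ub=var_ub,
        integrality=integrality,
        candidate_ids=cand_ids,
        y_offset=off_y,
        big_m=big_m,
    )


# ---------------------------------------------------------------------------
# solve + verification
# ---------------------------------------------------------------------------

def _coupling_eps(problem: GcOptProblem) -> float:
    try:
        uptake = problem.model.base.default_uptake_bound()
    except Exception:
        uptake = 1.0
    return 1e-6 * max(uptake, 1.0)


def solve_gcopt(
    problem: GcOptProblem,
    pool_size: int = 1,
    time_limit: float | None = None,
    mip_rel_gap: float = 1e-9,
    big_m: float | None = None,
    tighten_bounds: bool = True,
) -> SolveReport:
    """Solve the single-level MILP; optionally collect a pool of distinct
    suboptimal strategies via integer no-good cuts.

    Each incumbent's objective is re-computed with an independent inner LP;
    the verified value is reported (``gap`` records the largest deviation
    between MILP and verified objectives seen).
    """
    t0 = time.perf_counter()
    milp_data = build_single_level(problem, big_m=big_m, tighten_bounds=tighten_bounds)
    eps = _coupling_eps(problem)
    options: dict = {"mip_rel_gap": mip_rel_gap, "presolve": True}
    if time_limit is not None:
        options["time_limit"] = time_limit

    cuts: list[frozenset[str]] = []
    strategies: list[DeletionStrategy] = []
    worst_gap = 0.0
    status = "infeasible"
    cand_pos = {k: j for j, k in enumerate(milp_data.candidate_ids)}

    for _ in range(max(pool_size, 1)):
        A = milp_data.A
        row_lb, row_ub = milp_data.row_lb, milp_data.row_ub
        if cuts:
            extra_rows = []
            for cut in cuts:
                row = np.zeros(A.shape[1])
                for k in cut:
                    row[milp_data.y_offset + cand_pos[k]] = 1.0
                extra_rows.append(row)
            A = sparse.vstack([A, sparse.csr_matrix(np.array(extra_rows))])
            row_lb = np.concatenate([row_lb, np.ones(len(cuts))])
            row_ub = np.concatenate([row_ub, np.full(len(cuts), np.inf)])
        res = milp(
            milp_data.c,
            constraints=LinearConstraint(A, row_lb, row_ub),
            integrality=milp_data.integrality,
            bounds=Bounds(milp_data.var_lb, milp_data.var_ub),
            options=options,
        )
        if res.status == 1 and res.x is not None:
            status = "feasible_gap"
        elif res.status != 0 or res.x is None:
            break
        deleted = milp_data.extract_deleted(res.x)
        milp_obj = -res.fun
        try:
            verified = inner_min_rate(
                problem.model, deleted, problem.mu_fix, problem.target_id,
                biomass_id=problem.biomass_id,
            )
        except InfeasibleError:
            # big-M artifact produced a lethal incumbent; cut it away and retry
            cuts.append(deleted if deleted else frozenset(milp_data.candidate_ids))
            continue
        worst_gap = max(worst_gap, abs(milp_obj - verified))
        strategies.append(DeletionStrategy(deleted=deleted, objective=verified))
        if status != "feasible_gap":
            status = "optimal"
        if not deleted:
            break  # the empty cut would exclude everything
        cuts.append(deleted)

    strategies.sort(key=lambda s: (-s.objective, len(s.deleted), sorted(s.deleted)))
    if strategies and strategies[0].objective <= eps:
        status = "no_coupling"
    return SolveReport(
        status=status,
        strategies=strategies,
        gap=worst_gap,
        wall_time=time.perf_counter() - t0,
        solver="highs(scipy)",
    )


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def brute_force(
    problem: GcOptProblem, subset_guard: int = 100_000, tol: float = 1e-9
) -> tuple[DeletionStrategy, float]:
    """Enumerate all deletion subsets of size <= K and return the max-min
    optimum. Ties break toward smaller sets, then lexicographic ids.

    Independent of the MILP path: every subset is scored by a plain inner LP.
    """
    cand = sorted(problem.candidates)
    k_max = min(problem.max_deletions, len(cand))
    total = sum(math.comb(len(cand), k) for k in range(k_max + 1))
    if total > subset_guard:
        raise ValueError(
            f"{total} subsets exceed the enumeration guard of {subset_guard}"
        )
    best: DeletionStrategy | None = None
    any_feasible = False
    for k in range(k_max + 1):
        for combo in itertools.combinations(cand, k):
            deleted = frozenset(combo)
            try:
                value = inner_min_rate(
                    problem.model, deleted, problem.mu_fix, problem.target_id,
                    biomass_id=problem.biomass_id,
                )
            except InfeasibleError:
                continue
            any_feasible = True
            if best is None or value > best.objective + tol:
                best = DeletionStrategy(deleted=deleted, objective=value)
    if not any_feasible or best is None:
        raise InfeasibleError(
            "no deletion subset supports the fixed growth rate"
        )
    return best, best.objective
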