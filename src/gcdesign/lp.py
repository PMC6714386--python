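"""Thin LP layer over scipy's HiGHS interface.

All flux-balance LPs in the package go through :func:`optimize_flux`:
optimize a linear functional of the flux vector subject to ``S v = 0``,
bounds, per-reaction bound overrides (knockouts, fixed rates) and optional
extra equality rows. Infeasibility is reported through
:class:`InfeasibleError` so callers can distinguish lethal designs from
programming errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import MetabolicModel

_TOL_ZERO = 1e-9


class InfeasibleError(RuntimeError):
    """The LP has no feasible flux distribution under the given constraints."""


@dataclass
class LPResult:
    objective: float
    fluxes: np.ndarray  # aligned with model.reactions


def _apply_overrides(
    model: MetabolicModel,
    lb: np.ndarray,
    ub: np.ndarray,
    fixed: dict[str, float] | None,
    knockouts: set[str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    if fixed:
        for rid, value in fixed.items():
            j = model.reaction_index(rid)
            lb[j] = ub[j] = value
    if knockouts:
        for rid in knockouts:
            j = model.reaction_index(rid)
            lb[j] = ub[j] = 0.0
    return lb, ub


def optimize_flux(
    model: MetabolicModel,
    objective: str | dict[str, float],
    sense: str = "max",
    fixed: dict[str, float] | None = None,
    knockouts: set[str] | None = None,
) -> LPResult:
    """Optimize a linear flux functional subject to Sv = 0 and bounds.

    Parameters
    ----------
    objective
        Reaction id, or a sparse ``{reaction_id: coefficient}`` functional.
    sense
        ``"max"`` or ``"min"``.
    fixed
        Reactions pinned to an exact rate (both bounds set).
    knockouts
        Reactions pinned to zero.
    """
    if isinstance(objective, str):
        objective = {objective: 1.0}
    c = np.zeros(len(model.reactions))
    for rid, coeff in objective.items():
        c[model.reaction_index(rid)] = coeff
    if sense == "max":
        c = -c
    elif sense != "min":
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")

    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    lb, ub = _apply_overrides(model, lb, ub, fixed, knockouts)

    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError(
            f"no feasible flux distribution (fixed={fixed}, knockouts={knockouts})"
        )
    if not res.success:
        raise RuntimeError(f"LP solve failed: {res.message}")
    value = -res.fun if sense == "max" else res.fun
    return LPResult(objective=value, fluxes=res.x)


def max_growth(
    model: MetabolicModel,
    knockouts: set[str] | None = None,
    fixed: dict[str, float] | None = None,
) -> float:
    """Maximum biomass formation rate (FBA); raises if no biomass id set."""
    if model.biomass_id is None:
        raise ValueError("model has no biomass reaction configured")
    return optimize_flux(
        model, model.biomass_id, "max", fixed=fixed, knockouts=knockouts
    ).objective


def flux_range(
    model: MetabolicModel,
    reaction_id: str,
    fixed: dict[str, float] | None = None,
    knockouts: set[str] | None = None,
) -> tuple[float, float]:
    lo = optimize_flux(model, reaction_id, "min", fixed=fixed, knockouts=knockouts)
    hi = optimize_flux(model, reaction_id, "max", fixed=fixed, knockouts=knockouts)
    return lo.objective, hi.objective


def solve_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix,
    b_eq: np.ndarray,
    bounds: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Bare min-LP used by code that builds its own constraint systems."""
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleError("LP infeasible")
    if not res.success:
        raise RuntimeError(f"LP solve failed: {res.message}")
    return res.fun, res.x
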