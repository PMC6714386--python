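"""Production envelopes, coupling classification and the growth-coupling
strength (GCS) score.

A production envelope is the projection of the steady-state flux space onto
the (growth rate, target production rate) plane: per growth-rate grid point
the LP minimum and maximum of the target rate. Its lower bound is the
minimally guaranteed production rate; a positive lower bound means the
design couples production to metabolic activity.

Coupling classes:

* ``wGC`` (weak): production forced only above some growth rate,
* ``hGC`` (holistic): forced at every positive growth rate,
* ``sGC`` (strong): forced in every metabolic state including zero growth,
* ``none``: lower bound identically zero.

GCS condenses an envelope pair (wild type vs. mutant) into one number in
(-2, 1]. Working in yield coordinates (rate / substrate uptake bound), with
IA the area below the mutant's lower yield bound and TA the wild-type yield
space area up to the mutant's maximal growth rate,

    core = (IA / TA) * (Ymin_at_mumax / Ymax),
    GCS  = core - {0 sGC, 1 hGC, 2 wGC}.

So sGC lands in (0, 1], hGC in (-1, 0], wGC in (-2, -1]; -2 is the sentinel
for "no coupling at all". Scores <= -1.975 or in [-1, -0.975] are reported
as conferring no coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MetabolicModel
from .lp import InfeasibleError, max_growth, optimize_flux

COUPLING_CLASSES = ("none", "wGC", "hGC", "sGC")
_SUBTRAHEND = {"sGC": 0.0, "hGC": 1.0, "wGC": 2.0, "none": 2.0}
NO_COUPLING_SENTINEL = -2.0
DEFAULT_GRID_POINTS = 1001


class UndefinedMetricError(ValueError):
    """GCS is undefined (degenerate wild-type envelope, TA = 0)."""


@dataclass
class ProductionEnvelope:
    mu_grid: np.ndarray
    v_min: np.ndarray
    v_max: np.ndarray
    mu_max: float
    uptake_bound: float
    target_id: str = ""

    def __post_init__(self) -> None:
        if self.uptake_bound <= 0:
            raise ValueError("uptake bound must be positive")

    @property
    def y_min(self) -> np.ndarray:
        return self.v_min / self.uptake_bound

    @property
    def y_max(self) -> np.ndarray:
        return self.v_max / self.uptake_bound

    def v_min_at(self, mu: float | np.ndarray) -> np.ndarray:
        return np.interp(mu, self.mu_grid, self.v_min)

    def v_max_at(self, mu: float | np.ndarray) -> np.ndarray:
        return np.interp(mu, self.mu_grid, self.v_max)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mu": self.mu_grid,
                "v_min": self.v_min,
                "v_max": self.v_max,
                "y_min": self.y_min,
                "y_max": self.y_max,
            }
        )


@dataclass
class GcsResult:
    IA: float
    TA: float
    y_min_at_mu_max: float
    y_max_theoretical: float
    v_p_min_mu0: float
    mu_max_zero_yield: float
    coupling_class: str
    gcs: float

    def to_dict(self) -> dict:
        return {
            "IA": self.IA,
            "TA": self.TA,
            "y_min_at_mu_max": self.y_min_at_mu_max,
            "y_max_theoretical": self.y_max_theoretical,
            "v_p_min_mu0": self.v_p_min_mu0,
            "mu_max_zero_yield": self.mu_max_zero_yield,
            "coupling_class": self.coupling_class,
            "gcs": self.gcs,
        }


def production_envelope(
    model: MetabolicModel,
    target_id: str,
    deletions: set[str] | frozenset[str] = frozenset(),
    n_points: int = 51,
    uptake_bound: float | None = None,
) -> ProductionEnvelope:
    """Compute the (mu, v_target) envelope of a (possibly deleted) model.

    The growth grid spans [0, mu_max] inclusive; per grid point biomass is
    pinned and the target flux is minimized and maximized by LP. Raises
    :class:`~gcdesign.lp.InfeasibleError` if even zero growth is infeasible
    (e.g. the maintenance demand cannot be met under the deletions).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    deletions = set(deletions)
    if uptake_bound is None:
        uptake_bound = model.default_uptake_bound()
    mu_max = max(max_growth(model, knockouts=deletions), 0.0)
    grid = np.linspace(0.0, mu_max, n_points)
    v_min = np.empty(n_points)
    v_max = np.empty(n_points)
    for i, mu in enumerate(grid):
        fixed = {model.biomass_id: float(mu)}
        try:
            v_min[i] = optimize_flux(
                model, target_id, "min", fixed=fixed, knockouts=deletions
            ).objective
            v_max[i] = optimize_flux(
                model, target_id, "max", fixed=fixed, knockouts=deletions
            ).objective
        except InfeasibleError:
            if i == 0:
                raise
            # interior infeasibility can only be LP tolerance noise at mu_max
            v_min[i] = v_min[i - 1]
            v_max[i] = v_max[i - 1]
    v_min = np.maximum(v_min, 0.0)
    v_max = np.maximum(v_max, v_min)
    return ProductionEnvelope(
        mu_grid=grid,
        v_min=v_min,
        v_max=v_max,
        mu_max=mu_max,
        uptake_bound=uptake_bound,
        target_id=target_id,
    )


def classify(envelope: ProductionEnvelope, eps: float | None = None) -> str:
    """Coupling class of an envelope from its lower production bound."""
    if eps is None:
        eps = 1e-6 * envelope.uptake_bound
    positive = envelope.v_min > eps
    if positive[0]:
        return "sGC"
    interior = positive[envelope.mu_grid > 0]
    if interior.size and interior.all():
        return "hGC"
    if positive.any():
        return "wGC"
    return "none"


def _zero_yield_growth(envelope: ProductionEnvelope, eps: float) -> float:
    """Largest growth rate at which zero production is still admissible."""
    below = envelope.v_min <= eps
    if not below.any():
        return 0.0
    idx = int(np.max(np.nonzero(below)))
    if idx == len(envelope.mu_grid) - 1:
        return float(envelope.mu_max)
    # linear crossing between grid idx (<= eps) and idx+1 (> eps)
    mu0, mu1 = envelope.mu_grid[idx], envelope.mu_grid[idx + 1]
    v0, v1 = envelope.v_min[idx], envelope.v_min[idx + 1]
    if v1 <= v0:
        return float(mu1)
    return float(mu0 + (eps - v0) / (v1 - v0) * (mu1 - mu0))


def gcs(
    wt_env: ProductionEnvelope,
    mut_env: ProductionEnvelope,
    eps: float | None = None,
    mu_tolerance: float = 1e-6,
) -> GcsResult:
    """Growth-coupling strength of a mutant envelope against its wild type.

    Both envelopes must share the target and substrate uptake bound; areas
    are evaluated by trapezoidal integration in yield coordinates on the
    union of the two growth grids, restricted to [0, mu_max(mutant)].
    """
    if wt_env.target_id != mut_env.target_id:
        raise ValueError("envelopes target different reactions")
    if abs(wt_env.uptake_bound - mut_env.uptake_bound) > 1e-9:
        raise ValueError("envelopes use different uptake bounds")
    if mut_env.mu_max > wt_env.mu_max + max(mu_tolerance, 1e-6 * wt_env.mu_max):
        raise ValueError(
            f"mutant mu_max {mut_env.mu_max} exceeds wild-type {wt_env.mu_max}"
        )
    if eps is None:
        eps = 1e-6 * mut_env.uptake_bound

    upt = wt_env.uptake_bound
    mu_hi = mut_env.mu_max
    merged = np.union1d(
        wt_env.mu_grid[wt_env.mu_grid <= mu_hi], mut_env.mu_grid
    )
    merged = np.union1d(merged, [0.0, mu_hi])
    merged = merged[merged <= mu_hi + 1e-12]

    ta = float(np.trapezoid(wt_env.v_max_at(merged) / upt, merged))
    ia = float(np.trapezoid(np.maximum(mut_env.v_min_at(merged), 0.0) / upt, merged))
    if ta <= 0:
        raise UndefinedMetricError("wild-type yield-space area TA is zero")
    ia = min(ia, ta)

    y_max_theoretical = float(np.max(wt_env.y_max))
    y_min_at_mu_max = float(mut_env.v_min_at(mu_hi) / upt)
    v_p_min_mu0 = float(mut_env.v_min[0])
    mu_zero_yield = _zero_yield_growth(mut_env, eps)

    klass = classify(mut_env, eps=eps)
    core = 0.0
    if y_max_theoretical > 0:
        core = (ia / ta) * (max(y_min_at_mu_max, 0.0) / y_max_theoretical)
    value = core - _SUBTRAHEND[klass]

    rounded = round(value, 3)
    if rounded <= -1.975 or (-1.0 <= rounded <= -0.975):
        klass = "none"
    return GcsResult(
        IA=ia,
        TA=ta,
        y_min_at_mu_max=y_min_at_mu_max,
        y_max_theoretical=y_max_theoretical,
        v_p_min_mu0=v_p_min_mu0,
        mu_max_zero_yield=mu_zero_yield,
        coupling_class=klass,
        gcs=value,
    )
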