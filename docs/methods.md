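# Methods

## Model and scope

`gcdesign` operates on steady-state stoichiometric models: metabolites `M`,
reactions `R` with flux bounds in mmol gDW⁻¹ h⁻¹, mass balance `S v = 0`.
A reaction is reversible iff its lower bound is negative. Gene–protein–
reaction logic is out of scope — all interventions are *reaction* deletions;
thermodynamic (Gibbs) constraints beyond bound directionality are likewise
not modeled.

## The max–min design search

The design objective is the minimally guaranteed production rate of a
target export `v_t` at a fixed growth rate `mu_fix`, maximized over deletion
sets of size at most `K` drawn from a candidate set. `mu_fix` must lie below
the wild-type maximal growth rate (the inner LP pins biomass to `mu_fix`);
when unset, the CLI defaults to 50% of the wild-type maximum — a "medium"
growth rate that balances coupling strength against predicted viability.

### Irreversible split

The reformulation requires nonnegative fluxes, so each reversible reaction
`k` is split into `k_fwd` (bounds `[max(lb,0), max(ub,0)]`) and `k_rev`
(negated stoichiometry, bounds `[max(-ub,0), -lb]`). A mapping matrix
`B ∈ {0,1}^{N×R}` ties the split copies to their parents; deleting a parent
zeroes all of its copies. Reactions with a *positive* lower bound (the ATP
maintenance demand) are never split into a backward copy and are never
deletion candidates: a deletion (flux 0) would contradict the bound.

### Single-level MILP

The inner LP (`min v_t` s.t. `S v = 0`, `v_bm = mu_fix`,
`lb_i z_i ≤ v_i ≤ ub_i z_i` with `z = B y`) is dualized; the MILP carries
primal fluxes, equality duals, bound duals `u, w ≥ 0`, a strong-duality
equality tying `v_t` to the dual objective, and products `g_i = u_i y_k`
linearized with big-M rows. Only the upper-bound duals of candidate copies
need linearization: candidate copies always have `lb = 0`, and non-candidate
activities are constant 1.

Numerical choices:

* **Bound tightening.** Infinite upper bounds are replaced by wild-type FVA
  maxima before dualization (valid for every deletion subset, since
  deletions only shrink the flux polytope); unbounded FVA maxima fall back
  to a cap of 1000. This keeps big-M on the scale of the uptake rate.
* **Big-M / dual boxes.** `M = 2 × max(ub)` after tightening (floor 1.0);
  equality duals are boxed to `[−M, M]`, inequality duals to `[0, M]`.
* **Verification loop.** Every incumbent's objective is recomputed by an
  independent inner LP; the reported objective is the verified LP value and
  the report's `gap` field records the largest MILP-vs-LP deviation. A
  lethal incumbent (big-M artifact) is cut away and the search repeated.
* **Solver.** HiGHS through `scipy.optimize.milp`/`linprog`, relative MIP
  gap 1e−9 by default; LP infeasibility is the signal that a deletion set
  cannot sustain `mu_fix`.
* **Suboptimal designs.** A solution pool is collected by re-solving with
  integer no-good cuts `Σ_{k∈D*} y_k ≥ 1`, which exclude the incumbent
  deletion set and its supersets; strategies are sorted by objective, then
  smaller set, then lexicographic ids. A solve whose best objective is below
  `1e−6 ×` the substrate uptake bound reports `no_coupling`.
* **Oracle.** `brute_force` enumerates all subsets of size ≤ K (guarded at
  1e5 subsets) with the same tie-breaking; the MILP is required to match it
  on the fixture battery.

### Preprocessing

Blocked reactions are those whose feasibility FVA range is (0, 0) at
tolerance 1e−9; removal is idempotent and FVA runs with *no* objective or
growth fixing (pure feasibility ranges — whether growth should be fixed
during this step is genuinely open; the pure-feasibility choice is the more
conservative one, removing only reactions blocked in every state).
Deletion candidates exclude exchange/diffusion/transport/spontaneous/
maintenance reactions, five biosynthesis-membrane subsystems by default
(cell envelope biosynthesis, membrane lipid metabolism, murein biosynthesis,
tRNA charging, glycerophospholipid metabolism), reactions with positive
lower bounds, and essential reactions — a single knockout dropping maximal
growth below 1e−6 h⁻¹ counts as lethal.

## Envelopes and the GCS score

Production envelopes are computed on the *reversible* model: `mu_max` by
FBA, then per grid point (default 51–1001 evenly spaced growth rates,
endpoints included) the LP min/max of the target flux with biomass pinned.
Lower bounds are convex and upper bounds concave in `mu` (LP projection),
which the tests assert to 1e−5.

Classification uses `eps = 1e−6 ×` uptake bound: sGC if the lower bound is
positive at `mu = 0`, hGC if positive at every positive grid point, wGC if
positive somewhere, else none.

GCS works in yield coordinates `y = v / uptake bound`, where the uptake
bound is the substrate exchange's import capacity (explicitly configurable;
inferred as the largest carbon-source import capacity otherwise). On the
union of both growth grids up to the mutant's `mu_max`:

* `TA` = trapezoidal integral of the wild-type *upper* yield bound
  (the wild-type yield space up to the mutant's maximal growth; the
  wild-type lower bound is not subtracted),
* `IA` = integral of the mutant *lower* yield bound,
* `Ymax` = wild-type maximal yield over all growth rates, `Ymin@mumax` =
  mutant minimal yield at its own `mu_max`,
* `GCS = (IA/TA) · (Ymin@mumax / Ymax) − {0, 1, 2}` for sGC/hGC/wGC.

A lower bound that is identically zero gives `IA = 0`, `Ymin@mumax = 0` and
hence the sentinel −2. After rounding to three decimals, scores ≤ −1.975 or
inside `[−1, −0.975]` (both bands taken inclusive; the open/closed status of
the second band's ends is not settled, and three decimals is one digit finer
than the two typically reported) are reported as class `none` while the
numeric value is kept. `TA = 0` (degenerate wild type) raises an
`UndefinedMetricError` rather than returning a score.

The area ratio `IA/TA` is identical in rate and yield space when the uptake
bound is fixed; the yield-space formulation only affects the `Ymin/Ymax`
factor and is the one used throughout.

## Diagnostics

**Precursor availability.** The biomass equation is singularized: each
reactant `υ_m M` becomes an unbounded drain `υ_m M →`; consumption coupled
to production of a partner (pair table: ATP/ADP, NAD⁺/NADH, NADP⁺/NADPH;
H₂O, Pi, H⁺, PPi treated as free byproducts; user-extensible) becomes the
mass-balanced `υ_m M → υ_n N`; remaining products become sources; the
biomass reaction is removed. Availability of a precursor under a design is
the LP maximum of its drain with the deletions applied and the target export
pinned to zero; a maximum below 1e−9 means the precursor is lost. The ATP
maintenance lower bound is relaxed to zero during this probe — otherwise the
maintenance demand itself, not the deletions, can make the probe infeasible
and every precursor would trivially appear blocked.

**ATPsc / ATPcsc.** For each growth rate in a grid (default 11 points over
`[0, 0.95·mu_max]`), biomass is pinned and the maximal ATP-maintenance flux
is computed with the target rate fixed at 0 and at a finite-difference step
(default 1 mmol gDW⁻¹ h⁻¹ — "low production rates"); the slope is the ATPsc
at that growth rate. On an LP model the relation is piecewise linear, so the
step size is immaterial within the linear regime (asserted for steps 0.1
and 1.0). The reported ATPsc is the mean over the grid, with its standard
deviation; ATPcsc divides by the target's carbon count (parsed from the
formula by element tokenization, with explicit per-metabolite overrides).
The energy hierarchy ranks metabolites by ATPcsc, rank 1 highest, dense
ranks, ties shared (values rounded to 9 decimals first so LP noise cannot
split a tie).

**Relaxation screen.** Each relaxation spec (unbounded reversible ATP
maintenance; free NAD(P)H interconversion `nad(p) + h ↔ nad(p)h`, mass- but
not charge-balanced; free proton translocation `h_ex ↔ h_in`) is applied to
the model and GCS is recomputed — against the *relaxed* wild-type envelope,
so mutant and baseline see identical constraints (comparing a relaxed
mutant to an unrelaxed wild type can produce IA > TA artifacts). Cells whose
spec needs species the model lacks are marked not applicable.

The virtual NAD(P)H turnover demands used in screening (`add_redox_ngam`)
are oriented to consume the named cofactor with a default flux window of
5–20 mmol gDW⁻¹ h⁻¹; the ATP maintenance default is 8.39 mmol gDW⁻¹ h⁻¹
(the conventional *E. coli* value), with 4.2 and 12.2 as the ±50% screen
settings.

## Synthetic fixtures

The fixture generator emulates the minimal energetic mechanism of strong
coupling: an uptake-limited substrate, biomass formation consuming ATP,
parallel ATP-regeneration routes of which at least one co-produces a
byproduct `P`, and a positive ATP maintenance demand (without which the zero
flux vector is feasible and strong coupling is impossible). `T1`/`T2` differ
in the byproduct route's ATP yield (1 vs 2 per substrate); `T3` adds an
ATP-costing export. Random fixtures draw uptake capacity (8/10/12),
maintenance demand (0.5/1/2), biomass ATP stoichiometry (1/2), 2–3 ATP
routes with yields 1–3 and random byproduct emission, an optional reversible
shuttle (exercising the split machinery) and an optional costly export, all
from a seeded generator. Every fixture's ground truth (optimal deletion set,
objective, coupling class) is certified at build time by the exhaustive
enumeration oracle; generation fails on mismatch.

What the fixtures do **not** emulate: compartments and proton-motive force,
redox cofactor pools, realistic biomass compositions (two precursors instead
of dozens), alternative carbon sources, or genome-scale combinatorics.
Passing tests therefore demonstrate correctness of the optimization,
scoring and probing machinery, not predictive accuracy on real organisms;
applying the package to a published genome-scale model goes through the same
code paths but inherits that model's assumptions.

## Problem sizes and determinism

The test suite and the acceptance script run on networks of ≤ 15 reactions
with deletion budgets ≤ 3 and 50 random instances for the MILP-vs-oracle
comparison, with envelope grids of 101–1001 points — sizes chosen so the
full battery completes in about a minute on one CPU while still exercising
every code path, including reversible splits and solution pools. All
randomness flows through seeded NumPy generators; identical seeds give
byte-identical fixture models and identical solver inputs.

## Known limitations

* Dual variables are boxed at big-M; a pathological instance whose true
  duals exceed the box could make the optimal `y` infeasible in the master.
  The verification loop and the oracle-equivalence battery bound the risk
  but cannot exclude it for arbitrary genome-scale inputs; the `gap` field
  and re-verified objectives make any such failure visible.
* Bound tightening caps genuinely unbounded internal cycles at 1000, which
  mildly perturbs the dual geometry of models with thermodynamically
  infeasible loops.
* Intracellular targets are exported through a simple cytosolic demand
  reaction. For products whose physiology involves proton-coupled export
  (ethanol, pyruvate), a demand reaction ignores the proton balance that can
  itself carry the coupling; supplying an explicit transporter in the model
  is the faithful alternative.
* The no-coupling bands and the inclusive treatment of their endpoints are a
  reporting convention; scores near the band edges should be read with that
  in mind.
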