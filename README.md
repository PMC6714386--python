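# gcdesign

Strain design for **growth-coupled production** in constraint-based metabolic
models. Given a stoichiometric model, a target metabolite and a deletion
budget, `gcdesign` finds reaction-knockout sets that maximize the *minimally
guaranteed* production rate of the target at a fixed growth rate — designs in
which the cell cannot grow (or, in the strongest case, cannot even stay
metabolically active) without secreting the product. Such designs make
product formation selectable by growth and are the basis for adaptive
laboratory evolution of production strains.

## The optimization problem

With `S` the stoichiometric matrix of the irreversible (split) model,
`v >= 0` the flux vector, `y in {0,1}^R` a reaction-activity vector over the
reversible model and `B` the matrix mapping split copies onto their parents,
the search solves the bilevel max–min program

```
max_y   min_v   v_t
s.t.    S v = 0
        v_bm = mu_fix
        lb_i (B y)_i <= v_i <= ub_i (B y)_i
        sum_k (1 - y_k) <= K ,   y_k = 1 outside the candidate set
```

i.e. the outer level picks at most `K` deletions, the inner LP computes the
production rate the mutant is *forced* to sustain at growth rate `mu_fix`.
The bilevel program is collapsed to a single-level MILP via LP strong
duality (inner dual embedded, primal and dual objectives tied, dual × binary
products linearized with big-M constraints) and solved with HiGHS through
SciPy. Every incumbent is re-verified by an independent inner LP, and an
exhaustive enumerator (`brute_force`) provides an oracle for small networks.

Designs are scored with the **growth-coupling strength (GCS)**: in yield
coordinates, with `IA` the area below the mutant's minimal-yield curve and
`TA` the wild-type yield-space area up to the mutant's maximal growth rate,

```
GCS = (IA / TA) * (Ymin@mumax / Ymax)  -  {0 | 1 | 2}
```

where the subtrahend encodes the qualitative class — strong coupling (sGC,
production forced even at zero growth; GCS > 0), holistic (hGC, forced at
every positive growth rate; GCS in (−1, 0]), weak (wGC, forced only at high
growth; GCS in (−2, −1]) — and −2 is the no-coupling sentinel. Mechanistic
probes explain *why* a design couples: biomass-precursor availability under
blocked production, the ATP synthesis capability (ATPsc/ATPcsc, the change
in maximal ATP-maintenance flux per unit production, carbon-normalized) with
its induced "energy hierarchy" of metabolites, and screens that relax the
ATP-maintenance, NAD(P)H and proton-translocation constraints.

## Worked example

The bundled fixture `T1` is the minimal strong-coupling network: substrate
`S` feeds biomass (`S + ATP -> BM`), a clean ATP route (`S -> ATP`) and a
byproduct ATP route (`S -> ATP + P`), with an ATP maintenance demand of
1 mmol gDW⁻¹ h⁻¹ and an uptake capacity of 10.

```bash
gcdesign fixtures --name T1 --out-dir work
gcdesign solve --model work/T1.json --target EX_P --mu-fix 2 --max-ko 1 --out-dir work
```

prints

```json
{
 "status": "optimal",
 "mu_fix": 2.0,
 "wild_type_mu_max": 4.5,
 "target": "EX_P",
 "solver": "highs(scipy)",
 "gap": 3.552713678800501e-15,
 "strategies": [
  {
   "deletions": ["R_atp_clean"],
   "objective": 3.0
  }
 ]
}
```

Deleting the clean ATP route leaves the byproduct route as the only ATP
source, so every unit of maintenance (1) and of growth-linked ATP demand
(`mu = 2`) forces one unit of `P` export: the guaranteed rate is
`1 + mu = 3` mmol gDW⁻¹ h⁻¹. Scoring the design,

```bash
gcdesign gcs --model work/T1.json --target EX_P --delete R_atp_clean --out-dir work
```

prints

```json
{
 "IA": 1.4625,
 "TA": 3.4875,
 "y_min_at_mu_max": 0.55,
 "y_max_theoretical": 1.0,
 "v_p_min_mu0": 1.0,
 "mu_max_zero_yield": 0.0,
 "coupling_class": "sGC",
 "gcs": 0.23064516129032261
}
```

The score is exactly `(1.4625 / 3.4875) × 0.55`, the closed-form integrals
of the piecewise-linear envelope bounds `y_min = (1+mu)/10` and
`y_max = (10−mu)/10` over `[0, 4.5]`. Relaxing the ATP-maintenance constraint
(`gcdesign relax-screen ... --relax atpm`) drops the score to −2 (class
`none`): the coupling is purely energetic.

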