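# Methods

## Constraint-based model and steady state

A metabolic model is a stoichiometric matrix `S` (metabolites × reactions),
flux bounds `lb ≤ v ≤ ub`, and a linear biomass objective `c`. All analyses
assume steady state, `S·v = 0`. Exchange pseudo-reactions move a single
metabolite across the system boundary (negative flux = uptake, positive =
secretion); boundary species are implicit, so an exchange simply has a
one-metabolite stoichiometry. "Unbounded" fluxes are represented by
±`default_bound` (1000, the common convention in the field), since the
variability analysis presumes finite bounds. Bounds are in the usual
mmol·gDW⁻¹·h⁻¹ convention and dimensionless in the toy fixtures.

## Optimisation layer

Everything is plain LP solved with HiGHS through `scipy.optimize.linprog`.

- **FBA**: `max c'v` subject to steady state and bounds.
- **pFBA** (two-stage): stage 1 computes the optimum `z*`; stage 2 minimises
  `Σ|v|` subject to `c'v ≥ f·z*` (default `f = 1`). Absolute values are
  implemented by nonnegative forward/reverse splitting `v = v⁺ − v⁻`; with
  the cap `Σ(v⁺+v⁻) ≤ C` the feasible set in flux space is exactly
  `Σ|v| ≤ C`, so the split is lossless and no integer variables are needed.
- **FVA**: per reaction, minimise and maximise `v_r` subject to steady
  state, bounds, the biomass-fraction constraint `c'v ≥ f·z*` and, when a
  `pfba_factor` `p` is set, the total-flux cap `Σ|v| ≤ p·T` where `T` is the
  minimum total flux *under the same biomass constraint*. This reading —
  "at most p−1 more than the minimum necessary total flux, given the
  required biomass" — matches the behaviour of the established COBRA
  toolkit, which the test suite uses as an independent cross-check.
- **Objective**: biomass is maximised directly (no uptake normalisation).

Defaults for the pipeline are `fraction_of_optimum = 0.9`,
`pfba_factor = 1.1`, `loopless = True`.

A consequence of the relative cap worth knowing: raising
`fraction_of_optimum` with `pfba_factor` active can *widen* some ranges,
because the constrained minimum total flux — and hence the cap — rises with
the biomass requirement. Monotonicity of ranges in the fraction holds when
the cap is disabled or held fixed, and that is how it is tested.

## Loopless analysis

Thermodynamically infeasible loops are internal circulations (nullspace
vectors of `S` restricted to non-exchange reactions) that can inflate FVA
ranges without any boundary exchange. Loop removal follows the
CycleFreeFlux idea, LP-only: given a solution `v⁰`, fix all exchange fluxes
and the objective value, constrain each internal flux to keep the sign of
`v⁰` and not exceed its magnitude, optionally pin one reaction exactly, and
minimise the internal L1 norm. Because signs are fixed by the constraints,
the problem is linear in the original variables. Loop-free inputs are fixed
points of this operation.

Loopless FVA post-processes each per-reaction optimum: if the cycle-free
solution preserves the optimum, it is reported as-is; otherwise an "almost
loopless" step (pin the target reaction, remove all other loops, zero the
reactions that only carried loop flux through the target, re-optimise)
yields the reported bound. This mirrors the iteration used by the COBRA
toolkit and stays LP-only, at the cost of being a (tight, and on the bundled
fixtures exact) approximation of MILP loopless FVA — the exact MILP variant
is out of scope. On the fixtures the results are verified both against an
exact cycle-enumeration oracle and against the COBRA implementation.

## Metabolomics integration

- **Ratios** are ratios of replicate means (not medians), late over early
  timepoint, computed per condition; replicate counts and means are kept as
  provenance. Metabolites with a nonpositive denominator mean are dropped
  with a warning. Optional truncation bounds exist but default to
  pass-through, as does the handling of metabolites measured in only one
  condition (they simply get no ratio and leave the model untouched).
- **Artificial exchanges** are inserted *before* the reference pFBA, so a
  measured metabolite without a transport route can carry nonzero reference
  flux; inserting them afterwards would force a zero reference and make the
  added exchanges inert. Added reactions are flagged `is_artificial`, get
  bounds ±`default_bound` and the id `EX_<metabolite>_synthetic`.
- **Bound scaling**: the new capacity is `b = v* × ratio` on the active side
  of the reference flux only — an uptake reference rescales the lower bound,
  a secretion reference the upper bound, the opposite bound is untouched.
  Fixing both bounds would collapse the exchange's feasible range to a
  point and defeat a variability analysis. Ratios are strictly positive, so
  the scaling can never invert a bound pair or flip an exchange from
  uptake-capable to secretion-only.
- **Zero-reference exchanges** (reference flux ≈ 0) are left unchanged by
  default and recorded in the parameterized model's provenance notes;
  `clamp` (fix to zero) and `epsilon` (allow ±1e-6·default_bound) policies
  are available where a stricter reading is wanted.
- **Name mapping** is an explicit user-supplied table; there is deliberately
  no fuzzy matching, because silent mis-mapping is the dominant failure mode
  when joining metabolomics names to model species.

## Differential calls

Each condition's model is analysed with FVA constrained by *its own*
biomass optimum (a `shared_optimum` switch constrains both by the base
model's optimum for sensitivity analysis). A bound pair `(a, b)` is
"different" iff `|a − b| > max(abs_tol, rel_tol·max(|a|, |b|))` with
defaults `abs_tol = 1e-6`, `rel_tol = 1e-4`; without a tolerance, solver
jitter would flag every reaction. A reaction is *altered* if either bound
differs. Direction is classified from B − A: **decreased** when the maximum
dropped and the minimum did not drop (capacity shrank), **increased** as the
mirror image, **mixed** otherwise; the classification is antisymmetric
under swapping the condition labels. Note that a knockdown of a
biomass-essential uptake lowers the affected condition's optimum and drags
coupled reactions' minima down with it — such reactions come out "mixed",
and only genuine surplus-capacity losses (minimum pinned, maximum reduced)
are called "decreased". The binary altered call is always reported alongside
the direction.

## The toy model

The bundled fixture (18 metabolites, 24 reactions, +1 artificial exchange
in the pipeline) is built so every landmark is hand-verifiable:

- biomass consumes G3P, acetyl-CoA, AKG, glycine, serine, arginine and half
  a glutamine per unit; amino-acid uptakes cap at 5, so the FBA optimum is
  exactly 5;
- the parsimonious reference is a unique LP vertex (total flux 62.5,
  glucose uptake 5, AKG imported through its artificial exchange at 5);
- the PPP branch (G6PDH → TKT, plus an NADPH demand sink) carries no
  reference flux and acts as pure surplus capacity fed by glucose, so
  halving the glucose ratio in one condition shrinks the PPP maxima while
  the minima stay at zero — the canonical "decreased" pattern;
- a futile 2-cycle through a dead-ended pseudo-metabolite exists solely to
  exercise loopless analysis (standard FVA reports the default bound on it,
  loopless FVA zero).

Smaller fixtures isolate single behaviours: a linear chain (bound-limited
optimum 10), a diamond (two routes; pFBA total 30 through the short one;
with `fraction = 1.0`, `pfba_factor = 1.1` the cap of 33 leaves the long
route at most 3 and the short one in [7, 10]), and a chain+2-cycle network.

## Synthetic data

The generator emulates a two-genotype, two-timepoint targeted-metabolomics
design: conditions `flfl` and `r26`, timepoints 0 h and 20 h, 4 replicates
by default, baselines at plausible instrument scales, and per-(condition,
metabolite) true fold changes applied at the late timepoint. Replicate
noise is multiplicative log-normal with `ε ~ N(−σ²/2, σ²)`,
`σ² = ln(1 + cv²)`, so samples are positive, mean-unbiased, and have
multiplicative CV equal to `noise_cv` (default 0.2). It does **not** model
instrument drift, batch effects, missingness, or correlated noise between
metabolites — passing recovery tests therefore demonstrate correctness of
the pipeline's logic under the stated noise model, not robustness to every
artefact of real LC-MS data.

The knockdown scenario multiplies the late/early glucose fold change by
`strength` (default 0.5) in `r26` only and attaches ground truth computed by
running the deterministic, noise-free pipeline on the toy model: the
altered set, the decreased set, and its PPP subset (G6PDH, TKT, NADPHOX).
At the design's replicate scale (n = 4, CV 0.2) the PPP "decreased" call is
recovered in ≥ 90% of seeds; `scripts/acceptance.py` recomputes this
sensitivity over 20 seeds.

## Numerical choices

- Solver feasibility tolerance 1e-9; post-hoc invariant checks (mass
  balance, range sandwiches) at 1e-6; loop-detection zero cutoff 1e-6.
- FVA min/max pairs inverted by less than 1e-6 through solver jitter are
  clamped to their midpoint; larger inversions raise an error.
- Ties between equivalent LP optima are broken deterministically by the
  solver under a fixed variable ordering derived from the declared reaction
  order, so identical inputs give byte-identical outputs.
- The canonical JSON model dialect (schema in `docs/model_schema.json`)
  round-trips bit-identically; SBML L3/FBC-v2 support is a deliberate
  subset (species, stoichiometry, bounds, one active objective, subsystem
  and flags in reaction notes) — gene–protein–reaction rules, kinetic laws
  and annotation CV terms are ignored on read with a warning, since the
  pipeline uses none of them.

## Problem sizes

All shipped analyses run on desk-scale fixtures (≤ 25 reactions), chosen so
that every optimum can be verified by brute-force LP enumeration and by an
independent toolkit; the pipeline itself is size-agnostic and takes any
SBML/JSON model with finite bounds and a biomass objective.

## Known limitations

- Loopless FVA is the LP post-processing variant, not the MILP formulation;
  pathological networks can exist where the reported bound is conservative.
- Altered-flux calling is deterministic, as specified — no statistical test
  across replicate-level resamples is attempted.
- The exchange-bound scaling inherits the method's core assumption that
  pool-size ratios are a usable proxy for exchange-capacity ratios; the
  package implements, rather than validates, that assumption.
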