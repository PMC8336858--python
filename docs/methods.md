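# Methods

## Model and scope

`mcainfer` works at steady state, in log₂-fold-change coordinates, with
three classes of variables for a network of *n* internal metabolites and
*m* transport/reaction processes: concentration changes Δlog x, flux
changes Δlog J, and individual-activity changes Δlog v. The linear model

    Δlog x = C_x · Δlog v,      Δlog J = C_J · Δlog v

is the first-order (log-linear) expansion of the steady-state response
around a reference state, with C_x (n×m) and C_J (m×m) the scaled
concentration and flux control-coefficient matrices. It is exact for
infinitesimal perturbations and increasingly approximate for large ones;
the package therefore aims at *signs and trends*, not quantitative fold
changes. All logarithms are base 2 throughout (results are base-invariant;
reports state the base).

## Control coefficients from elasticities

`mca.compute_control_matrix` uses a link-matrix formulation written
entirely in scaled (log) coordinates:

1. independent metabolite rows N_R of the stoichiometric matrix (one
   dependent member per conserved pool is dropped);
2. the scaled link matrix L mapping independent log-deviations to all
   metabolites — the dependent member of a pool with members i and
   conserved total Σx_i satisfies Σ (x_i/x_dep)·dlog x_i = 0, so only
   *concentration ratios* of pool partners enter, never absolute
   concentrations;
3. steady-state balance N_R·diag(J)·dlog v = 0 with
   dlog v = dlog a + E·L·dlog x_ind, where E is the m×n scaled
   elasticity matrix and a the activities, giving

       C_x = −L (N_R diag(J) E L)⁻¹ N_R diag(J),     C_J = I + E C_x.

Only flux *ratios* and moiety concentration *ratios* appear (verified by a
scale-invariance test). The implementation is validated two independent
ways rather than against any particular historical variant of the matrix
method: (a) the full MCA theorem suite — flux summation (rows of C_J sum
to 1), concentration summation (rows of C_x sum to 0), generalized
connectivity (C_J E L = 0 and C_x E L = −L), moiety-pair proportionality
(r·C_x[A] + C_x[B] = 0 for a conserved pair with ratio r = A/B), and the
stoichiometric flux dependencies (N diag(J) C_J = 0) — at 1e-8; and
(b) brute-force centred finite differences d log(x, J)/d log(Vmax) on the
kinetic fixtures (relative step 1e-6), which agree to better than 1e-4
relative. The classical single-metabolite connectivity sum is only
asserted for metabolites outside conserved pools, where it applies; pool
members are covered by the generalized link-matrix form and reported as
skipped in `TheoremReport`.

Samples whose system matrix has condition number above 1e12 raise
`SingularSampleError` and are discarded upstream (counted in the
generation tally).

## Elasticity sampling

Where kinetics are unknown, scaled elasticities are sampled per reaction:

* **Saturation bounds.** Forward-rate elasticities are uniform on
  (0, h) for substrates and (−h, 0) for products; h defaults to 1
  (hyperbolic Michaelis–Menten saturation) and is the Hill coefficient
  for cooperative steps (`elasticity_upper`). The distribution is a
  package choice (independent uniforms); intervals are kept open by a
  margin δ = 1e-3 to avoid exact-saturation degeneracies.
* **Thermodynamics.** Net-rate elasticities follow from the
  disequilibrium ratio ρ = v_r/v_f ∈ [0, 1) (net-flux-positive
  orientation): ε^v = ρ/(1−ρ) + ε^vf for substrates and
  −ρ/(1−ρ) + ε^vf for products. |ε^v| → ∞ monotonically as ρ → 1
  (near-equilibrium sensitivity); at ρ = 0 the product term keeps the
  sampled ε^vf, so products matter even for irreversible steps. Reverse
  elasticities are never sampled — they are fixed by
  ε^vf − ε^vr = +1 (substrate) / −1 (product).
* **Competitive substrate/product pairs.** The constraint
  0 < ε^v_S + ε^v_P < 1 is ρ-invariant (the thermodynamic terms cancel),
  so it is imposed on the forward elasticities by direct construction:
  draw the sum uniformly on (0, 1), then split. A rejection-sampling
  backend exists as a cross-check; the direct construction avoids
  unbounded rejection loops.
* **Modifiers.** Allosteric activators/inhibitors get net-rate terms
  uniform on (0, 1) / (−1, 0). A metabolite that is both reactant and
  modifier of the same reaction contributes the *sum* of both terms —
  an interpretation (the alternative, replacing the reactant term, would
  discard the thermodynamic part).
* **Reproducibility.** One root seed; per-reaction substreams keyed by a
  stable CRC32 hash of the reaction id, so adding a reaction leaves other
  reactions' draws untouched. Ensembles index an extra substream per
  attempted sample, making problems order-independent.

Stoichiometric coefficients larger than one do not scale the elasticity
bounds (the saturation bounds are taken as mechanism-level properties;
per-reactant overrides cover exceptions). Pool partners appearing in one
reaction (e.g. NADP and NADPH in a dehydrogenase) are ordinary
substrate/product reactants of that reaction.

## Initial domains

Every variable starts at the generic enclosure [−E, +E], E = 3 log₂
units by default — an explicit assumption that larger changes are not
entertained. Measured variables are restricted to
[log₂(after_lo) − log₂(before) + σ, log₂(after_hi) − log₂(before) + σ],
clipped to the enclosure with a warning (the enclosure is an assumption,
not data, so clipping rather than rejection). σ is an additive volume
correction applied to every measurement-derived bound (default 0) and
never to enclosure bounds. Activities of boundary reactions — simplified
processes linking the modelled core to the wider metabolic environment —
copy their flux domains, slaving those lightly modelled steps to their
observed fluxes. Zero net flux is allowed only for boundary reactions;
scaled control coefficients are undefined at zero internal flux.

## Bound contraction

One problem = one control matrix + one domain table (+ activity-coupling
equalities Δlog v_a = Δlog v_b). Feasibility of the shared polytope is
decided once by a phase-1 LP; each of the n + 2m variables is then
minimised and maximised (2n + 4m LPs; for n=5, m=6 that is 34). The LP
backend is scipy's HiGHS; only proven-optimal statuses are accepted, an
unbounded status is an internal error (box bounds preclude it), and dual
simplex and interior point agree to 1e-6 on the fixtures. Final bounds
are clipped into the initial box to absorb solver round-off (≤1e-9).
Coupled activities are re-solved rather than copied by default, keeping
the 2n + 4m accounting; `dedupe=True` copies the representative's
interval instead and reports the smaller count.

A final interval is classified `positive` if lb > ε, `negative` if
ub < −ε, with ε = 1e-6 log₂ units: a required change must exclude zero,
so a bound exactly at zero classifies as `none`. Percent gain is
100·(w_init − w_final)/w_init; a point-valued initial domain reports 0.

Correctness of the projections is established against an exhaustive
vertex-enumeration oracle on small instances (all vertices of
{G u ≤ h} in activity space, per-variable min/max over the vertex set),
plus idempotence (re-contracting final domains reproduces them) and
monotonicity (tightening inputs never widens outputs).

## Ensembles and driver scoring

`EnsembleBoundContraction` keeps sampling matrices until `n_problems`
(default 100) pass the magnitude screen max|C| ≤ `cc_bound` (default
3.5, rejecting unrealistically sensitive models), recording the total
generated; it aborts if the acceptance rate falls below a configurable
floor. Sign percentages are reported over *solved* problems; the mean %
gain is over all variables and all *formulated* problems, infeasible ones
contributing zero gain — both denominators are recorded. Interval unions
and intersections of the final domains summarise magnitude and sampling
dependence; coinciding union and intersection bounds mean the result does
not depend on the sampled elasticities at all. The intersection may be
empty (lb > ub) when solved problems disagree on the exact interval.

Driver verdicts compare an expected direction (from differential gene
expression) with the sign percentages of the affected activity:
`supported` requires the same-direction percentage ≥ `strong` (default
80) with opposite-direction calls ≤ `opposite_max` (default 0);
an opposite percentage ≥ `strong` is `contradicted`; anything in between
is "supported/not supported, but sampling dependent". The thresholds are
package defaults, not measured quantities; when both percentages are zero
the verdict is "not supported, but sampling dependent" (no signal).

## Synthetic data generator

`fixtures` ships five topologies with explicit rate laws (mass action,
reversible uni-uni Michaelis–Menten in Haldane form, irreversible
multi-substrate MM with noncompetitive inhibitors, Hill): two linear
chains (one with reversible near-equilibrium steps), a branched pathway,
a minimal conserved-pool cycle, and a glycolysis/PPP-style branch (5
metabolites, 6 reactions, an NADP/NADPH moiety with one ramification).
The glycolysis-style model replicates a classic textbook *topology*; its
parameters are package-chosen for a well-conditioned positive steady
state and are not taken from any published model. Steady states are found
by Newton iteration (scipy `root`/hybr on the moiety-reduced system) with
an ODE-integration fallback, to residual < 1e-11 relative; solving is
deterministic given the initial point.

`simulate_adaptation` scales limiting rates, re-solves, and emits exact
log₂ ground truth plus a measurement set:

* **Noise-free measurements** carry an after-state interval of half-width
  0.1 log₂ units (instrument precision). This is not cosmetic: the
  constraint system is first-order while the re-solved steady state is
  exact, so zero-width measured domains are generically infeasible — the
  tolerance absorbs the linearization error.
* **Noisy measurements** model replicate averaging: the reported point is
  the geometric mean of `n_replicates` = 3 lognormal draws at the given
  CV (defaults 10% fluxes, 20% concentrations), with intervals built from
  the assay CV — mean ± 1 SD for concentrations, 95% CI for fluxes. The
  before-state is taken as known exactly.

What passing tests on these fixtures do **not** show about real data:
the generator has no systematic biases (volume shifts are handled by σ
but never injected), no model-structure error (the inference network is
exactly the simulation network), and its ρ values are read off the true
rate decomposition rather than estimated. Real applications inherit all
three gaps.

### Identifiability limit

Near-equilibrium steps (ρ close to 1) have small control-coefficient
columns: their activity changes barely move any flux or concentration,
so the data barely constrain them in return. In the glycolysis-style
fixture the isomerase sits at ρ ≈ 0.9 by construction and its activity
domain stays wide even under full, noise-free data — the correct
behaviour, mirrored in the validation suite, which asserts sign recovery
only for perturbed activities with ρ ≤ 0.5. Relatedly, the soundness
guarantee "no inferred sign contradicts the truth" is conditional on
every measured interval containing its true value; with mean ± 1 SD
concentration intervals a miss is expected ~8% of the time per
measurement, and an inference from such data can legitimately disagree
with the ground truth. The validation suite asserts zero contradictions
whenever the intervals bracket the truth; the acceptance script reports
the unconditional count as well.

## Numerical choices (summary)

| quantity | value | note |
|---|---|---|
| enclosure E | 3 log₂ units | generic bound on all changes |
| σ volume correction | 0 | additive, measurement-derived bounds only |
| control-coefficient screen | ±3.5 | ensemble acceptance filter |
| ensemble size | 100 problems | default; scale with network size |
| sign tolerance ε | 1e-6 log₂ | bounds at 0 classify as `none` |
| sampling margin δ | 1e-3 | open-interval guard |
| condition-number cutoff | 1e12 | singular-sample discard |
| steady-state residual | <1e-11 rel. | Newton + ODE fallback |
| theorem tolerance | 1e-8 | acceptance level; machine precision observed |
| LP agreement | 1e-6 | across HiGHS variants and vertex oracle |

Validation problem sizes (chosen to exercise every code path at small
cost): 1,050 sampled elasticity sets across five topologies for the
theorem suite; 100 random domain configurations against the vertex
oracle on ≤3-metabolite/≤3-reaction networks; 200 simulated adaptations
for sign recovery; one 100-problem ensemble.

## Known limitations

* First-order model: quantitative fold-change prediction is out of scope
  by design; only signs/trends are claimed.
* ρ is treated as known and fixed per reaction; the inference's sign
  calls can depend on it strongly (see identifiability above).
* Elasticity sampling distribution (independent uniforms) is an
  assumption; only the bounds, not the shape, are constrained by theory.
* The ensemble size needed for stable percentages grows with network
  size; 100 is adequate for the shipped fixtures, not a universal value.
* No SBML/SBtab import; the package JSON/TSV formats are the interface.
* No statistical test on sign percentages; they are descriptive.
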