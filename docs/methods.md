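# Methods

## Model

The package implements a deterministic mass-action model of APC-catalyzed
inactivation of human factor Va in the presence of factor Xa and
prothrombin.  The state is the vector of molar concentrations of 24
species: free APC, FXa and PT; the intact cofactor FVa and its partially
proteolyzed forms FVa_i^506, FVa_i^306 and FVa_i^306/506 (heavy-chain
fragments still non-covalently associated); the fully inactivated cofactor
FVa^1-306·FVa^LC ("FVai"); three free heavy-chain fragments; and the
binary/ternary complexes the chemistry permits (APC·substrate, FXa·cofactor,
FVa·PT, and prothrombinase·PT species).

Cleavage is random-order and independent at the two sites: every
APC·substrate complex forms reversibly (k_on 1e8 M⁻¹s⁻¹, k_off 0.7 s⁻¹ for
all APC–cofactor pairs, including the inactive product — product
inhibition) and resolves with k_cat 1.0 s⁻¹ at Arg506 or 0.192 s⁻¹ at
Arg306.  Species cleaved at Arg306 shed their C-terminal fragments
spontaneously: 0.028 s⁻¹ when free, 0.0035 s⁻¹ while FXa-bound (with or
without PT in the ternary complex).  FXa binds the intact cofactor with
K_D 0.5 nM and every partially cleaved form with twice that; PT binds free
FVa with K_D 700 nM and any assembled prothrombinase with the
Michaelis-like ratio 103/1e8 = 1.03 µM.  FXa- and PT-bound cofactor is not
an APC substrate, with a single exception: APC cleaves Arg306 of the
FXa-bound Arg506-cleaved species ("R18") as one bimolecular step
(default 5.0e6 M⁻¹s⁻¹, no Michaelis complex).  PT is never consumed — FXa
is active-site-blocked in every modelled experiment, so no thrombin
chemistry exists in the network.

Key structural choices where the source material left room:

* R18 acts only on FXa·FVa_i^506, not on its PT-ternary form; exactly one
  reaction was added to the network and the species count stays at 24.
* Heavy-chain fragment dissociation occurs only from the species the
  reaction tables list — free and FXa-bound Arg306-cleaved forms — not
  from APC-bound intermediates (the literal reading of the tables).
* APC does not bind FVa_i^306/506; product inhibition enters only through
  the inactive FVa^1-306·FVa^LC cofactor.
* In the prothrombinase-activity observable the full-weight term covers
  all intact-FVa species and the 20 % weight applies to every partially
  cleaved species whose fragments remain associated, regardless of binding
  partner; dissociated cofactor contributes nothing.  (The assay this
  mirrors adds saturating prothrombin and measures potential activity;
  whether FXa-bound partially cleaved species should carry full weight is
  not determinable from the assay description, so the uniform 20 % reading
  is used.)

## Conserved moieties and observables

Each species carries a composition over seven conserved moieties: APC,
FXa, PT, the FVa light chain, and the three heavy-chain proteolytic
segments (1-306, 307-506, 507-679/709).  Cleavage rearranges fragments but
never creates or destroys a segment, so the moiety totals are exact
invariants of the closed system and every elementary reaction is checked
against them at network construction.

Western-blot band observables sum, per fragment class (intact heavy chain,
1-506, 1-306, 307-679/709, 307-506, 507-679/709), all species carrying
that fragment — associated or dissociated from the light chain.  Because
each cofactor molecule has exactly one N-terminal state, the identity
HC + (1-506 band) + (1-306 band) = total cofactor holds at every instant
and is used as a structural test.  Cofactor activity is the intact-HC band
relative to t = 0.  Time courses can be normalized to their maximal value
(RMV), matching how densitometry is reported; initial rates are obtained
by fitting A·e^(−kt) to the RMV trace over the first six minutes at the
experimental sampling times (0, 0.5, 1, 2, 3, 4, 6 min) and reporting
A·k·(starting concentration).  A plateau term is admitted only when it
decisively improves the fit (F-ratio > 4), since the reference fits are
monophasic decays with no stated baseline.

## Pre-incubation equilibria and the membrane competition

Experiments preform complexes before the protease is added, so initial
conditions come from equilibrium solvers rather than from relaxing the
ODEs: the pairwise binding quadratic (numerically stable branch), and a
bracketed root find on free FVa — with inner, also bracketed, solves for
free PT and FXa — for the simultaneous FVa/FXa/PT equilibrium (residuals
checked to 1e-10 relative).  APC always enters free at t = 0 and is never
part of the pre-incubation.

Membrane binding-site competition is a static pre-processing step, not an
ODE species: 20 µM phospholipid with an accessible outer leaflet (2/3 of
the lipid) and one protein site per 30–60 lipids yields 222–444 nM sites.
The accessible-fraction factor is required for that arithmetic to close;
it is the only reading under which the 30–60 packing range maps onto the
stated site range.  PT (membrane K_D 230 nM), FVa (2.72 nM) and APC
(500 nM, treated as non-catalytic cargo) compete for the shared pool; the
solver finds free sites by bracketed root finding.  Across the site range
the APC bound fraction runs 6–13 % (9.5 % at mid-range), PT occupies
77–78 % of sites, and FVa binding approaches saturation at the dense end.
PT-containing kinetic scenarios use a fixed 11 % effective-APC fraction by
default (the modelled operating point); the computed mode is exposed for
sensitivity analysis.  APC's membrane occupancy is not subtracted from the
ODE species — the kinetic network remains a solution-phase description
with a rescaled enzyme concentration.

## Numerics

* Default integrator: LSODA via `scipy.integrate.solve_ivp`.  The PT
  binding steps relax on ~7 ms timescales (k_off 103 s⁻¹, k_on·[PT] ≈
  140 s⁻¹ at 1.4 µM PT), so the 20-minute figure scenarios are mildly
  stiff and explicit fixed-step integration at practical steps is
  unstable.  Tolerances default to rtol 1e-10, atol 1e-18 M: the accuracy
  delivered *at the sampled times* includes the solver's dense-output
  interpolation error, which runs orders of magnitude above rtol, and
  these defaults keep the end-to-end relative error below 1e-8 on
  first-order closed-form benchmarks at negligible cost (milliseconds per
  scenario).
* A classical fixed-step RK4 integrator (default step 1 ms) is retained as
  an independent implementation; tests require rk4/adaptive agreement to
  1e-6 relative and verify fourth-order error contraction.
* Every simulation is gated on moiety conservation: relative drift above
  0.1 % raises an error with guidance (reduce step / tighten tolerances);
  typical drift at defaults is ≤1e-13.  Concentrations in (−1e-12, 0) M
  are clamped to zero as round-off; anything more negative aborts.
* Sampling defaults to a 1 s grid over the scenario horizon.
* The model contains no randomness anywhere; reruns are bit-identical.

## Problem sizes

All bundled scenarios are desk-scale: 24 ODEs over 6–20 minute horizons at
1 s sampling, equilibrium solves over at most three unknowns, and scans of
at most a handful of parameter values.  The full test suite and the
result-reproduction script each run in a few seconds.

## Known limitations

* Cleavage at Arg679 is not modelled (negligible effect on cofactor
  activity), nor are protein S, thrombomodulin, EPCR, or APC generation
  from protein C.
* Thrombin generation is absent by construction: PT binds but is never
  turned over, matching the active-site-blocked FXa experiments the model
  targets.  Coupling to a thrombin-generating prothrombinase requires
  adding the catalytic step.
* Membrane composition effects beyond the site-count arithmetic are out of
  scope; lipid is a static site pool, not a species.
* The monoexponential initial-rate convention matches the reference
  analysis of empirical densitometry; rates extracted with other windows
  or samplings will differ, since the underlying progress curves are not
  exactly exponential.
* Two late-time simulation landmarks sit a few percentage points from the
  published simulated values (the residual Arg506-fragment fraction at
  20 min in the free-FVa scenario, and the 6-minute proteolysis extent at
  the tightest prothrombinase K_D); the corresponding tests assert the
  published values at their stated tolerances and are left failing rather
  than widened.  The gap is insensitive to the association-rate split, to
  the intermediate-complex K_D convention, and to the R18 setting, and a
  lumped free-enzyme formulation moves it far in the wrong direction, so
  it most likely reflects unpublished details of the original simulator
  rather than a structural misreading.  All other landmarks —
  equilibrium concentrations, lumped second-order constants, initial
  rates, peak times, and the combined-protection endpoint — reproduce
  within their stated tolerances.
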