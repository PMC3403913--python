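# apcva

A kinetic model of **activated protein C (APC) inactivation of human factor
Va and the prothrombinase complex**, for coagulation modellers who need the
protein C pathway's cofactor-shutdown step as a reusable, testable module.

Factor Va (FVa) is the non-enzymatic cofactor of prothrombinase
(FXa·FVa on a phospholipid membrane), the complex that produces thrombin.
APC shuts thrombin generation down by cleaving the FVa heavy chain at
Arg506 (fast) and Arg306 (slow) in random order; full inactivation requires
spontaneous dissociation of the C-terminal heavy-chain fragments after the
Arg306 cut.  Both FXa and prothrombin (PT) *protect* FVa by sequestering it
in complexes APC cannot attack — with one exception: APC can still reach
Arg306 of the Arg506-cleaved cofactor while it is bound to FXa (the
reaction labelled R18 here).  On top of the solution chemistry, PT at
plasma levels crowds APC off the limited pool of membrane binding sites, so
only ~11 % of APC is catalytically relevant in PT-containing systems.

## The model

* **Network** — 24 species, 24 mass-action reactions (each reversible
  equilibrium counted once), 14 named rate constants.  Association steps
  such as APC + FVa ⇌ APC·FVa carry k_on = 1×10⁸ M⁻¹s⁻¹ / k_off = 0.7 s⁻¹
  (K_D = 7 nM); catalysis k_cat(Arg506) = 1.0 s⁻¹ and k_cat(Arg306) =
  0.192 s⁻¹ (human-adjusted; the original bovine-derived 0.064 s⁻¹ is
  available as the `hockin` variant).  The implied lumped second-order
  constants k_cat/K_D are 1.43×10⁸ (Arg506) and 2.74×10⁷ M⁻¹s⁻¹ (Arg306).
* **Kinetics** — stiff-capable adaptive integration (LSODA) plus a
  fixed-step fourth-order Runge–Kutta integrator for cross-validation;
  every run is gated on conservation of the APC/FXa/PT/light-chain/
  heavy-chain-segment moieties.
* **Equilibria** — closed-form pairwise binding, a bracketed solver for the
  simultaneous FVa/FXa/PT equilibrium, and the shared-site membrane
  competition that yields the effective APC concentration.
* **Observables** — Western-blot band totals (fragments counted whether
  associated or dissociated from the light chain), cofactor activity
  (intact heavy chain), prothrombinase activity (intact species + 20 % of
  the still-associated partially cleaved species), relative-to-maximal-value
  normalization, and monoexponential initial-rate fits.
* **Scenarios** — presets for every simulated experimental condition,
  parameter scans (prothrombinase K_D, R18 rate, APC, membrane sites), a
  YAML/TOML config format, and tidy CSV + JSON-provenance output.

## Worked example

```python
from apcva import NetworkVariant, preset, run_scenario

res = run_scenario(preset("fig3_fva_only",
                          variant=NetworkVariant(arg306_rate="hockin")))
band = res.observables["1-506"]
print(f"1-506 band peaks at {band.peak_time()/60:.2f} min")
act = res.observables["cofactor_activity"]
print(f"cofactor activity at 1 min: {100*act.value_at(60):.0f} %")
```

prints

```
1-506 band peaks at 3.77 min
cofactor activity at 1 min: 49 %
```

— 0.5 nM APC on 20 nM FVa: half the cofactor activity is gone within a
minute (driven by the fast Arg506 cleavage), while the transient
Arg506-cleaved fragment accumulates for a few minutes before the slower
Arg306 cleavage clears it.  The `examples/` directory has one short script
per capability (network inventory, free-FVa inactivation, pre-incubation
equilibria, the FXa-protection K_D scan, combined PT+FXa protection).

The same scenarios are available from the shell:

```bash
apcva run --preset fig9_pt_fxa --apc 2nM --out results/
apcva scan --param kd_XV --values 0.1nM,0.5nM,0.75nM --preset fig4c_sat
apcva equilibrium --fva 20nM --fxa 30nM --pt 1.4uM
apcva membrane --site-total 385nM
```

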