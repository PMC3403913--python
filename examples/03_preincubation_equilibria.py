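"""Pre-incubation equilibria and the membrane binding-site competition.

The experiments preform complexes before adding the protease; these
solvers compute the equilibrium initial conditions.  The membrane
calculation shows how plasma-level prothrombin crowds APC off the
phospholipid surface, leaving only ~10 % of it catalytically relevant.
"""

from apcva import (
    MembraneCompetition,
    PairwiseProblem,
    TernaryPreincubation,
    membrane_bound_fractions,
    pairwise_complex,
    ternary_preincubation,
)

# Prothrombinase preformed from 200 pM FVa + 100 pM FXa
for kd in (0.5e-9, 0.1e-9):
    x = pairwise_complex(PairwiseProblem(0.2e-9, 0.1e-9, kd))
    print(f"prothrombinase at K_D {kd * 1e9:.1f} nM: {x * 1e12:.1f} pM")

# FVa·PT at physiological prothrombin
vpt = pairwise_complex(PairwiseProblem(20e-9, 1.4e-6, 700e-9))
print(f"FVa-PT complex (20 nM FVa, 1.4 uM PT): {vpt * 1e9:.1f} nM")

# Three-way equilibrium of FVa, FXa* and PT
s = ternary_preincubation(TernaryPreincubation(20e-9, 30e-9, 1.4e-6))
pool = (s["FXa:FVa"] + s["FXa:FVa:PT"]) * 1e9
print(f"\nternary equilibrium: {pool:.1f} nM FVa in prothrombinase complexes,")
print(f"  {s['FVa:PT'] * 1e12:.0f} pM in FVa-PT, {s['FVa'] * 1e12:.0f} pM free")

# Membrane site competition across the plausible site-density range
m = MembraneCompetition()
lo, hi = m.site_range()
print(f"\nbinding sites from 20 uM lipid (outer leaflet, 30-60 lipids/site): "
      f"{lo * 1e9:.0f}-{hi * 1e9:.0f} nM")
for st in (lo, 0.5 * (lo + hi), hi):
    res = membrane_bound_fractions(m.with_site_total(st))
    print(f"  sites {st * 1e9:3.0f} nM: APC bound {100 * res.bound_fraction['APC']:5.1f} %, "
          f"FVa bound {100 * res.bound_fraction['FVa']:.1f} %, "
          f"PT occupies {100 * res.site_occupancy['PT']:.1f} % of sites")
print("-> the effective APC concentration in the PT scenarios is ~11 % of total")
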