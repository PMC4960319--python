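"""Simulate the full redox-switch scheme and watch zinc release gate it.

Builds the mass-action network (binding + oxidation + PAR capture), mixes
2 uM sensor-sigma complex with 1 mM oxidant, and reports how fast zinc
leaves and sigma is liberated.
"""

import numpy as np

from redoxswitch import SchemeParams, build_scheme, simulate, observe
from redoxswitch.fitting import fit_exponential

params = SchemeParams()
scheme = build_scheme(params)
print(f"species: {', '.join(scheme.species)}")
print(f"reactions: {len(scheme.reactions)}, conserved moieties: "
      f"{[m[0] for m in scheme.conserved_moieties]}")

ox0 = 1e-3  # 1 mM oxidant
kobs_expected = params.k2_ox * ox0 / (params.K1_ox + ox0)
times = np.linspace(0, 7 * np.log(2) / kobs_expected, 300)
traj = simulate(scheme, {"RZnS": 2e-6, "Ox": ox0}, times)

par_trace = observe(traj, "absorbance_500", {"ZnPAR": 6.6e4})
fit = fit_exponential(par_trace)
released = traj.concentrations["ZnPAR"][-1]
freed = traj.concentrations["S"][-1]

print(f"\nzinc release at [Ox] = {ox0*1e3:.0f} mM:")
print(f"  observed rate    {fit.kobs:.4f} s^-1")
print(f"  closed form      {kobs_expected:.4f} s^-1  (k2[Ox]/(K1+[Ox]))")
print(f"  zinc captured    {released*1e6:.2f} uM of 2.00 uM")
print(f"  sigma released   {freed*1e6:.2f} uM")
print("\nThe observed rate sits on the rapid-equilibrium hyperbola: zinc")
print("release, not oxidant encounter, limits oxidation of the sensor.")
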