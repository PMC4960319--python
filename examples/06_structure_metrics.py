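"""Structural metrics: distances, ensemble SASA and crosslink checks.

Runs on a small synthetic helix ensemble generated in-script so the example
is self-contained.  With network access the same calls apply directly to
the deposited sensor ensembles — reduced/zinc-bound (PDB 5frf) and oxidized
(PDB 5frh) — e.g. the His37 NE2 to Cys11 SG distance that reports
destruction of the metal site, and the ~13% loss of solvent-accessible
surface on oxidation.
"""

import math
import tempfile
from pathlib import Path

import numpy as np

from redoxswitch import structure as st

# build a 3-model synthetic helix ensemble (CA trace + one SG/NE2 pair)
rng = np.random.default_rng(0)
lines = []
for model in range(1, 4):
    lines.append(f"MODEL     {model:>4}\n")
    serial = 1
    for i in range(12):
        x = 2.3 * math.cos(i * 1.745) + rng.normal(0, 0.2)
        y = 2.3 * math.sin(i * 1.745) + rng.normal(0, 0.2)
        z = 1.5 * i + rng.normal(0, 0.2)
        lines.append(f"ATOM  {serial:5d} {'CA':<4} {'ALA':>3} A{i+1:4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
        serial += 1
    lines.append(f"ATOM  {serial:5d} {'SG':<4} {'CYS':>3} A{2:4d}    "
                 f"{1.0:8.3f}{2.0:8.3f}{3.0:8.3f}  1.00  0.00           S\n")
    lines.append(f"ATOM  {serial+1:5d} {'NE2':<4} {'HIS':>3} A{9:4d}    "
                 f"{-1.0:8.3f}{1.5:8.3f}{12.0:8.3f}  1.00  0.00           N\n")
    lines.append("ENDMDL\n")
lines.append("END\n")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "synthetic_ensemble.pdb"
    path.write_text("".join(lines))
    ens = st.load_ensemble(path)

    print(f"ensemble: {len(ens)} models, {len(ens.models[0])} atoms each")

    d = st.atom_distance(ens.lowest_energy, ("A", 9, "NE2"), ("A", 2, "SG"))
    print(f"His NE2 - Cys SG distance (model 1): {d:.1f} A")
    print("  (in the oxidized sensor 5frh this pair sits ~15 A apart —")
    print("   the zinc site is destroyed; run with fetch_pdb('5frh'))")

    mean, sd = st.ensemble_sasa(ens, residue_range=(1, 12), n_points=960)
    print(f"\nensemble SASA (residues 1-12): {mean:.0f} +/- {sd:.0f} A^2")
    print("  (reduced vs oxidized sensor ensembles differ by ~13% here)")

    links = [st.Crosslink(("A", 1), ("A", 8), "BS2G"),
             st.Crosslink(("A", 2), ("A", 12), "BS3")]
    report = st.check_crosslinks(ens.lowest_energy, links)
    for line in report.details:
        print(f"  {line}")
    print(f"crosslinks satisfied: {report.fraction_satisfied:.0%}")

print("\nFor the deposited ensembles (network required):")
print("  path = st.fetch_pdb('5frh'); ens = st.load_ensemble(path)")
print("  st.atom_distance(ens.lowest_energy, ('A',37,'NE2'), ('A',11,'SG'))")
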