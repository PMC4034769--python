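"""Turn coupling scores into sigmoidal distance restraints.

Fits a small planted complex, selects the top inter-protein pairs and
writes both centroid (Cbeta-Cbeta) and ambiguous full-atom restraints,
printing the Rosetta-style constraint lines.
"""

from pathlib import Path

import coevcontact as cc
from coevcontact.potts import FitOptions
from coevcontact.restraints import write_rosetta_constraints

planted = [(1, 11), (4, 14), (7, 17)]
spec = cc.PlantedComplexSpec(
    p=10, q=10, planted_pairs=planted, coupling=1.5, n_seqs=600, seed=3
)
paln, _ = cc.sample_potts(spec)
model = cc.fit_plm(paln, opts=FitOptions(max_iter=200))
scores = cc.score_pairs(model, boundary=10, N=600)

seq_a = "ACDEFGHIKL"  # query sequences give residue types for atom naming
seq_b = "MNPQRSTVWY"
centroid = cc.build_restraints(scores, "centroid", seq_a, seq_b, top_k=3)
fullatom = cc.build_restraints(scores, "fullatom", seq_a, seq_b, top_k=2)

print("centroid restraints (atom_i - atom_j, weight ~ ncs, sigmoid cutoff/slope):")
for r in centroid:
    print(f"  {r.atom_i} - {r.atom_j}  weight={r.weight:.2f} "
          f"cutoff={r.cutoff} slope={r.slope}")
print(f"\nfull-atom: {len(fullatom)} ambiguous restraints; first has "
      f"{len(fullatom[0].alternatives)} side-chain atom-pair alternatives "
      f"(cutoff 5.5 A, slope 4)")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
write_rosetta_constraints(centroid, out / "centroid.cst")
print(f"\nRosetta constraint lines written to {out / 'centroid.cst'}:")
print((out / "centroid.cst").read_text())
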