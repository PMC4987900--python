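"""Cluster conformers in dihedral space and recover the two states.

The pairwise metric is the mean circular distance over the selected
phi/psi angles of positions 9-13; complete-linkage clustering cut at the
default 60-degree radius splits the ensemble into exactly the two
generating families.
"""

import numpy as np

from confstats import (ChainSpec, FamilySpec, PositionSelection,
                       align_by_numbering, build_ensemble, cluster, to_newick)
from confstats.torsions import all_torsions

offsets = np.zeros(20)
offsets[8:13] = 120.0
base = ChainSpec(sequence="AKLSEDTFRVMAKLSEDTFR", perturbation_sd=5.0, seed=7)
structures, _ = build_ensemble(base, 10, [
    FamilySpec("closed"), FamilySpec("open", {"phi": offsets, "psi": offsets})],
    seed=7)

alignment = align_by_numbering(structures)
maps = {s.label: {(r.residue_index, r.angle): r.value
                  for r in all_torsions(s) if r.value is not None}
        for s in structures}
selection = PositionSelection(ranges=[(9, 13)], angles={"phi", "psi"})

dm, tree, result = cluster(maps, [s.label for s in structures], selection,
                           alignment, radius=60.0)
print(f"{result.n_clusters} clusters at radius {result.radius} deg")
for s in structures:
    print(f"  {s.label:12s} family={s.family:7s} cluster={result.labels[s.label]}")
print("newick:", to_newick(tree)[:80], "...")
# Within-family distances sit near 5-6 degrees (the generating noise);
# between-family distances near 120, so the 60-degree cut separates the
# two states with no misassignment.
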