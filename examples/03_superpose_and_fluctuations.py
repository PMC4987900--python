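"""Superpose an ensemble and locate its flexible region.

After least-squares superposition of every structure onto the first one
(over shared backbone N, CA, C, O atoms), the per-position Cartesian
fluctuation profile peaks where the two conformational states diverge.
"""

import numpy as np

from confstats import (ChainSpec, FamilySpec, align_by_numbering,
                       build_ensemble, cartesian_table, superpose_ensemble)

offsets = np.zeros(20)
offsets[8:13] = 120.0
base = ChainSpec(sequence="AKLSEDTFRVMAKLSEDTFR", perturbation_sd=5.0, seed=7)
structures, _ = build_ensemble(base, 10, [
    FamilySpec("closed"), FamilySpec("open", {"phi": offsets, "psi": offsets})],
    seed=7)

alignment = align_by_numbering(structures)
result = superpose_ensemble(structures, alignment, atom_set="backbone")
print(f"reference: {result.reference}; "
      f"max RMSD to reference: {max(result.rmsd_to_reference.values()):.2f} A")

rows = [r for r in cartesian_table(structures, alignment) if r.group == "backbone"]
peak = max(rows, key=lambda r: r.fluctuation)
print("position  backbone fluctuation (A)")
for r in rows:
    marker = "  <- peak" if r.position == peak.position else ""
    print(f"{r.position:8d}  {r.fluctuation:8.3f}{marker}")
# The peak falls inside (or just downstream of) the switching stretch
# 9-13; flat near-zero values elsewhere mark the rigid helical scaffold.
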