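"""Compute backbone/sidechain torsions and per-position circular statistics.

Builds a small two-family ensemble in memory, extracts phi/psi/omega and
chi angles, and summarizes the psi angle at the switching position: the
family means sit near the two generating centers (-47 and +73 degrees)
while the global circular sd is large, flagging the position as bimodal.
"""

import numpy as np

from confstats import (ChainSpec, FamilySpec, align_by_numbering,
                       build_ensemble, position_summaries)
from confstats.torsions import all_torsions

offsets = np.zeros(20)
offsets[8:13] = 120.0
base = ChainSpec(sequence="AKLSEDTFRVMAKLSEDTFR", perturbation_sd=5.0, seed=7)
structures, _ = build_ensemble(base, 10, [
    FamilySpec("closed"), FamilySpec("open", {"phi": offsets, "psi": offsets})],
    seed=7)

alignment = align_by_numbering(structures)
torsions = {s.label: all_torsions(s) for s in structures}

summaries = position_summaries(torsions, structures, alignment)
print("psi at position 10 (inside the switching stretch):")
for c in summaries:
    if c.position == 10 and c.angle == "psi":
        print(f"  {c.family:>7s}: n={c.n:2d} mean={c.mean:8.2f} sd={c.sd:6.2f} deg")
# The per-family sds stay near the generating 5-degree noise; the GLOBAL
# sd is an order of magnitude larger because it mixes both states.
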