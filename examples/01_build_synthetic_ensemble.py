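"""Build a torsion-controlled synthetic ensemble and write it to disk.

Two conformational families share a 20-residue sequence; the "open"
family is rotated by 120 degrees in phi and psi over positions 9-13,
mimicking a loop that switches between two states.  Each structure adds
wrapped-normal noise (sd 5 degrees) around its family center.
"""

import numpy as np

from confstats import ChainSpec, FamilySpec, build_ensemble
from confstats.builder import write_ensemble

offsets = np.zeros(20)
offsets[8:13] = 120.0
base = ChainSpec(sequence="AKLSEDTFRVMAKLSEDTFR", phi=-57.0, psi=-47.0,
                 omega=180.0, perturbation_sd=5.0, seed=7)
families = [FamilySpec("closed"),
            FamilySpec("open", {"phi": offsets, "psi": offsets})]

structures, list_text = build_ensemble(base, n=10, families=families, seed=7)
write_ensemble(structures, list_text, "scratch/ensemble")

print(f"built {len(structures)} structures "
      f"({len(structures[0].residues)} residues each)")
print("structure list:")
print(list_text[:200])
# Each line is "<basename> <chain spec> <family>"; the PDB files next to
# it are valid inputs for every other stage of the package.
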