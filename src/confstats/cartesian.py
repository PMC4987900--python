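"""Per-alignment-position Cartesian fluctuations and mean B-factors.

For each atom name present in >= 2 structures at a position, the per-atom
fluctuation is the population root-mean-square deviation about the mean
position, f_a = sqrt((1/N_a) sum_s |r_sa - r_a_mean|^2); the row value
RMS-combines the per-atom fluctuations.  Atoms seen in only one structure
still contribute to the mean B-factor.  Structures must already be
superposed for the numbers to be meaningful.

Groups: backbone = {N, CA, C, O}; sidechain = every other heavy atom
(hydrogens and OXT excluded).  A position occupied only by glycine has an
empty sidechain group and reports fluctuation 0 — the classic zero points
in sidechain fluctuation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .io import Structure

__all__ = ["CartesianRow", "cartesian_fluctuation", "cartesian_table",
           "GROUPS"]

BACKBONE = {"N", "CA", "C", "O"}
EXCLUDED = {"OXT"}
GROUPS = ("backbone", "sidechain")


def _in_group(name: str, group: str) -> bool:
    if name in EXCLUDED or name.startswith("H") or name[:1].isdigit():
        return False
    return (name in BACKBONE) == (group == "backbone")


@dataclass
class CartesianRow:
    position: int
    group: str
    fluctuation: float  # Angstrom
    mean_b: float       # Angstrom^2
    n_structures: int
    n_atoms: int        # distinct atom names contributing to the fluctuation


def cartesian_fluctuation(structures: list[Structure], alignment: Alignment,
                          position: int, group: str) -> CartesianRow:
    """Fluctuation and mean B-factor of one atom group at one position."""
    col = alignment.column_of(position)
    coords: dict[str, list[np.ndarray]] = {}
    b_values: list[float] = []
    n_structures = 0
    for s in structures:
        ridx = alignment.cells[s.label][col]
        if ridx is None:
            continue
        res = s.residues[ridx]
        found = False
        for a in res.atoms:
            if not _in_group(a.name, group):
                continue
            found = True
            coords.setdefault(a.name, []).append(a.position)
            b_values.append(a.b_factor)
        if found:
            n_structures += 1

    fluct_sq = []
    for name, pts in coords.items():
        if len(pts) < 2:
            continue
        arr = np.array(pts)
        dev = arr - arr.mean(axis=0)
        fluct_sq.append(float(np.mean(np.sum(dev ** 2, axis=1))))
    fluctuation = float(np.sqrt(np.mean(fluct_sq))) if fluct_sq else 0.0
    mean_b = float(np.mean(b_values)) if b_values else 0.0
    return CartesianRow(position=position, group=group, fluctuation=fluctuation,
                        mean_b=mean_b, n_structures=n_structures,
                        n_atoms=len(fluct_sq))


def cartesian_table(structures: list[Structure],
                    alignment: Alignment) -> list[CartesianRow]:
    """All positions x both groups, ordered by position then group."""
    return [cartesian_fluctuation(structures, alignment, pos, group)
            for pos in alignment.positions for group in GROUPS]
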