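"""Backbone (phi, psi, omega) and sidechain (chi1..chi4) torsion angles.

Sign convention: the torsion of a bonded quadruple p1-p2-p3-p4 is the
signed angle between the plane (p1,p2,p3) and the plane (p2,p3,p4), with
the sign taken from the projection of n1 x n2 onto the central bond
p3 - p2 (IUPAC).  Values lie in (-180, 180].

phi(i) = C(i-1)-N(i)-CA(i)-C(i), psi(i) = N(i)-CA(i)-C(i)-N(i+1) and
omega(i) = CA(i)-C(i)-N(i+1)-CA(i+1) are defined only when the neighbour
residue is contiguous: phi is undefined at the N-terminal side of a run of
contiguous residues, psi and omega at the C-terminal side.  Two residues
are contiguous when their peptide C-N distance is below 2.5 Angstrom.
Missing atoms always yield UNDEFINED, never an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Residue, Structure

__all__ = ["UNDEFINED", "TorsionRecord", "torsion", "backbone_torsions",
           "sidechain_torsions", "all_torsions", "structure_torsion_map",
           "CHI_ATOMS", "PEPTIDE_BOND_MAX"]

log = logging.getLogger(__name__)

UNDEFINED = None

#: Maximum C(i)-N(i+1) distance (Angstrom) for residues to count as bonded.
PEPTIDE_BOND_MAX = 2.5

# Normative chi atom-quadruple table.  chi1 = N-CA-CB-G; subsequent chis
# walk outward along the sidechain.  Residues absent here (Ala, Gly) have
# no chi angles; two-fold-degenerate terminal chis are reported raw.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
}


@dataclass
class TorsionRecord:
    structure: str
    residue_index: int
    residue: Residue
    angle: str
    value: float | None  # degrees in (-180, 180], or UNDEFINED


def torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, degrees in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-9 or np.linalg.norm(b1) < 1e-9 or np.linalg.norm(b3) < 1e-9:
        raise ValueError("coincident points in torsion")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("collinear points in torsion")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _pos(res: Residue, name: str):
    a = res.atom(name)
    return None if a is None else a.position


def _contiguous(prev: Residue, curr: Residue) -> bool:
    c, n = _pos(prev, "C"), _pos(curr, "N")
    if c is None or n is None:
        return False
    return bool(np.linalg.norm(n - c) < PEPTIDE_BOND_MAX)


def _try_torsion(points) -> float | None:
    if any(p is None for p in points):
        return UNDEFINED
    try:
        return torsion(*points)
    except ValueError:
        return UNDEFINED


def backbone_torsions(s: Structure) -> list[TorsionRecord]:
    """phi, psi and omega for every residue (UNDEFINED where not applicable).

    omega is attributed to residue i (the peptide bond towards i+1).
    """
    out = []
    n = len(s.residues)
    for i, res in enumerate(s.residues):
        prev_ok = i > 0 and _contiguous(s.residues[i - 1], res)
        next_ok = i < n - 1 and _contiguous(res, s.residues[i + 1])
        phi = psi = omega = UNDEFINED
        if prev_ok:
            phi = _try_torsion([_pos(s.residues[i - 1], "C"), _pos(res, "N"),
                                _pos(res, "CA"), _pos(res, "C")])
        if next_ok:
            nxt = s.residues[i + 1]
            psi = _try_torsion([_pos(res, "N"), _pos(res, "CA"),
                                _pos(res, "C"), _pos(nxt, "N")])
            omega = _try_torsion([_pos(res, "CA"), _pos(res, "C"),
                                  _pos(nxt, "N"), _pos(nxt, "CA")])
        for name, val in (("phi", phi), ("psi", psi), ("omega", omega)):
            if val is UNDEFINED and ((name == "phi" and prev_ok)
                                     or (name != "phi" and next_ok)):
                log.info("%s %s%d%s: %s undefined (missing atoms)",
                         s.label, res.name3, res.number, res.icode, name)
            out.append(TorsionRecord(s.label, i, res, name, val))
    return out


def sidechain_torsions(s: Structure) -> list[TorsionRecord]:
    """chi1..chi4 for every residue; UNDEFINED where the chi does not exist
    or atoms are missing."""
    out = []
    for i, res in enumerate(s.residues):
        quads = CHI_ATOMS.get(res.name3, [])
        for k in range(4):
            name = f"chi{k + 1}"
            if k < len(quads):
                val = _try_torsion([_pos(res, a) for a in quads[k]])
            else:
                val = UNDEFINED
            out.append(TorsionRecord(s.label, i, res, name, val))
    return out


def all_torsions(s: Structure) -> list[TorsionRecord]:
    """All seven torsions for every residue of one structure."""
    return backbone_torsions(s) + sidechain_torsions(s)


def structure_torsion_map(s: Structure) -> dict[tuple[int, str], float]:
    """Map (residue index, angle name) -> defined value, for fast lookup."""
    return {(r.residue_index, r.angle): r.value
            for r in all_torsions(s) if r.value is not UNDEFINED}
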