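"""Rigid-body least-squares superposition (Kabsch).

Every structure is superposed onto a reference over the atoms they share
at mutually non-gap alignment columns.  The optimal rotation is the
closed-form SVD solution with the reflection branch corrected so that
det(R) = +1; the transform is then applied to *all* atoms of the
structure.  Torsion angles, being internal coordinates, are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .io import EnsembleError, Structure

__all__ = ["RigidTransform", "SuperpositionResult", "kabsch",
           "superpose_ensemble", "BACKBONE_ATOMS", "apply_transform"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class RigidTransform:
    rotation: np.ndarray   # 3x3, orthonormal, det +1
    translation: np.ndarray  # 3-vector, Angstrom

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    transforms: dict[str, RigidTransform]
    rmsd_to_reference: dict[str, float]
    atoms_used: dict[str, int]
    reference: str


def kabsch(ref_points, mov_points) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid transform taking mov onto ref.

    Returns the transform and the residual RMSD.  Requires >= 3
    non-collinear point pairs.
    """
    P = np.asarray(ref_points, dtype=float)
    Q = np.asarray(mov_points, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: rank of the centered reference cloud
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    H = Q0.T @ P0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    tr = RigidTransform(rotation=R, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(Q) - P) ** 2, axis=1))))
    return tr, rmsd


def _matched_points(ref: Structure, mov: Structure, alignment: Alignment,
                    atom_names: tuple[str, ...]):
    ref_row = alignment.cells[ref.label]
    mov_row = alignment.cells[mov.label]
    rp, mp = [], []
    for ri, mi in zip(ref_row, mov_row):
        if ri is None or mi is None:
            continue
        rres, mres = ref.residues[ri], mov.residues[mi]
        for name in atom_names:
            ra, ma = rres.atom(name), mres.atom(name)
            if ra is not None and ma is not None:
                rp.append(ra.position)
                mp.append(ma.position)
    return np.array(rp), np.array(mp)


def apply_transform(s: Structure, tr: RigidTransform) -> None:
    """Apply a rigid transform in place to every atom of a structure."""
    for res in s.residues:
        for a in res.atoms:
            a.position = tr.apply(a.position)


def superpose_ensemble(structures: list[Structure], alignment: Alignment,
                       reference_label: str | None = None,
                       atom_set: str = "backbone") -> SuperpositionResult:
    """Superpose every structure onto the reference (first, by default).

    ``atom_set`` is ``"backbone"`` (N, CA, C, O) or ``"calpha"``.  Matched
    atoms are those present in both structures at mutually non-gap
    columns.  Structures are modified in place.
    """
    if atom_set == "backbone":
        atom_names = BACKBONE_ATOMS
    elif atom_set == "calpha":
        atom_names = ("CA",)
    else:
        raise ValueError(f"unknown atom set {atom_set!r}")
    if reference_label is None:
        reference_label = structures[0].label
    by_label = {s.label: s for s in structures}
    if reference_label not in by_label:
        raise EnsembleError(f"reference structure {reference_label!r} not in ensemble")
    ref = by_label[reference_label]

    transforms, rmsds, counts = {}, {}, {}
    for s in structures:
        if s.label == reference_label:
            transforms[s.label] = RigidTransform.identity()
            rmsds[s.label] = 0.0
            rp, _ = _matched_points(ref, ref, alignment, atom_names)
            counts[s.label] = len(rp)
            continue
        rp, mp = _matched_points(ref, s, alignment, atom_names)
        if len(rp) < 3:
            raise EnsembleError(
                f"{s.label}: only {len(rp)} atoms shared with the reference; "
                "at least 3 are required for superposition")
        tr, rmsd = kabsch(rp, mp)
        apply_transform(s, tr)
        transforms[s.label] = tr
        rmsds[s.label] = rmsd
        counts[s.label] = len(rp)
    return SuperpositionResult(transforms=transforms, rmsd_to_reference=rmsds,
                               atoms_used=counts, reference=reference_label)
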