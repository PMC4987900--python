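"""Reading protein ensembles and the plain-text list formats.

PDB handling follows a deliberately narrow, reproducible policy:

* only ``ATOM`` records are read (``HETATM`` is ignored entirely);
* only the first ``MODEL`` of a multi-model (e.g. NMR) file is kept;
* when an atom has alternate locations, the first one *in file order* wins;
* chain selection is controlled by a chain spec: an explicit chain id,
  ``"first"`` (the chain of the first ATOM record), ``"*"`` (all chains)
  or ``"_"`` (blank chain id).

Columns are parsed at the fixed offsets of the PDB 3.3 format.  Lines too
short to carry a B-factor get ``b_factor = 0`` and a warning.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureListEntry",
    "PositionSelection",
    "EnsembleError",
    "read_pdb",
    "write_pdb",
    "extract_sequence",
    "parse_structure_list",
    "parse_position_list",
    "load_ensemble",
    "ANGLE_NAMES",
]

#: The seven dihedral angle names handled throughout the package.
ANGLE_NAMES = ("phi", "psi", "omega", "chi1", "chi2", "chi3", "chi4")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class EnsembleError(Exception):
    """Raised for unreadable or ill-formed ensemble inputs."""


@dataclass
class Atom:
    name: str
    position: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    element: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be 3 finite components")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    name3: str
    number: int
    icode: str = ""
    chain_id: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        self.name3 = self.name3.upper()

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atom(self, name: str) -> bool:
        return self.atom(name) is not None


@dataclass
class Structure:
    label: str
    residues: list[Residue]
    chain_spec: str = "first"
    chains_used: list[str] = field(default_factory=list)
    family: str | None = None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureListEntry:
    basename: str
    chain_spec: str = "first"
    family: str | None = None

    @property
    def label(self) -> str:
        """Structure label: basename, plus ``:chain`` for an explicit chain."""
        if self.chain_spec in ("first", "*", "_"):
            return self.basename
        return f"{self.basename}:{self.chain_spec}"


@dataclass
class PositionSelection:
    """Alignment positions and dihedral angles retained for clustering.

    ``ranges`` are inclusive ``[lo, hi]`` intervals over alignment position
    numbers; ``None`` means all positions.
    """

    ranges: list[tuple[int, int]] | None = None
    angles: frozenset[str] = frozenset({"phi", "psi"})

    def __post_init__(self):
        self.angles = frozenset(self.angles)
        bad = self.angles - set(ANGLE_NAMES)
        if bad:
            raise ValueError(f"unknown angle name(s): {sorted(bad)}")
        if self.ranges is not None:
            for lo, hi in self.ranges:
                if hi < lo:
                    raise ValueError(f"inverted range {lo}-{hi}")

    def contains(self, position: int) -> bool:
        if self.ranges is None:
            return True
        return any(lo <= position <= hi for lo, hi in self.ranges)


# ---------------------------------------------------------------------------
# PDB reading / writing

def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, int, str, str]:
    # Fixed columns of the PDB 3.3 ATOM record (0-based slices).
    name = line[12:16].strip()
    altloc = line[16:17].strip()
    resname = line[17:20].strip().upper()
    chain = line[21:22].strip()
    try:
        resnum = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise EnsembleError(f"line {lineno}: malformed ATOM record: {line.rstrip()!r}") from exc
    occ = 1.0
    if len(line) >= 60 and line[54:60].strip():
        occ = float(line[54:60])
    if len(line) >= 66 and line[60:66].strip():
        b = float(line[60:66])
    else:
        warnings.warn(f"line {lineno}: ATOM record too short for a B-factor; using 0")
        b = 0.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    atom = Atom(name=name, position=(x, y, z), b_factor=b,
                occupancy=occ, altloc=altloc, element=element)
    return atom, resname, resnum, icode, chain


def read_pdb(path: str | os.PathLike, chain_spec: str = "first") -> Structure:
    """Read one PDB file into a chain-filtered :class:`Structure`.

    Only ATOM records of the first MODEL are used.  For duplicated atom
    names within a residue (alternate locations) the first-encountered
    record wins.  ``chain_spec`` is ``"first"``, ``"*"``, ``"_"`` or an
    explicit chain id character.
    """
    if not os.path.exists(path):
        raise EnsembleError(f"PDB file not found: {path}")
    records: list[tuple[Atom, str, int, str, str]] = []
    in_model = 0  # 0 = no MODEL seen yet, 1 = first model, 2 = past it
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model += 1
                if in_model > 1:
                    break
            elif rec == "ENDMDL":
                if in_model >= 1:
                    break
            elif rec == "ATOM  ":
                records.append(_parse_atom_line(line, lineno))
    if not records:
        raise EnsembleError(f"{path}: no ATOM records")

    all_chains: list[str] = []
    for *_, chain in records:
        if chain not in all_chains:
            all_chains.append(chain)
    if chain_spec == "first":
        keep = [all_chains[0]]
    elif chain_spec == "*":
        keep = all_chains
    else:
        want = "" if chain_spec == "_" else chain_spec
        keep = [c for c in all_chains if c == want]
        if not keep:
            raise EnsembleError(
                f"{path}: chain spec {chain_spec!r} matches no chain "
                f"(chains present: {[c or '_' for c in all_chains]})")

    residues: list[Residue] = []
    index: dict[tuple[str, int, str], Residue] = {}
    for atom, resname, resnum, icode, chain in records:
        if chain not in keep:
            continue
        key = (chain, resnum, icode)
        res = index.get(key)
        if res is None:
            res = Residue(name3=resname, number=resnum, icode=icode, chain_id=chain)
            index[key] = res
            residues.append(res)
        if not res.has_atom(atom.name):  # first altloc in file order wins
            res.atoms.append(atom)

    # Order: chain order of appearance, then residue number, then icode.
    chain_rank = {c: i for i, c in enumerate(keep)}
    residues.sort(key=lambda r: (chain_rank[r.chain_id], r.number, r.icode))
    label = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return Structure(label=label, residues=residues,
                     chain_spec=chain_spec, chains_used=list(keep))


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write a Structure back out as standard PDB ATOM records."""
    with open(path, "w") as fh:
        serial = 0
        for res in structure.residues:
            for a in res.atoms:
                serial += 1
                # atom names of <4 chars start in column 14 per convention
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    "ATOM  {serial:5d} {name:4s}{alt:1s}{res:3s} {ch:1s}"
                    "{num:4d}{ic:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
                    "{b:6.2f}          {el:>2s}\n".format(
                        serial=serial, name=name, alt=a.altloc or " ",
                        res=res.name3, ch=res.chain_id or " ",
                        num=res.number, ic=res.icode or " ",
                        x=a.position[0], y=a.position[1], z=a.position[2],
                        occ=a.occupancy, b=a.b_factor, el=a.element))
        fh.write("TER\nEND\n")


def extract_sequence(structure: Structure) -> tuple[str, list[Residue]]:
    """One-letter sequence plus the parallel residue list.

    Non-standard residue names map to ``'X'``.
    """
    if not structure.residues:
        raise EnsembleError(f"{structure.label}: empty structure")
    seq = "".join(THREE_TO_ONE.get(r.name3, "X") for r in structure.residues)
    return seq, list(structure.residues)


# ---------------------------------------------------------------------------
# List-file parsing

def _content_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line


def parse_structure_list(text: str) -> list[StructureListEntry]:
    """Parse a Structure list: ``basename [chain] [family]`` per line.

    The chain field accepts an explicit chain character, ``first``
    (default), ``*`` for all chains and ``_`` for a blank chain id.
    Comment lines start with ``#``; blank lines are ignored.
    """
    entries = []
    for lineno, line in _content_lines(text):
        fields = line.split()
        if len(fields) > 3:
            raise EnsembleError(f"structure list line {lineno}: expected at most "
                                f"3 fields, got {len(fields)}: {line!r}")
        basename = fields[0]
        chain = fields[1] if len(fields) >= 2 else "first"
        family = fields[2] if len(fields) == 3 else None
        entries.append(StructureListEntry(basename=basename, chain_spec=chain,
                                          family=family))
    return entries


def parse_position_list(text: str) -> PositionSelection:
    """Parse a Position list of number ranges and dihedral-angle names.

    Tokens are whitespace-separated: ``144-166`` (inclusive range), ``150``
    (single position), or an angle name among phi, psi, omega, chi1..chi4.
    An empty list means all positions with angles {phi, psi}.
    """
    ranges: list[tuple[int, int]] = []
    angles: set[str] = set()
    for lineno, line in _content_lines(text):
        for tok in line.split():
            if tok.lower() in ANGLE_NAMES:
                angles.add(tok.lower())
            elif "-" in tok[1:]:  # allow a leading minus to fail as non-numeric
                lo_s, _, hi_s = tok.partition("-")
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError:
                    raise EnsembleError(f"position list line {lineno}: "
                                        f"malformed range {tok!r}") from None
                if hi < lo:
                    raise EnsembleError(f"position list line {lineno}: "
                                        f"inverted range {tok!r}")
                ranges.append((lo, hi))
            else:
                try:
                    v = int(tok)
                except ValueError:
                    raise EnsembleError(f"position list line {lineno}: "
                                        f"unrecognized token {tok!r}") from None
                ranges.append((v, v))
    if not ranges and not angles:
        return PositionSelection()
    return PositionSelection(ranges=ranges or None,
                             angles=frozenset(angles) or frozenset({"phi", "psi"}))


def load_ensemble(entries: list[StructureListEntry],
                  pdb_dir: str | os.PathLike) -> list[Structure]:
    """Read every entry's PDB file and attach labels and family tags."""
    structures = []
    for e in entries:
        path = os.path.join(os.fspath(pdb_dir), e.basename + ".pdb")
        s = read_pdb(path, chain_spec=e.chain_spec)
        structures.append(replace(s, label=e.label, family=e.family))
    return structures
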