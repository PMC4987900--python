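"""Residue-to-alignment-position correspondence.

Two routes are supported: deriving the alignment from author residue
numbering (assumes the ensemble is numbered consistently), or ingesting a
pre-computed multiple sequence alignment (aligned FASTA or CLUSTAL) and
validating it against the structures.  Every downstream statistic is
indexed by alignment position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import AlignIO

from .io import EnsembleError, Structure, extract_sequence

__all__ = ["Alignment", "align_by_numbering", "read_alignment", "renumber",
           "column_residues"]

GAP = None  # a gap cell


@dataclass
class Alignment:
    """Rows are structures, columns are alignment positions.

    ``cells[label][col]`` is a residue index into that structure's residue
    list, or ``None`` for a gap.  Reported position numbers are
    ``column index + first_position``.
    """

    structures: list[str]
    n_columns: int
    cells: dict[str, list[int | None]] = field(default_factory=dict)
    first_position: int = 1

    @property
    def positions(self) -> range:
        return range(self.first_position, self.first_position + self.n_columns)

    def column_of(self, position: int) -> int:
        col = position - self.first_position
        if not 0 <= col < self.n_columns:
            raise EnsembleError(
                f"position {position} outside [{self.first_position}, "
                f"{self.first_position + self.n_columns - 1}]")
        return col

    def residue_at(self, label: str, position: int) -> int | None:
        return self.cells[label][self.column_of(position)]


def align_by_numbering(structures: list[Structure]) -> Alignment:
    """Alignment columns are the sorted union of residue numbering keys.

    The key is ``(resnum, icode)`` when every structure uses a single
    chain, and ``(chain, resnum, icode)`` otherwise, so multi-chain
    ensembles cannot collide numbers across chains.
    """
    if not structures:
        raise EnsembleError("no structures to align")
    multi = any(len(s.chains_used) > 1 for s in structures)

    def key(res):
        return (res.chain_id, res.number, res.icode) if multi else (res.number, res.icode)

    keys: set = set()
    per_structure: list[dict] = []
    for s in structures:
        seen: dict = {}
        for i, r in enumerate(s.residues):
            k = key(r)
            if k in seen:
                raise EnsembleError(
                    f"{s.label}: duplicate residue key {k} — numbering is not "
                    "consistent; use a sequence alignment instead")
            seen[k] = i
        per_structure.append(seen)
        keys |= seen.keys()

    columns = sorted(keys)
    col_of = {k: c for c, k in enumerate(columns)}
    cells = {}
    for s, seen in zip(structures, per_structure):
        row: list[int | None] = [GAP] * len(columns)
        for k, i in seen.items():
            row[col_of[k]] = i
        cells[s.label] = row
    return Alignment(structures=[s.label for s in structures],
                     n_columns=len(columns), cells=cells)


def read_alignment(path: str, structures: list[Structure]) -> Alignment:
    """Read an aligned FASTA or CLUSTAL file and bind rows to structures.

    Rows are matched to structures by label; each row's gap-stripped
    sequence must equal the structure's extracted one-letter sequence.
    """
    fmt = "clustal" if str(path).endswith((".aln", ".clustal")) else "fasta"
    try:
        msa = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise EnsembleError(f"{path}: not a valid {fmt} alignment: {exc}") from exc
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    if len(rows) != len(msa):
        raise EnsembleError(f"{path}: duplicate row labels")
    n_columns = msa.get_alignment_length()

    cells = {}
    for s in structures:
        if s.label not in rows:
            raise EnsembleError(
                f"alignment has no row for structure {s.label!r} "
                f"(rows: {sorted(rows)})")
        row = rows[s.label]
        seq, _ = extract_sequence(s)
        stripped = row.replace("-", "").replace(".", "")
        if stripped != seq:
            offset = next((i for i, (a, b) in enumerate(zip(stripped, seq), 1)
                           if a != b), min(len(stripped), len(seq)) + 1)
            raise EnsembleError(
                f"alignment row for {s.label!r} does not match the structure "
                f"sequence (first mismatch at residue offset {offset})")
        cell_row: list[int | None] = []
        i = 0
        for ch in row:
            if ch in "-.":
                cell_row.append(GAP)
            else:
                cell_row.append(i)
                i += 1
        cells[s.label] = cell_row
    return Alignment(structures=[s.label for s in structures],
                     n_columns=n_columns, cells=cells)


def renumber(a: Alignment, first_position: int) -> Alignment:
    """Shift reported position numbers; cells are unchanged."""
    return Alignment(structures=list(a.structures), n_columns=a.n_columns,
                     cells={k: list(v) for k, v in a.cells.items()},
                     first_position=first_position)


def column_residues(a: Alignment, position: int) -> list[tuple[str, int | None]]:
    """Per-structure residue index (or gap) at one alignment position."""
    col = a.column_of(position)
    return [(label, a.cells[label][col]) for label in a.structures]
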