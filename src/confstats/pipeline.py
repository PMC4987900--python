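"""End-to-end run: ensemble in, result directory of tables out.

Mirrors the staged workflow: read the Structure list and PDB files, build
the residue/alignment-position correspondence, then run the requested
optional stages — superposition, Cartesian statistics, dihedral
calculation and statistics, and dihedral-space clustering.  Outputs are
deterministic plain-text tables (TSV), aligned FASTA, superposed PDB
files, a Newick tree and a JSON run summary, so repeated runs on the same
inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

from . import alignment as almod
from . import cartesian as cartmod
from . import circular as circmod
from . import clustering as clmod
from . import superposition as supmod
from . import torsions as tormod
from .io import (EnsembleError, PositionSelection, Structure,
                 StructureListEntry, extract_sequence, load_ensemble,
                 parse_position_list, parse_structure_list, write_pdb)

__all__ = ["RunConfig", "run"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    structure_list: str
    pdb_dir: str
    out_dir: str
    position_list: str | None = None
    alignment_method: str = "numbering"  # "numbering" or a file path
    superpose: bool = True
    reference: str | None = None
    cartesian: bool = True
    dihedral: bool = True
    cluster: bool = False
    radius: float = 60.0
    first_position: int = 1
    atom_set: str = "backbone"
    distance_aggregation: str = "mean"


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        msg = self.format(record)
        if msg not in self.messages:
            self.messages.append(msg)


def _write_tsv(path: str, header: list[str], rows: list[list]) -> None:
    def fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, float):
            return f"{v:.4f}"
        return str(v)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(v) for v in row) + "\n")


def _write_alignment_fasta(path, align, structures: list[Structure]) -> None:
    seqs = {s.label: extract_sequence(s)[0] for s in structures}
    with open(path, "w") as fh:
        for label in align.structures:
            row = "".join("-" if i is None else seqs[label][i]
                          for i in align.cells[label])
            fh.write(f">{label}\n{row}\n")


def run(config: RunConfig) -> dict:
    """Execute the configured stages and write the result directory.

    Returns the run summary (also written to ``summary.json``).
    """
    collector = _WarningCollector()
    logging.getLogger("confstats").addHandler(collector)
    try:
        return _run(config, collector)
    finally:
        logging.getLogger("confstats").removeHandler(collector)


def _run(config: RunConfig, collector: _WarningCollector) -> dict:
    os.makedirs(config.out_dir, exist_ok=True)
    notes: list[str] = []
    if config.cluster and not config.dihedral:
        notes.append("clustering requires dihedral analysis: enabled")
        config.dihedral = True
    if config.cartesian and not config.superpose:
        notes.append("Cartesian statistics require superposition: enabled")
        config.superpose = True

    with open(config.structure_list) as fh:
        entries = parse_structure_list(fh.read())
    if not entries:
        raise EnsembleError(f"{config.structure_list}: empty structure list")
    structures = load_ensemble(entries, config.pdb_dir)

    if config.position_list:
        with open(config.position_list) as fh:
            selection = parse_position_list(fh.read())
    else:
        selection = PositionSelection()
        if config.cluster:
            notes.append("no position list: clustering over all positions "
                         "with angles {phi, psi}")

    if config.alignment_method == "numbering":
        align = almod.align_by_numbering(structures)
    else:
        align = almod.read_alignment(config.alignment_method, structures)
    if config.first_position != 1:
        align = almod.renumber(align, config.first_position)
    _write_alignment_fasta(os.path.join(config.out_dir, "alignment.fasta"),
                           align, structures)

    summary: dict = {
        "n_structures": len(structures),
        "n_alignment_positions": align.n_columns,
        "first_position": align.first_position,
        "stages": {"superpose": config.superpose, "cartesian": config.cartesian,
                   "dihedral": config.dihedral, "cluster": config.cluster},
        "notes": notes,
    }

    if config.superpose:
        reference = config.reference or structures[0].label
        if config.reference is None:
            notes.append(f"no reference given: using first structure {reference!r}")
        sup = supmod.superpose_ensemble(structures, align,
                                        reference_label=reference,
                                        atom_set=config.atom_set)
        sup_dir = os.path.join(config.out_dir, "superposed")
        os.makedirs(sup_dir, exist_ok=True)
        for s in structures:
            write_pdb(s, os.path.join(sup_dir, s.label.replace(":", "_") + ".pdb"))
        _write_tsv(os.path.join(config.out_dir, "superposition.tsv"),
                   ["structure", "rmsd_A", "atoms_used"],
                   [[lab, sup.rmsd_to_reference[lab], sup.atoms_used[lab]]
                    for lab in align.structures])
        summary["superposition"] = {"reference": reference,
                                    "max_rmsd_A": max(sup.rmsd_to_reference.values())}

    if config.cartesian:
        table = cartmod.cartesian_table(structures, align)
        _write_tsv(os.path.join(config.out_dir, "cartesian.tsv"),
                   ["position", "group", "fluctuation_A", "mean_b",
                    "n_structures", "n_atoms"],
                   [[r.position, r.group, r.fluctuation, r.mean_b,
                     r.n_structures, r.n_atoms] for r in table])
        backbone = [r for r in table if r.group == "backbone" and r.n_atoms]
        if backbone:
            peak = max(backbone, key=lambda r: r.fluctuation)
            summary["cartesian"] = {"peak_backbone_position": peak.position,
                                    "peak_backbone_fluctuation_A": peak.fluctuation}

    torsions_by_structure = None
    if config.dihedral:
        torsions_by_structure = {s.label: tormod.all_torsions(s)
                                 for s in structures}
        rows = []
        for label in align.structures:
            for rec in torsions_by_structure[label]:
                res = rec.residue
                rows.append([label, res.chain_id, res.number, res.icode or "",
                             res.name3, rec.angle, rec.value])
        _write_tsv(os.path.join(config.out_dir, "torsions.tsv"),
                   ["structure", "chain", "resnum", "icode", "resname",
                    "angle", "value_deg"], rows)
        summaries = circmod.position_summaries(torsions_by_structure,
                                               structures, align)
        _write_tsv(os.path.join(config.out_dir, "circular_summary.tsv"),
                   ["position", "angle", "family", "n", "mean_deg", "sd_deg"],
                   [[c.position, c.angle, c.family, c.n, c.mean, c.sd]
                    for c in summaries])
        summary["dihedral"] = {"n_summaries": len(summaries)}

    if config.cluster:
        maps = {label: {(r.residue_index, r.angle): r.value
                        for r in recs if r.value is not None}
                for label, recs in torsions_by_structure.items()}
        dm, tree, result = clmod.cluster(maps, align.structures, selection,
                                         align, radius=config.radius,
                                         aggregation=config.distance_aggregation)
        labels = dm.labels
        rows = []
        k = 0
        for i, li in enumerate(labels):
            for lj in labels[i + 1:]:
                rows.append([li, lj, float(dm.values[k]), dm.n_variables_used[k]])
                k += 1
        _write_tsv(os.path.join(config.out_dir, "distances.tsv"),
                   ["structure_a", "structure_b", "distance_deg", "n_dihedrals"],
                   rows)
        with open(os.path.join(config.out_dir, "tree.nwk"), "w") as fh:
            fh.write(clmod.to_newick(tree) + "\n")
        _write_tsv(os.path.join(config.out_dir, "clusters.tsv"),
                   ["structure", "cluster"],
                   [[lab, result.labels[lab]] for lab in labels])
        with open(os.path.join(config.out_dir, "structures_clustered.txt"), "w") as fh:
            fh.write(clmod.emit_cluster_families(result, entries))
        summary["clustering"] = {"radius_deg": config.radius,
                                 "n_clusters": result.n_clusters,
                                 "aggregation": config.distance_aggregation}

    summary["warnings"] = collector.messages
    summary["notes"] = notes
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
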