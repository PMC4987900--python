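"""Circular statistics on angles in degrees.

Angles live on the circle, so averages are taken on unit vectors: with
R-bar the mean resultant length, the circular mean is the direction of the
resultant and the circular standard deviation is sqrt(-2 ln R-bar)
(Mardia), converted to degrees.  The circular distance between two angles
is the shorter arc, in [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .io import ANGLE_NAMES, PositionSelection, Structure
from .torsions import TorsionRecord, UNDEFINED

__all__ = ["AngleSample", "CircularSummary", "circ_dist", "circular_mean",
           "circular_sd", "position_summaries", "GLOBAL"]

GLOBAL = "GLOBAL"

_RESULTANT_EPS = 1e-12


@dataclass
class AngleSample:
    values: np.ndarray

    def __init__(self, values):
        v = np.asarray(values, dtype=float)
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("angle sample contains non-finite values")
        self.values = v

    def __len__(self):
        return self.values.size


@dataclass
class CircularSummary:
    position: int
    angle: str
    family: str
    n: int
    mean: float | None  # degrees, None when the resultant vanishes
    sd: float | None


def circ_dist(a: float, b: float) -> float:
    """Shortest arc between two angles, degrees in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _resultant(values: np.ndarray) -> tuple[float, float, float]:
    rad = np.radians(values)
    c, s = float(np.mean(np.cos(rad))), float(np.mean(np.sin(rad)))
    return c, s, float(np.hypot(c, s))


def circular_mean(sample: AngleSample) -> float:
    """Direction of the vector resultant, degrees in (-180, 180]."""
    if len(sample) == 0:
        raise ValueError("empty angle sample")
    c, s, r = _resultant(sample.values)
    if r <= _RESULTANT_EPS:
        raise ValueError("circular mean undefined: zero resultant length")
    ang = float(np.degrees(np.arctan2(s, c)))
    if ang <= -180.0:
        ang += 360.0
    return ang

def circular_sd(sample: AngleSample) -> float:
    """Mardia circular standard deviation sqrt(-2 ln R-bar), in degrees."""
    if len(sample) == 0:
        raise ValueError("empty angle sample")
    if len(sample) == 1:
        return 0.0
    _, _, r = _resultant(sample.values)
    if r <= _RESULTANT_EPS:
        raise ValueError("circular sd undefined: zero resultant length")
    # guard against r marginally above 1 from rounding
    r = min(r, 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def position_summaries(torsions_by_structure: dict[str, list[TorsionRecord]],
                       structures: list[Structure],
                       alignment: Alignment,
                       selection: PositionSelection | None = None,
                       ) -> list[CircularSummary]:
    """Circular mean/sd per (alignment position, angle), globally and per
    family when families were assigned.

    UNDEFINED torsions and gap cells are skipped; a summary exists whenever
    at least one structure contributes.  Degenerate samples (vanishing
    resultant) yield ``mean = sd = None`` with their count intact.
    """
    angles = sorted(selection.angles, key=ANGLE_NAMES.index) if selection \
        else list(ANGLE_NAMES)
    families = sorted({s.family for s in structures if s.family is not None})
    family_of = {s.label: s.family for s in structures}

    # (residue_index, angle) -> value per structure
    tmap = {label: {(r.residue_index, r.angle): r.value
                    for r in recs if r.value is not UNDEFINED}
            for label, recs in torsions_by_structure.items()}

    out = []
    for position in alignment.positions:
        if selection is not None and not selection.contains(position):
            continue
        col = alignment.column_of(position)
        for angle in angles:
            groups: dict[str, list[float]] = {GLOBAL: []}
            for fam in families:
                groups[fam] = []
            for label in alignment.structures:
                ridx = alignment.cells[label][col]
                if ridx is None:  # gap
                    continue
                val = tmap[label].get((ridx, angle))
                if val is None:
                    continue
                groups[GLOBAL].append(val)
                fam = family_of.get(label)
                if fam is not None:
                    groups[fam].append(val)
            for fam, vals in groups.items():
                if not vals:
                    continue
                sample = AngleSample(vals)
                try:
                    mean, sd = circular_mean(sample), circular_sd(sample)
                except ValueError:
                    mean = sd = None
                out.append(CircularSummary(position=position, angle=angle,
                                           family=fam, n=len(vals),
                                           mean=mean, sd=sd))
    return out
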