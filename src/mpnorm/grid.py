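"""MAIA-style 37-locus microperimetry test grid.

The MAIA microperimeter samples retinal sensitivity at 37 loci arranged in
an annular pattern: one central locus plus three concentric annuli of 12
loci each at 2.3, 4 and 6 degrees eccentricity.  For ring-level summaries
the grid is partitioned into an inner ring (centre + 2.3 deg annulus,
13 loci), a middle ring (4 deg, 12 loci) and an outer ring (6 deg, 12 loci).

Coordinates are visual-field degrees in right-eye orientation: x positive
rightward on the chart, y positive upward.  Left-eye exams are brought into
this frame by reflecting across the vertical axis (x -> -x) before any
pooled analysis, so that anatomically corresponding loci line up across
eyes.

The device manual does not pin down the angular phase of the annuli; the
loci here are placed every 30 degrees starting on the positive x-axis,
identically on all three annuli.  This preserves the two properties the
analysis relies on -- the per-eccentricity counts and exact mirror symmetry
-- and can be swapped for another layout by constructing a ``TestGrid``
directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .exams import SensitivityExam

#: The four stimulus eccentricities (degrees of visual angle).
ECCENTRICITIES: tuple[float, ...] = (0.0, 2.3, 4.0, 6.0)

#: Number of loci in the standard grid.
N_LOCI = 37

#: Ring labels in centrifugal order.
RINGS: tuple[str, ...] = ("inner", "middle", "outer")

#: Eccentricity -> ring label (inner ring pools the centre with 2.3 deg).
RING_OF_ECCENTRICITY: dict[float, str] = {0.0: "inner", 2.3: "inner", 4.0: "middle", 6.0: "outer"}

#: Expected ring sizes for the standard grid.
RING_SIZES: dict[str, int] = {"inner": 13, "middle": 12, "outer": 12}

_COORD_TOL = 1e-9


@dataclass(frozen=True)
class GridLocus:
    """One stimulus location.

    ``polar_angle`` is measured counter-clockwise from the positive x-axis,
    in degrees.  ``ring`` may be ``None`` for a grid that has not yet been
    through :func:`assign_rings`.
    """

    locus_id: int
    eccentricity: float
    polar_angle: float
    x: float
    y: float
    ring: Optional[str] = None

    def __post_init__(self) -> None:
        ex = self.eccentricity * math.cos(math.radians(self.polar_angle))
        ey = self.eccentricity * math.sin(math.radians(self.polar_angle))
        if abs(ex - self.x) > _COORD_TOL or abs(ey - self.y) > _COORD_TOL:
            raise ValueError(
                f"locus {self.locus_id}: cartesian coordinates ({self.x}, {self.y}) "
                f"inconsistent with eccentricity/angle ({self.eccentricity}, {self.polar_angle})"
            )


@dataclass(frozen=True)
class TestGrid:
    """An ordered collection of 37 grid loci."""

    loci: tuple[GridLocus, ...]

    def __post_init__(self) -> None:
        if len(self.loci) != N_LOCI:
            raise ValueError(f"expected {N_LOCI} loci, got {len(self.loci)}")
        ids = sorted(l.locus_id for l in self.loci)
        if ids != list(range(N_LOCI)):
            raise ValueError("locus_id values must be unique and cover 0..36")
        counts = {e: 0 for e in ECCENTRICITIES}
        for l in self.loci:
            if l.eccentricity not in counts:
                raise ValueError(
                    f"locus {l.locus_id}: unexpected eccentricity {l.eccentricity}"
                )
            counts[l.eccentricity] += 1
        if counts[0.0] != 1 or any(counts[e] != 12 for e in ECCENTRICITIES[1:]):
            raise ValueError(f"eccentricity counts {counts} violate the 1+12+12+12 layout")

    def __iter__(self):
        return iter(self.loci)

    @property
    def eccentricities(self) -> np.ndarray:
        """Per-locus eccentricity in locus_id order."""
        return np.array([l.eccentricity for l in sorted(self.loci, key=lambda l: l.locus_id)])

    @property
    def rings(self) -> tuple[Optional[str], ...]:
        """Per-locus ring label in locus_id order."""
        return tuple(l.ring for l in sorted(self.loci, key=lambda l: l.locus_id))

    def ring_loci(self, ring: str) -> list[int]:
        """locus_ids belonging to ``ring``."""
        if ring not in RINGS:
            raise ValueError(f"unknown ring {ring!r}")
        return sorted(l.locus_id for l in self.loci if l.ring == ring)

    def ring_counts(self) -> dict[str, int]:
        out = {r: 0 for r in RINGS}
        for l in self.loci:
            if l.ring is not None:
                out[l.ring] += 1
        return out


def build_maia_grid() -> TestGrid:
    """Construct the standard 37-locus grid with ring labels.

    Deterministic: locus 0 is the centre; ids 1-12, 13-24 and 25-36 run
    counter-clockwise from the positive x-axis on the 2.3, 4 and 6 degree
    annuli respectively.
    """
    loci = [GridLocus(0, 0.0, 0.0, 0.0, 0.0)]
    lid = 1
    for ecc in ECCENTRICITIES[1:]:
        for k in range(12):
            ang = 30.0 * k
            x = ecc * math.cos(math.radians(ang))
            y = ecc * math.sin(math.radians(ang))
            loci.append(GridLocus(lid, ecc, ang, x, y))
            lid += 1
    return assign_rings(TestGrid(tuple(loci)))


def assign_rings(grid: TestGrid) -> TestGrid:
    """Label every locus with its eccentricity ring.

    Centre and 2.3 deg loci are *inner*, 4 deg *middle*, 6 deg *outer*,
    giving the 13/12/12 partition used for ring-level summaries.
    """
    new = []
    for l in grid.loci:
        try:
            ring = RING_OF_ECCENTRICITY[l.eccentricity]
        except KeyError:
            raise ValueError(
                f"locus {l.locus_id}: no ring defined for eccentricity {l.eccentricity}"
            ) from None
        new.append(dataclasses.replace(l, ring=ring))
    return TestGrid(tuple(new))


def mirror_permutation(grid: TestGrid) -> np.ndarray:
    """Permutation ``p`` with ``p[j]`` = locus whose coordinates are (-x_j, y_j).

    The reflection across the vertical axis maps a right-eye chart onto a
    left-eye chart; ``p`` is an involution.  Raises if any locus lacks a
    mirror partner (cannot happen for the standard grid).
    """
    loci = sorted(grid.loci, key=lambda l: l.locus_id)
    perm = np.full(len(loci), -1, dtype=int)
    for l in loci:
        for m in loci:
            if abs(m.x + l.x) < 1e-6 and abs(m.y - l.y) < 1e-6 and abs(m.eccentricity - l.eccentricity) < 1e-9:
                perm[l.locus_id] = m.locus_id
                break
        else:
            raise ValueError(f"locus {l.locus_id} has no horizontal mirror partner in the grid")
    return perm


def mirror_to_right_eye(exam: "SensitivityExam", grid: TestGrid) -> "SensitivityExam":
    """Transform a left-eye exam to right-eye orientation.

    Right-eye exams are returned unchanged.  For left eyes, the value
    measured at the locus at (x, y) is reassigned to the locus at (-x, y)
    and the laterality flag is set to ``"right"``.  Applying the transform
    twice to coordinates is the identity.
    """
    if exam.laterality == "right":
        return exam
    if exam.laterality != "left":
        raise ValueError(f"unknown laterality {exam.laterality!r}")
    perm = mirror_permutation(grid)
    sens = np.asarray(exam.sensitivities)
    mirrored = np.empty_like(sens)
    mirrored[perm] = sens
    return dataclasses.replace(exam, laterality="right", sensitivities=mirrored)


def grid_to_frame(grid: TestGrid) -> pd.DataFrame:
    """Tabulate the grid, one row per locus in locus_id order."""
    rows = [
        {
            "locus_id": l.locus_id,
            "eccentricity_deg": l.eccentricity,
            "polar_angle_deg": l.polar_angle,
            "x_deg": l.x,
            "y_deg": l.y,
            "ring": l.ring,
        }
        for l in sorted(grid.loci, key=lambda l: l.locus_id)
    ]
    return pd.DataFrame(rows)


def write_grid_csv(grid: TestGrid, path) -> None:
    grid_to_frame(grid).to_csv(path, index=False)


def grid_hash(grid: TestGrid) -> str:
    """Stable content hash of the grid layout (used to key serialized references)."""
    h = hashlib.sha256()
    for l in sorted(grid.loci, key=lambda l: l.locus_id):
        h.update(
            f"{l.locus_id},{l.eccentricity:.6f},{l.polar_angle:.6f},{l.ring}\n".encode()
        )
    return h.hexdigest()
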