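"""Exam data model, CSV interchange, dB scale and fixation-stability metrics.

A microperimetry exam is one eye's test: the subject's age, eye laterality,
37 integer thresholds in dB aligned to the grid's locus order, and a
fixation-stability index (63% bivariate contour ellipse area, BCEA).  The
device encodes "not seen at maximum luminance" as -1 dB; that sentinel is
kept as the numeric value -1 throughout the analysis, matching how the
exams are exported.

The CSV schema is: ``subject_id, age, eye (L/R), cohort (healthy/cd),
bcea63, s00..s36`` with sensitivities in locus_id order.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .grid import N_LOCI

logger = logging.getLogger("mpnorm")

#: Device dynamic range in dB (0 = brightest stimulus, 36 = dimmest).
DB_MIN, DB_MAX = 0, 36

#: Brightest differential stimulus luminance, cd/m^2 (defines 0 dB).
MAX_LUMINANCE = 317.04

#: Sentinel for "not seen at maximum luminance".
NOT_SEEN = -1

#: Default fixation-stability inclusion cutoff, deg^2.
BCEA_LIMIT = 5.0

_COHORT_LABELS = ("healthy", "cuticular_drusen")
_COHORT_CSV = {"healthy": "healthy", "cuticular_drusen": "cd"}
_COHORT_FROM_CSV = {v: k for k, v in _COHORT_CSV.items()}
_SENS_COLS = [f"s{i:02d}" for i in range(N_LOCI)]
_REQUIRED_COLS = ["subject_id", "age", "eye", "cohort", "bcea63", *_SENS_COLS]


class ValidationError(ValueError):
    """Malformed exam data (bad field, bad row, duplicate eye)."""


@dataclass
class SensitivityExam:
    """One eye's exam.

    ``sensitivities`` holds 37 integers in [-1, 36] in locus_id order;
    ``bcea63`` is the 63% bivariate contour ellipse area in deg^2 or
    ``None`` when fixation data were not recorded.
    """

    subject_id: str
    age: float
    laterality: str
    sensitivities: np.ndarray
    bcea63: Optional[float] = None
    cohort_label: str = "healthy"

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities)
        validate_exam(self)


def validate_exam(exam: SensitivityExam) -> None:
    if not (math.isfinite(exam.age) and exam.age > 0):
        raise ValidationError(f"{exam.subject_id}: age must be a positive number, got {exam.age}")
    if exam.laterality not in ("left", "right"):
        raise ValidationError(f"{exam.subject_id}: laterality must be 'left' or 'right'")
    if exam.cohort_label not in _COHORT_LABELS:
        raise ValidationError(f"{exam.subject_id}: unknown cohort label {exam.cohort_label!r}")
    s = np.asarray(exam.sensitivities)
    if s.shape != (N_LOCI,):
        raise ValidationError(f"{exam.subject_id}: expected {N_LOCI} sensitivities, got shape {s.shape}")
    if not np.all(np.isfinite(s.astype(float))):
        raise ValidationError(f"{exam.subject_id}: non-finite sensitivity value")
    if np.any(s.astype(float) != np.round(s.astype(float))):
        raise ValidationError(f"{exam.subject_id}: sensitivities must be integers")
    if np.any(s < NOT_SEEN) or np.any(s > DB_MAX):
        raise ValidationError(f"{exam.subject_id}: sensitivity outside [{NOT_SEEN}, {DB_MAX}]")
    if exam.bcea63 is not None and not (math.isfinite(exam.bcea63) and exam.bcea63 >= 0):
        raise ValidationError(f"{exam.subject_id}: bcea63 must be non-negative")


@dataclass
class FixationTrace:
    """Sequence of fixation positions (deg); at least 3 samples."""

    samples: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("fixation trace must be an (n, 2) array of (x, y) degrees")
        if len(self.samples) < 3:
            raise ValueError("fixation trace needs at least 3 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("fixation trace contains non-finite coordinates")


@dataclass
class CohortTable:
    """A collection of exams with unique (subject_id, laterality) keys."""

    exams: list[SensitivityExam]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for e in self.exams:
            key = (e.subject_id, e.laterality)
            if key in seen:
                raise ValidationError(f"duplicate subject-eye {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.exams)

    def __iter__(self):
        return iter(self.exams)

    def ages(self) -> np.ndarray:
        return np.array([e.age for e in self.exams], dtype=float)

    def sensitivity_matrix(self) -> np.ndarray:
        """(n_eyes, 37) float matrix in locus_id order."""
        return np.array([e.sensitivities for e in self.exams], dtype=float)


def db_from_luminance(stimulus_luminance: float, max_luminance: float = MAX_LUMINANCE) -> float:
    """Stimulus attenuation in dB: ``10*log10(max/stimulus)``.

    0 dB is the brightest stimulus the device can show; larger dB means a
    dimmer stimulus.  Raises for luminances outside (0, max].
    """
    if not (max_luminance > 0):
        raise ValueError("max_luminance must be positive")
    if not (0 < stimulus_luminance <= max_luminance):
        raise ValueError(
            f"stimulus luminance {stimulus_luminance} outside (0, {max_luminance}]"
        )
    return 10.0 * math.log10(max_luminance / stimulus_luminance)


def luminance_from_db(db: float, max_luminance: float = MAX_LUMINANCE) -> float:
    """Inverse of :func:`db_from_luminance`."""
    if not (max_luminance > 0):
        raise ValueError("max_luminance must be positive")
    return max_luminance * 10.0 ** (-db / 10.0)


def bcea(trace: FixationTrace, coverage: float = 0.63) -> float:
    """Bivariate contour ellipse area at the given coverage, in deg^2.

    ``2 * k * pi * sx * sy * sqrt(1 - rho^2)`` with ``k = -ln(1 - coverage)``,
    sample (n-1) standard deviations and sample correlation.  When one axis
    has zero variance the correlation is taken as 0 and the area is a
    legitimate 0 (collinear fixations); fewer than 3 samples is an error
    raised by :class:`FixationTrace` itself.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    x = trace.samples[:, 0]
    y = trace.samples[:, 1]
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0.0 or sy == 0.0:
        rho = 0.0
    else:
        rho = float(np.corrcoef(x, y)[0, 1])
    k = -math.log(1.0 - coverage)
    return 2.0 * k * math.pi * sx * sy * math.sqrt(max(0.0, 1.0 - rho * rho))


def apply_inclusion_filter(table: CohortTable, bcea_limit: float = BCEA_LIMIT) -> CohortTable:
    """Keep exams with stable fixation: ``bcea63 < bcea_limit`` (strict).

    Exams without a recorded bcea63 are excluded (and logged) rather than
    given the benefit of the doubt.
    """
    if not bcea_limit > 0:
        raise ValueError("bcea_limit must be positive")
    kept = []
    for e in table.exams:
        if e.bcea63 is None:
            logger.warning("excluding %s/%s: no bcea63 recorded", e.subject_id, e.laterality)
        elif e.bcea63 < bcea_limit:
            kept.append(e)
        else:
            logger.info(
                "excluding %s/%s: bcea63 %.3g >= %.3g", e.subject_id, e.laterality, e.bcea63, bcea_limit
            )
    return CohortTable(kept, provenance=table.provenance)


def mean_sensitivity(exam: SensitivityExam) -> float:
    """Arithmetic mean of the 37 thresholds, -1 sentinels included as -1."""
    return float(np.mean(np.asarray(exam.sensitivities, dtype=float)))


def cohort_to_frame(table: CohortTable) -> pd.DataFrame:
    rows = []
    for e in table.exams:
        row = {
            "subject_id": e.subject_id,
            "age": e.age,
            "eye": "R" if e.laterality == "right" else "L",
            "cohort": _COHORT_CSV[e.cohort_label],
            "bcea63": e.bcea63 if e.bcea63 is not None else np.nan,
        }
        for i, col in enumerate(_SENS_COLS):
            row[col] = int(e.sensitivities[i])
        rows.append(row)
    return pd.DataFrame(rows, columns=_REQUIRED_COLS)


def write_cohort_csv(table: CohortTable, path) -> None:
    cohort_to_frame(table).to_csv(path, index=False)


def cohort_from_frame(df: pd.DataFrame, provenance: str = "") -> CohortTable:
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {', '.join(missing)}")
    exams = []
    keys = set()
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2  # 1-based, after the header
        eye = str(row["eye"]).strip().upper()
        if eye not in ("L", "R"):
            raise ValidationError(f"row {line}: eye must be L or R, got {row['eye']!r}")
        cohort_csv = str(row["cohort"]).strip().lower()
        if cohort_csv not in _COHORT_FROM_CSV:
            raise ValidationError(f"row {line}: cohort must be healthy or cd, got {row['cohort']!r}")
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            raise ValidationError(f"row {line}: age is not numeric: {row['age']!r}") from None
        sens = np.empty(N_LOCI, dtype=int)
        for i, col in enumerate(_SENS_COLS):
            try:
                v = float(row[col])
            except (TypeError, ValueError):
                raise ValidationError(f"row {line}: field {col} is not numeric: {row[col]!r}") from None
            if not math.isfinite(v) or v != round(v):
                raise ValidationError(f"row {line}: field {col} must be an integer, got {row[col]!r}")
            if not NOT_SEEN <= v <= DB_MAX:
                raise ValidationError(
                    f"row {line}: field {col} value {int(v)} outside [{NOT_SEEN}, {DB_MAX}]"
                )
            sens[i] = int(v)
        b = row["bcea63"]
        bcea63 = None if pd.isna(b) else float(b)
        try:
            exam = SensitivityExam(
                subject_id=str(row["subject_id"]),
                age=age,
                laterality="right" if eye == "R" else "left",
                sensitivities=sens,
                bcea63=bcea63,
                cohort_label=_COHORT_FROM_CSV[cohort_csv],
            )
        except ValidationError as err:
            raise ValidationError(f"row {line}: {err}") from None
        key = (exam.subject_id, exam.laterality)
        if key in keys:
            raise ValidationError(f"row {line}: duplicate subject-eye {key}")
        keys.add(key)
        exams.append(exam)
    return CohortTable(exams, provenance=provenance)


def read_cohort_csv(path) -> CohortTable:
    """Read a cohort CSV, validating every row (errors name row and field)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    return cohort_from_frame(df, provenance=str(path))
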