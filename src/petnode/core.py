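"""Domain types and node-level CSV I/O.

The unit of analysis is the sampled lymph node: one row per node, with
patient-level covariates (primary-tumour SUVmax, laterality, histology,
largest echelon-2 SUVmax) denormalised onto the node rows.  Real-world
files carry no latent truth column; synthetic cohorts optionally do, which
is why ``truth_positive`` is the only optional field in the schema.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "LymphNodeRecord",
    "Cohort",
    "SchemaError",
    "CohortValidationError",
    "load_cohort",
    "save_cohort",
    "validate_cohort",
    "CSV_COLUMNS",
]

#: Canonical CSV column order.  ``truth_positive`` is optional on input.
CSV_COLUMNS = [
    "patient_id",
    "echelon",
    "suv_max",
    "suv_max_primary",
    "short_diameter_cm",
    "conglomerate",
    "station4R_left_primary",
    "histology_adeno",
    "primary_right_sided",
    "largest_suv_echelon2",
    "ebus_positive",
    "truth_positive",
]

#: Nodes with diffuse mediastinal infiltration are assigned to the largest
#: size group, short-axis diameter >= 6 cm.
CONGLOMERATE_MIN_DIAMETER_CM = 6.0


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class CohortValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class LymphNodeRecord:
    """One EBUS-sampled lymph node with its PET/CT features.

    ``echelon`` orders the node station along the lymphatic drainage from
    the primary tumour (1 = ipsilateral hilum, 2 = ipsilateral central
    mediastinum, 3 = upper/contralateral mediastinum or contralateral
    hilum).  ``ebus_positive`` is the histopathologic reference label;
    ``truth_positive`` is the latent involvement status and is only present
    for synthetic cohorts, where EBUS observes it with configurable
    sensitivity and perfect specificity.
    """

    patient_id: str
    echelon: int
    suv_max: float
    suv_max_primary: float
    short_diameter_cm: float
    conglomerate: int
    station4R_left_primary: int
    histology_adeno: int
    primary_right_sided: int
    largest_suv_echelon2: float
    ebus_positive: int
    truth_positive: Optional[int] = None

    def replace(self, **changes) -> "LymphNodeRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of lymph-node records with provenance."""

    records: tuple[LymphNodeRecord, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LymphNodeRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def has_truth(self) -> bool:
        return all(r.truth_positive is not None for r in self.records)

    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        cols = {name: [getattr(r, name) for r in self.records] for name in CSV_COLUMNS}
        if not self.has_truth:
            cols.pop("truth_positive")
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "Cohort":
        records = []
        has_truth = "truth_positive" in frame.columns
        for _, row in frame.iterrows():
            records.append(
                LymphNodeRecord(
                    patient_id=str(row["patient_id"]),
                    echelon=int(row["echelon"]),
                    suv_max=float(row["suv_max"]),
                    suv_max_primary=float(row["suv_max_primary"]),
                    short_diameter_cm=float(row["short_diameter_cm"]),
                    conglomerate=int(row["conglomerate"]),
                    station4R_left_primary=int(row["station4R_left_primary"]),
                    histology_adeno=int(row["histology_adeno"]),
                    primary_right_sided=int(row["primary_right_sided"]),
                    largest_suv_echelon2=float(row["largest_suv_echelon2"]),
                    ebus_positive=int(row["ebus_positive"]),
                    truth_positive=int(row["truth_positive"]) if has_truth else None,
                )
            )
        return cls(records=tuple(records), provenance=provenance)

    def labels(self, use_truth: bool = False) -> np.ndarray:
        if use_truth:
            if not self.has_truth:
                raise ValueError("cohort carries no truth_positive column")
            return np.array([r.truth_positive for r in self.records], dtype=int)
        return np.array([r.ebus_positive for r in self.records], dtype=int)


def load_cohort(path: str | Path) -> Cohort:
    """Read a node-level CSV and return a validated :class:`Cohort`.

    Raises :class:`SchemaError` when a required column is missing or a
    numeric cell fails to parse, and :class:`CohortValidationError` when a
    record violates a domain invariant (error messages cite the 0-based
    row index).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    required = [c for c in CSV_COLUMNS if c != "truth_positive"]
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    numeric = [c for c in frame.columns if c in CSV_COLUMNS and c != "patient_id"]
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise SchemaError(f"non-numeric value in column {col!r} at row {bad[0]}")
        if coerced.isna().any():
            raise SchemaError(f"missing value in column {col!r} at row {coerced.index[coerced.isna()][0]}")
        frame[col] = coerced
    cohort = Cohort.from_frame(frame, provenance=str(path))
    violations = validate_cohort(cohort)
    if violations:
        raise CohortValidationError("; ".join(violations))
    return cohort


def save_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write the cohort as CSV (booleans as 0/1, full float precision)."""
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False)
    return path


def validate_cohort(cohort: Cohort) -> list[str]:
    """Check every record against the domain invariants.

    Returns one human-readable violation descriptor per failure, each
    citing the record index and the rule; an empty list means the cohort
    is valid.  Never raises.
    """
    violations: list[str] = []
    largest_e2: dict[str, float] = {}
    for i, r in enumerate(cohort):
        if r.echelon not in (1, 2, 3):
            violations.append(f"row {i}: echelon {r.echelon} outside {{1,2,3}}")
        if not r.suv_max > 0:
            violations.append(f"row {i}: suv_max must be > 0")
        if not r.short_diameter_cm > 0:
            violations.append(f"row {i}: short_diameter_cm must be > 0")
        if r.conglomerate and r.short_diameter_cm < CONGLOMERATE_MIN_DIAMETER_CM:
            violations.append(
                f"row {i}: conglomerate node requires short_diameter_cm >= "
                f"{CONGLOMERATE_MIN_DIAMETER_CM} cm (largest size group rule)"
            )
        if r.truth_positive is not None and r.truth_positive == 0 and r.ebus_positive == 1:
            violations.append(
                f"row {i}: ebus_positive=1 with truth_positive=0 violates "
                "perfect EBUS specificity"
            )
        for flag in ("conglomerate", "station4R_left_primary", "histology_adeno",
                     "primary_right_sided", "ebus_positive"):
            v = getattr(r, flag)
            if v not in (0, 1):
                violations.append(f"row {i}: {flag} must be 0/1, got {v}")
        prev = largest_e2.setdefault(r.patient_id, r.largest_suv_echelon2)
        if prev != r.largest_suv_echelon2:
            violations.append(
                f"row {i}: largest_suv_echelon2 differs within patient {r.patient_id}"
            )
    return violations
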