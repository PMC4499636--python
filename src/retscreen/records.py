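"""Core data records shared across the screening pipeline.

A screening study record set is organised at eye level: each enrolled
patient contributes two eyes, and an :class:`EyeRecord` carries the per-eye
microaneurysm (MA) count, the tear-fluid protein concentration vector and
the clinical diabetic-retinopathy (DR) label.  Fundus photographs are held
as :class:`FundusImage` grids; hand-marked lesion locations as
:class:`GroundTruthMA`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Number of tear-fluid protein concentrations measured per sample.
N_PROTEINS = 34

#: Fixed, documented protein column order: P01 ... P34.
PROTEIN_COLUMNS = tuple(f"P{i + 1:02d}" for i in range(N_PROTEINS))

LATERALITIES = ("L", "R")


@dataclass
class FundusImage:
    """An RGB fundus photograph with eye/patient metadata.

    ``pixels`` is an H x W x 3 float array with all intensities in [0, 1].
    Microaneurysms contrast best in the green channel (index 1).
    """

    pixels: np.ndarray
    image_id: str = ""
    patient_id: str = ""
    eye: str = "L"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"fundus image must be H x W x 3, got shape {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("fundus intensities must lie in [0, 1]")
        if self.eye not in LATERALITIES:
            raise ValueError(f"eye must be one of {LATERALITIES}, got {self.eye!r}")


@dataclass(frozen=True)
class GroundTruthMA:
    """A hand-marked microaneurysm: centre (row, col) and diameter, in pixels."""

    center_row: float
    center_col: float
    diameter_px: float

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ValueError("diameter_px must be positive")


@dataclass
class EyeRecord:
    """One eye's fused analysis row: MA count, protein vector, DR label.

    ``ma_count`` or ``proteins`` may be ``None`` when that modality was not
    acquired; a record enters a given screening model only if the features
    that model consumes are present.
    """

    patient_id: str
    eye: str
    dr_label: bool
    ma_count: int | None = None
    proteins: np.ndarray | None = None
    volume_uL: float | None = None
    time_min: float | None = None
    tear_excluded: bool = False
    photo_excluded: bool = False

    def __post_init__(self) -> None:
        if self.eye not in LATERALITIES:
            raise ValueError(f"eye must be one of {LATERALITIES}, got {self.eye!r}")
        if self.proteins is not None:
            self.proteins = np.asarray(self.proteins, dtype=float)
        if self.ma_count is not None and self.ma_count < 0:
            raise ValueError("ma_count must be non-negative")

    @property
    def included(self) -> bool:
        return not (self.tear_excluded or self.photo_excluded)

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_id, self.eye)

    @property
    def fellow_key(self) -> tuple[str, str]:
        """Key of the fellow eye: same patient, other laterality."""
        other = "R" if self.eye == "L" else "L"
        return (self.patient_id, other)


def cohort_to_frame(records: list[EyeRecord]) -> pd.DataFrame:
    """Flatten eye records into the cohort CSV schema.

    Columns: patient_id, eye, dr_label, ma_count, volume_uL, time_min,
    P01...P34, tear_excluded, photo_excluded.
    """
    rows = []
    for r in records:
        row: dict = {
            "patient_id": r.patient_id,
            "eye": r.eye,
            "dr_label": int(r.dr_label),
            "ma_count": r.ma_count,
            "volume_uL": r.volume_uL,
            "time_min": r.time_min,
        }
        if r.proteins is None:
            row.update({c: np.nan for c in PROTEIN_COLUMNS})
        else:
            row.update(dict(zip(PROTEIN_COLUMNS, r.proteins)))
        row["tear_excluded"] = int(r.tear_excluded)
        row["photo_excluded"] = int(r.photo_excluded)
        rows.append(row)
    cols = ["patient_id", "eye", "dr_label", "ma_count", "volume_uL", "time_min"]
    cols += list(PROTEIN_COLUMNS) + ["tear_excluded", "photo_excluded"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_cohort(frame: pd.DataFrame) -> list[EyeRecord]:
    """Inverse of :func:`cohort_to_frame`."""
    records = []
    for _, row in frame.iterrows():
        proteins = row[list(PROTEIN_COLUMNS)].to_numpy(dtype=float)
        if np.isnan(proteins).all():
            proteins = None
        ma = row["ma_count"]
        records.append(
            EyeRecord(
                patient_id=str(row["patient_id"]),
                eye=str(row["eye"]),
                dr_label=bool(int(row["dr_label"])),
                ma_count=None if pd.isna(ma) else int(ma),
                proteins=proteins,
                volume_uL=None if pd.isna(row.get("volume_uL")) else float(row["volume_uL"]),
                time_min=None if pd.isna(row.get("time_min")) else float(row["time_min"]),
                tear_excluded=bool(int(row.get("tear_excluded", 0))),
                photo_excluded=bool(int(row.get("photo_excluded", 0))),
            )
        )
    return records
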