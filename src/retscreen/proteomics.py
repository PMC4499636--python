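"""Tear-fluid sample handling: secretion-rate QC and the protein feature table.

Tear fluid is collected with glass capillaries over a noted time; the
secretion rate (collected volume / collection time, uL/min) gates sample
quality — unusually slow or fast secretion indicates unreliable sampling.
Samples inside the closed 5-15 uL/min window with a complete 34-protein
concentration profile form the proteomics feature table, one row per eye.
Concentrations are treated as opaque positive abundances; no transform or
scaling is applied before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import N_PROTEINS, PROTEIN_COLUMNS

__all__ = [
    "TearSample",
    "QCReport",
    "RATE_WINDOW_UL_MIN",
    "compute_secretion_rate",
    "qc_filter",
    "build_feature_table",
    "samples_to_frame",
    "frame_to_samples",
]

#: Closed secretion-rate acceptance window, uL/min.
RATE_WINDOW_UL_MIN = (5.0, 15.0)


def compute_secretion_rate(volume_uL: float, time_min: float) -> float:
    """Tear secretion rate: collected volume divided by collection time."""
    if time_min <= 0:
        raise ValueError("collection time must be positive")
    return volume_uL / time_min


@dataclass
class TearSample:
    """One eye's tear collection record.

    ``concentrations`` has exactly ``N_PROTEINS`` entries; missing
    measurements are NaN.  The secretion rate is derived exactly as
    volume / time.
    """

    patient_id: str
    eye: str
    volume_uL: float
    time_min: float
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        if self.volume_uL < 0:
            raise ValueError("volume_uL must be >= 0")
        if self.time_min <= 0:
            raise ValueError("time_min must be > 0")
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (N_PROTEINS,):
            raise ValueError(
                f"expected {N_PROTEINS} protein concentrations, "
                f"got {self.concentrations.shape}"
            )

    @property
    def secretion_rate_uL_min(self) -> float:
        return compute_secretion_rate(self.volume_uL, self.time_min)

    @property
    def complete(self) -> bool:
        return not np.isnan(self.concentrations).any()


@dataclass
class QCReport:
    """Partition of the input samples by QC outcome.

    ``n_input == n_retained + n_rate_excluded + n_incomplete_excluded``;
    the rate criterion is assessed first, so a sample failing both causes
    counts as rate-excluded.
    """

    n_input: int = 0
    n_rate_excluded: int = 0
    n_incomplete_excluded: int = 0
    n_retained: int = 0
    excluded_ids: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_rate_excluded": self.n_rate_excluded,
            "n_incomplete_excluded": self.n_incomplete_excluded,
            "n_retained": self.n_retained,
            "excluded_ids": [list(k) for k in self.excluded_ids],
        }


def qc_filter(
    samples: list[TearSample],
    rate_window: tuple[float, float] = RATE_WINDOW_UL_MIN,
) -> tuple[list[TearSample], QCReport]:
    """Retain samples inside the closed secretion-rate window with complete data.

    The window is inclusive at both endpoints.  Rate exclusion is assessed
    before completeness so each excluded sample has a single unambiguous
    cause.  Idempotent: filtering an already-filtered list retains all.
    """
    lo, hi = rate_window
    retained: list[TearSample] = []
    report = QCReport(n_input=len(samples))
    for s in samples:
        rate = s.secretion_rate_uL_min
        if not lo <= rate <= hi:
            report.n_rate_excluded += 1
            report.excluded_ids.append((s.patient_id, s.eye))
        elif not s.complete:
            report.n_incomplete_excluded += 1
            report.excluded_ids.append((s.patient_id, s.eye))
        else:
            retained.append(s)
    report.n_retained = len(retained)
    return retained, report


def build_feature_table(samples: list[TearSample]) -> pd.DataFrame:
    """Assemble the per-eye 34-protein feature matrix.

    One row per (patient_id, eye) key, rows sorted by key, columns P01-P34
    in fixed order; concentration values pass through unchanged.  Duplicate
    keys are rejected.
    """
    keys = [(s.patient_id, s.eye) for s in samples]
    seen: set = set()
    for k in keys:
        if k in seen:
            raise ValueError(f"duplicate sample key {k}")
        seen.add(k)
    index = pd.MultiIndex.from_tuples(keys, names=["patient_id", "eye"])
    table = pd.DataFrame(
        [s.concentrations for s in samples],
        index=index,
        columns=list(PROTEIN_COLUMNS),
    )
    return table.sort_index()


def samples_to_frame(samples: list[TearSample]) -> pd.DataFrame:
    """Flatten samples to the CSV schema (patient_id, eye, volume_uL, time_min, P01-P34)."""
    rows = []
    for s in samples:
        row = {
            "patient_id": s.patient_id,
            "eye": s.eye,
            "volume_uL": s.volume_uL,
            "time_min": s.time_min,
        }
        row.update(dict(zip(PROTEIN_COLUMNS, s.concentrations)))
        rows.append(row)
    cols = ["patient_id", "eye", "volume_uL", "time_min", *PROTEIN_COLUMNS]
    return pd.DataFrame(rows, columns=cols)


def frame_to_samples(frame: pd.DataFrame) -> list[TearSample]:
    """Inverse of :func:`samples_to_frame`; missing concentrations read as NaN."""
    samples = []
    for _, row in frame.iterrows():
        samples.append(
            TearSample(
                patient_id=str(row["patient_id"]),
                eye=str(row["eye"]),
                volume_uL=float(row["volume_uL"]),
                time_min=float(row["time_min"]),
                concentrations=row[list(PROTEIN_COLUMNS)].to_numpy(dtype=float),
            )
        )
    return samples
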