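"""Synthetic study-condition generators: fundus images, proteomes, cohorts.

Real screening studies pair gradable fundus photographs with tear-fluid
proteomics per eye; no such data ships with this package, so every
downstream stage is exercised on synthetic material that reproduces the
relevant structure:

* fundus images whose green channel carries a smooth illumination field,
  dark curvilinear vessels and planted dark circular microaneurysms (MAs)
  with known ground-truth centres;
* 34-protein concentration vectors whose log-scale location shifts between
  DR and non-DR groups on a configurable set of informative proteins;
* paired-eye cohorts with patient-level DR status, per-eye MA counts and
  the two per-eye exclusion causes (tear sampling failure, ungradable
  photograph) seen in clinical enrolment tables.

All generators are pure functions of their spec plus a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from .records import EyeRecord, FundusImage, GroundTruthMA, N_PROTEINS

__all__ = [
    "SyntheticFundusSpec",
    "SyntheticCohortSpec",
    "ExclusionSummary",
    "PlacementError",
    "generate_fundus",
    "generate_proteome",
    "generate_cohort",
]


class PlacementError(ValueError):
    """Raised when an image is too small to place the requested lesions."""


@dataclass(frozen=True)
class SyntheticFundusSpec:
    """Parameters of one synthetic fundus image.

    ``ma_diameter_px`` is the (min, max) lesion diameter; diameters must stay
    below 10 px so planted MAs remain "small circular objects" relative to
    the detector's 10 px opening disk.  ``ma_contrast`` is the fractional
    intensity dip at the lesion centre.  Lesions are 2-D Gaussian intensity
    dips; the quoted diameter is the full width at 20% of the dip depth.
    """

    height_px: int = 256
    width_px: int = 256
    n_mas: int = 5
    ma_diameter_px: tuple[float, float] = (3.0, 7.0)
    ma_contrast: float = 0.2
    vessel_count: int = 6
    illumination_gradient_amplitude: float = 0.15
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_mas < 0 or self.vessel_count < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.ma_diameter_px
        if not (0 < lo <= hi):
            raise ValueError("ma_diameter_px must satisfy 0 < min <= max")
        if hi >= 10:
            raise ValueError(
                "max MA diameter must be < 10 px so lesions stay below the "
                "detector's 10 px opening disk"
            )
        if not 0 <= self.ma_contrast <= 1:
            raise ValueError("ma_contrast must lie in [0, 1]")
        if not 0 <= self.illumination_gradient_amplitude <= 1:
            raise ValueError("illumination_gradient_amplitude must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Full width at 20% depth of a Gaussian dip: d = 2 sigma sqrt(2 ln 5).
_FWHM20 = 2.0 * math.sqrt(2.0 * math.log(5.0))

_BASE_GREEN = 0.55
_VESSEL_CONTRAST = 0.3


def _illumination_field(h: int, w: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order polynomial illumination surface, peak-to-peak == amplitude."""
    if amplitude == 0:
        return np.zeros((h, w))
    yy, xx = np.meshgrid(
        np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij"
    )
    c = rng.uniform(-1, 1, size=5)
    surf = c[0] * xx + c[1] * yy + c[2] * xx * yy + c[3] * xx**2 + c[4] * yy**2
    span = surf.max() - surf.min()
    if span == 0:
        return np.zeros((h, w))
    return (surf - surf.min()) / span * amplitude - amplitude / 2.0


def _stamp_vessels(
    green: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Darken ``count`` random smooth curvilinear tracks in place.

    Each vessel is a cubic spline through random waypoints, rasterised with
    a round brush of width 2-5 px and fractional contrast 0.3.  Returns the
    boolean vessel mask.
    """
    h, w = green.shape
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.indices((h, w))
    for _ in range(count):
        n_way = rng.integers(4, 7)
        rows = rng.uniform(0, h - 1, size=n_way)
        cols = np.sort(rng.uniform(0, w - 1, size=n_way))
        # parametrise along the column coordinate; vertical jitter from rows
        t = np.linspace(0, 1, n_way)
        try:
            spl_r = make_interp_spline(t, rows, k=min(3, n_way - 1))
            spl_c = make_interp_spline(t, cols, k=min(3, n_way - 1))
        except Exception:
            continue
        dense = np.linspace(0, 1, 4 * max(h, w))
        pr, pc = spl_r(dense), spl_c(dense)
        keep = (pr >= 0) & (pr <= h - 1) & (pc >= 0) & (pc <= w - 1)
        pr, pc = pr[keep], pc[keep]
        if pr.size == 0:
            continue
        width = rng.uniform(2.0, 5.0)
        radius = width / 2.0
        track = np.zeros((h, w), dtype=bool)
        for r, c in zip(pr, pc):
            r0, r1 = int(max(0, r - radius - 1)), int(min(h, r + radius + 2))
            c0, c1 = int(max(0, c - radius - 1)), int(min(w, c + radius + 2))
            sub = (yy[r0:r1, c0:c1] - r) ** 2 + (xx[r0:r1, c0:c1] - c) ** 2 <= radius**2
            track[r0:r1, c0:c1] |= sub
        green[track] -= _VESSEL_CONTRAST * _BASE_GREEN
        mask |= track
    return mask


def generate_fundus(
    spec: SyntheticFundusSpec,
    image_id: str = "synthetic",
    patient_id: str = "",
    eye: str = "L",
) -> tuple[FundusImage, list[GroundTruthMA]]:
    """Render a synthetic fundus image with planted MAs and their ground truth.

    The green channel is built as base level + illumination field, then
    vessels and Gaussian-dip MAs are subtracted and Gaussian pixel noise
    added.  MA placements avoid vessels and each other (no overlap beyond
    1 px).  Deterministic for a fixed spec (the seed lives on the spec).

    Raises
    ------
    PlacementError
        If ``n_mas`` non-overlapping lesions cannot be placed in the image.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    green = np.full((h, w), _BASE_GREEN)
    green += _illumination_field(h, w, spec.illumination_gradient_amplitude, rng)
    vessel_mask = _stamp_vessels(green, spec.vessel_count, rng)

    truths: list[GroundTruthMA] = []
    centers: list[tuple[float, float, float]] = []  # (row, col, radius)
    yy, xx = np.indices((h, w))
    max_attempts = 2000 * max(1, spec.n_mas)
    attempts = 0
    while len(truths) < spec.n_mas:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"image {h}x{w} too small to place {spec.n_mas} non-overlapping "
                f"microaneurysms clear of {spec.vessel_count} vessels"
            )
        d = rng.uniform(*spec.ma_diameter_px)
        radius = d / 2.0
        margin = radius + 2.0
        if 2 * margin >= min(h, w):
            raise PlacementError(
                f"image {h}x{w} too small for lesion diameter {d:.1f} px"
            )
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        # pairwise separation: blobs may overlap by at most 1 px
        if any(
            math.hypot(r - r2, c - c2) < radius + rad2 + 1.0
            for r2, c2, rad2 in centers
        ):
            continue
        # keep clear of vessels within radius + 1
        r0, r1 = int(max(0, r - radius - 1)), int(min(h, r + radius + 2))
        c0, c1 = int(max(0, c - radius - 1)), int(min(w, c + radius + 2))
        near = (yy[r0:r1, c0:c1] - r) ** 2 + (xx[r0:r1, c0:c1] - c) ** 2 <= (radius + 1.0) ** 2
        if vessel_mask[r0:r1, c0:c1][near].any():
            continue
        centers.append((r, c, radius))
        truths.append(GroundTruthMA(center_row=r, center_col=c, diameter_px=d))

    for (r, c, radius), truth in zip(centers, truths):
        sigma = truth.diameter_px / _FWHM20
        ext = int(math.ceil(4 * sigma)) + 1
        r0, r1 = int(max(0, r - ext)), int(min(h, r + ext + 1))
        c0, c1 = int(max(0, c - ext)), int(min(w, c + ext + 1))
        d2 = (yy[r0:r1, c0:c1] - r) ** 2 + (xx[r0:r1, c0:c1] - c) ** 2
        green[r0:r1, c0:c1] -= spec.ma_contrast * np.exp(-d2 / (2 * sigma**2))

    if spec.noise_sd > 0:
        green = green + rng.normal(0.0, spec.noise_sd, size=green.shape)
    green = np.clip(green, 0.0, 1.0)

    # red channel brighter, blue darker, as in colour fundus photographs
    red = np.clip(0.6 * green + 0.35, 0.0, 1.0)
    blue = np.clip(0.5 * green, 0.0, 1.0)
    pixels = np.stack([red, green, blue], axis=-1)
    image = FundusImage(pixels=pixels, image_id=image_id, patient_id=patient_id, eye=eye)
    return image, truths


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic paired-eye screening cohort.

    Each patient contributes exactly two eyes; DR status is assigned at
    patient level and shared by both eyes, while MA counts are Poisson
    draws per eye with status-dependent means.  Log protein concentrations
    are Gaussian with unit-free standard deviation ``protein_log_sd``; the
    first ``n_informative_proteins`` coordinates are shifted by
    ``protein_effect_size`` standard deviations in DR patients.
    """

    n_patients: int = 52
    dr_fraction: float = 0.75
    tear_exclusion_rate: float = 0.09
    photo_exclusion_rate: float = 0.20
    n_proteins: int = N_PROTEINS
    n_informative_proteins: int = 10
    protein_effect_size: float = 1.0
    protein_log_sd: float = 0.5
    ma_rate_dr: float = 6.0
    ma_rate_nondr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 <= self.dr_fraction <= 1:
            raise ValueError("dr_fraction must lie in [0, 1]")
        for name in ("tear_exclusion_rate", "photo_exclusion_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_informative_proteins > self.n_proteins:
            raise ValueError("n_informative_proteins cannot exceed n_proteins")
        if self.n_informative_proteins < 0:
            raise ValueError("n_informative_proteins must be non-negative")
        if self.ma_rate_dr < 0 or self.ma_rate_nondr < 0:
            raise ValueError("MA rates must be non-negative")
        if self.protein_log_sd <= 0:
            raise ValueError("protein_log_sd must be positive")


def _baseline_log_abundance(n_proteins: int) -> np.ndarray:
    # fixed per-protein baseline, shared by both groups
    return np.log(50.0) + 0.05 * np.arange(n_proteins)


def generate_proteome(
    dr_status: bool, spec: SyntheticCohortSpec, seed: int
) -> np.ndarray:
    """Draw one eye's protein concentration vector.

    Concentrations are log-normal: log values are Gaussian around a fixed
    per-protein baseline, with the informative coordinates shifted upward by
    ``protein_effect_size * protein_log_sd`` when ``dr_status`` is true.
    Strictly positive; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    mu = _baseline_log_abundance(spec.n_proteins).copy()
    if dr_status and spec.n_informative_proteins > 0:
        mu[: spec.n_informative_proteins] += (
            spec.protein_effect_size * spec.protein_log_sd
        )
    log_conc = rng.normal(mu, spec.protein_log_sd)
    return np.exp(log_conc)


@dataclass
class ExclusionSummary:
    """Accounting of cohort enrolment: candidate eyes and exclusion causes."""

    n_candidate_eyes: int
    n_tear_excluded: int
    n_photo_excluded: int
    n_included: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_candidate_eyes": self.n_candidate_eyes,
            "n_tear_excluded": self.n_tear_excluded,
            "n_photo_excluded": self.n_photo_excluded,
            "n_included": self.n_included,
        }


def generate_cohort(
    spec: SyntheticCohortSpec,
    fixed_exclusions: tuple[int, int] | None = None,
) -> tuple[list[EyeRecord], ExclusionSummary]:
    """Generate a paired-eye cohort with exclusion structure.

    Every patient contributes a left and a right eye.  Each eye is
    independently flagged tear-excluded / photo-excluded with the spec's
    Bernoulli rates, unless ``fixed_exclusions=(n_tear, n_photo)`` is given,
    in which case exactly those counts are assigned deterministically to the
    first eyes in enrolment order (disjoint causes) — the mode used to
    reproduce published enrolment arithmetic.  The returned list contains
    ALL candidate eyes with their flags; included records are those with
    neither flag.

    Tear collection volumes/times are drawn so that secretion rates centre
    on the clinically usual ~10 uL/min.
    """
    rng = np.random.default_rng(spec.seed)
    n_eyes = 2 * spec.n_patients
    if fixed_exclusions is not None:
        n_tear, n_photo = fixed_exclusions
        if n_tear + n_photo > n_eyes:
            raise ValueError("fixed exclusion counts exceed the number of eyes")
        tear_flags = np.zeros(n_eyes, dtype=bool)
        photo_flags = np.zeros(n_eyes, dtype=bool)
        tear_flags[:n_tear] = True
        photo_flags[n_tear : n_tear + n_photo] = True
    else:
        tear_flags = rng.random(n_eyes) < spec.tear_exclusion_rate
        photo_flags = rng.random(n_eyes) < spec.photo_exclusion_rate

    dr_status = rng.random(spec.n_patients) < spec.dr_fraction
    records: list[EyeRecord] = []
    idx = 0
    for p in range(spec.n_patients):
        pid = f"P{p + 1:04d}"
        dr = bool(dr_status[p])
        rate = spec.ma_rate_dr if dr else spec.ma_rate_nondr
        for eye in ("L", "R"):
            ma_count = int(rng.poisson(rate))
            time_min = float(rng.uniform(1.0, 3.0))
            secretion = float(np.clip(rng.normal(10.0, 2.5), 0.5, None))
            proteome_seed = int(rng.integers(0, 2**31 - 1))
            proteins = generate_proteome(dr, spec, proteome_seed)
            records.append(
                EyeRecord(
                    patient_id=pid,
                    eye=eye,
                    dr_label=dr,
                    ma_count=ma_count,
                    proteins=proteins,
                    volume_uL=secretion * time_min,
                    time_min=time_min,
                    tear_excluded=bool(tear_flags[idx]),
                    photo_excluded=bool(photo_flags[idx]),
                )
            )
            idx += 1

    summary = ExclusionSummary(
        n_candidate_eyes=n_eyes,
        n_tear_excluded=int(tear_flags.sum()),
        n_photo_excluded=int(photo_flags.sum()),
        n_included=int((~tear_flags & ~photo_flags).sum()),
    )
    return records, summary
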