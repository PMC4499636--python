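"""Microaneurysm detection in fundus photographs.

The detector follows a classical morphological chain on the green plane,
where microaneurysms (MAs) — small dark round dots — contrast best:

1. shade correction: subtract a large-window (35 x 35) median-filtered
   background estimate, removing slow illumination variation;
2. polarity inversion + contrast-limited adaptive histogram equalisation
   (CLAHE), so dark lesions become bright local maxima;
3. 3 x 3 median smoothing;
4. top-hat by morphological reconstruction: the image minus its
   reconstruction-by-dilation from an eroded marker, which isolates bright
   peaks smaller than the structuring element while preserving larger
   structures exactly;
5. grayscale opening by a 10 px disk; structures removed by the opening
   (too small to contain the disk) are thresholded into candidate regions.

Each 8-connected candidate region yields five features — area, rotational
inertia about the centroid, mean intensity in the opened image, and
mean/SD of the raw green plane over the region — which a seeded gradient
boosting classifier scores as MA / non-MA.  The per-image MA count is the
number of candidates scoring at or above a decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy import ndimage
from skimage import exposure, morphology
from skimage.measure import label as cc_label
from sklearn.ensemble import GradientBoostingClassifier

from .records import FundusImage, GroundTruthMA

__all__ = [
    "DetectorConfig",
    "CandidateFeatures",
    "MACandidate",
    "extract_green",
    "shade_correct",
    "enhance_clahe",
    "median_smooth",
    "tophat_reconstruction",
    "disk_footprint",
    "extract_candidates",
    "compute_features",
    "run_chain",
    "detect_candidates",
    "match_to_ground_truth",
    "train_candidate_classifier",
    "score_candidates",
    "count_mas",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the detection chain.

    Window sizes are in pixels; ``opening_disk_px`` is the diameter of the
    disk structuring element (bounding box ``opening_disk_px`` square).
    ``residual_threshold`` binarises the small-object residual relative to
    its maximum.  ``candidate_score_threshold`` is the classifier
    probability above which a candidate is counted as an MA.
    """

    shade_window_px: int = 35
    clahe_clip: float = 0.05
    clahe_tiles: tuple[int, int] = (8, 8)
    smooth_window_px: int = 3
    opening_disk_px: int = 10
    residual_threshold: float = 0.1
    min_area_px: int = 1
    max_area_px: int = 120
    match_tolerance_px: float = 3.0
    candidate_score_threshold: float = 0.5
    gbm_n_estimators: int = 200
    gbm_max_depth: int = 2
    gbm_learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shade_window_px % 2 == 0 or self.shade_window_px < 3:
            raise ValueError("shade_window_px must be odd and >= 3")
        if self.smooth_window_px % 2 == 0:
            raise ValueError("smooth_window_px must be odd")
        if self.opening_disk_px < 2:
            raise ValueError("opening_disk_px must be >= 2")
        if not 0 < self.residual_threshold < 1:
            raise ValueError("residual_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class CandidateFeatures:
    """Five-feature description of a candidate region."""

    area: int
    rotational_inertia: float
    mean_intensity_opened: float
    mean_intensity_green: float
    sd_intensity_green: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.area,
                self.rotational_inertia,
                self.mean_intensity_opened,
                self.mean_intensity_green,
                self.sd_intensity_green,
            ]
        )


FEATURE_NAMES = (
    "area",
    "rotational_inertia",
    "mean_intensity_opened",
    "mean_intensity_green",
    "sd_intensity_green",
)


@dataclass
class MACandidate:
    """An 8-connected candidate region with centroid, features and score."""

    image_id: str
    pixel_set: np.ndarray  # (n, 2) array of (row, col)
    centroid: tuple[float, float]
    features: CandidateFeatures | None = None
    score: float | None = None
    gt_label: bool | None = None


def extract_green(image: FundusImage) -> np.ndarray:
    """Return the green plane (channel index 1) unchanged."""
    px = np.asarray(image.pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected a three-channel RGB image")
    return px[:, :, 1]


def shade_correct(gray: np.ndarray, window_px: int = 35) -> np.ndarray:
    """Signed shade-correction residual: gray minus its windowed median.

    Uses a square median window with reflective boundary handling.  Dark
    lesions yield negative residuals; a constant image yields all zeros.
    """
    if window_px % 2 == 0 or window_px < 3:
        raise ValueError("window_px must be odd and >= 3")
    if window_px > max(gray.shape):
        raise ValueError(
            f"median window {window_px} exceeds both image dimensions {gray.shape}"
        )
    background = ndimage.median_filter(gray, size=window_px, mode="reflect")
    return gray - background


def enhance_clahe(
    residual: np.ndarray,
    clip: float = 0.05,
    tiles: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Invert, rescale and contrast-enhance the shade-corrected residual.

    The residual is sign-inverted and min-max rescaled to [0, 1] first, so
    that dark lesions (negative residuals) become bright maxima, then CLAHE
    is applied tile-wise.  A constant input returns a constant 0.5 grid by
    convention.
    """
    residual = np.asarray(residual, dtype=float)
    if not np.all(np.isfinite(residual)):
        raise ValueError("residual grid must be finite")
    inverted = -residual
    lo, hi = inverted.min(), inverted.max()
    if hi == lo:
        return np.full_like(residual, 0.5)
    rescaled = (inverted - lo) / (hi - lo)
    kernel = (
        max(1, residual.shape[0] // tiles[0]),
        max(1, residual.shape[1] // tiles[1]),
    )
    return exposure.equalize_adapthist(rescaled, kernel_size=kernel, clip_limit=clip)


def median_smooth(grid: np.ndarray, window_px: int = 3) -> np.ndarray:
    """Windowed median smoothing with reflective boundaries."""
    if window_px % 2 == 0:
        raise ValueError("window_px must be odd")
    return ndimage.median_filter(grid, size=window_px, mode="reflect")


def disk_footprint(diameter_px: int) -> np.ndarray:
    """Boolean disk of the given diameter (bounding box diameter x diameter)."""
    c = (diameter_px - 1) / 2.0
    yy, xx = np.indices((diameter_px, diameter_px))
    return (yy - c) ** 2 + (xx - c) ** 2 <= (diameter_px / 2.0) ** 2


def tophat_reconstruction(
    grid: np.ndarray, footprint: np.ndarray | None = None, disk_px: int = 10
) -> np.ndarray:
    """Top-hat by morphological reconstruction.

    Marker = grayscale erosion of the grid by the disk; background =
    reconstruction-by-dilation of the marker under the grid as mask; output
    = grid - background.  Nonnegative everywhere; peaks too small to
    contain the disk are returned at (almost) full height, larger bright
    structures are reconstructed exactly and vanish from the output.
    """
    if footprint is None:
        footprint = disk_footprint(disk_px)
    marker = morphology.erosion(grid, footprint)
    background = morphology.reconstruction(marker, grid, method="dilation")
    return grid - background


def compute_features(
    pixel_set: np.ndarray, opened: np.ndarray, green: np.ndarray
) -> CandidateFeatures:
    """Five-feature vector of a candidate pixel set.

    Rotational inertia is the second moment of the pixel set about its own
    centroid, sum((r - rbar)^2 + (c - cbar)^2); intensity statistics are
    population mean/SD over the set.
    """
    pixel_set = np.asarray(pixel_set)
    if pixel_set.size == 0:
        raise ValueError("candidate pixel set must be nonempty")
    rows, cols = pixel_set[:, 0], pixel_set[:, 1]
    rbar, cbar = rows.mean(), cols.mean()
    inertia = float(((rows - rbar) ** 2 + (cols - cbar) ** 2).sum())
    green_vals = green[rows, cols]
    return CandidateFeatures(
        area=int(len(pixel_set)),
        rotational_inertia=inertia,
        mean_intensity_opened=float(opened[rows, cols].mean()),
        mean_intensity_green=float(green_vals.mean()),
        sd_intensity_green=float(green_vals.std()),
    )


def extract_candidates(
    tophat: np.ndarray,
    config: DetectorConfig,
    image_id: str = "",
    green: np.ndarray | None = None,
) -> list[MACandidate]:
    """Read candidate regions off the top-hat grid.

    The top-hat image is opened by the disk; the residual (top-hat minus
    opening) holds exactly the bright structures too small to contain the
    disk.  The residual is binarised at ``residual_threshold`` times its
    maximum, 8-connected components are gated on area, and each surviving
    component becomes a candidate with features computed over the opened
    image and the raw green plane.  Candidates are ordered by centroid
    (row, col).
    """
    footprint = disk_footprint(config.opening_disk_px)
    opened = morphology.opening(tophat, footprint)
    residual = tophat - opened
    peak = residual.max()
    if peak <= 0:
        return []
    binary = residual >= config.residual_threshold * peak
    labels = cc_label(binary, connectivity=2)
    if green is None:
        green = tophat
    candidates: list[MACandidate] = []
    for region_label in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == region_label)
        area = rows.size
        if area < config.min_area_px or area > config.max_area_px:
            continue
        pixel_set = np.column_stack([rows, cols])
        feats = compute_features(pixel_set, opened, green)
        candidates.append(
            MACandidate(
                image_id=image_id,
                pixel_set=pixel_set,
                centroid=(float(rows.mean()), float(cols.mean())),
                features=feats,
            )
        )
    candidates.sort(key=lambda c: c.centroid)
    return candidates


def run_chain(image: FundusImage, config: DetectorConfig) -> dict[str, np.ndarray]:
    """Run the preprocessing chain, returning every intermediate grid."""
    green = extract_green(image)
    residual = shade_correct(green, config.shade_window_px)
    enhanced = enhance_clahe(residual, config.clahe_clip, config.clahe_tiles)
    smoothed = median_smooth(enhanced, config.smooth_window_px)
    tophat = tophat_reconstruction(smoothed, disk_px=config.opening_disk_px)
    return {
        "green": green,
        "residual": residual,
        "enhanced": enhanced,
        "smoothed": smoothed,
        "tophat": tophat,
    }


def detect_candidates(image: FundusImage, config: DetectorConfig) -> list[MACandidate]:
    """Full chain: preprocess and extract featured candidates."""
    grids = run_chain(image, config)
    return extract_candidates(
        grids["tophat"], config, image_id=image.image_id, green=grids["green"]
    )


def match_to_ground_truth(
    candidates: list[MACandidate],
    truths: list[GroundTruthMA],
    tolerance_px: float = 3.0,
) -> None:
    """Label candidates by greedy nearest-first one-to-one matching.

    All candidate-truth pairs within ``tolerance_px`` are sorted by
    distance; pairs are accepted greedily, each candidate and each truth
    matched at most once.  Matched candidates get ``gt_label=True``, the
    rest ``False``.
    """
    pairs = []
    for ci, cand in enumerate(candidates):
        for ti, truth in enumerate(truths):
            d = np.hypot(
                cand.centroid[0] - truth.center_row,
                cand.centroid[1] - truth.center_col,
            )
            if d <= tolerance_px:
                pairs.append((d, ci, ti))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    for _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
    for ci, cand in enumerate(candidates):
        cand.gt_label = ci in used_c


def _feature_matrix(candidates: list[MACandidate]) -> np.ndarray:
    return np.array([c.features.as_array() for c in candidates])


def train_candidate_classifier(
    candidates: list[MACandidate], config: DetectorConfig
) -> GradientBoostingClassifier:
    """Fit the seeded gradient boosting candidate classifier.

    Candidates must carry ``gt_label``; both classes must be present.
    """
    labeled = [c for c in candidates if c.gt_label is not None]
    if not labeled:
        raise ValueError("no labelled candidates to train on")
    y = np.array([bool(c.gt_label) for c in labeled])
    if y.all() or not y.any():
        raise ValueError("candidate training set contains a single class")
    X = _feature_matrix(labeled)
    model = GradientBoostingClassifier(
        n_estimators=config.gbm_n_estimators,
        max_depth=config.gbm_max_depth,
        learning_rate=config.gbm_learning_rate,
        random_state=config.seed,
    )
    model.fit(X, y)
    return model


def score_candidates(
    candidates: list[MACandidate], model: GradientBoostingClassifier
) -> None:
    """Attach MA probabilities to candidates in place."""
    if not candidates:
        return
    probs = model.predict_proba(_feature_matrix(candidates))[:, 1]
    for cand, p in zip(candidates, probs):
        cand.score = float(p)


def count_mas(
    image: FundusImage,
    model: GradientBoostingClassifier,
    config: DetectorConfig,
) -> int:
    """Number of candidates scoring at or above the decision threshold."""
    candidates = detect_candidates(image, config)
    score_candidates(candidates, model)
    return sum(
        1 for c in candidates if c.score is not None and c.score >= config.candidate_score_threshold
    )


def save_model(model: GradientBoostingClassifier, config: DetectorConfig, path) -> None:
    """Serialise the candidate classifier together with its config."""
    joblib.dump({"format_version": 1, "config": config, "model": model}, path)


def load_model(path) -> tuple[GradientBoostingClassifier, DetectorConfig]:
    payload = joblib.load(path)
    return payload["model"], payload["config"]
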