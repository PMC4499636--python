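"""Microaneurysm detector: operator semantics and chain behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from skimage import morphology

from conftest import make_fixture
from retscreen.detector import (
    DetectorConfig,
    compute_features,
    count_mas,
    detect_candidates,
    disk_footprint,
    enhance_clahe,
    extract_candidates,
    extract_green,
    match_to_ground_truth,
    median_smooth,
    run_chain,
    score_candidates,
    shade_correct,
    tophat_reconstruction,
    train_candidate_classifier,
)
from retscreen.records import FundusImage
from retscreen.synthetic import SyntheticFundusSpec, generate_fundus

small_grids = arrays(
    dtype=float,
    shape=st.tuples(st.integers(12, 24), st.integers(12, 24)),
    elements=st.floats(0, 1, allow_nan=False),
)


def rgb(green):
    return FundusImage(pixels=np.stack([green * 0, green, green * 0], axis=-1))


class TestExtractGreen:
    def test_returns_channel_one_unchanged(self):
        px = np.zeros((8, 8, 3))
        px[:, :, 1] = 0.5
        assert (extract_green(FundusImage(pixels=px)) == 0.5).all()

    def test_pure_red_image_gives_zero_grid(self):
        px = np.zeros((8, 8, 3))
        px[:, :, 0] = 1.0
        assert (extract_green(FundusImage(pixels=px)) == 0.0).all()

    def test_roundtrip_with_generator(self):
        image, _ = generate_fundus(SyntheticFundusSpec(seed=1))
        np.testing.assert_array_equal(extract_green(image), image.pixels[:, :, 1])

    def test_single_channel_input_rejected(self):
        img = FundusImage(pixels=np.zeros((4, 4, 3)))
        img.pixels = np.zeros((4, 4))  # bypass constructor validation
        with pytest.raises(ValueError, match="three-channel"):
            extract_green(img)


class TestShadeCorrect:
    def test_constant_image_annihilated(self):
        assert (shade_correct(np.full((40, 40), 0.7), 35) == 0).all()

    def test_single_dark_pixel_residual(self):
        gray = np.full((64, 64), 0.5)
        gray[30, 30] = 0.3
        res = shade_correct(gray, 35)
        assert res[30, 30] == pytest.approx(-0.2)
        mask = np.ones_like(gray, dtype=bool)
        mask[30, 30] = False
        assert np.abs(res[mask]).max() == pytest.approx(0.0, abs=1e-12)

    def test_smooth_polynomial_field_mostly_removed(self):
        yy, xx = np.meshgrid(
            np.linspace(-1, 1, 256), np.linspace(-1, 1, 256), indexing="ij"
        )
        field = 0.5 + 0.1 * (xx**2 - 0.5 * yy + 0.3 * xx * yy)  # amplitude ~0.2
        res = shade_correct(field, 35)
        interior = res[17:-17, 17:-17]
        assert np.abs(interior).max() < 0.01

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            shade_correct(np.zeros((10, 10)), 35)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            shade_correct(np.zeros((40, 40)), 34)


class TestEnhanceClahe:
    def test_constant_residual_maps_to_half(self):
        out = enhance_clahe(np.zeros((32, 32)))
        assert (out == 0.5).all()

    def test_two_level_ordering_preserved_after_inversion(self):
        grid = np.zeros((64, 64))
        grid[:, 32:] = 1.0  # right half bright -> after inversion it is dark
        out = enhance_clahe(grid)
        assert out[:, :16].mean() > out[:, 48:].mean()
        assert out.min() >= 0 and out.max() <= 1

    def test_planted_mas_become_brighter_than_background(self):
        spec = SyntheticFundusSpec(seed=5, noise_sd=0.0)
        image, truths = generate_fundus(spec)
        cfg = DetectorConfig()
        grids = run_chain(image, cfg)
        enhanced = grids["enhanced"]
        yy, xx = np.indices(enhanced.shape)
        ma_mask = np.zeros_like(enhanced, dtype=bool)
        for t in truths:
            ma_mask |= (yy - t.center_row) ** 2 + (xx - t.center_col) ** 2 <= (
                t.diameter_px / 2
            ) ** 2
        assert enhanced[ma_mask].mean() > enhanced[~ma_mask].mean()

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            enhance_clahe(np.full((8, 8), np.nan))


class TestMedianSmooth:
    def test_constant_unchanged(self):
        grid = np.full((16, 16), 0.3)
        np.testing.assert_array_equal(median_smooth(grid, 3), grid)

    def test_isolated_outlier_removed(self):
        grid = np.full((16, 16), 0.2)
        grid[8, 8] = 1.0
        assert median_smooth(grid, 3)[8, 8] == 0.2

    def test_checkerboard_interior_keeps_majority_value(self):
        # in a 3x3 window on a checkerboard the centre colour occupies 5 of 9
        # cells (centre + diagonals), so the median equals the centre value
        grid = np.indices((5, 5)).sum(axis=0) % 2
        out = median_smooth(grid.astype(float), 3)
        np.testing.assert_array_equal(out[1:-1, 1:-1], grid[1:-1, 1:-1])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_smooth(np.zeros((8, 8)), 4)


class TestTophatReconstruction:
    def test_constant_grid_gives_zero(self):
        out = tophat_reconstruction(np.full((32, 32), 0.6))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_small_blob_preserved_at_full_height(self):
        grid = np.full((64, 64), 0.2)
        blob = disk_footprint(5)
        grid[30:35, 30:35][blob] = 0.8
        out = tophat_reconstruction(grid)
        assert out[32, 32] == pytest.approx(0.6)
        assert np.abs(out[:20, :20]).max() == pytest.approx(0.0, abs=1e-12)

    def test_large_plateau_fully_reconstructed(self):
        grid = np.full((64, 64), 0.2)
        plateau = disk_footprint(30)
        grid[17:47, 17:47][plateau] = 0.9
        out = tophat_reconstruction(grid)
        assert np.abs(out[plateau.nonzero()[0] + 17, plateau.nonzero()[1] + 17]).max() == pytest.approx(
            0.0, abs=1e-9
        )

    @settings(max_examples=30, deadline=None)
    @given(small_grids)
    def test_nonnegative_on_fuzzed_inputs(self, grid):
        out = tophat_reconstruction(grid, disk_px=4)
        assert (out >= -1e-12).all()


class TestOpening:
    @settings(max_examples=20, deadline=None)
    @given(small_grids)
    def test_opening_is_idempotent(self, grid):
        # quantize so equality is exact
        q = np.round(grid * 64) / 64
        fp = disk_footprint(4)
        once = morphology.opening(q, fp)
        twice = morphology.opening(once, fp)
        np.testing.assert_array_equal(once, twice)


class TestExtractCandidates:
    def test_blank_image_yields_no_candidates(self):
        assert extract_candidates(np.zeros((64, 64)), DetectorConfig()) == []

    def test_large_bright_disk_survives_opening_hence_no_candidates(self):
        grid = np.zeros((64, 64))
        disk = disk_footprint(15)
        grid[20:35, 20:35][disk] = 0.8
        assert extract_candidates(grid, DetectorConfig()) == []

    def test_five_planted_mas_recovered(self, detector_config):
        cands, truths = make_fixture(
            26, detector_config, vessel_count=0, illumination_gradient_amplitude=0.05
        )
        assert len(truths) == 5
        assert len(cands) == 5
        # one-to-one matching within 3 px of distinct ground-truth centres
        assert sum(c.gt_label for c in cands) == 5

    def test_candidates_sorted_by_centroid(self, detector_config):
        cands, _ = make_fixture(22, detector_config)
        centroids = [c.centroid for c in cands]
        assert centroids == sorted(centroids)


class TestComputeFeatures:
    def test_single_pixel(self):
        grid = np.full((8, 8), 0.4)
        f = compute_features(np.array([[3, 3]]), grid, grid)
        assert f.area == 1
        assert f.rotational_inertia == 0.0
        assert f.sd_intensity_green == 0.0

    def test_square_block_inertia_matches_enumeration(self):
        # offsets {-1,0,1}^2: sum of r^2 + c^2 = 6 + 6 = 12
        px = np.array([[r, c] for r in range(3) for c in range(3)]) + 5
        grid = np.zeros((16, 16))
        f = compute_features(px, grid, grid)
        assert f.area == 9
        assert f.rotational_inertia == pytest.approx(12.0)

    def test_line_inertia_exceeds_square(self):
        px = np.array([[5, c] for c in range(9)])
        grid = np.zeros((16, 16))
        f = compute_features(px, grid, grid)
        assert f.area == 9
        assert f.rotational_inertia == pytest.approx(60.0)

    def test_empty_pixel_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compute_features(np.empty((0, 2)), np.zeros((4, 4)), np.zeros((4, 4)))


class TestCandidateClassifier:
    def _separable_candidates(self):
        rng = np.random.default_rng(0)
        grid = np.linspace(0, 1, 400 * 400).reshape(400, 400)
        cands = []
        for i in range(30):
            # true MAs: compact 10-40 px blobs; noise: 200-400 px blobs
            small = rng.integers(10, 41)
            big = rng.integers(200, 401)
            for area, label in ((small, True), (big, False)):
                side = int(np.sqrt(area))
                r0, c0 = rng.integers(0, 350, size=2)
                px = np.array(
                    [[r0 + r, c0 + c] for r in range(side) for c in range(side)]
                )
                from retscreen.detector import MACandidate

                cands.append(
                    MACandidate(
                        image_id="x",
                        pixel_set=px,
                        centroid=(px[:, 0].mean(), px[:, 1].mean()),
                        features=compute_features(px, grid, grid),
                        gt_label=label,
                    )
                )
        return cands

    def test_separable_features_fit_perfectly(self):
        cfg = DetectorConfig()
        cands = self._separable_candidates()
        model = train_candidate_classifier(cands, cfg)
        score_candidates(cands, model)
        preds = [c.score >= 0.5 for c in cands]
        assert preds == [bool(c.gt_label) for c in cands]

    def test_single_class_training_rejected(self):
        cfg = DetectorConfig()
        cands = [c for c in self._separable_candidates() if c.gt_label]
        with pytest.raises(ValueError, match="single class"):
            train_candidate_classifier(cands, cfg)

    def test_same_seed_gives_identical_scores(self):
        cfg = DetectorConfig()
        cands = self._separable_candidates()
        m1 = train_candidate_classifier(cands, cfg)
        m2 = train_candidate_classifier(cands, cfg)
        held = self._separable_candidates()[:5]
        score_candidates(held, m1)
        s1 = [c.score for c in held]
        score_candidates(held, m2)
        assert s1 == [c.score for c in held]


class TestCountMAs:
    def test_blank_image_counts_zero(self, detector_config, trained_candidate_model):
        image = FundusImage(pixels=np.full((128, 128, 3), 0.5))
        assert count_mas(image, trained_candidate_model, detector_config) == 0

    def test_noiseless_fixture_counts_planted_mas(
        self, detector_config, trained_candidate_model
    ):
        spec = SyntheticFundusSpec(
            seed=23, noise_sd=0.0, vessel_count=0, illumination_gradient_amplitude=0.05
        )
        image, truths = generate_fundus(spec)
        assert count_mas(image, trained_candidate_model, detector_config) == len(truths)

    def test_count_monotone_nonincreasing_in_threshold(
        self, detector_config, trained_candidate_model
    ):
        from dataclasses import replace

        spec = SyntheticFundusSpec(seed=24, noise_sd=0.0)
        image, _ = generate_fundus(spec)
        counts = [
            count_mas(
                image,
                trained_candidate_model,
                replace(detector_config, candidate_score_threshold=t),
            )
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_pipeline_deterministic(self, detector_config, trained_candidate_model):
        spec = SyntheticFundusSpec(seed=25)
        image, _ = generate_fundus(spec)
        c1 = detect_candidates(image, detector_config)
        c2 = detect_candidates(image, detector_config)
        assert [c.centroid for c in c1] == [c.centroid for c in c2]
        assert count_mas(image, trained_candidate_model, detector_config) == count_mas(
            image, trained_candidate_model, detector_config
        )


class TestGroundTruthMatching:
    def test_greedy_one_to_one_matching(self):
        from retscreen.detector import MACandidate
        from retscreen.records import GroundTruthMA

        def cand(r, c):
            return MACandidate(
                image_id="x", pixel_set=np.array([[r, c]]), centroid=(r, c)
            )

        cands = [cand(10, 10), cand(11, 10), cand(40, 40)]
        truths = [GroundTruthMA(10.4, 10.0, 4)]
        match_to_ground_truth(cands, truths, tolerance_px=3.0)
        # only the nearest candidate matches the single truth
        assert [c.gt_label for c in cands] == [True, False, False]
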