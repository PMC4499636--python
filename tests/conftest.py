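import numpy as np
import pytest

from retscreen.detector import (
    DetectorConfig,
    detect_candidates,
    match_to_ground_truth,
    train_candidate_classifier,
)
from retscreen.synthetic import SyntheticFundusSpec, generate_fundus


def make_fixture(seed, cfg, **spec_overrides):
    """One noiseless fundus fixture with matched, featured candidates."""
    spec = SyntheticFundusSpec(seed=seed, noise_sd=0.0, **spec_overrides)
    image, truths = generate_fundus(spec, image_id=f"I{seed}")
    cands = detect_candidates(image, cfg)
    match_to_ground_truth(cands, truths, cfg.match_tolerance_px)
    return cands, truths


@pytest.fixture(scope="session")
def detector_config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def trained_candidate_model(detector_config):
    """Candidate classifier trained on 60 seeded noiseless fixtures."""
    cands = []
    for seed in range(100, 160):
        c, _ = make_fixture(seed, detector_config)
        cands.extend(c)
    return train_candidate_classifier(cands, detector_config)
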