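import warnings

import numpy as np
import pytest

from octdr.phantom import PhantomConfig, generate_cohort, generate_scan, _jitter_config
from octdr.segmentation import ShapeAtlas


@pytest.fixture(scope="session")
def noiseless_config():
    return PhantomConfig(noise_scale=0.0, seed=42)


@pytest.fixture(scope="session")
def noiseless_scan(noiseless_config):
    return generate_scan(noiseless_config, "normal")


@pytest.fixture(scope="session")
def noisy_scan():
    return generate_scan(PhantomConfig(seed=7), "normal")


@pytest.fixture(scope="session")
def dr_scan():
    return generate_scan(PhantomConfig(seed=7), "DR")


@pytest.fixture(scope="session")
def phantom_family_atlas(noiseless_config):
    """Atlas of 4 jittered same-family noiseless phantoms + a held-out
    test scan of the same family."""
    master = np.random.default_rng(7)
    imgs, lms = [], []
    for i in range(4):
        cfg = _jitter_config(noiseless_config, master, 100 + i)
        s = generate_scan(cfg, "normal")
        imgs.append(s.image)
        lms.append(s.truth_labels)
    atlas = ShapeAtlas.build(imgs, lms)
    test_scan = generate_scan(_jitter_config(noiseless_config, master, 999),
                              "normal")
    return atlas, test_scan


@pytest.fixture(scope="session")
def small_cohort_features():
    """10-subject phantom cohort with per-scan features from truth labels."""
    from octdr.fusion import extract_layer_features

    scans, manifest = generate_cohort(PhantomConfig(seed=11), 10, 0.5, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feats = [
            extract_layer_features(
                s.image, s.truth_labels, scan_id=f"scan{i:03d}",
                subject_id=s.subject_id, class_label=s.class_label)
            for i, s in enumerate(scans)
        ]
    return scans, manifest, feats
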