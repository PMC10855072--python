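import numpy as np
import pytest

import imcpipe as ip

SMALL_TYPES = ["tumor", "stromal", "macrophage", "cd8_t"]


@pytest.fixture(scope="session")
def small_signatures():
    return ip.example_signatures(cell_types=SMALL_TYPES)


@pytest.fixture(scope="session")
def small_layout():
    return ip.LayoutSpec(mode="random", image_size=(300, 300),
                         n_cells={t: 30 for t in SMALL_TYPES})


@pytest.fixture(scope="session")
def small_cells(small_layout):
    return ip.place_cells(small_layout, seed=11)


@pytest.fixture(scope="session")
def clean_roi(small_cells, small_signatures, small_layout):
    """Noise-free rendered ROI: (image, ground-truth mask)."""
    return ip.render_roi(small_cells, small_signatures,
                         ip.NoiseSpec.noiseless(seed=11),
                         small_layout.image_size)


@pytest.fixture(scope="session")
def noisy_roi(small_cells, small_signatures, small_layout):
    """ROI with Poisson noise and planted hot pixels."""
    return ip.render_roi(small_cells, small_signatures, ip.NoiseSpec(seed=11),
                         small_layout.image_size)


@pytest.fixture(scope="session")
def small_panel(small_signatures):
    return ip.synthetic_panel(small_signatures)


@pytest.fixture(scope="session")
def segmented(clean_roi, small_cells, small_panel):
    """Full segmentation pass on the clean fixture: (probmaps, pred_mask)."""
    image, _ = clean_roi
    stack = ip.build_stack(image, small_panel, "segmentation")
    feats = ip.compute_pixel_features(stack.data)
    scribbles = ip.scribbles_from_ground_truth(small_cells, stack.shape)
    clf = ip.train_pixel_classifier(feats, scribbles, seed=5)
    probs = ip.predict_probability_maps(clf, feats)
    return probs, ip.segment_cells(probs)
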