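import numpy as np
import pytest

from tubequant import phantom, pipeline


@pytest.fixture(scope="session")
def noiseless_suite():
    """The deterministic noiseless validation phantoms."""
    return phantom.validation_suite(scale=1.0, seed=0, include_noisy=False)


@pytest.fixture(scope="session")
def tuned():
    return phantom.tuned_profile(scale=1.0)


@pytest.fixture(scope="session")
def suite_analyses(noiseless_suite, tuned):
    """Metrics for every noiseless phantom under the tuned profile."""
    out = []
    for e in noiseless_suite:
        m, masks = pipeline.analyze_arrays(e.image, tuned, source=e.name)
        out.append((e, m, masks))
    return out


def random_blob_masks(n, seed, min_size=40, max_size=120):
    """Randomized binary masks: thresholded smoothed noise (blobby shapes)."""
    from scipy import ndimage as ndi

    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(n):
        h, w = rng.integers(min_size, max_size, 2)
        img = ndi.gaussian_filter(rng.random((int(h), int(w))), sigma=rng.uniform(1, 4))
        masks.append(img > np.quantile(img, rng.uniform(0.5, 0.9)))
    return masks
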