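import numpy as np
import pytest

from benthoscope.aen import AENConfig, train_dbm
from benthoscope.image_store import ImageDataset, ImageRecord


def textured_image(rng, h=96, w=96, base=0.5, amp=0.05):
    """Small smooth textured background, float32 RGB in [0,1]."""
    from scipy.ndimage import gaussian_filter

    noise = gaussian_filter(rng.standard_normal((h, w)).astype(np.float32), 2.0)
    peak = np.abs(noise).max()
    if peak > 0:
        noise = noise / peak * amp
    img = np.clip(base + noise, 0, 1).astype(np.float32)
    return np.repeat(img[:, :, None], 3, axis=2)


def plant_disk(img, cx, cy, radius, value=1.0):
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    img[mask] = value
    return mask


@pytest.fixture(scope="session")
def tiny_cluster():
    """Three small textured background images held in memory."""
    rng = np.random.default_rng(42)
    pixels = {f"im{i}": textured_image(rng) for i in range(3)}
    records = [ImageRecord(id=k, path=f"<mem:{k}>", width=96, height=96,
                           cluster_id=0) for k in pixels]
    return records, pixels


@pytest.fixture(scope="session")
def tiny_dbm(tiny_cluster):
    """A quickly trained background model on the tiny cluster (15-px patches)."""
    records, pixels = tiny_cluster
    config = AENConfig(patch_edge=15, compression=0.1, epochs=15,
                       n_train_patches=600, minibatch=64, seed=3)
    return train_dbm(records, config, cluster_id=0, pixels_by_id=pixels)


@pytest.fixture(scope="session")
def tiny_cluster_pixels(tiny_cluster):
    return tiny_cluster[1]
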