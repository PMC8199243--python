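import numpy as np
import pytest

from lvprop.phantoms import PhantomSpec, make_phantom
from lvprop.pipeline import DictionaryProposalModel, RunConfig


def noiseless_training_phantoms(n=6, seed=0, image_size=(256, 256)):
    """Clean phantoms spanning a range of LV sizes, for dictionary training."""
    rng = np.random.default_rng(seed)
    h, w = image_size
    imgs, masks = [], []
    for _ in range(n):
        r = float(rng.uniform(12, 45))
        t = max(1.0, 0.33 * r)
        margin = r + t + 2
        spec = PhantomSpec(
            image_size=image_size,
            lv_center=(
                float(rng.uniform(margin, h - 1 - margin)),
                float(rng.uniform(margin, w - 1 - margin)),
            ),
            blood_pool_radius=r,
            myocardium_thickness=t,
            noise_sd=0.0,
            n_distractors=int(rng.integers(1, 4)),
            seed=int(rng.integers(0, 2**31)),
        )
        img, mask, _ = make_phantom(spec)
        imgs.append(img)
        masks.append(mask)
    return imgs, masks


@pytest.fixture(scope="session")
def trained_proposal_model():
    """Dictionary-path proposer fitted on clean phantoms (shared, ~15 s)."""
    imgs, masks = noiseless_training_phantoms(6, seed=0)
    cfg = RunConfig(dict_max_iter=10, seed=0)
    return DictionaryProposalModel(cfg).fit(imgs, masks)


@pytest.fixture()
def test_phantom():
    """A clean phantom with distractors, plus its ground truth."""
    spec = PhantomSpec(
        lv_center=(120.0, 140.0),
        blood_pool_radius=25.0,
        myocardium_thickness=9.0,
        noise_sd=0.0,
        n_distractors=2,
        seed=7,
    )
    img, mask, box = make_phantom(spec)
    return img, mask, box
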