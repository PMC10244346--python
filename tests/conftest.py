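import numpy as np
import pytest
from scipy import ndimage as ndi

from pscml.synthetic_data import SyntheticPlan, generate_well


@pytest.fixture(scope="session")
def plan() -> SyntheticPlan:
    return SyntheticPlan(seed=7)


@pytest.fixture(scope="session")
def well_triplet(plan):
    """One synthetic well at the optimal dose: (bright, fluor, mask)."""
    return generate_well(plan, 6.0, seed=1)


@pytest.fixture(scope="session")
def textured_image() -> np.ndarray:
    """A 128-px band-limited texture with enough contrast for detectors."""
    rng = np.random.default_rng(5)
    tex = ndi.gaussian_filter(rng.standard_normal((128, 128)), 1.2)
    tex = 0.5 + 0.15 * tex / tex.std()
    return np.clip(tex, 0, 1)


@pytest.fixture(scope="session")
def codebooks(plan):
    """Small SIFT-256 / ORB-64 codebooks fit on a disjoint image pool."""
    from pscml.features_local import fit_codebook

    pool = [generate_well(plan, 6.0, 1000 + i)[0] for i in range(8)]
    ids = tuple(f"pool-{i}" for i in range(8))
    sift = fit_codebook(pool, "sift", 256, seed=0, image_ids=ids)
    orb = fit_codebook(pool, "orb", 64, seed=0, image_ids=ids)
    return sift, orb
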