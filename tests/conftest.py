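import numpy as np
import pytest

from slidemil.bags import FeatureBag
from slidemil.synthetic import SynthBagConfig, generate_bags, generate_toy_slide


@pytest.fixture(scope="session")
def small_cohort():
    """30 small synthetic bags (dim 16) with the cohort's class imbalance."""
    cfg = SynthBagConfig(n_cases=30, dim=16, bag_size_range=(8, 20), seed=7)
    bags, truth = generate_bags(cfg)
    return bags, truth


@pytest.fixture(scope="session")
def toy_slide():
    """One toy stained slide (512 x 512) and its exact tissue mask."""
    return generate_toy_slide(512, 512, artifact_specks=0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_bag(rng, n=9, d=6, tier=1, case_id="b0") -> FeatureBag:
    coords = np.array([(256 * (j % 4), 256 * (j // 4)) for j in range(n)])
    return FeatureBag(
        case_id=case_id,
        features=rng.standard_normal((n, d)).astype(np.float32),
        coords=coords,
        tier=tier,
    )
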