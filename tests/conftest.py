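import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from hepaquant import TissueSpec, generate_tissue_image


@pytest.fixture(scope="session")
def clean_tissue():
    """Noise-free default tissue image with its full ground truth."""
    spec = TissueSpec(seed=11, noise_sd=0)
    image, truths, zone_truth, vessel_mask = generate_tissue_image(spec)
    return spec, image, truths, zone_truth, vessel_mask


@pytest.fixture(scope="session")
def noisy_tissue():
    """Default tissue image with the default additive noise."""
    spec = TissueSpec(seed=11)
    image, truths, zone_truth, vessel_mask = generate_tissue_image(spec)
    return spec, image, truths, zone_truth, vessel_mask
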