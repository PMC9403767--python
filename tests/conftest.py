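import numpy as np
import pytest

from hepaseg import (ArchitectureConfig, Lesion, PhantomSpec, build_hybrid_wnet,
                     generate_phantom)


@pytest.fixture(scope="session")
def small_phantom():
    """A compact phantom with three well-separated lesions (one with a rim)."""
    spec = PhantomSpec(
        volume_shape=(32, 96, 96),
        spacing=(2.5, 1.0, 1.0),
        liver_semiaxes_mm=(35.0, 40.0, 40.0),
        lesions=(
            Lesion((40.0, 30.0, 30.0), 18.0, rim_width_mm=2.0),
            Lesion((40.0, 66.0, 60.0), 12.0),
            Lesion((28.0, 48.0, 72.0), 8.0),
        ),
        noise_sd=10.0,
        rng_seed=7,
    )
    return generate_phantom(spec)


def tiny_hybrid_config(**overrides) -> ArchitectureConfig:
    """A scaled-down hybrid W-Net that runs in seconds on one CPU."""
    base = dict(
        style="hybrid_wnet",
        backbone_blocks=(2, 2),
        backbone_growth=4,
        backbone_init_filters=8,
        backbone_in_channels=3,
        decoder_channels=(16, 8, 8),
        feature_channels=8,
        filters_3d=4,
        blocks_3d=(2, 3),
    )
    base.update(overrides)
    return ArchitectureConfig(**base)


@pytest.fixture()
def tiny_hybrid():
    return build_hybrid_wnet(tiny_hybrid_config(), rng_seed=0)
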