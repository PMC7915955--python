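import numpy as np
import pytest

from adaptseg.phantom import (AnatomyConfig, StructureSpec, default_anatomy,
                              derive_adaptive, generate_subject)
from adaptseg.profiles import desk_anatomy


@pytest.fixture(scope="session")
def desk_subject():
    """One paired planning/adaptive phantom at the desk-scale grid."""
    subj = generate_subject(desk_anatomy(), seed=42)
    return derive_adaptive(subj, shrink_fraction={"glandular": 0.10},
                           deform_amplitude_mm=2.0, seed=43)


@pytest.fixture(scope="session")
def smoke_subject():
    subj = generate_subject(default_anatomy(6), seed=7)
    return derive_adaptive(subj, seed=8)


def single_ellipsoid_config(semiaxes_mm=(5.0, 5.0, 5.0), spacing=(1.0, 1.0, 1.0),
                            image_size=(32, 32, 32), hu=300.0, hu_sd=0.0,
                            noise_sd=0.0, group="glandular") -> AnatomyConfig:
    """A one-structure anatomy with deterministic size and center."""
    spec = StructureSpec(
        name="blob", shape="ellipsoid", group=group, mean_hu=hu, hu_sd=hu_sd,
        semiaxes_mm=tuple((s, s) for s in semiaxes_mm),
        center_frac=((0.5, 0.5), (0.5, 0.5), (0.5, 0.5)))
    return AnatomyConfig(structure_specs=[spec], image_size=image_size,
                         spacing_mm=spacing, noise_sd=noise_sd, min_gap_mm=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
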