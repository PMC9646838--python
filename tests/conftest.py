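import numpy as np
import pytest

from hipomap import experiments
from hipomap.cohort import SyntheticCohortSpec, TextureParams, generate_cohort
from hipomap.scoring import train_patch_model


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small clean-texture 32-px cohort for fast pipeline tests."""
    textures = TextureParams(confounder_fraction=0.0,
                             severity_range=(1.0, 1.0),
                             noise_multiplier_range=(1.0, 1.0))
    spec = SyntheticCohortSpec(n_slides_pos=10, n_slides_neg=10,
                               patches_per_slide_range=(6, 10),
                               lesion_fraction=0.4, patch_size=32,
                               texture_params=textures, seed=7)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_model(tiny_cohort):
    """Patch scorer trained on the tiny cohort."""
    _, slides = tiny_cohort
    xs = np.concatenate([s.patch_array() for s in slides])
    ys = [int(t) for s in slides for t in s.patch_truth]
    return train_patch_model(xs, ys, epochs=25, seed=11)


@pytest.fixture(scope="session")
def classification_run():
    """Full desk-scale classification experiment (shared across tests)."""
    return experiments.run_classification(1)


@pytest.fixture(scope="session")
def survival_run(classification_run):
    """Survival experiment reusing the classification patch scorer."""
    _, model = classification_run
    return experiments.run_survival(1, model)
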