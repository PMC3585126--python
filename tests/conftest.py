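import numpy as np
import pytest

from lipidscreen.params import Assay
from lipidscreen.pipeline import candidate_set
from lipidscreen.synth import (
    ControlSpec,
    EffectSpec,
    SceneSpec,
    make_plate_layout,
    render_images,
    simulate_cell_population,
    simulate_screen,
)


@pytest.fixture(scope="session")
def layout_384():
    return make_plate_layout("plate_384", candidate_set(100, 3), ControlSpec(), seed=11)


@pytest.fixture(scope="session")
def layout_96():
    return make_plate_layout("plate_96", candidate_set(15, 3), ControlSpec(mock=3), seed=7)


@pytest.fixture(scope="session")
def fc_scene():
    return SceneSpec(assay=Assay.FREE_CHOLESTEROL.value, seed=3)


@pytest.fixture(scope="session")
def noise_free_scene():
    return SceneSpec(
        assay=Assay.FREE_CHOLESTEROL.value, noise_sd_frac=0.0, poisson_noise=False, seed=3
    )


@pytest.fixture(scope="session")
def rendered_scene(noise_free_scene):
    """One noise-free rendered field with ground truth."""
    _, truth = simulate_cell_population(EffectSpec.null("s0"), noise_free_scene, geometry=True)
    image = render_images(truth, noise_free_scene)
    return image, truth


@pytest.fixture(scope="session")
def null_screen_fc(layout_96, fc_scene):
    """Small all-null screen (tables only), FC assay, 3 replicates."""
    return simulate_screen(layout_96, {}, 3, fc_scene, seed=21)


def planted_effects(n_true=10, sirnas_per_gene=3, shifts=None):
    shifts = shifts or {"fc_total": 0.3}
    effects = {}
    for g in range(1, n_true + 1):
        gene = f"G{g:03d}"
        for s in range(1, sirnas_per_gene + 1):
            sid = f"s{gene}_{s}"
            effects[sid] = EffectSpec(sid, dict(shifts))
    return effects


@pytest.fixture(scope="session")
def planted_screen_fc(layout_384, fc_scene):
    """384-position FC screen with ten planted effector genes (knockdown)."""
    effects = planted_effects(10)
    return simulate_screen(layout_384, effects, 3, fc_scene, seed=5), effects
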