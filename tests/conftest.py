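import numpy as np
import pandas as pd
import pytest

from springhab.field_sampling import (
    build_patches,
    draw_absences,
    draw_presences,
    extract_covariates,
)
from springhab.raster_core import GridSpec, RasterLayer
from springhab.reference import model1_reference, model2_reference
from springhab.synthetic_springbrook import (
    ChannelTemplate,
    build_scene,
    simulate_observations,
)


@pytest.fixture(scope="session")
def template():
    return ChannelTemplate(seed=1)


@pytest.fixture(scope="session")
def scene(template):
    return build_scene(template)


@pytest.fixture(scope="session")
def model1():
    return model1_reference()


@pytest.fixture(scope="session")
def model2():
    return model2_reference()


@pytest.fixture(scope="session")
def observations(scene, model2):
    return simulate_observations(scene, model2, n_fish=141, seed=3)


@pytest.fixture(scope="session")
def samples(scene, observations):
    """Full sampling chain: patches -> presences -> 309 absences -> covariates."""
    patches = build_patches(observations, buffer_radius=0.5)
    presences = draw_presences(patches, seed=4, scene=scene)
    absences = draw_absences(scene, patches, 309, seed=5, existing_points=presences)
    points = pd.concat([presences, absences], ignore_index=True)
    return extract_covariates(points, scene)


def make_layer(values, tag, cell_size=0.12, origin=(0.0, 0.0)):
    """Small helper: wrap a 2-D array as a layer on a fresh grid."""
    values = np.asarray(values, dtype=float)
    grid = GridSpec(origin_x=origin[0], origin_y=origin[1],
                    n_rows=values.shape[0], n_cols=values.shape[1],
                    cell_size=cell_size)
    return RasterLayer(grid, tag, values)
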