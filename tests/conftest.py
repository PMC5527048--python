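from types import SimpleNamespace

import numpy as np
import pytest

from marrowniche.spatial_metrics import (
    annotate_population,
    distance_map,
    summarize_population,
)
from marrowniche.synthetic_data import GeneratorConfig, synthesize_volume


@pytest.fixture(scope="session")
def paper_volume():
    """One synthetic marrow volume under the reference study conditions.

    Default generator config: 240 × 240 × 180 µm domain, 43 µm target vessel
    spacing, bone shell, 80 MKs with 20.36 ± 8.19 µm diameters placed with a
    0.7 vessel bias.  Shared (read-only) across tests that need a realistic
    scaffold; nothing may mutate the grid.
    """
    config = GeneratorConfig(seed=1)
    grid, network, objects = synthesize_volume(config)
    vessel_map = distance_map(grid.vessel_mask, grid.spacing)
    bone_map = distance_map(grid.bone_mask, grid.spacing)
    _, annotations = annotate_population(
        grid, objects, vessel_map=vessel_map, bone_map=bone_map
    )
    observed = summarize_population(annotations, objects)
    return SimpleNamespace(
        config=config,
        grid=grid,
        network=network,
        objects=objects,
        vessel_map=vessel_map,
        bone_map=bone_map,
        annotations=annotations,
        observed=observed,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
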