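import numpy as np
import pytest

from qbind import TOWER_TEMPLATE, generate_blockworld, learn_category_positions
from qbind.pipeline import child_seed
from qbind.scene_coding import CognitiveEntity, Scene, category_vector


@pytest.fixture(scope="session")
def tower_world():
    """The standard blockworld fixture: noisy scene, trained memory, and the
    noise-free learned category vector at the planted position."""
    world = generate_blockworld(seed=child_seed(1, "scene"))
    W, learned = learn_category_positions(TOWER_TEMPLATE, world.learned_positions)
    truth = category_vector(TOWER_TEMPLATE, *world.planted_position)
    return world, W, truth


def raw_scene(E) -> Scene:
    """A scene whose entities are arbitrary bit vectors (empty position bars);
    convenient for small exhaustive tests."""
    empty = np.zeros(0, dtype=np.uint8)
    ents = [CognitiveEntity(identity_field=np.asarray(row, dtype=np.uint8),
                            x_field=empty, y_field=empty)
            for row in np.atleast_2d(E)]
    return Scene(entities=ents, specs=None, canvas_shape=(0, 0))
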