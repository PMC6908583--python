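import numpy as np
import pytest

from edgegan.cgan import (
    ClassModel,
    DiscriminatorSpec,
    GeneratorSpec,
    TrainingConfig,
    train_class_model,
)
from edgegan.edges import EdgeParams
from edgegan.registry import ModelRegistry
from edgegan.synthetic import STROMALIKE, TUMORLIKE, generate_tiles

TINY_GSPEC = GeneratorSpec(depth=2, base_filters=8, dropout_rate=0.5)
TINY_DSPEC = DiscriminatorSpec(conv_stages=2, base_filters=8)
TINY_TCFG = TrainingConfig(epochs=2, batch_size=4, learning_rate=1e-3, seed=17)


class StubModel(ClassModel):
    """A ClassModel whose generator is an arbitrary pixel function; used to
    test classification logic independently of training."""

    def __init__(self, label: str, tile_size: int, fn):
        super().__init__(
            label=label,
            tile_size=tile_size,
            generator_spec=GeneratorSpec(),
            edge_params=EdgeParams(),
            training_config=TrainingConfig(),
            generator_weights=[np.asarray([hash(label) % 97], dtype=np.float32)],
        )
        self._fn = fn

    def reconstruct_batch(self, tiles_px):
        return np.stack([self._fn(t) for t in tiles_px])

    def reconstruct(self, tile):
        return self._fn(tile)


def make_stub_registry(tile_size: int, fns: dict) -> ModelRegistry:
    reg = ModelRegistry()
    for label, fn in fns.items():
        reg.add_class(StubModel(label, tile_size, fn))
    return reg


@pytest.fixture(scope="session")
def tiny_trained_registry():
    """Two small class models (32 px, 40 tiles, 4 epochs) for registry,
    classification and CLI tests that need real trained weights."""
    reg = ModelRegistry()
    for spec, seed in [(TUMORLIKE, 301), (STROMALIKE, 302)]:
        tiles = generate_tiles(spec, 40, 32)
        cfg = TrainingConfig(epochs=4, batch_size=4, learning_rate=1e-3, seed=seed)
        reg.add_class(train_class_model(tiles, EdgeParams(sigma=2.0),
                                        TINY_GSPEC, TINY_DSPEC, cfg))
    return reg
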