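import numpy as np
import pytest

from slenet.slenet_model import BlockSpec, ModelConfig, ScalingConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def mini_model_config(attention="seca", use_nonlocal=True, num_classes=4):
    """A 3-block, 32-pixel configuration for fast training tests."""
    blocks = [
        BlockSpec(3, 1, 8, 8, 1, attention),
        BlockSpec(3, 4, 8, 16, 2, attention),
        BlockSpec(5, 4, 16, 24, 2, attention),
    ]
    return ModelConfig(
        scaling=ScalingConfig(phi=0.0),
        attention=attention,
        use_nonlocal=use_nonlocal,
        num_classes=num_classes,
        dropout=0.0,
        input_size=32,
        blocks=blocks,
        head_channels=64,
    )


def blob_dataset(n_per_class=4, size=32, seed=0):
    """Tiny linearly separable image classes: class-dependent channel means."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    means = [(200, 60, 60), (60, 200, 60), (60, 60, 200), (160, 160, 60)]
    for label, mean in enumerate(means):
        for _ in range(n_per_class):
            img = rng.normal(mean, 25.0, size=(size, size, 3)).clip(0, 255)
            xs.append(img.transpose(2, 0, 1).astype(np.uint8))
            ys.append(label)
    x = np.stack(xs)
    y = np.array(ys, dtype=np.int64)
    order = rng.permutation(len(y))
    return x[order], y[order]
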