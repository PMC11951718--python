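import numpy as np
import pytest

from ssipaw import PipelineConfig, RoiPolygon, SceneSpec, process_frames
from ssipaw.scenes import iter_frames

# Small-frame scene used by most image tests: quarter-resolution geometry,
# an order of magnitude faster to render and segment than full HD.
SMALL = (960, 540)


@pytest.fixture
def small_spec():
    return SceneSpec.default(frame_size=SMALL, seed=123)


@pytest.fixture
def small_roi():
    return RoiPolygon.full_frame(*SMALL)


def run_scene(spec: SceneSpec, n_frames: int, config: PipelineConfig = PipelineConfig()):
    """Stream a synthetic scene through the full pipeline."""
    roi = RoiPolygon.full_frame(*spec.frame_size)
    frames = ((i, img) for i, img, _ in iter_frames(spec, n_frames))
    return process_frames(frames, roi, config)


def random_spread_pairs(rng: np.random.Generator, n: int):
    """Random physiologically-shaped SpreadPairs for property tests."""
    from ssipaw import SpreadPair

    pairs = []
    for _ in range(n):
        ts_c = rng.uniform(20.0, 150.0)
        ts_o = rng.uniform(10.0, 150.0)
        its_c = ts_c * rng.uniform(0.3, 0.9)
        its_o = ts_o * rng.uniform(0.3, 0.9)
        pairs.append(SpreadPair(ts_o=ts_o, ts_c=ts_c, its_o=its_o, its_c=its_c))
    return pairs
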