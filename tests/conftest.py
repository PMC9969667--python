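"""Shared fixtures: the pretrained reduced segmenter and evaluation videos.

Training runs once per session at the desk-scale study conditions
(3 synthetic videos x 200 frames, SGD lr 0.01, batch 8, up to 20 epochs)
and is reused by every test that needs a working model.
"""

import pytest

from apextrack.benchmarks import sample_reduced_specs, train_reduced_segmenter
from apextrack.synthetic_data import generate_video

SUITE_SEED = 1


@pytest.fixture(scope="session")
def train_specs():
    return sample_reduced_specs(SUITE_SEED, 3, n_frames=200)


@pytest.fixture(scope="session")
def pretrained(train_specs):
    """Segmenter trained at the benchmark's study conditions (slow: ~1-2 min)."""
    return train_reduced_segmenter(train_specs, SUITE_SEED)


@pytest.fixture(scope="session")
def eval_videos():
    """The two held-out evaluation videos of the scaled-down benchmark."""
    return [generate_video(s)
            for s in sample_reduced_specs(SUITE_SEED, 2, n_frames=200, group=1)]
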