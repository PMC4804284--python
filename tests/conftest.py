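import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import nucliq as nq


@pytest.fixture(scope="session")
def small_scene():
    """A compact noiseless-gain scene: fast, fully recoverable nuclei."""
    spec = nq.SceneSpec(
        height=160,
        width=160,
        n_target_nuclei=8,
        n_other_nuclei=16,
        noise_sigma=0.0,
        illumination_gain="none",
        seed=5,
    )
    return nq.generate_scene(spec, image_id="small")


@pytest.fixture(scope="session")
def small_corrected(small_scene):
    stack = nq.correct_illumination(small_scene.stack)
    nuclei = nq.segment_nuclei(stack)
    return stack, nuclei


def build_labels(scenes, nuclei_by_image, radius=15.0):
    """Truth labels by radius-matching planted target centers to nuclei."""
    labels = nq.LabelSet(labels={}, provenance={})
    for scene in scenes:
        dots = [t.center for t in scene.truth if t.is_target]
        part = nq.match_annotations(nuclei_by_image[scene.stack.image_id], dots, radius)
        labels.labels.update(part.labels)
        labels.provenance.update(part.provenance)
    return labels


def featurize_scenes(scenes, cfg=None):
    """Correct, segment and featurize a list of scenes.

    Returns (vectors, labels, nuclei_by_image, stacks_by_image).
    """
    cfg = cfg or nq.FeatureConfig()
    vectors, nuclei_by_image, stacks = [], {}, {}
    for scene in scenes:
        stack = nq.correct_illumination(scene.stack)
        nuclei = nq.segment_nuclei(stack)
        nuclei_by_image[stack.image_id] = nuclei
        stacks[stack.image_id] = stack
        vectors.extend(nq.featurize_image(stack, nuclei, cfg))
    labels = build_labels(scenes, nuclei_by_image)
    return vectors, labels, nuclei_by_image, stacks
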