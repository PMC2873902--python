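import numpy as np
import pytest

from bubblegaze import synth
from bubblegaze.stimulus import Bubble, Fixation, ScreenGeometry, Stimulus, Trial


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


def make_bubble(bubble_id, x, y, task="gender", image="img_000", cls="male", **kw):
    return Bubble(bubble_id, task, image, cls, x, y, **kw)


def make_trial(points, stimulus_id="s1", participant="p0", response="male"):
    """Trial from (x, y) points; an excluded order-0 fixation is prepended."""
    fixes = [Fixation(15.5, 11.9, 0)] + [
        Fixation(x, y, i + 1) for i, (x, y) in enumerate(points)
    ]
    return Trial(participant, stimulus_id, tuple(fixes), response)


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic study shared by read-only tests."""
    design = synth.ExperimentDesign(n_participants=10, trials_per_participant=60)
    return synth.make_world(
        task="gender", n_bubbles=30, n_stimuli=100, design=design, seed=42
    )


@pytest.fixture(scope="session")
def design_world():
    """A full-scale synthetic study (75 x 280 trials) shared by the
    acceptance checks that need the recorded study's scale."""
    return synth.make_world(task="gender", n_bubbles=94, n_stimuli=300, seed=7)
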