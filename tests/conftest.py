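"""Shared fixtures: phantom batches and trained desk-scale model bundles.

The expensive fixture is ``trained_bundle``: the scaled-down training
experiment (30 phantoms at 64 cubed, 24 for training / 6 held out) shared by
the end-to-end tests. ``tiny_bundle`` is a minimally-fitted pipeline for
contract-level tests that only need fitted (not accurate) networks.
"""

from __future__ import annotations

import numpy as np
import pytest

from angioseg import CascadePipeline, PhantomSpec, generate_phantom

N_TRAIN, N_HELD_OUT = 24, 6


@pytest.fixture(scope="session")
def phantoms4():
    """Four small phantoms for unit tests (deterministic seeds)."""
    return [generate_phantom(PhantomSpec(seed=s)) for s in range(4)]


@pytest.fixture(scope="session")
def tiny_bundle(phantoms4):
    """A pipeline fitted with very few steps: fitted state, not accuracy."""
    vols = [p[0] for p in phantoms4[:3]]
    labs = [p[1] for p in phantoms4[:3]]
    brs = [p[2] for p in phantoms4[:3]]
    pipe = CascadePipeline(steps_bone=8, refine_steps=5, steps_vessel=8,
                           steps_repair=8, random_state=0)
    return pipe.fit(vols, labs, brs)


@pytest.fixture(scope="session")
def study_phantoms():
    """The 30 phantoms (seeds 0-29) of the scaled-down training experiment."""
    return [generate_phantom(PhantomSpec(seed=s)) for s in range(30)]


@pytest.fixture(scope="session")
def trained_bundle(study_phantoms):
    """Desk-scale trained cascade: 24 training phantoms, 6 held out.

    Step counts follow the desk configuration (well under the 2,000-step
    budget); the optimizer is SGD with momentum 0.9, weight decay 1e-4, and
    lr 0.01 decaying by 0.99995 per step.
    """
    vols = [p[0] for p in study_phantoms[:N_TRAIN]]
    labs = [p[1] for p in study_phantoms[:N_TRAIN]]
    brs = [p[2] for p in study_phantoms[:N_TRAIN]]
    pipe = CascadePipeline(steps_bone=700, refine_steps=400, steps_vessel=500,
                           steps_repair=600, random_state=0)
    return pipe.fit(vols, labs, brs)


@pytest.fixture(scope="session")
def held_out(study_phantoms):
    return study_phantoms[N_TRAIN:]


def assert_volumes_equal(a, b):
    np.testing.assert_array_equal(a.data, b.data)
    assert a.spacing == b.spacing
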