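import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pose_recording():
    """A small simulated 13-point recording with inferred arena and kinematics."""
    from bflow import (BehaviorKernel, infer_arena, preprocess_recording,
                       simulate_labels, simulate_pose)
    from bflow.synth import CORNER_NAMES

    kernel = BehaviorKernel.uniform(3)
    seq = simulate_labels(kernel, n_frames=800, seed=7, recording_id="fix")
    rec = simulate_pose(seq, seed=7)
    rec.arena = infer_arena(rec, list(CORNER_NAMES), real_size_cm2=1600.0)
    return preprocess_recording(rec, exclude_points=CORNER_NAMES)


def random_label_sequence(rng, n=None, k=None, fps=25.0):
    from bflow.flow import LabelSequence

    n = n or int(rng.integers(2, 80))
    k = k or int(rng.integers(2, 8))
    return LabelSequence(recording_id="r", labels=rng.integers(0, k, n),
                         alphabet=np.arange(k), fps=fps)


def random_transition_matrices(rng, n_mats, nc=5, lam=4.0):
    from bflow.flow import TransitionMatrix

    out = []
    for i in range(n_mats):
        c = rng.poisson(lam, size=(nc, nc)).astype(np.int64)
        np.fill_diagonal(c, 0)
        out.append(TransitionMatrix(counts=c, alphabet=np.arange(nc),
                                    recording_id=f"m{i}"))
    return out
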