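import numpy as np
import pytest

from graspmvpa.design import build_design
from graspmvpa.preprocess import PatternSample

#: Reduced layout used by most unit tests: 3 participants, 4 runs of 16
#: trials (8 repetitions of each of the 8 settings), same trial timing.
SMALL_DESIGN_OVERRIDES = dict(n_participants=3, n_runs=4, repetitions_per_setting=8)


@pytest.fixture(scope="session")
def small_design():
    return build_design(**SMALL_DESIGN_OVERRIDES)


@pytest.fixture(scope="session")
def default_design():
    return build_design()


def make_gaussian_samples(rng, *, n_runs=4, per_run_per_class=2, n_features=10,
                          separation=0.0, pattern=None, condition="DG",
                          phase="action", roi="V1", participant=0,
                          label_sign=1):
    """Hand-built pattern samples: class means at +/- separation*pattern/2."""
    if pattern is None:
        pattern = np.zeros(n_features)
        pattern[0] = 1.0
    pattern = np.asarray(pattern, float)
    samples = []
    for run in range(n_runs):
        trial = 0
        for orient in (45, -45):
            for _ in range(per_run_per_class):
                sign = 1.0 if orient * label_sign > 0 else -1.0
                feats = rng.standard_normal(n_features) + sign * separation / 2.0 * pattern
                samples.append(PatternSample(feats, orient, condition, phase,
                                             run, trial, participant, roi))
                trial += 1
    return samples
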