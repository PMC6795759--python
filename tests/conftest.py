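import numpy as np
import pytest

import musclemorph as mm


@pytest.fixture(scope="session")
def small_cohort():
    """21-subject three-muscle synthetic cohort with ground truth (seed 7)."""
    stacks, truth = mm.make_cohort(mm.older_female_ts(n=21, seed=7))
    return stacks, truth


@pytest.fixture(scope="session")
def small_cohort_morphologies(small_cohort):
    stacks, truth = small_cohort
    return [mm.measure_morphology(s) for s in stacks], truth


@pytest.fixture
def unit_square_stack():
    """Two unit-square slices at z = 0 and 2 mm."""
    square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return mm.ContourStack(
        muscle_label="SOL",
        contours=[mm.Contour(z=0.0, vertices=square), mm.Contour(z=2.0, vertices=square)],
        slice_positions=np.array([0.0, 2.0]),
        shank_landmarks=(0.0, 360.0),
        subject_id="S1",
    )
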