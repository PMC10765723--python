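import numpy as np
import pytest

from hrvthresh import SyntheticSpec, gen_exercise_rri
from hrvthresh.series import RRISeries


@pytest.fixture(scope="session")
def exercise_series():
    """One artifact-free synthetic incremental test (shared, read-only)."""
    return gen_exercise_rri(SyntheticSpec(seed=101))


@pytest.fixture(scope="session")
def exercise_series_with_artifacts():
    series, info = gen_exercise_rri(
        SyntheticSpec(seed=202, artifact_rates=(0.0025, 0.0025)), return_info=True
    )
    return series, info


@pytest.fixture()
def constant_series():
    return RRISeries.from_intervals(np.full(50, 700.0))
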