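import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_trace():
    """The seven-sample hand-worked calcium trace."""
    from neuroassay.calcium import FluorescenceTrace
    return FluorescenceTrace(np.array([0, 0, 1, 3, 1, 0, 0], dtype=float),
                             dt=1.0, background_subtracted=True)


@pytest.fixture
def tiny_params():
    """Small-but-complete cohort parameters for fast end-to-end tests."""
    from neuroassay.synth import SynthParams
    return SynthParams(seed=7, n_case_lines=2, n_control_lines=2,
                       wells_per_group=3, replicates=2, n_electrodes=8,
                       mea_duration_s=2.0, ca_duration_s=120.0,
                       ca_rois_per_field=3, mea_rate_control=5.0,
                       silent_fraction=0.25)
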