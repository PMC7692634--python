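import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from itcdimer import BindingParameters, TitrationProtocol


@pytest.fixture
def bench_params():
    """The two-event parameter set used as ground truth throughout."""
    return BindingParameters(kd1=2.9e-6, kd2=61.5e-6, dh1=-8000.0, dh2=8000.0, q_dil=0.0)


@pytest.fixture
def bench_protocol():
    """250 µM ligand, 56 x 8 µL into 1.4 mL of 20 µM receptor, 25 C."""
    return TitrationProtocol.vp_itc_default()
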