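import numpy as np
import pytest

from microscaff import ExtrusionParams, PrintSettings, ScaffoldSpec
from microscaff.validation import PrinterProfile


@pytest.fixture
def ref_spec():
    """Reference rectilinear scaffold: L=20, d1=1.0, d2=2.5, h=0.2, 4 layers."""
    return ScaffoldSpec()


@pytest.fixture
def ref_params():
    return ExtrusionParams()


@pytest.fixture
def ref_settings():
    return PrintSettings()


@pytest.fixture
def ref_profile():
    return PrinterProfile()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
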