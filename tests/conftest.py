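import math

import pytest
from hypothesis import HealthCheck, settings

from triscore import CorrelationModel, ReferencePanel, SiteReference

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def identity_model() -> CorrelationModel:
    return CorrelationModel.equicorrelation(0.0)


@pytest.fixture
def equicorr06() -> CorrelationModel:
    return CorrelationModel.equicorrelation(0.6)


@pytest.fixture
def real_corr_model() -> CorrelationModel:
    return CorrelationModel(0.6558, 0.6145, 0.7508)


@pytest.fixture
def panel(real_corr_model) -> ReferencePanel:
    # arbitrary but realistic young-adult reference panel (g/cm^2)
    return ReferencePanel(
        refs=(
            SiteReference("L1L4", mean_bmd=1.18, sd_bmd=0.12),
            SiteReference("femoral_neck", mean_bmd=0.94, sd_bmd=0.12, sample_size=409),
            SiteReference("total_hip", mean_bmd=0.98, sd_bmd=0.12, sample_size=math.inf),
        ),
        correlation=real_corr_model,
    )
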