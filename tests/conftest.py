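import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def toy_recording():
    """Tiny two-channel pressure recording with DCS and markers."""
    from autoregkit.recording_io import Channel, EventMarker, RawRecording

    fs = 100.0
    t = np.arange(0, 30.0, 1.0 / fs)
    abp = 100 + 15 * np.sin(2 * np.pi * 2.0 * t)
    icp = 8 + 1.0 * np.sin(2 * np.pi * 2.0 * t)
    t_dcs = np.arange(0.0, 30.0, 1.0)
    alpha = 1e-8 * (1 + 0.01 * np.sin(0.1 * t_dcs))
    beta = np.full_like(t_dcs, 0.5)
    return RawRecording(
        subject_id="toy",
        group="fentanyl",
        channels={
            "abp": Channel(t, abp, "mmHg"),
            "icp": Channel(t, icp, "mmHg"),
            "alpha_db": Channel(t_dcs, alpha, "cm^2/s"),
            "beta": Channel(t_dcs, beta, ""),
        },
        markers=[EventMarker(0.0, 10.0, "baseline", 0.0, 6.0)],
        vitals=np.array([[0.0, 120.0, 38.0], [30.0, 121.0, 38.5]]),
        anesthesia_log=np.array([[0.0, 0.8, 15.0]]),
    )


@pytest.fixture(scope="session")
def short_intact_recording():
    """A fast baseline-only intact-CA simulation shared across tests."""
    from autoregkit import synthetic_data as sd

    proto = sd.OscillationProtocol(
        icp_baselines=(6,), include_icp_osc=False, include_abp_osc=False
    )
    return sd.simulate_subject("fentanyl", 7, proto, {"duration_per_baseline": 900.0})
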