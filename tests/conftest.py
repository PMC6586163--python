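import pytest

from rootprobe import ProbeSystem, RootGeometry, TransportParams


@pytest.fixture
def control_params() -> TransportParams:
    """Control-condition transport triple of a barley seminal root."""
    return TransportParams(Lpr=8.11e-8, Psr=2.24e-9, sigma=0.38)


@pytest.fixture
def probe() -> ProbeSystem:
    """Probe constants giving t½w ≈ 5 s at the control Lpr."""
    return ProbeSystem(beta=1.09e10, Ar=1.57e-4)


@pytest.fixture
def geometry() -> RootGeometry:
    """0.1 m conductive length, 0.5 mm diameter, 1.5 % functional xylem."""
    return RootGeometry(
        conductive_length=0.10,
        root_diameter=5.0e-4,
        endodermis_radius=2.0e-4,
        xylem_fraction=0.015,
    )
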