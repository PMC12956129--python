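import pytest

from solvex import DeviceConfig, VirtualDevice, builtin_pi_routines


@pytest.fixture(scope="session")
def pi_store():
    return builtin_pi_routines()


@pytest.fixture()
def config():
    return DeviceConfig()


@pytest.fixture()
def make_device():
    """Factory for virtual devices with enough stock for full protocols."""

    def _make(**kwargs):
        kwargs.setdefault("initial_stock_volume", 4000.0)
        return VirtualDevice(**kwargs)

    return _make
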