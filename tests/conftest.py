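import pytest

from odormix import load_preset, load_registry
from odormix.simulate import PanelSimConfig


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def aldehyde_family(registry):
    return load_preset("aldehydes", registry)


@pytest.fixture(scope="session")
def ester_family(registry):
    return load_preset("esters", registry)


def noiseless_panel_config(registry, family="aldehydes", **overrides):
    """Panel config with all stochastic/quantization effects off."""
    params = {
        "aldehydes": dict(k=5.6, b=-5.6, slope=0.62, lnoav_range=(1.0, 3.5)),
        "esters": dict(k=1.4, b=-2.7, slope=0.79, lnoav_range=(2.0, 4.5)),
    }[family]
    members = tuple(
        od for od in registry.family(family)
        if od.abbreviation in ("A", "P", "B", "EA", "BA", "EB")
    )
    base = dict(
        odorants=members,
        assessor_sd=0.0,
        n_assessors=1,
        oirs_resolution=0.0,
        seed=0,
        **params,
    )
    base.update(overrides)
    return PanelSimConfig(**base)


@pytest.fixture(scope="session")
def aldehyde_noiseless_config(registry):
    return noiseless_panel_config(registry, "aldehydes")


@pytest.fixture(scope="session")
def ester_noiseless_config(registry):
    return noiseless_panel_config(registry, "esters")
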