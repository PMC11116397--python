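"""Shared fixtures: small rendered scenes at known effective resolution."""

import warnings

import numpy as np
import pytest

from mitograph.imaging import (
    AcquisitionSettings,
    depletion_power_for_fwhm,
    simulate_acquisition,
)
from mitograph.scene import (
    NucleoidPlacement,
    SceneParams,
    generate_network,
    render_density,
    sample_nucleoids,
)

HBMITO_IS_MW = 0.864  # printed saturation power of the inner-membrane probe


@pytest.fixture(autouse=True)
def _quiet_geometry_warnings():
    # under-sampling / truncation warnings are exercised explicitly in the
    # tests that target them
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def sted_settings(fwhm_nm: float = 40.0, photon_budget: float = 1000.0,
                  **kw) -> AcquisitionSettings:
    """High-SNR STED settings with the PSF sharpened to ``fwhm_nm``."""
    return AcquisitionSettings(
        I_dep_mW=depletion_power_for_fwhm(fwhm_nm, 250.0, HBMITO_IS_MW),
        photon_budget=photon_budget, background=2.0, read_noise_std=1.0, **kw
    )


def confocal_settings(photon_budget: float = 1000.0) -> AcquisitionSettings:
    return AcquisitionSettings(
        I_dep_mW=0.0, photon_budget=photon_budget, background=2.0,
        read_noise_std=1.0,
    )


def acquire_scene(scene, channel: str, settings: AcquisitionSettings, seed: int):
    density = render_density(scene, channel, settings.pixel_size_nm)
    return simulate_acquisition(density, settings, HBMITO_IS_MW, seed)


@pytest.fixture(scope="session")
def network_scene():
    """A mid-size network scene with nucleoids, shared across read-only tests."""
    params = SceneParams(field_size_um=(15.0, 15.0), n_components=3)
    scene = generate_network(params, seed=3)
    return sample_nucleoids(
        scene, NucleoidPlacement(interior_per_um=0.3), seed=4
    )
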