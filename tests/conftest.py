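"""Shared fixtures.

Heavy Monte-Carlo products (the six-model multispectral stacks) are
session-scoped so the acceptance tests and the oximetry tests share one set
of simulations. Photon budgets are desk-scale choices documented in the
methods note.
"""
import numpy as np
import pytest

from paoxsim import adding_doubling as ad
from paoxsim import monte_carlo as mc
from paoxsim import scenes
from paoxsim import spectra as sp

# desk-scale problem sizes for the shared simulation fixtures
MC_EXTENT = (12.0, 12.0, 7.2)
MC_SPACING = 0.06
N_PHOT_MULTI = 100_000      # per wavelength, six-model multispectral stacks
SEED = 1


@pytest.fixture(scope="session")
def nir_grid():
    return sp.nir_grid()


@pytest.fixture(scope="session")
def six_model_reflectance():
    """Adding-doubling reflectance spectra of the six layer-only models."""
    out = {}
    for f in scenes.melanosome_series():
        out[round(f, 6)] = ad.reflectance_spectrum(
            scenes.build_layer_model(f), sp.colorimetry_grid())
    return out


@pytest.fixture(scope="session")
def clinical_source():
    return mc.SourceGeometry(kind="clinical_fiber")


@pytest.fixture(scope="session")
def vessel_scenes(nir_grid):
    """Voxelized fully-oxygenated vessel models for all six skin types."""
    return {
        round(f, 6): scenes.voxelize(
            scenes.build_vessel_model(f, 1.0, extent_mm=MC_EXTENT),
            MC_SPACING, nir_grid)
        for f in scenes.melanosome_series()
    }


@pytest.fixture(scope="session")
def six_model_stacks(vessel_scenes, clinical_source):
    """Multispectral p0 stacks for the six vessel models (shared budget)."""
    out = {}
    for i, (f, scene) in enumerate(sorted(vessel_scenes.items())):
        out[f] = mc.multispectral_p0(scene, clinical_source, N_PHOT_MULTI,
                                     SEED + 7919 * i)
    return out


@pytest.fixture(scope="session")
def decoloring_model():
    """Learned-decoloring regressor trained on a reduced simulated corpus."""
    from paoxsim import oximetry as ox

    ts = ox.build_training_set(n_volumes=12, seed=11, n_photons=10_000)
    return ox.train_decoloring(ts, seed=0)
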