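"""Shared fixtures: schemes, phantoms and (expensive) inverted ensembles.

Inversions are session-scoped so the end-to-end fixtures are computed
once and shared between module tests and the acceptance suite.
"""

import numpy as np
import pytest

import fibert1 as f


@pytest.fixture(scope="session")
def scheme():
    """Default 363-point tensor-valued diffusion-T1 scheme."""
    return f.make_scheme()


@pytest.fixture(scope="session")
def single_fiber_voxel():
    """One stick-like fiber along x: D_par=2, D_perp=0.2, R1=0.5."""
    return f.make_crossing_phantom(90.0, (0.5, 1.0), weights=(1.0, 0.0))


@pytest.fixture(scope="session")
def single_fiber_solution(scheme, single_fiber_voxel):
    """Noise-free single-fiber inversion with the default settings."""
    signal = f.simulate_measurement(single_fiber_voxel, scheme)
    return f.quasi_genetic_fit(
        signal, scheme, f.InversionConfig(), np.random.default_rng(101)
    )


@pytest.fixture(scope="session")
def crossing_voxel():
    """90-degree crossing with R1 = 0.5 and 1.0 /s, equal weights."""
    return f.make_crossing_phantom(90.0, (0.5, 1.0))


@pytest.fixture(scope="session")
def crossing_ensemble(scheme, crossing_voxel):
    """Noise-free crossing-fiber bootstrap ensemble (20 bootstraps)."""
    signal = f.simulate_measurement(crossing_voxel, scheme)
    config = f.InversionConfig(n_bootstrap=20)
    return f.bootstrap_invert(signal, scheme, config,
                              rng=np.random.default_rng(202))


@pytest.fixture(scope="session")
def tissue_ensembles(scheme):
    """Noise-free inversions of archetypal WM, GM and CSF voxels."""
    config = f.InversionConfig(n_bootstrap=12)
    out = {}
    for i, kind in enumerate(("wm", "gm", "csf")):
        voxel = f.make_tissue_voxel(kind)
        signal = f.simulate_measurement(voxel, scheme)
        out[kind] = f.bootstrap_invert(
            signal, scheme, config, rng=np.random.default_rng(300 + i)
        )
    return out


@pytest.fixture(scope="session")
def crossing_snr40_ensembles(scheme, crossing_voxel):
    """Crossing-fiber voxels at SNR=40 with the full 96-bootstrap
    ensemble (5 independent noise realizations)."""
    noise = f.NoiseModel("rician", 40.0)
    config = f.InversionConfig(n_bootstrap=96)
    rng = np.random.default_rng(404)
    ensembles = []
    for _ in range(5):
        signal = f.simulate_measurement(crossing_voxel, scheme, noise, rng)
        ensembles.append(
            f.bootstrap_invert(signal, scheme, config, rng=rng.spawn(1)[0])
        )
    return ensembles
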