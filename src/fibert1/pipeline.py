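"""Volume-level orchestration of the per-voxel inversion.

Voxels are embarrassingly parallel; each voxel's random stream is
derived from the master seed and the voxel index, so results are
bit-identical regardless of the number of workers.
"""

from __future__ import annotations

import numpy as np
from joblib import Parallel, delayed

from .mc_inversion import InversionConfig, bootstrap_invert

__all__ = ["voxel_rng", "invert_volume"]


def voxel_rng(seed: int, voxel) -> np.random.Generator:
    """Per-voxel generator derived from the master seed + voxel index."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, voxel)]))


def invert_volume(
    data: np.ndarray,
    mask: np.ndarray,
    scheme,
    config: InversionConfig,
    seed: int = 0,
    n_workers: int = 1,
    resample: bool = True,
) -> dict:
    """Bootstrap-invert every masked voxel of a 4D volume.

    Returns ``{(i, j, k): VoxelEnsemble}``.
    """
    voxels = [tuple(idx) for idx in np.argwhere(mask)]

    def run(voxel):
        signal = data[voxel]
        return voxel, bootstrap_invert(
            signal, scheme, config, rng=voxel_rng(seed, voxel),
            resample=resample,
        )

    if n_workers == 1:
        results = [run(v) for v in voxels]
    else:
        results = Parallel(n_jobs=n_workers)(delayed(run)(v) for v in voxels)
    return dict(results)
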