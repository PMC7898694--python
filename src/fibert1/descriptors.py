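"""Statistical descriptors of P(D, R1) and tissue-targeting bins.

Each bootstrap solution yields weight-normalized means, variances and
covariances of the scalar observables Diso, DDelta^2 and R1; the
voxel-level descriptor is the median of these per-bootstrap statistics
across the bootstrap ensemble.  Components can first be restricted to
rectangular bins of (Diso, D_par/D_perp, R1) space that target white
matter ("thin": elongated tensors), gray matter ("thick": low
anisotropy) and CSF ("big": fast isotropic diffusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mc_inversion import BootstrapSolution, VoxelEnsemble
from .tensor_model import ComponentSet

__all__ = [
    "BinDefinition",
    "THIN_BIN",
    "THICK_BIN",
    "BIG_BIN",
    "DEFAULT_BINS",
    "CHI_NAMES",
    "classify_bin",
    "filter_bin",
    "per_bootstrap_stats",
    "median_descriptors",
    "map_over_volume",
]

CHI_NAMES = ("d_iso", "d_delta2", "r1")


@dataclass(frozen=True)
class BinDefinition:
    """Closed rectangular region of (Diso, D_par/D_perp, R1) space."""

    name: str
    d_iso_range: tuple
    ratio_range: tuple
    r1_range: tuple

    def __post_init__(self):
        for rng in (self.d_iso_range, self.ratio_range, self.r1_range):
            if not rng[0] < rng[1]:
                raise ValueError("bin ranges must have lower < upper")


THIN_BIN = BinDefinition("thin", (0.1, 2.0), (4.0, 1000.0), (0.01, 10.0))
THICK_BIN = BinDefinition("thick", (0.1, 2.0), (0.01, 4.0), (0.01, 10.0))
BIG_BIN = BinDefinition("big", (2.0, 10.0), (0.01, 1000.0), (0.01, 10.0))
DEFAULT_BINS = (THIN_BIN, THICK_BIN, BIG_BIN)


def classify_bin(components, bin_def: BinDefinition) -> np.ndarray:
    """Boolean mask: which components fall inside the (closed) bin."""
    if not isinstance(components, ComponentSet):
        components = ComponentSet.from_components(
            components if np.iterable(components) else [components]
        )
    d_iso, ratio, r1 = components.d_iso, components.ratio, components.r1
    inside = (
        (d_iso >= bin_def.d_iso_range[0]) & (d_iso <= bin_def.d_iso_range[1])
        & (ratio >= bin_def.ratio_range[0]) & (ratio <= bin_def.ratio_range[1])
        & (r1 >= bin_def.r1_range[0]) & (r1 <= bin_def.r1_range[1])
    )
    return inside


def filter_bin(components: ComponentSet, bin_def) -> ComponentSet:
    """Components restricted to a bin (``None`` means no restriction)."""
    if bin_def is None:
        return components
    return components[classify_bin(components, bin_def)]


def _chi_matrix(components: ComponentSet) -> np.ndarray:
    return np.stack(
        [components.d_iso, components.d_delta ** 2, components.r1], axis=0
    )


def per_bootstrap_stats(solution: BootstrapSolution, bin_def=None) -> dict | None:
    """Weighted E/V/C statistics of one bootstrap solution.

    Returns a dict with keys ``e[chi]``, ``v[chi]``, ``c[chi,chi']`` for
    chi in (d_iso, d_delta2, r1), the bin weight fraction ``f``, the
    total weight ``s0`` and the weighted mean tensor diagonal
    ``e_dxx/e_dyy/e_dzz``; or ``None`` when no component falls in the
    bin (the statistic is then undefined for this bootstrap).
    """
    comps = solution.components
    total_w = float(np.sum(comps.w))
    sub = filter_bin(comps, bin_def)
    wsum = float(np.sum(sub.w))
    if len(sub) == 0 or wsum <= 0:
        return None

    w = sub.w / wsum
    chi = _chi_matrix(sub)  # (3, N)
    e = chi @ w
    centered = chi - e[:, None]
    cov = (centered * w) @ centered.T  # weighted central second moments

    diag = np.einsum("nii,n->i", sub.tensors, w)
    out = {}
    for i, name in enumerate(CHI_NAMES):
        out[f"e[{name}]"] = float(e[i])
        out[f"v[{name}]"] = float(cov[i, i])
    for i, a in enumerate(CHI_NAMES):
        for j, b in enumerate(CHI_NAMES):
            if i < j:
                out[f"c[{a},{b}]"] = float(cov[i, j])
    out["f"] = wsum / total_w if total_w > 0 else 0.0
    out["s0"] = total_w
    out["e_dxx"], out["e_dyy"], out["e_dzz"] = (float(d) for d in diag)
    return out


def median_descriptors(ensemble: VoxelEnsemble, bins=DEFAULT_BINS) -> dict:
    """Median across bootstraps of the per-bootstrap statistics.

    Returns ``{scope: {stat: value}}`` for scope in ``global`` plus one
    entry per bin.  Medians are taken element-wise over the bootstraps
    in which the statistic is defined; the bin fraction ``f`` is instead
    the average across bootstraps (with empty bootstraps contributing
    f = 0), matching how bin-specific map intensity is rendered.
    """
    scopes = {"global": None}
    scopes.update({b.name: b for b in bins})

    out = {}
    for scope, bin_def in scopes.items():
        rows = [
            per_bootstrap_stats(sol, bin_def)
            for sol in ensemble
            if not sol.is_empty
        ]
        fractions = [0.0 if r is None else r["f"] for r in rows]
        rows = [r for r in rows if r is not None]
        if not rows:
            out[scope] = {"f": 0.0}
            continue
        keys = rows[0].keys()
        med = {k: float(np.median([r[k] for r in rows])) for k in keys}
        med["f"] = float(np.mean(fractions)) if fractions else 0.0
        out[scope] = med
    return out


def map_over_volume(ensembles: dict, shape, bins=DEFAULT_BINS) -> dict:
    """Descriptor maps over a voxel grid.

    Parameters
    ----------
    ensembles : dict
        Mapping ``(i, j, k) -> VoxelEnsemble`` for the masked voxels.
    shape : tuple
        Spatial shape of the output volumes.
    bins : sequence of BinDefinition

    Returns a dict of volumes: one scalar volume per
    ``{scope}/{statistic}`` (NaN outside the mask), a segmentation RGB
    volume ``segmentation_rgb`` with channels proportional to the bin
    weight fractions, and per-bin orientation RGB volumes
    ``{bin}/orientation_rgb`` built from the mean-tensor diagonal.
    """
    scope_names = ["global"] + [b.name for b in bins]
    stat_keys = None
    maps = {}

    voxel_desc = {idx: median_descriptors(ens, bins) for idx, ens in ensembles.items()}
    for desc in voxel_desc.values():
        for scope in scope_names:
            if scope in desc and len(desc[scope]) > 1:
                stat_keys = {s: list(desc[s].keys()) for s in scope_names if s in desc}
                break
        if stat_keys:
            break
    if stat_keys is None:
        stat_keys = {s: ["f"] for s in scope_names}

    for scope in scope_names:
        for key in stat_keys.get(scope, ["f"]):
            maps[f"{scope}/{key}"] = np.full(shape, np.nan)

    for idx, desc in voxel_desc.items():
        for scope in scope_names:
            for key, val in desc.get(scope, {}).items():
                name = f"{scope}/{key}"
                if name not in maps:
                    maps[name] = np.full(shape, np.nan)
                maps[name][idx] = val

    # segmentation RGB: [f_thin, f_thick, f_big] / max
    seg = np.full(shape + (3,), np.nan)
    for idx, desc in voxel_desc.items():
        f = np.array([desc.get(b.name, {}).get("f", 0.0) for b in bins[:3]])
        peak = f.max()
        seg[idx] = f / peak if peak > 0 else 0.0
    maps["segmentation_rgb"] = seg

    # per-bin orientation RGB: [E[Dxx], E[Dyy], E[Dzz]] / max, scaled by f
    for b in bins:
        vol = np.full(shape + (3,), np.nan)
        for idx, desc in voxel_desc.items():
            d = desc.get(b.name, {})
            if "e_dxx" in d:
                diag = np.array([d["e_dxx"], d["e_dyy"], d["e_dzz"]])
                peak = diag.max()
                vol[idx] = (diag / peak if peak > 0 else 0.0) * d.get("f", 0.0)
            else:
                vol[idx] = 0.0
        maps[f"{b.name}/orientation_rgb"] = vol
    return maps
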