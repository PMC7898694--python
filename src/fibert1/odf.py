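"""Orientation distribution functions on a geodesic spherical mesh.

Thin-bin (highly anisotropic) components of each bootstrap solution are
smeared onto the nodes of an icosahedral mesh with an antipodally
symmetric Watson-type kernel exp(kappa * (u.n)^2).  Node radii are the
median across bootstraps of the deposited weight; in addition each node
carries kernel-weighted means of Diso, DDelta^2 and R1, so ODF lobes can
be colored by orientation-resolved diffusion-relaxation properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .descriptors import THIN_BIN, filter_bin
from .mc_inversion import VoxelEnsemble

__all__ = ["SphericalMesh", "ODF", "build_mesh", "map_components",
           "extract_peaks", "kappa_for_fwhm"]

CHI_NAMES = ("d_iso", "d_delta2", "r1")


@dataclass
class SphericalMesh:
    """Geodesic icosphere: unit node directions plus triangulation."""

    vertices: np.ndarray  # (N, 3) unit vectors
    faces: np.ndarray  # (F, 3) vertex indices
    subdivisions: int

    @property
    def n_nodes(self) -> int:
        return len(self.vertices)

    @property
    def adjacency(self) -> list:
        """Neighbor index lists derived from the triangulation."""
        if not hasattr(self, "_adjacency"):
            neighbors = [set() for _ in range(self.n_nodes)]
            for a, b, c in self.faces:
                neighbors[a].update((b, c))
                neighbors[b].update((a, c))
                neighbors[c].update((a, b))
            self._adjacency = [sorted(s) for s in neighbors]
        return self._adjacency

    @property
    def edge_length_deg(self) -> float:
        """Typical angular spacing between adjacent nodes (degrees)."""
        a = self.faces[:, 0]
        b = self.faces[:, 1]
        dots = np.abs(np.sum(self.vertices[a] * self.vertices[b], axis=1))
        return float(np.degrees(np.arccos(np.clip(dots, -1, 1))).mean())


@dataclass
class ODF:
    """Per-voxel orientation distribution function on a mesh.

    ``radii`` are medians across bootstraps of the weight deposited on
    each node; ``e_hat[chi]`` are the corresponding medians of the
    per-bootstrap kernel-weighted means, defined (non-NaN) only on
    nodes with positive radius.
    """

    mesh: SphericalMesh
    radii: np.ndarray  # (N,)
    e_hat: dict = field(default_factory=dict)  # chi -> (N,) medians
    per_bootstrap_radii: np.ndarray | None = None  # (Nb, N)


def build_mesh(subdivisions: int = 4) -> SphericalMesh:
    """Geodesic subdivision of the icosahedron; 10 * 4**s + 2 nodes."""
    if subdivisions < 1:
        raise ValueError("need subdivisions >= 1")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    vertices = np.asarray(ico.vertices, dtype=float)
    vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    return SphericalMesh(vertices, np.asarray(ico.faces), subdivisions)


def kappa_for_fwhm(fwhm_deg: float) -> float:
    """Watson concentration giving the requested kernel FWHM."""
    half = np.deg2rad(fwhm_deg / 2.0)
    return float(np.log(2.0) / np.sin(half) ** 2)


# FWHM ~ 12 degrees: comparable to the mesh spacing at subdivisions=4
DEFAULT_KAPPA = kappa_for_fwhm(12.0)


def map_components(
    ensemble: VoxelEnsemble,
    mesh: SphericalMesh,
    kappa: float = DEFAULT_KAPPA,
    bin_def=THIN_BIN,
) -> ODF:
    """Map thin-bin components of every bootstrap onto the mesh.

    Per bootstrap, each component deposits its weight on the nodes
    through the normalized kernel exp(kappa * ((u.n)^2 - 1)); the kernel
    is normalized over nodes so the total deposited weight equals the
    bootstrap's total thin-bin weight.  Radii and E-hat values are
    medians across bootstraps (E-hat only over bootstraps supporting
    the node).
    """
    n_nodes = mesh.n_nodes
    radii_nb = []
    ehat_nb = {chi: [] for chi in CHI_NAMES}

    for sol in ensemble:
        comps = filter_bin(sol.components, bin_def)
        if len(comps) == 0 or np.sum(comps.w) <= 0:
            radii_nb.append(np.zeros(n_nodes))
            for chi in CHI_NAMES:
                ehat_nb[chi].append(np.full(n_nodes, np.nan))
            continue
        cos2 = (mesh.vertices @ comps.orientations.T) ** 2  # (N, K)
        kernel = np.exp(kappa * (cos2 - 1.0))
        kernel /= kernel.sum(axis=0, keepdims=True)  # normalize over nodes
        deposited = kernel * comps.w[None, :]  # (N, K)
        node_w = deposited.sum(axis=1)
        radii_nb.append(node_w)
        chi_vals = {
            "d_iso": comps.d_iso,
            "d_delta2": comps.d_delta ** 2,
            "r1": comps.r1,
        }
        with np.errstate(invalid="ignore", divide="ignore"):
            for chi, vals in chi_vals.items():
                num = deposited @ vals
                e = np.where(node_w > 0, num / np.where(node_w > 0, node_w, 1.0),
                             np.nan)
                ehat_nb[chi].append(e)

    radii_nb = np.asarray(radii_nb)
    radii = np.median(radii_nb, axis=0)
    e_hat = {}
    for chi in CHI_NAMES:
        stack = np.asarray(ehat_nb[chi])
        med = np.full(stack.shape[1], np.nan)
        defined = ~np.all(np.isnan(stack), axis=0)
        if np.any(defined):
            med[defined] = np.nanmedian(stack[:, defined], axis=0)
        med[radii <= 0] = np.nan
        e_hat[chi] = med
    return ODF(mesh, radii, e_hat, per_bootstrap_radii=radii_nb)


def extract_peaks(odf: ODF, min_relative_radius: float = 0.05,
                  merge_angle_deg: float = 15.0):
    """Local ODF maxima over the mesh adjacency graph.

    Returns a list of ``(direction, radius)`` sorted by decreasing
    radius.  Maxima are deduplicated antipodally and within
    ``merge_angle_deg`` of a stronger peak (plateau ties on a symmetric
    lobe otherwise yield spurious duplicates).  Nodes below
    ``min_relative_radius`` times the maximum radius are ignored; a flat
    (all-zero) ODF yields an empty list.
    """
    radii = odf.radii
    peak_max = radii.max() if len(radii) else 0.0
    if peak_max <= 0:
        return []
    floor = min_relative_radius * peak_max
    adjacency = odf.mesh.adjacency
    candidates = []
    for i in range(odf.mesh.n_nodes):
        if radii[i] < floor:
            continue
        if all(radii[i] >= radii[j] for j in adjacency[i]):
            candidates.append(i)

    candidates.sort(key=lambda i: -radii[i])
    peaks = []
    for i in candidates:
        u = odf.mesh.vertices[i]
        if any(
            np.abs(u @ v) > np.cos(np.deg2rad(merge_angle_deg)) for v, _ in peaks
        ):  # antipode or near-duplicate of a stronger peak
            continue
        peaks.append((u, float(radii[i])))
    return peaks
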