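"""Synthetic acquisition schemes and ground-truth phantoms.

The default scheme mirrors a 363-point tensor-valued diffusion-T1
protocol: per repetition time (1, 2 and 5 s) one b=0 reference, a few
spherically encoded b-values, and linear and planar shells up to
b = 2 ms/um^2 with repulsion-distributed directions, 121 points per
repetition-time block, at a constant echo time of 120 ms.

Phantoms are voxel-level component sets: crossing stick-like fibers
with distinct R1 values, optionally mixed with gray-matter-like and
CSF-like isotropic pools.  Noise is Rician by default (magnitude MRI),
with the noise level tied to the signal-to-noise ratio of the
spherically encoded signal at b = 0.1 ms/um^2 and the longest
repetition time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tensor_model import (
    AcquisitionScheme,
    ComponentSet,
    cartesian_to_spherical,
    predict_signal,
)

__all__ = [
    "NoiseModel",
    "PhantomVoxel",
    "repulsion_directions",
    "make_scheme",
    "make_crossing_phantom",
    "make_tissue_voxel",
    "simulate_measurement",
    "angular_deviation",
]

# typical white-matter stick diffusivities (um^2/ms)
FIBER_D_PAR = 2.0
FIBER_D_PERP = 0.2
# isotropic pool archetypes: (d_iso um^2/ms, r1 1/s)
GM_POOL = (0.8, 0.6)
CSF_POOL = (3.0, 0.25)
WM_R1 = 0.8


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: 'rician' (magnitude MRI), 'gaussian' or 'none'."""

    kind: str = "rician"
    snr: float = 40.0

    def __post_init__(self):
        if self.kind not in ("rician", "gaussian", "none"):
            raise ValueError("noise kind must be rician, gaussian or none")
        if self.kind != "none" and not self.snr > 0:
            raise ValueError("SNR must be positive")


NO_NOISE = NoiseModel("none", np.inf)


@dataclass
class PhantomVoxel:
    """Ground truth for one voxel: a component set with weights summing
    to the nominal S0."""

    components: ComponentSet
    name: str = "voxel"

    @property
    def s0(self) -> float:
        return float(np.sum(self.components.w))

    @property
    def fiber_orientations(self) -> np.ndarray:
        """Orientations of the anisotropic (ratio > 4) components."""
        aniso = self.components.ratio > 4.0
        return self.components.orientations[aniso]


def repulsion_directions(n: int, n_iter: int = 200, step: float = 0.05) -> np.ndarray:
    """Quasi-uniform antipodally symmetric unit directions.

    A deterministic Fibonacci-hemisphere start refined by electrostatic
    repulsion between all +/- pairs; adequate for shell direction sets
    of a few dozen points.
    """
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    i = np.arange(n)
    z = (i + 0.5) / n  # upper hemisphere
    phi = 2.0 * np.pi * i / golden
    st = np.sqrt(1.0 - z ** 2)
    pts = np.stack([st * np.cos(phi), st * np.sin(phi), z], axis=1)

    for _ in range(n_iter):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]
            d2 = np.sum(diff ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            force += np.sum(diff / (d2 ** 1.5)[..., None], axis=1)
        # project the force onto the tangent plane and step
        force -= np.sum(force * pts, axis=1, keepdims=True) * pts
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        pts = pts + step * force / norm
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= np.where(pts[:, 2] < 0, -1.0, 1.0)[:, None]
    return pts


# per-repetition-time shell layout totaling 121 points
_DEFAULT_LINEAR = {0.5: 12, 1.0: 21, 2.0: 25}
_DEFAULT_PLANAR = {0.5: 12, 1.0: 21, 2.0: 25}
_DEFAULT_SPHERICAL = (0.1, 0.5, 1.0, 2.0)


def make_scheme(
    linear_shells: dict | None = None,
    planar_shells: dict | None = None,
    spherical_b: tuple = _DEFAULT_SPHERICAL,
    tr_values: tuple = (1.0, 2.0, 5.0),
    te: float = 0.120,
    b_zero: bool = True,
) -> AcquisitionScheme:
    """Tensor-valued diffusion-T1 scheme; defaults give 363 points.

    ``linear_shells`` / ``planar_shells`` map b-value (ms/um^2) to the
    number of repulsion-distributed directions on that shell;
    spherically encoded shells need one entry per b-value only (the
    signal is orientation-independent).  The full block is repeated for
    every repetition time.
    """
    linear_shells = _DEFAULT_LINEAR if linear_shells is None else linear_shells
    planar_shells = _DEFAULT_PLANAR if planar_shells is None else planar_shells

    b_list, bd_list, th_list, ph_list = [], [], [], []
    if b_zero:
        b_list.append(0.0)
        bd_list.append(0.0)
        th_list.append(0.0)
        ph_list.append(0.0)
    for b in spherical_b:
        b_list.append(b)
        bd_list.append(0.0)
        th_list.append(0.0)
        ph_list.append(0.0)
    for shells, b_delta in ((linear_shells, 1.0), (planar_shells, -0.5)):
        for b, n_dir in sorted(shells.items()):
            dirs = repulsion_directions(n_dir)
            theta, phi = cartesian_to_spherical(dirs)
            b_list.extend([b] * n_dir)
            bd_list.extend([b_delta] * n_dir)
            th_list.extend(theta)
            ph_list.extend(phi)

    block = len(b_list)
    b = np.tile(b_list, len(tr_values))
    b_delta = np.tile(bd_list, len(tr_values))
    theta = np.tile(th_list, len(tr_values))
    phi = np.tile(ph_list, len(tr_values))
    tr = np.repeat(tr_values, block)
    return AcquisitionScheme(b, b_delta, theta, phi, tr, te)


def make_crossing_phantom(
    angle_deg: float = 90.0,
    r1_pair: tuple = (0.5, 1.0),
    weights: tuple = (0.5, 0.5),
    d_par: float = FIBER_D_PAR,
    d_perp: float = FIBER_D_PERP,
    gm_fraction: float = 0.0,
    csf_fraction: float = 0.0,
    s0: float = 1.0,
) -> PhantomVoxel:
    """Two stick-like fiber populations crossing at ``angle_deg``.

    The first fiber lies along x; the second is rotated by the crossing
    angle in the x-y plane.  Optional isotropic pools emulate partial
    voluming with gray matter and CSF; fiber weights are rescaled so all
    weights sum to ``s0``.
    """
    if not 0.0 < angle_deg <= 90.0:
        raise ValueError("crossing angle must lie in (0, 90] degrees")
    fiber_total = 1.0 - gm_fraction - csf_fraction
    if fiber_total < 0:
        raise ValueError("pool fractions exceed 1")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum() * fiber_total * s0 if w.sum() > 0 else w

    dirs = [
        np.array([1.0, 0.0, 0.0]),
        np.array(
            [np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg)), 0.0]
        ),
    ]
    d_pars, d_perps, thetas, phis, r1s, ws = [], [], [], [], [], []
    for direction, r1, wi in zip(dirs, r1_pair, w):
        if wi <= 0:
            continue
        theta, phi = cartesian_to_spherical(direction)
        d_pars.append(d_par)
        d_perps.append(d_perp)
        thetas.append(float(theta))
        phis.append(float(phi))
        r1s.append(r1)
        ws.append(wi)
    for fraction, (pool_diso, pool_r1) in (
        (gm_fraction, GM_POOL), (csf_fraction, CSF_POOL),
    ):
        if fraction > 0:
            d_pars.append(pool_diso)
            d_perps.append(pool_diso)
            thetas.append(0.0)
            phis.append(0.0)
            r1s.append(pool_r1)
            ws.append(fraction * s0)
    comps = ComponentSet(d_pars, d_perps, thetas, phis, r1s, ws)
    return PhantomVoxel(comps, name=f"crossing_{angle_deg:g}deg")


def make_tissue_voxel(kind: str, s0: float = 1.0) -> PhantomVoxel:
    """Archetypal single-tissue voxels with R1 ordered WM > GM > CSF."""
    if kind == "wm":
        theta, phi = cartesian_to_spherical(np.array([1.0, 0.0, 0.0]))
        comps = ComponentSet(
            [FIBER_D_PAR], [FIBER_D_PERP], [float(theta)], [float(phi)],
            [WM_R1], [s0],
        )
    elif kind == "gm":
        comps = ComponentSet([GM_POOL[0]], [GM_POOL[0]], [0.0], [0.0],
                             [GM_POOL[1]], [s0])
    elif kind == "csf":
        comps = ComponentSet([CSF_POOL[0]], [CSF_POOL[0]], [0.0], [0.0],
                             [CSF_POOL[1]], [s0])
    else:
        raise ValueError("kind must be wm, gm or csf")
    return PhantomVoxel(comps, name=kind)


def _noise_sigma(voxel: PhantomVoxel, scheme: AcquisitionScheme,
                 snr: float) -> float:
    """Noise SD from the SNR convention: reference signal is the mean
    noise-free spherically encoded signal at b = 0.1 ms/um^2 and the
    longest repetition time."""
    clean = predict_signal(scheme, voxel.components)
    ref = (
        np.isclose(scheme.b, 0.1)
        & np.isclose(scheme.b_delta, 0.0)
        & np.isclose(scheme.tr, scheme.tr.max())
    )
    if np.any(ref):
        s_ref = float(np.mean(clean[ref]))
    else:
        warnings.warn(
            "scheme has no spherical b=0.1 point at the longest repetition "
            "time; falling back to sigma = S0/SNR",
            stacklevel=2,
        )
        s_ref = voxel.s0
    return s_ref / snr


def simulate_measurement(
    voxel: PhantomVoxel, scheme: AcquisitionScheme,
    noise: NoiseModel = NO_NOISE, rng=None,
) -> np.ndarray:
    """Forward-simulate a voxel's signal, optionally with noise.

    Rician noise forms the magnitude of a complex Gaussian perturbation,
    sqrt((S + e1)^2 + e2^2); Gaussian noise adds e1 only.
    """
    clean = predict_signal(scheme, voxel.components)
    if noise.kind == "none":
        return clean
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sigma = _noise_sigma(voxel, scheme, noise.snr)
    e1 = rng.normal(0.0, sigma, len(clean))
    if noise.kind == "gaussian":
        return clean + e1
    e2 = rng.normal(0.0, sigma, len(clean))
    return np.sqrt((clean + e1) ** 2 + e2 ** 2)


def angular_deviation(estimated, truth_orientations) -> float:
    """Shortest antipodal angle (degrees) from an estimated direction to
    any ground-truth fiber orientation."""
    truth = np.atleast_2d(np.asarray(truth_orientations, dtype=float))
    if truth.size == 0:
        raise ValueError("truth orientation set is empty")
    u = np.asarray(estimated, dtype=float)
    u = u / np.linalg.norm(u)
    truth = truth / np.linalg.norm(truth, axis=1, keepdims=True)
    dots = np.abs(truth @ u)
    return float(np.degrees(np.arccos(np.clip(dots.max(), 0.0, 1.0))))
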