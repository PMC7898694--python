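"""Axisymmetric tensor algebra and the diffusion-T1 forward signal model.

The signal model describes a saturation-recovery spoiled spin-echo
acquisition with tensor-valued diffusion encoding.  Each measurement is
characterized by an axisymmetric b-tensor (size ``b``, normalized
anisotropy ``b_delta``, orientation) together with a repetition time
``tr`` and a constant echo time ``te``.  A voxel is modelled as a
discrete set of diffusion-relaxation components, each an axisymmetric
diffusion tensor (axial/radial diffusivities, orientation) with a
longitudinal relaxation rate R1 and a non-negative signal weight.

Units are fixed package-wide: diffusivities in um^2/ms, b-values in
ms/um^2 (so that b:D is dimensionless), times in seconds and R1 in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiffusionComponent",
    "ComponentSet",
    "AcquisitionPoint",
    "AcquisitionScheme",
    "spherical_to_cartesian",
    "make_axisymmetric_tensor",
    "frobenius_inner",
    "axisymmetric_inner",
    "t1_recovery_factor",
    "design_matrix",
    "predict_signal",
]


def spherical_to_cartesian(theta, phi):
    """Unit vector(s) from polar angle ``theta`` and azimuth ``phi`` (rad)."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    return np.stack(
        [st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1
    )


def cartesian_to_spherical(u):
    """(theta, phi) of unit vector(s), with the antipodal representative
    chosen so that cos(theta) >= 0."""
    u = np.asarray(u, dtype=float)
    flip = np.where(u[..., 2] < 0, -1.0, 1.0)
    u = u * flip[..., None]
    theta = np.arccos(np.clip(u[..., 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(u[..., 1], u[..., 0]), 2.0 * np.pi)
    return theta, phi


@dataclass(frozen=True)
class DiffusionComponent:
    """One candidate micro-environment of the voxel-level distribution.

    Parameters
    ----------
    d_par : float
        Axial diffusivity D_par (um^2/ms), > 0.
    d_perp : float
        Radial diffusivity D_perp (um^2/ms), > 0.
    theta, phi : float
        Polar angle and azimuth (rad) of the tensor symmetry axis; the
        antipodal representative with cos(theta) >= 0 is conventional.
    r1 : float
        Longitudinal relaxation rate (1/s), > 0.
    weight : float
        Non-negative signal weight (same units as S0).
    """

    d_par: float
    d_perp: float
    theta: float
    phi: float
    r1: float
    weight: float = 0.0

    def __post_init__(self):
        if self.d_par <= 0 or self.d_perp <= 0:
            raise ValueError("diffusivities must be positive")
        if self.r1 <= 0:
            raise ValueError("R1 must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")

    @property
    def d_iso(self) -> float:
        """Isotropic diffusivity (D_par + 2 D_perp) / 3."""
        return (self.d_par + 2.0 * self.d_perp) / 3.0

    @property
    def d_delta(self) -> float:
        """Normalized anisotropy (D_par - D_perp)/(D_par + 2 D_perp) in [-0.5, 1]."""
        return (self.d_par - self.d_perp) / (self.d_par + 2.0 * self.d_perp)

    @property
    def t1(self) -> float:
        """Longitudinal relaxation time 1/R1 (s)."""
        return 1.0 / self.r1

    @property
    def orientation(self) -> np.ndarray:
        return spherical_to_cartesian(self.theta, self.phi)

    @property
    def tensor(self) -> np.ndarray:
        """Full symmetric 3x3 diffusion tensor."""
        return make_axisymmetric_tensor(
            3.0 * self.d_iso, self.d_delta, self.orientation
        )


class ComponentSet:
    """A weighted set of diffusion-relaxation components, stored columnwise.

    The columnar layout (one numpy array per parameter) is what the
    inversion machinery operates on; :class:`DiffusionComponent` is the
    scalar view at the API boundary.
    """

    _FIELDS = ("d_par", "d_perp", "theta", "phi", "r1", "w")

    def __init__(self, d_par, d_perp, theta, phi, r1, w=None):
        self.d_par = np.atleast_1d(np.asarray(d_par, dtype=float))
        self.d_perp = np.atleast_1d(np.asarray(d_perp, dtype=float))
        self.theta = np.atleast_1d(np.asarray(theta, dtype=float))
        self.phi = np.atleast_1d(np.asarray(phi, dtype=float))
        self.r1 = np.atleast_1d(np.asarray(r1, dtype=float))
        if w is None:
            w = np.zeros_like(self.d_par)
        self.w = np.atleast_1d(np.asarray(w, dtype=float))
        n = len(self.d_par)
        for name in self._FIELDS:
            if len(getattr(self, name)) != n:
                raise ValueError("all component columns must share one length")

    # -- construction -------------------------------------------------
    @classmethod
    def from_components(cls, components) -> "ComponentSet":
        comps = list(components)
        if not comps:
            return cls.empty()
        return cls(
            [c.d_par for c in comps],
            [c.d_perp for c in comps],
            [c.theta for c in comps],
            [c.phi for c in comps],
            [c.r1 for c in comps],
            [c.weight for c in comps],
        )

    @classmethod
    def empty(cls) -> "ComponentSet":
        z = np.empty(0)
        return cls(z, z, z, z, z, z)

    def to_components(self):
        return [
            DiffusionComponent(
                self.d_par[i], self.d_perp[i], self.theta[i],
                self.phi[i], self.r1[i], self.w[i],
            )
            for i in range(len(self))
        ]

    # -- container protocol -------------------------------------------
    def __len__(self) -> int:
        return len(self.d_par)

    def __getitem__(self, index) -> "ComponentSet":
        if np.isscalar(index) or isinstance(index, (int, np.integer)):
            index = [index]
        return ComponentSet(*[getattr(self, f)[index] for f in self._FIELDS])

    def concat(self, other: "ComponentSet") -> "ComponentSet":
        return ComponentSet(
            *[
                np.concatenate([getattr(self, f), getattr(other, f)])
                for f in self._FIELDS
            ]
        )

    def copy(self) -> "ComponentSet":
        return ComponentSet(*[getattr(self, f).copy() for f in self._FIELDS])

    # -- derived quantities -------------------------------------------
    @property
    def d_iso(self) -> np.ndarray:
        return (self.d_par + 2.0 * self.d_perp) / 3.0

    @property
    def d_delta(self) -> np.ndarray:
        return (self.d_par - self.d_perp) / (self.d_par + 2.0 * self.d_perp)

    @property
    def t1(self) -> np.ndarray:
        return 1.0 / self.r1

    @property
    def ratio(self) -> np.ndarray:
        """Axial-to-radial diffusivity ratio D_par / D_perp."""
        return self.d_par / self.d_perp

    @property
    def orientations(self) -> np.ndarray:
        """(N, 3) unit vectors of the symmetry axes."""
        return spherical_to_cartesian(self.theta, self.phi)

    @property
    def tensors(self) -> np.ndarray:
        """(N, 3, 3) full diffusion tensors."""
        u = self.orientations
        eye = np.eye(3)
        return (
            self.d_perp[:, None, None] * eye
            + (self.d_par - self.d_perp)[:, None, None]
            * np.einsum("ni,nj->nij", u, u)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f: getattr(self, f) for f in self._FIELDS})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ComponentSet":
        return cls(*[df[f].to_numpy(dtype=float) for f in cls._FIELDS])


@dataclass(frozen=True)
class AcquisitionPoint:
    """One measurement: an axisymmetric b-tensor plus timing parameters.

    ``b`` in ms/um^2, ``b_delta`` in [-0.5, 1], orientation angles in
    rad, ``tr`` (repetition time) and ``te`` (echo time) in seconds.
    """

    b: float
    b_delta: float
    theta: float
    phi: float
    tr: float
    te: float

    def __post_init__(self):
        if self.b < 0:
            raise ValueError("b must be non-negative")
        if not -0.5 <= self.b_delta <= 1.0:
            raise ValueError("b_delta must lie in [-0.5, 1]")
        if not self.tr > self.te / 2.0 > 0:
            raise ValueError("need tr > te/2 > 0")

    @property
    def b_tensor(self) -> np.ndarray:
        return make_axisymmetric_tensor(
            self.b, self.b_delta, spherical_to_cartesian(self.theta, self.phi)
        )


class AcquisitionScheme:
    """Ordered collection of measurements with a shared echo time."""

    def __init__(self, b, b_delta, theta, phi, tr, te):
        self.b = np.atleast_1d(np.asarray(b, dtype=float))
        self.b_delta = np.atleast_1d(np.asarray(b_delta, dtype=float))
        self.theta = np.atleast_1d(np.asarray(theta, dtype=float))
        self.phi = np.atleast_1d(np.asarray(phi, dtype=float))
        self.tr = np.atleast_1d(np.asarray(tr, dtype=float))
        te = np.asarray(te, dtype=float)
        if te.ndim == 0:
            te = np.full_like(self.b, float(te))
        self.te = np.atleast_1d(te)
        n = len(self.b)
        if n == 0:
            raise ValueError("acquisition scheme must be non-empty")
        for arr in (self.b_delta, self.theta, self.phi, self.tr, self.te):
            if len(arr) != n:
                raise ValueError("all scheme columns must share one length")
        if np.any(self.b < 0):
            raise ValueError("b must be non-negative")
        if np.any(self.b_delta < -0.5) or np.any(self.b_delta > 1.0):
            raise ValueError("b_delta must lie in [-0.5, 1]")
        if not np.all(self.tr > self.te / 2.0):
            raise ValueError("need tr > te/2 for every measurement")
        if not np.allclose(self.te, self.te[0]):
            raise ValueError("the sequence uses one constant echo time")

    def __len__(self) -> int:
        return len(self.b)

    def __getitem__(self, index):
        if np.isscalar(index) or isinstance(index, (int, np.integer)):
            return AcquisitionPoint(
                self.b[index], self.b_delta[index], self.theta[index],
                self.phi[index], self.tr[index], self.te[index],
            )
        return AcquisitionScheme(
            self.b[index], self.b_delta[index], self.theta[index],
            self.phi[index], self.tr[index], self.te[index],
        )

    @property
    def echo_time(self) -> float:
        return float(self.te[0])

    @property
    def orientations(self) -> np.ndarray:
        return spherical_to_cartesian(self.theta, self.phi)

    @classmethod
    def from_points(cls, points) -> "AcquisitionScheme":
        pts = list(points)
        return cls(
            [p.b for p in pts], [p.b_delta for p in pts],
            [p.theta for p in pts], [p.phi for p in pts],
            [p.tr for p in pts], [p.te for p in pts],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "b": self.b, "b_delta": self.b_delta, "theta": self.theta,
                "phi": self.phi, "tr": self.tr, "te": self.te,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AcquisitionScheme":
        return cls(
            df["b"].to_numpy(), df["b_delta"].to_numpy(),
            df["theta"].to_numpy(), df["phi"].to_numpy(),
            df["tr"].to_numpy(), df["te"].to_numpy(),
        )

    def resample(self, indices) -> "AcquisitionScheme":
        """Scheme restricted to (possibly repeated) measurement indices."""
        return self[np.asarray(indices, dtype=int)]


def make_axisymmetric_tensor(size, shape, orientation) -> np.ndarray:
    """Symmetric 3x3 tensor with trace ``size``, anisotropy ``shape`` and
    symmetry axis ``orientation``.

    Eigenvalues are (size/3)(1 + 2*shape) along the axis and
    (size/3)(1 - shape), twice, transverse to it.
    """
    size = float(size)
    shape = float(shape)
    if size < 0:
        raise ValueError("tensor size (trace) must be non-negative")
    if not -0.5 <= shape <= 1.0:
        raise ValueError("tensor shape must lie in [-0.5, 1]")
    u = np.asarray(orientation, dtype=float)
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        raise ValueError("orientation vector is degenerate (zero norm)")
    u = u / norm
    radial = (size / 3.0) * (1.0 - shape)
    return radial * np.eye(3) + size * shape * np.outer(u, u)


def frobenius_inner(bt, dt) -> float:
    """Frobenius inner product sum_ij bt_ij * dt_ij of two symmetric tensors."""
    bt = np.asarray(bt, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if bt.shape != (3, 3) or dt.shape != (3, 3):
        raise ValueError("expected 3x3 tensors")
    return float(np.sum(bt * dt))


def axisymmetric_inner(b, b_delta, d_iso, d_delta, cos_beta):
    """Closed-form b:D for axisymmetric pairs.

    b:D = b * Diso * (1 + 2 * b_delta * d_delta * P2(cos beta)) with beta
    the angle between the two symmetry axes and P2 the second Legendre
    polynomial.
    """
    p2 = 0.5 * (3.0 * np.asarray(cos_beta) ** 2 - 1.0)
    return b * d_iso * (1.0 + 2.0 * b_delta * d_delta * p2)


def t1_recovery_factor(te, tr, r1):
    """Longitudinal recovery factor of the saturation-recovery spin echo.

    ``1 - 2*exp((te/2 - tr)*r1) + exp(-tr*r1)``; tends to 1 as tr -> inf
    (full recovery) and to 0 as r1 -> 0+ (fully saturated).
    """
    te = np.asarray(te, dtype=float)
    tr = np.asarray(tr, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    if np.any(r1 <= 0):
        raise ValueError("R1 must be positive")
    if np.any(tr <= te / 2.0):
        raise ValueError("need tr > te/2")
    return 1.0 - 2.0 * np.exp((te / 2.0 - tr) * r1) + np.exp(-tr * r1)


def design_matrix(scheme: AcquisitionScheme, components: ComponentSet) -> np.ndarray:
    """Kernel matrix K with K[m, n] = exp(-b_m : D_n) * recovery(m, n).

    The signal is the matrix-vector product ``K @ w``.
    """
    if not isinstance(components, ComponentSet):
        components = ComponentSet.from_components(components)
    if len(components) == 0:
        return np.zeros((len(scheme), 0))
    cos_beta = scheme.orientations @ components.orientations.T  # (M, N)
    bd = axisymmetric_inner(
        scheme.b[:, None], scheme.b_delta[:, None],
        components.d_iso[None, :], components.d_delta[None, :], cos_beta,
    )
    recovery = t1_recovery_factor(
        scheme.te[:, None], scheme.tr[:, None], components.r1[None, :]
    )
    return np.exp(-bd) * recovery


def predict_signal(scheme: AcquisitionScheme, components) -> np.ndarray:
    """Forward signal S_m = sum_n w_n exp(-b_m:D_n) * recovery factor.

    An empty component set yields the all-zero signal.
    """
    if not isinstance(components, ComponentSet):
        components = ComponentSet.from_components(components)
    if len(components) == 0:
        return np.zeros(len(scheme))
    return design_matrix(scheme, components) @ components.w
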